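# Synthetic stand-in for a curated pharmacogenomics knowledge-base
# snapshot (constructed for tests and demos; not real curated content).
# chem <TAB> mesh_id <TAB> kb_chemical_id
# assoc <TAB> kb_chemical_ids(';') <TAB> variant key
# star <TAB> normalized star allele <TAB> rsid
chem	MESH:D014859	PA451906
chem	MESH:D000077144	PA449053
chem	MESH:D000068598	PA448004
chem	MESH:D003061	PA449088
chem	MESH:D019821	PA451363
assoc	PA451906	rs9923231
assoc	PA449053	rs4244285
assoc	PA449053	CYP2C19*2
assoc	PA448004	HLA-B*57:01
assoc	PA451363;PA449088	rs4149056
assoc	PA451906	rs1057868
star	POR*28	rs1057868
star	CYP2C19*2	rs4244285
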