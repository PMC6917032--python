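# mesh_id	preferred_name	categories (';'-separated)
MESH:D014859	warfarin	Anticoagulants
MESH:D000077144	clopidogrel	Platelet Aggregation Inhibitors
MESH:D019821	simvastatin	Hydroxymethylglutaryl-CoA Reductase Inhibitors
MESH:D003061	codeine	Analgesics, Opioid
MESH:D000068598	abacavir	Anti-HIV Agents
MESH:D002220	carbamazepine	Anticonvulsants
MESH:D000077304	telmisartan	Angiotensin II Receptor Antagonists
MESH:D001379	azathioprine	Immunosuppressive Agents
MESH:D008687	metformin	Hypoglycemic Agents
MESH:D009853	omeprazole	Proton Pump Inhibitors
MESH:D000068679	efavirenz	Anti-HIV Agents
MESH:D016898	interferon alpha	Antineoplastic Agents, Immunological
MESH:D016899	interferon beta	Immunologic Factors
MESH:D013629	tamoxifen	Antineoplastic Agents, Hormonal
MESH:D000069347	erlotinib	Antineoplastic Agents
MESH:D000077156	gefitinib	Antineoplastic Agents
MESH:D000077146	irinotecan	Antineoplastic Agents
MESH:D000255	ATP	Nucleotides
MESH:D005978	glutathione	Amino Acids and Peptides
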