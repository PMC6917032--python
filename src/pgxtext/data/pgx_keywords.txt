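# Pharmacogenomics keyword gate: one term per line, whole-word and
# case-insensitive; a trailing '*' marks a prefix stem.
response
resistance
metaboli*
efficacy
toxicity
adverse
dose
dosing
dosage
pharmacogen*
genotype
allele*
polymorphism*
clearance
concentration
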