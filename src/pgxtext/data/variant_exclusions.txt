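# Terms that look like variants but are not (mostly cell-line names).
T47D
HEK293
MCF7
A549
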