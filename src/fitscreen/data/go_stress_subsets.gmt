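GO:0042026	Protein refolding	HSP104	HSP78	SSE2
GO:0065002	Intracellular protein transmembrane transport	HSP78	SSA4	SSA3
GO:0007010	Cytoskeleton organization	CDC48	HSP42
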