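gene	residue	position	process
P0001	T	10	carcinogenesis
P0002	Y	10	cell cycle regulation
P0003	S	10	apoptosis
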