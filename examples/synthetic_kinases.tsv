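kinase	substrate_gene	residue	position	evidence	source
P0001	CAV1	Y	14	validated	synthetic_ksr_db
P0002	CAV1	Y	14	predicted	synthetic_prediction
P0021	CAV1	Y	14	predicted	synthetic_prediction
P0003	CAV1	S	37	predicted	synthetic_prediction
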