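simulate = sim.cfg
protein = CAV1
out = demo_out
kinases = synthetic_kinases.tsv
ppi = synthetic_ppi.tsv
processes = synthetic_processes.tsv
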