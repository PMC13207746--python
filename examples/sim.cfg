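# canonical synthetic study corpus: 5 studies x 12 conditions,
# CAV1_Y14 / CAV1_S37 predominant, 20 planted partner sites, 200 null sites
preset = default_study
seed = 1
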