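partner	source_db
P0003	synthdb_A
P0003	synthdb_B
P0004	synthdb_A
P0022	synthdb_A
P0022	synthdb_B
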