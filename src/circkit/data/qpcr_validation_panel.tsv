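circ_id	read_count	delta_ct
hsa_circ_0000284	210	18.23
hsa_circ_0000615	67	19.14
hsa_circ_0001727	61	19.33
hsa_circ_0008285	54	20.50
hsa_circ_0001400	39	21.84
hsa_circ_0001730	35	21.39
hsa_circ_0001801	27	21.20
hsa_circ_0000043	11	26.65
hsa_circ_0001423	7	21.40
hsa_circ_0004087	6	26.22
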