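gene_id	with_event	without_event
CALM1	46	6
CALM2	37	16
CALM3	20	15
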