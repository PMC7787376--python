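word	valence	arousal	dominance
inevitable	4.10	4.27	3.15
sad	2.10	3.49	3.84
fear	2.93	6.14	3.32
scary	3.00	5.35	3.70
peaceful	8.00	4.38	6.84
peace	7.75	4.65	7.17
natural	6.42	3.67	5.16
death	1.89	5.53	3.42
die	1.67	6.90	3.29
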