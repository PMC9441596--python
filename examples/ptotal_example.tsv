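mu	p_total
0.0	0.38
0.1	0.40
0.2	0.43
0.3	0.47
0.4	0.52
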