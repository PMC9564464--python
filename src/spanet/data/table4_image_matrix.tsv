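block	I	II	III	IV
I	1	0	0	0
II	1	0	0	0
III	0	0	1	0
IV	1	0	1	1
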