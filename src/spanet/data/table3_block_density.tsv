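block	I	II	III	IV
I	0.867	0.000	0.111	0.000
II	0.867	0.250	0.178	0.055
III	0.259	0.000	0.694	0.020
IV	0.364	0.018	0.444	0.355
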