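block	inside_received	outside_received	inside_sent	outside_sent	expected_internal_ratio	actual_internal_ratio
I	26	64	26	8	17	76
II	5	1	5	37	13	12
III	50	58	50	16	30	76
IV	39	7	39	69	37	36
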