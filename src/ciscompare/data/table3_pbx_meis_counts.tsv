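binding_site	1UP1.4	4UP1.3	2D0.8	1CiHox3	1intro1.7	mb1	mb2	ma2	ma3	mb1RARE
pbx-1b	3	1	2	3	0	2	2	1	0	0
Pbx-1	7	3	2	4	2	1	3	1	4	0
Pbx	1	1	0	1	0	4	1	2	0	0
MEIS1A	2	2	1	6	1	0	4	1	3	0
MEIS1	0	1	0	2	0	0	4	1	0	0
MEIS1B	0	0	0	0	0	0	1	0	0	0
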