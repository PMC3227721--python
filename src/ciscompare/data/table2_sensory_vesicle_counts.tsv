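binding_site	1UP1.4	4UP1.3	2D0.8	1CiHox3	mb1	mb2	ma2	ma3	mb1RARE
GR	2	3	4	3	1	4	2	0	1
HSF	2	5	5	2	3	2	2	1	0
LEF1	2	1	1	1	2	3	0	1	1
Pax6	8	4	3	5	1	0	0	0	0
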