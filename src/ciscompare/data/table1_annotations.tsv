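sequence_id	species	territories
1UP1.4	Ciona intestinalis	SV,VG,NC,r4
1intro1.7	Ciona intestinalis	SV,VG,NC,hindbrain
2D0.8	Ciona intestinalis	SV,VG,Ph,TSN
1CiHox3	Ciona intestinalis	SV,VG,r4,r6,NC_crest
4UP1.3	Ciona intestinalis	SV
2B	Branchiostoma floridae	SV,VG,Ph,TSN,ganglia_V_VIII
mb1	Mus musculus	SV,NC,r4
ma3	Mus musculus	TSN,r5,r6,NC_crest
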