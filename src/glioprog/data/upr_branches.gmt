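IRE1	UPR branch	XBP1	TRAF2	MAPK8	MAPK14
ATF6	UPR branch	ATF6	MBTPS1	MBTPS2
PERK	UPR branch	EIF2AK3	EIF2S1	ATF4
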