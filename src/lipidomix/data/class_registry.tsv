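class_code	synonyms	category	backbone_chains
TAG	TG	GL	3
DAG	DG	GL	2
MG	MAG	GL	1
PC		GP	2
PE		GP	2
PS		GP	2
PI		GP	2
PG		GP	2
PA		GP	2
LPC	LysoPC	GP	1
LPE	LysoPE	GP	1
LPS	LysoPS	GP	1
LPI	LysoPI	GP	1
LPG	LysoPG	GP	1
LPA	LysoPA	GP	1
SM		SP	2
Cer		SP	2
HexCer	GlcCer,GalCer	SP	2
CE	ChE,CholE	ST	1
FA	FFA	FA	1
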