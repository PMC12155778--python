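attribute	group	unit	scaling	weight
Biowin1	persistence	unitless	-x	1/9
Biowin3	persistence	unitless	-x	1/9
Biowin5	persistence	unitless	-x	1/9
BAF	bioaccumulation	L/kg	log10(x)	1/6
LogKow	bioaccumulation	unitless	x	1/6
Fish LC50	ecotox	mg/L	-log10(x)	1/27
Daphnid LC50	ecotox	mg/L	-log10(x)	1/27
Green Algae EC50	ecotox	mg/L	-log10(x)	1/27
Carcinogenicity	human-health	unitless	x	1/45
Developmental toxicity	human-health	unitless	x	1/45
Mutagenicity	human-health	unitless	x	1/45
Skin sensitization	human-health	unitless	x	1/45
Oral rat LD50	human-health	mg/L	-log10(x)	1/45
ERa	docking	unitless	x	1/45
ERb	docking	unitless	x	1/45
AR	docking	unitless	x	1/45
PPARa	docking	unitless	x	1/45
TRa	docking	unitless	x	1/45
TRb	docking	unitless	x	1/45
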