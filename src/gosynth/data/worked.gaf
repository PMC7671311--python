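!gaf-version: 2.1
SYNTH	S_G01	G01		GO:0000004	SYNTH_REF:0000001	EXP		P	G01 protein		protein	taxon:0001	20200101	SYNTH		
SYNTH	S_G01	G01		GO:0000002	SYNTH_REF:0000001	IEA		P	G01 protein		protein	taxon:0001	20200101	SYNTH		
SYNTH	S_G02	G02		GO:0000004	SYNTH_REF:0000001	IDA		P	G02 protein		protein	taxon:0001	20200101	SYNTH		
SYNTH	S_G03	G03		GO:0000005	SYNTH_REF:0000001	EXP		P	G03 protein		protein	taxon:0001	20200101	SYNTH		
SYNTH	S_G04	G04		GO:0000005	SYNTH_REF:0000001	IEA		P	G04 protein		protein	taxon:0001	20200101	SYNTH		
SYNTH	S_G05	G05		GO:0000006	SYNTH_REF:0000001	EXP		P	G05 protein		protein	taxon:0001	20200101	SYNTH		
SYNTH	S_G06	G06		GO:0000006	SYNTH_REF:0000001	IEA		P	G06 protein		protein	taxon:0001	20200101	SYNTH		
SYNTH	S_G06	G06		GO:0000001	SYNTH_REF:0000001	IEA		P	G06 protein		protein	taxon:0001	20200101	SYNTH		
SYNTH	S_G07	G07		GO:0000002	SYNTH_REF:0000001	EXP		P	G07 protein		protein	taxon:0001	20200101	SYNTH		
SYNTH	S_G08	G08		GO:0000005	SYNTH_REF:0000001	ND		P	G08 protein		protein	taxon:0001	20200101	SYNTH		
SYNTH	S_G08	G08		GO:0000005	SYNTH_REF:0000001	EXP		P	G08 protein		protein	taxon:0001	20200101	SYNTH		
SYNTH	S_G09	G09	NOT	GO:0000006	SYNTH_REF:0000001	IDA		P	G09 protein		protein	taxon:0001	20200101	SYNTH		
SYNTH	S_G10	G10		GO:0000003	SYNTH_REF:0000001	EXP		P	G10 protein		protein	taxon:0001	20200101	SYNTH		
SYNTH	S_G10	G10		GO:0000006	SYNTH_REF:0000001	IEA		P	G10 protein		protein	taxon:0001	20200101	SYNTH		
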