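# Transcription of Table 2, Garton M, Sayadi M, Kim PM (2017) PLOS ONE
# 12(11):e0187524, doi:10.1371/journal.pone.0187524.
# Thermodynamic-integration binding energy changes (kcal/mol) for
# non-canonical mutations of D-RFX001; 26 filled cells over 11 positions.
position	code	value
V22	DPP	-1.24
V22	IGL	-2.84
V22	004	-0.51
V22	D4P	-1.20
F23	DPP	-0.61
F23	004	+1.21
F23	D4P	-1.12
F26	NAL	-1.6
D27	DPP	-4.25
D27	D4P	-3.72
F30	D4P	+1.01
F30	26P	+2.18
S38	IGL	-0.35
F40	HSE	+2.81
F40	DAB	+3.22
W43	004	-1.05
W43	D4P	-1.01
W43	ALC	-0.89
W43	ABA	+0.35
T44	D4P	-1.15
T44	26P	-3.70
Y45	DPP	+0.97
Y45	26P	-0.49
Y45	ABA	+1.11
F52	DPP	+1.37
F52	ABA	+0.50
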