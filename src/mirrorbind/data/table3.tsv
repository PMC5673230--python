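# Transcription of Table 3, Garton M, Sayadi M, Kim PM (2017) PLOS ONE
# 12(11):e0187524, doi:10.1371/journal.pone.0187524.
# Thermodynamic-integration binding energy changes (kcal/mol) for double and
# triple non-canonical mutants; members are position:code pairs joined by +.
kind	combo	members	value
double	1	V22:IGL+D27:DPP	-4.42
double	2	V22:IGL+D27:D4P	-3.41
double	3	V22:IGL+T44:26P	-6.68
double	4	D27:DPP+T44:26P	-6.74
double	5	D27:D4P+T44:26P	-6.25
triple	1	V22:IGL+D27:DPP+T44:26P	-6.97
triple	2	V22:IGL+D27:D4P+T44:26P	-7.18
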