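# Transcription of Table 1, Garton M, Sayadi M, Kim PM (2017) PLOS ONE
# 12(11):e0187524, doi:10.1371/journal.pone.0187524.
# Thermodynamic-integration binding energy changes (kcal/mol) for canonical
# mutations of D-RFX001; value "N" marks the native residue where the table
# prints it.  Signs are transcribed as printed (+0.0 and -0.0 differ).
library	position	code	value
1	D21	D	N
1	D21	T	+0.3
1	V22	S	+0.3
1	V22	V	N
1	Y23	F	-1.5
1	Y23	R	-0.4
1	D24	D	N
1	D24	E	+0.2
1	D24	A	+0.8
2	F26	F	N
2	F26	W	+0.7
2	D27	D	N
2	D27	E	+0.5
2	F30	F	N
2	F30	Y	+0.0
2	V31	I	-0.8
2	V31	A	-0.2
3	A34	S	-0.3
3	A34	A	N
3	S35	K	-0.2
3	S35	S	N
3	F37	F	N
3	S38	T	+0.7
3	S38	S	N
4	D39	D	N
4	D39	F	-0.1
4	D39	W	-0.6
4	F40	F	N
4	F40	I	-0.2
4	D41	D	N
4	D41	E	-0.0
4	D42	D	N
4	D42	A	+1.1
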