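# Backbone-independent rotamer library for the coarse residue templates.
# Format: rot NAME chi1_mean chi1_sigma [chi2_mean chi2_sigma ...]
# Angles in degrees.  Residues without chi angles (GLY, ALA, PRO, IGL) take
# a single implicit null rotamer and need no entry.

rot SER -60 9
rot SER 180 9
rot SER  60 9

rot CYS -60 9
rot CYS 180 9
rot CYS  60 9

rot THR -60 9
rot THR 180 9
rot THR  60 9

rot VAL -60 9
rot VAL 180 9
rot VAL  60 9

rot PHE -60 9
rot PHE 180 9
rot PHE  60 9

rot TYR -60 9
rot TYR 180 9
rot TYR  60 9

rot TRP -60 9
rot TRP 180 9
rot TRP  60 9

rot HIS -60 9
rot HIS 180 9
rot HIS  60 9

rot ASP -60 9
rot ASP 180 9
rot ASP  60 9

rot LEU -60 9 180 9
rot LEU 180 9 180 9
rot LEU  60 9 180 9

rot ILE -60 9 180 9
rot ILE 180 9 180 9
rot ILE -60 9 -60 9

rot ASN -60 9 -60 11
rot ASN 180 9  60 11
rot ASN -60 9 120 11

rot GLU -60 9 180 10
rot GLU 180 9 180 10
rot GLU  60 9 180 10

rot MET -60 9 180 10 180 11
rot MET 180 9 180 10 180 11

rot GLN -60 9 180 10 180 11
rot GLN 180 9 180 10 180 11

rot LYS -60 9 180 10 180 11
rot LYS 180 9 180 10 180 11
rot LYS -60 9 180 10 -60 11

rot ARG -60 9 180 10 180 11
rot ARG 180 9 180 10 180 11
rot ARG -60 9 180 10 -60 11

# non-canonical residues

rot DPP -60 9
rot DPP 180 9
rot DPP  60 9

rot 004 -60 9
rot 004 180 9
rot 004  60 9

rot D4P -60 9
rot D4P 180 9
rot D4P  60 9

rot NAL -60 9
rot NAL 180 9
rot NAL  60 9

rot ALC -60 9
rot ALC 180 9
rot ALC  60 9

rot ABA -60 9
rot ABA 180 9
rot ABA  60 9

rot HSE -60 9 180 10
rot HSE 180 9 180 10
rot HSE  60 9 180 10

rot DAB -60 9 180 10
rot DAB 180 9 180 10
rot DAB  60 9 180 10

rot 26P -60 9 180 10 180 11
rot 26P 180 9 180 10 180 11
rot 26P -60 9 180 10 -60 11
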