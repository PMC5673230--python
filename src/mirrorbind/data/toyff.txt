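# Desk-scale united-heavy-atom force field for toy host-guest systems and
# coarse amino-acid side chains.  Units: epsilon kcal/mol, sigma Angstrom,
# charge e.  Format: type KEY EPS SIGMA CHARGE FORMAL HYDRO SIZE DONOR ACCEPTOR
#
# backbone
type NBB 0.17 3.25 -0.40 0 polar medium 1 0
type CAB 0.11 3.40 0.10 0 hydrophobic medium 0 0
type CBB 0.09 3.40 0.45 0 polar medium 0 0
type OBB 0.21 2.96 -0.45 0 polar small 0 1
# aliphatic united carbons
type CH2 0.12 3.40 0.00 0 hydrophobic small 0 0
type CH3 0.16 3.50 0.00 0 hydrophobic small 0 0
# united ring beads
type RNG 0.25 4.50 0.00 0 hydrophobic large 0 0
type RNL 0.32 5.20 0.00 0 hydrophobic large 0 0
type CHX 0.28 4.80 0.00 0 hydrophobic large 0 0
type RNH 0.22 4.00 0.00 0 polar medium 1 1
# polar / charged groups
type OH  0.18 3.05 -0.35 0 polar small 1 1
type NPL 0.17 3.25 -0.35 0 polar small 1 0
type OCB 0.21 2.96 -0.38 0 polar small 0 1
type NPO 0.17 3.25 1.00 1 charged small 1 0
type GDM 0.20 4.20 1.00 1 charged medium 1 0
type OMI 0.21 3.60 -1.00 -1 charged small 0 1
type TCX 0.25 4.20 -1.00 -1 charged medium 0 1
type SUL 0.25 3.60 0.00 0 hydrophobic medium 0 0
# host beads for generated toy complexes
type HBP 0.15 3.40 1.00 1 charged small 1 0
type HBM 0.15 3.40 -1.00 -1 charged small 0 1
type HBN 0.15 3.40 0.00 0 hydrophobic small 0 0
type HBH 0.25 4.20 0.00 0 hydrophobic large 0 0
#
option cutoff 12.0
option dielectric_model constant
option dielectric 1.0
option coulomb_constant 332.0636
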