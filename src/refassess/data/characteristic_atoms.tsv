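# Characteristic side-chain atom per residue type for GDC-SC:
# the distal functional atom of each of the 19 non-glycine standard residues.
# Editable; a residue whose characteristic atom is absent from a structure
# falls back to CB (flagged).
ALA	CB
ARG	NH1
ASN	OD1
ASP	OD1
CYS	SG
GLN	OE1
GLU	OE1
HIS	NE2
ILE	CD1
LEU	CD1
LYS	NZ
MET	CE
PHE	CZ
PRO	CG
SER	OG
THR	OG1
TRP	CH2
TYR	OH
VAL	CG1
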