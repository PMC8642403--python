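# Reduced protein force-field parameter table.
#
# Partial charges (units of e) for the backbone atoms N, CA, C, O and the
# first side-chain carbon CB of the 20 standard amino acids.  The backbone
# amide group carries the classic four-point charge pattern (N -0.50,
# CA +0.14, C +0.50, O -0.50, net ~0.14 absorbed on CA-H which is not
# modelled here); formal side-chain charges of Asp/Glu (-1) and Lys/Arg (+1)
# are lumped onto CB so that coarse heavy-atom models still produce sensible
# cross-chain electrostatics.  This table is user-replaceable; pass any file
# in the same dialect.
#
# [charges]  residue  atom  charge_e
# [lj]       element  epsilon_kcal_mol  sigma_A

[charges]
ALA N -0.500
ALA CA 0.140
ALA C 0.500
ALA O -0.500
ALA CB 0.000
ARG N -0.500
ARG CA 0.140
ARG C 0.500
ARG O -0.500
ARG CB 1.000
ASN N -0.500
ASN CA 0.140
ASN C 0.500
ASN O -0.500
ASN CB 0.000
ASP N -0.500
ASP CA 0.140
ASP C 0.500
ASP O -0.500
ASP CB -1.000
CYS N -0.500
CYS CA 0.140
CYS C 0.500
CYS O -0.500
CYS CB 0.000
GLN N -0.500
GLN CA 0.140
GLN C 0.500
GLN O -0.500
GLN CB 0.000
GLU N -0.500
GLU CA 0.140
GLU C 0.500
GLU O -0.500
GLU CB -1.000
GLY N -0.500
GLY CA 0.140
GLY C 0.500
GLY O -0.500
HIS N -0.500
HIS CA 0.140
HIS C 0.500
HIS O -0.500
HIS CB 0.000
ILE N -0.500
ILE CA 0.140
ILE C 0.500
ILE O -0.500
ILE CB 0.000
LEU N -0.500
LEU CA 0.140
LEU C 0.500
LEU O -0.500
LEU CB 0.000
LYS N -0.500
LYS CA 0.140
LYS C 0.500
LYS O -0.500
LYS CB 1.000
MET N -0.500
MET CA 0.140
MET C 0.500
MET O -0.500
MET CB 0.000
PHE N -0.500
PHE CA 0.140
PHE C 0.500
PHE O -0.500
PHE CB 0.000
PRO N -0.300
PRO CA 0.140
PRO C 0.500
PRO O -0.500
PRO CB 0.000
SER N -0.500
SER CA 0.140
SER C 0.500
SER O -0.500
SER CB 0.000
THR N -0.500
THR CA 0.140
THR C 0.500
THR O -0.500
THR CB 0.000
TRP N -0.500
TRP CA 0.140
TRP C 0.500
TRP O -0.500
TRP CB 0.000
TYR N -0.500
TYR CA 0.140
TYR C 0.500
TYR O -0.500
TYR CB 0.000
VAL N -0.500
VAL CA 0.140
VAL C 0.500
VAL O -0.500
VAL CB 0.000

[lj]
C 0.10 3.40
N 0.17 3.25
O 0.21 2.96
S 0.25 3.56
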