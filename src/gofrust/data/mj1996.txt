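# Miyazawa-Jernigan effective inter-residue contact energies e_ij (RT units),
# from S. Miyazawa & R. L. Jernigan, J. Mol. Biol. 256:623-644 (1996), Table 5
# (upper triangle, contact energies relative to the solvent reference).
# Row i gives e(a_i, a_j) for j = i..19 in the residue order of the first line.
# Only relative magnitudes matter here: native-contact weights are |e_ij|
# rescaled to unit mean over each contact list.
CYS MET PHE ILE LEU VAL TRP TYR ALA GLY THR SER ASN GLN ASP GLU HIS ARG LYS PRO
CYS -5.44 -4.99 -5.80 -5.50 -5.83 -4.96 -4.95 -4.16 -3.57 -3.16 -3.11 -2.86 -2.59 -2.85 -2.41 -2.27 -3.60 -2.57 -1.95 -3.07
MET -5.46 -6.56 -6.02 -6.41 -5.32 -5.55 -4.91 -3.94 -3.39 -3.51 -3.03 -2.95 -3.30 -2.57 -2.89 -3.98 -3.12 -2.48 -3.45
PHE -7.26 -6.84 -7.28 -6.29 -6.16 -5.66 -4.81 -4.13 -4.28 -4.02 -3.75 -4.10 -3.48 -3.56 -4.77 -3.98 -3.36 -4.25
ILE -6.54 -7.04 -6.05 -5.78 -5.25 -4.58 -3.78 -4.03 -3.52 -3.24 -3.67 -3.17 -3.27 -4.14 -3.63 -3.01 -3.76
LEU -7.37 -6.48 -6.14 -5.67 -4.91 -4.16 -4.34 -3.92 -3.74 -4.04 -3.40 -3.59 -4.54 -4.03 -3.37 -4.20
VAL -5.52 -5.18 -4.62 -4.04 -3.38 -3.46 -3.05 -2.83 -3.07 -2.48 -2.67 -3.58 -3.07 -2.49 -3.32
TRP -5.06 -4.66 -3.82 -3.42 -3.22 -2.99 -3.07 -3.11 -2.84 -2.99 -3.98 -3.41 -2.69 -3.73
TYR -4.17 -3.36 -3.01 -3.01 -2.78 -2.76 -2.97 -2.76 -2.79 -3.52 -3.16 -2.60 -3.19
ALA -2.72 -2.31 -2.32 -2.01 -1.84 -1.89 -1.70 -1.51 -2.41 -1.83 -1.31 -2.03
GLY -2.24 -2.08 -1.82 -1.74 -1.66 -1.59 -1.22 -2.15 -1.72 -1.15 -1.87
THR -2.12 -1.96 -1.88 -1.90 -1.80 -1.74 -2.42 -1.90 -1.31 -1.90
SER -1.67 -1.58 -1.49 -1.63 -1.48 -2.11 -1.62 -1.05 -1.57
ASN -1.68 -1.71 -1.68 -1.51 -2.08 -1.64 -1.21 -1.53
GLN -1.54 -1.46 -1.42 -1.98 -1.80 -1.29 -1.73
ASP -1.21 -1.02 -2.32 -2.29 -1.68 -1.33
GLU -0.91 -2.15 -2.27 -1.80 -1.26
HIS -3.05 -2.16 -1.35 -2.25
ARG -1.55 -0.59 -1.70
LYS -0.12 -0.97
PRO -1.75
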