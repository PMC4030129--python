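"""Physical constants and the average residue-mass table.

Internal unit system: length in Å, energy in kcal/mol, mass in amu (g/mol),
time in ps.  In these units 1 kcal/mol = 418.4 amu Å² ps⁻², which is the
single conversion factor the integrator needs.
"""

# Boltzmann constant, kcal mol^-1 K^-1
KB_KCAL = 1.987204259e-3

# 1 kcal/mol expressed in amu Å² ps⁻² (4184 J/mol divided by 10 J/mol per amu Å² ps⁻²)
KCAL_TO_AMU_A2_PS2 = 418.4

# Average residue masses (amino acid minus one water), amu.
# Used to assign one bead mass per residue from its three-letter code.
RESIDUE_MASSES = {
    "GLY": 57.0519,
    "ALA": 71.0788,
    "SER": 87.0782,
    "PRO": 97.1167,
    "VAL": 99.1326,
    "THR": 101.1051,
    "CYS": 103.1388,
    "LEU": 113.1594,
    "ILE": 113.1594,
    "ASN": 114.1038,
    "ASP": 115.0886,
    "GLN": 128.1307,
    "LYS": 128.1741,
    "GLU": 129.1155,
    "MET": 131.1926,
    "HIS": 137.1411,
    "PHE": 147.1766,
    "ARG": 156.1875,
    "TYR": 163.1760,
    "TRP": 186.2132,
}

# Fallback for unknown residue types: the canonical "average residue" mass.
DEFAULT_RESIDUE_MASS = 110.0
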