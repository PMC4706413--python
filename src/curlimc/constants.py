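"""Physical constants and fixed covalent geometry tables.

Units throughout the peptide model: lengths in Å, energies in kcal/mol,
temperatures in K. Toy systems use reduced units (kB = 1) by passing
``kB=1.0`` explicitly where a temperature enters.
"""

# Boltzmann constant, kcal/(mol K)
KB_KCAL = 0.0019872

# Avogadro's number, 1/mol
N_AVOGADRO = 6.02214076e23

# One-letter codes of the 20 canonical amino acids
AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

# Number of sampled side-chain torsions per residue type. The side chain is a
# coarse model: CB plus one pseudo-bead ("SC") placed by a single chi1
# torsion; GLY has no side chain and ALA only the fixed CB.
N_CHI = {aa: 1 for aa in AMINO_ACIDS}
N_CHI["G"] = 0
N_CHI["A"] = 0

# Formal side-chain charge at neutral pH carried by the SC bead
SC_CHARGE = {aa: 0.0 for aa in AMINO_ACIDS}
SC_CHARGE.update({"D": -1.0, "E": -1.0, "K": +1.0, "R": +1.0})

# Distance CB -> SC pseudo-bead (Å), a coarse per-residue side-chain extent
SC_EXTENT = {
    "S": 1.2, "C": 1.3, "T": 1.3, "V": 1.3, "P": 1.2,
    "D": 1.8, "N": 1.8, "I": 1.8, "L": 1.8, "M": 2.2,
    "E": 2.4, "Q": 2.4, "H": 2.2, "F": 2.4, "Y": 2.9,
    "K": 3.0, "R": 3.4, "W": 2.8,
}

# Fixed covalent geometry (Engh & Huber-like standard values).
# Bond lengths in Å.
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_N_H = 1.000
BOND_CA_CB = 1.530

# Bond angles in degrees.
ANGLE_C_N_CA = 121.7
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_CA_C_O = 120.8
ANGLE_C_N_H = 119.5
ANGLE_N_CA_CB = 110.5
ANGLE_CA_CB_SC = 114.0

# Improper torsion C(i)-N(i)-CA(i)-CB(i) fixing L-chirality (degrees,
# standard dihedral sign convention).
TORSION_CB_IMPROPER = -122.6

# Pairwise contact diameters for the excluded-volume term (Å), by atom
# kind; sigma_ij = (sigma_i + sigma_j)/2. Calibrated so that ideal
# alpha-helix and beta-strand geometries are essentially clash-free
# (O and amide-H are small because their close approaches are the
# hydrogen bond itself, which E_hb scores).
EV_SIGMA = {"N": 2.9, "CA": 3.2, "C": 3.2, "O": 2.6, "H": 1.4, "CB": 3.4, "SC": 3.6}
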