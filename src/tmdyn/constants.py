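"""Physical constants, standard peptide geometry and the C99 construct.

Units throughout the package: lengths in Angstrom, energies in kcal/mol,
spring constants in kcal mol^-1 A^-2, times in ns, angles in degrees unless
noted otherwise.
"""

# Boltzmann constant in kcal/(mol K); k_B*T = 0.58225 kcal/mol at 293 K.
KB_KCAL = 1.9872041e-3

DEFAULT_TEMPERATURE_K = 293.0


def kbt(temperature: float = DEFAULT_TEMPERATURE_K) -> float:
    """Thermal energy k_B*T in kcal/mol."""
    return KB_KCAL * temperature


# Standard backbone bond lengths (A) and angles (deg) used by the helix
# builder and by amide-hydrogen reconstruction.
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_N_H = 1.01

ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8

# Geometry of an exact mathematical alpha-helix Calpha trace: 3.6 residues
# per turn, 1.5 A rise, 2.28 A radius.  The 1.5 A rise is the conventional
# back-of-envelope value used for straight-helix arc lengths.
IDEAL_TWIST_DEG = 100.0
IDEAL_RISE = 1.5
IDEAL_CA_RADIUS = 2.28

# The C99 transmembrane-domain model construct: residues 28-55 of C99
# preceded by a KKW solubilisation/label tag.  C99 numbering is the public
# residue coordinate of the package.
C99_WT_CONSTRUCT = "KKWKGAIIGLMVGGVVIATVIVITLVMLKKK"
C99_TAG_LENGTH = 3          # leading KKW
C99_FIRST_NUMBER = 28       # construct residue 4 (K) is C99 K28

BACKBONE_HEAVY = ("N", "CA", "C", "O")
BACKBONE = ("N", "H", "CA", "C", "O")
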