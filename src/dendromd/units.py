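"""Internal unit system and physical constants.

Lengths are stored in angstroms, energies in kcal/mol, masses in amu and
time in picoseconds (the AKMA convention).  With these units an
acceleration computed as force/mass must be multiplied by
``KCAL_PER_MOL_TO_AKMA`` to come out in A/ps^2.
"""

# 1 kcal/mol expressed in amu * A^2 / ps^2
KCAL_PER_MOL_TO_AKMA = 418.4

# Boltzmann constant, kcal/(mol K)
KB = 0.0019872041

# Coulomb prefactor: q_i q_j / r with charges in e and r in A gives energy
# in units of COULOMB_K kcal/mol.
COULOMB_K = 332.0637

# Atomic / united-atom site masses, amu
MASSES = {
    "Si": 28.086,
    "O": 15.999,
    "C": 12.011,
    "H": 1.008,
    "CH2": 14.027,
    "CH3": 15.035,
}
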