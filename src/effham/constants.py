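"""Physical constants and unit conversions (CODATA 2018)."""

HARTREE_EV = 27.211386245988
BOHR_ANGSTROM = 0.529177210903
EV_CM = 8065.544  # 1 eV in cm^-1
KB_EV = 8.617333262e-5  # Boltzmann constant, eV/K
HBAR_EV_FS = 0.6582119569  # hbar, eV*fs

# Atomic numbers of the supported element set.
ATOMIC_NUMBERS = {"H": 1, "C": 6, "N": 7, "O": 8}
ELEMENT_SYMBOLS = {z: s for s, z in ATOMIC_NUMBERS.items()}
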