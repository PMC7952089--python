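"""Unit conventions and conversion constants.

Lengths are nm, energies k_BT (temperature fixed at 1), time in reduced
units, concentrations mM.  One molecule per nm^3 equals
1e24 / N_A mol/L = 1660.539... mM.
"""

AVOGADRO = 6.02214076e23

#: concentration of one molecule per nm^3, in mM
MM_PER_COUNT_PER_NM3 = 1e24 / AVOGADRO * 1e3


def count_per_nm3_to_mM(number_density: float) -> float:
    """Convert a number density (molecules / nm^3) to mM."""
    return number_density * MM_PER_COUNT_PER_NM3


def mM_to_count_per_nm3(concentration: float) -> float:
    """Convert a concentration in mM to molecules / nm^3."""
    return concentration / MM_PER_COUNT_PER_NM3
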