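"""Unit conventions and physical constants.

Internal units: length Å, energy kcal/mol, mass Da, time ps, temperature K.
Distance thresholds quoted in nm at the interface layer are converted once
(`nm_to_angstrom`) and stored in Å everywhere else.
"""

import math

#: Boltzmann constant, kcal mol^-1 K^-1
KB_KCAL = 1.987204259e-3

#: 1 kcal/mol expressed in Da Å^2 ps^-2 (the natural dynamics energy unit)
KCAL_TO_DA_A2_PS2 = 418.4

#: B-factor prefactor: B = (8 pi^2 / 3) <dr^2>
B_FACTOR_PREFACTOR = 8.0 * math.pi**2 / 3.0


def nm_to_angstrom(x_nm: float) -> float:
    return 10.0 * x_nm


def angstrom_to_nm(x_a: float) -> float:
    return 0.1 * x_a


def kbt_kcal(temperature: float) -> float:
    """k_B T in kcal/mol."""
    return KB_KCAL * temperature


def kbt_dyn(temperature: float) -> float:
    """k_B T in Da Å^2 ps^-2 (for velocities/kinetic energy)."""
    return KB_KCAL * temperature * KCAL_TO_DA_A2_PS2
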