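"""Physical constants in the unit systems used across the package.

Two unit systems coexist:

* tweezers side: pN, nm, s, energies in k_BT;
* coarse-grained side: kcal/mol, Angstrom, reduced time, unit bead masses.
"""

import scipy.constants as _sc

#: Boltzmann constant, pN nm / K  (tweezers side)
KB_PN_NM = _sc.k * 1e21

#: Boltzmann constant, kcal mol^-1 K^-1  (coarse-grained side)
KB_KCAL = 0.0019872

#: Coulomb prefactor e^2/(4 pi eps0), kcal mol^-1 Angstrom (vacuum)
COULOMB_KCAL_A = (
    _sc.e**2 / (4.0 * _sc.pi * _sc.epsilon_0) * _sc.Avogadro / (_sc.calorie * 1e3) * 1e10
)

#: kcal/mol per k_BT at a given temperature
def kt_kcal(temperature: float = 300.0) -> float:
    return KB_KCAL * temperature


def kt_pn_nm(temperature: float = 300.0) -> float:
    """Thermal energy in pN nm at ``temperature`` (4.142 at 300 K)."""
    return KB_PN_NM * temperature
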