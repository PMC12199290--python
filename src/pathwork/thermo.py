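"""Thermodynamic context and physical constants.

Internal units throughout the package: Å, Å², kcal/mol, ps, K, amu.
Quantities quoted in the metadynamics/SMD literature in kJ/mol and nm are
converted at the configuration boundary, never inside the core.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Boltzmann constant, kcal/(mol K).
KB_KCAL = 0.0019872041

#: Avogadro constant, 1/mol.
N_AVOGADRO = 6.02214076e23

#: Volume per molecule at 1 M standard concentration, Å³ (exact value
#: 1e27/N_A ≈ 1660.54; the conventional rounded constant 1661 Å³ is used in
#: the standard-state correction).
STANDARD_VOLUME_EXACT_A3 = 1.0e27 / N_AVOGADRO
STANDARD_VOLUME_A3 = float(round(STANDARD_VOLUME_EXACT_A3))

#: Coulomb prefactor, kcal Å / (mol e²).
COULOMB_KCAL_A_E2 = 332.0637

#: 1 kcal/mol expressed in amu Å²/ps² (acceleration conversion for dynamics).
KCALMOL_TO_AMU_A2_PS2 = 418.4

#: kJ/mol → kcal/mol.
KJ_TO_KCAL = 1.0 / 4.184


@dataclass(frozen=True)
class ThermoContext:
    """Temperature and derived quantities for one analysis.

    Attributes
    ----------
    T : float
        Absolute temperature in K.
    """

    T: float = 300.0
    beta: float = field(init=False)
    RT: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.T > 0:
            raise ValueError(f"temperature must be positive, got {self.T}")
        object.__setattr__(self, "RT", KB_KCAL * self.T)
        object.__setattr__(self, "beta", 1.0 / self.RT)
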