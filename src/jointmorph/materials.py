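"""Poroelastic tissue constants.

Unit system: mm - kPa - s.  Hydraulic permeability is accepted in the
field-standard mm^4 N^-1 s^-1 and converted internally to mm^2 kPa^-1 s^-1
(factor 1e-3), so the Darcy flux q = -k grad(p) comes out in mm/s.

The default constants are soft-tissue placeholders on a kPa scale, exposed in
the configuration; the interzone is softer and an order of magnitude more
permeable than cartilage, which is the qualitative relation that matters for
the field patterns.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class TissueProps:
    E: float           # Young's modulus, kPa
    nu: float          # Poisson ratio
    alpha: float = 1.0  # Biot coefficient
    k: float = 20.0    # hydraulic permeability, mm^4 N^-1 s^-1

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise ValueError("E must be > 0")
        if not 0.0 <= self.nu < 0.5:
            raise ValueError("nu must be in [0, 0.5)")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must be in (0, 1]")
        if self.k <= 0:
            raise ValueError("permeability must be > 0")

    @property
    def k_internal(self) -> float:
        """Permeability in mm^2 kPa^-1 s^-1."""
        return self.k * 1e-3

    @property
    def lame(self) -> tuple[float, float]:
        lam = self.E * self.nu / ((1 + self.nu) * (1 - 2 * self.nu))
        mu = self.E / (2 * (1 + self.nu))
        return lam, mu

    @property
    def confined_modulus(self) -> float:
        lam, mu = self.lame
        return lam + 2 * mu

    @property
    def consolidation_coefficient(self) -> float:
        """c_v = k' * (lambda + 2 mu), mm^2/s (incompressible constituents)."""
        return self.k_internal * self.confined_modulus


@dataclass(frozen=True)
class MaterialMap:
    cartilage: TissueProps = TissueProps(E=1.0, nu=0.3, alpha=1.0, k=20.0)
    interzone: TissueProps = TissueProps(E=0.1, nu=0.3, alpha=1.0, k=200.0)

    def by_label(self) -> tuple[TissueProps, ...]:
        """Props indexed by tissue label (cartilage=0, interzone=1)."""
        return (self.cartilage, self.interzone)


def default_materials() -> MaterialMap:
    return MaterialMap()
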