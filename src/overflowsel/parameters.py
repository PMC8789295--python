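"""Model parameters for the biphasic (glucose -> acetate) growth model.

The default values describe *E. coli* MG1655 growing in M9 + 2.5 mM glucose:
cell density and yields from the literature, phase cell volumes of 1 and
0.5 um^3, an acetate growth rate of 0.3 /h, and the four shape constants of
the overflow-dependent glucose growth-rate curve mu_g(phi).

The default glucose amount and inoculum correspond to a single ~50 um
emulsion droplet of 2.5 mM glucose medium seeded with one cell, which puts
the model in the 5-6 generations-per-droplet regime of the droplet
selection experiment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace

__all__ = [
    "ModelParameters",
    "DROPLET_DIAMETER_UM",
    "sphere_volume_um3",
    "droplet_glucose_mol",
]

#: Diameter of an average emulsion droplet, um.
DROPLET_DIAMETER_UM = 50.0

#: Glucose concentration of the growth medium, mol per liter (2.5 mM).
MEDIUM_GLUCOSE_M = 2.5e-3


def sphere_volume_um3(diameter_um: float) -> float:
    """Volume of a sphere in um^3 given its diameter in um."""
    return math.pi / 6.0 * diameter_um**3


def droplet_glucose_mol(
    diameter_um: float = DROPLET_DIAMETER_UM,
    glucose_molar: float = MEDIUM_GLUCOSE_M,
) -> float:
    """Moles of glucose contained in one droplet of the given diameter.

    1 um^3 = 1e-15 liter.
    """
    return glucose_molar * sphere_volume_um3(diameter_um) * 1e-15


@dataclass(frozen=True)
class ModelParameters:
    """All constants of the biphasic overflow-metabolism fitness model.

    Attributes
    ----------
    rho : float
        Mass density of a cell, g per um^3.
    Y_xg : float
        Gram biomass yield on glucose, g per mol.
    Y_xa : float
        Gram biomass yield on acetate, g per mol.
    Y_ag : float
        Acetate yield on glucose, mol acetate per mol glucose at phi=1.
    V_cg : float
        Single-cell volume during growth on glucose, um^3.
    V_ca : float
        Single-cell volume during growth on acetate, um^3.
    mu_a : float
        Growth rate on acetate, per h.
    alpha, beta, gamma, delta : float
        Dimensionless shape constants of the mu_g(phi) curve
        mu_g(phi) = (1 - phi) * (alpha + delta * exp(-(beta - phi)^2 / gamma^2)).
    glc0 : float
        Initial amount of glucose, mol.  Defaults to the content of one
        average droplet.
    N0 : float
        Initial number of cells.  Defaults to a single founder cell.
    """

    rho: float = 280e-15
    Y_xg: float = 88.0
    Y_xa: float = 20.0
    Y_ag: float = 2.0
    V_cg: float = 1.0
    V_ca: float = 0.5
    mu_a: float = 0.3
    alpha: float = 0.2
    beta: float = 0.5
    gamma: float = 0.4
    delta: float = 2.0
    glc0: float = droplet_glucose_mol()
    N0: float = 1.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValueError(f"parameter {f.name!r} must be finite, got {v!r}")
            if f.name == "glc0":
                if v < 0:
                    raise ValueError(f"glc0 must be >= 0, got {v}")
            elif v <= 0:
                raise ValueError(f"parameter {f.name!r} must be > 0, got {v}")
        if not 0.0 < self.Y_ag <= 3.0:
            raise ValueError(
                f"Y_ag must lie in (0, 3] (glucose has at most 3 two-carbon "
                f"units worth of acetate), got {self.Y_ag}"
            )
        if self.V_ca > self.V_cg:
            raise ValueError(
                f"V_ca ({self.V_ca}) must not exceed V_cg ({self.V_cg}): "
                "acetate-grown cells are not larger than glucose-grown cells"
            )

    def with_overrides(self, **overrides: float) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **overrides)

    @property
    def glucose_cell_yield(self) -> float:
        """Maximum cells per mol glucose during the glucose phase (phi=0)."""
        return self.Y_xg / (self.rho * self.V_cg)

    @property
    def acetate_cell_yield(self) -> float:
        """Cells per mol acetate during the acetate phase."""
        return self.Y_xa / (self.rho * self.V_ca)
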