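"""Synthetic biphasic batch-culture time series.

Emulates plate-reader / Coulter-counter / HPLC time courses of *E. coli*
growing in glucose-limited minimal medium: a fast glucose phase during
which acetate accumulates, a slow acetate phase during which the mean cell
volume shrinks, then stationary phase once all carbon is gone.  The
noise-free trajectories are built directly on the closed-form biphasic
model, so every generated curve has known ground-truth phase rates, yields
and volumes; multiplicative lognormal noise emulates measurement error.

Strain presets encode the wild-type (MG1655-like) and evolved (IR1-like)
phenotypes as multiplicative factors on the phase growth rates, the cell
volumes and the numerical cell yield per mole glucose.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .biphasic import growth_rate_on_glucose
from .parameters import ModelParameters

__all__ = [
    "StrainPreset",
    "SyntheticDesign",
    "TIMESERIES_COLUMNS",
    "generate_timeseries",
    "wildtype_and_evolved_presets",
]

TIMESERIES_COLUMNS = [
    "strain",
    "replicate",
    "time",
    "glucose_mM",
    "acetate_mM",
    "od",
    "counts_ml",
    "volume_um3",
]

#: OD proxy constant: OD units per um^3 of biovolume per ml.  Only ratios of
#: OD are analyzed downstream, so the absolute scale is inconsequential.
OD_PER_BIOVOLUME = 1e-9


@dataclass(frozen=True)
class StrainPreset:
    """Multiplicative phenotype factors applied on top of the base model.

    ``cell_yield_factor`` scales the numerical cell yield (cells per mol
    substrate) in both phases; ``volume_factor`` scales both phase cell
    volumes.  The two are independent knobs: their product is the implied
    change in gram-biomass yield.
    """

    name: str
    mu_g_factor: float = 1.0
    mu_a_factor: float = 1.0
    volume_factor: float = 1.0
    cell_yield_factor: float = 1.0
    phi: float = 0.25

    def __post_init__(self) -> None:
        for f in ("mu_g_factor", "mu_a_factor", "volume_factor",
                  "cell_yield_factor"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")
        if not 0.0 <= self.phi < 1.0:
            raise ValueError(f"phi must lie in [0, 1), got {self.phi}")


def wildtype_and_evolved_presets(phi: float = 0.25) -> tuple[StrainPreset, StrainPreset]:
    """The wild-type reference and the evolved small-cell strain.

    The evolved strain grows 39% faster on glucose, has 11% smaller cells,
    and produces 23% more cells per mole of consumed glucose, with the
    overflow fraction (hence acetate per glucose) unchanged.  The implied
    biomass-yield increase is 1.23 * 0.89 ~ 1.09.
    """
    wt = StrainPreset(name="WT", phi=phi)
    ev = StrainPreset(
        name="IR1",
        mu_g_factor=1.39,
        volume_factor=0.89,
        cell_yield_factor=1.23,
        phi=phi,
    )
    return wt, ev


@dataclass(frozen=True)
class SyntheticDesign:
    """Sampling scheme and noise level of a synthetic growth experiment.

    Defaults: a reading every 5 min for 12 h, 3 biological replicates, 5%
    multiplicative measurement noise.  ``volume_relaxation_rate`` is the
    exponential rate (per h) at which the mean cell volume decays from the
    glucose-phase toward the acetate-phase value after the diauxic switch;
    cell division immediately after the switch is faster than steady-state
    acetate growth because oversized glucose-phase mothers need little new
    biomass to divide, so the default is 1.0/h (most of the shrinkage
    happens within the acetate phase).
    """

    interval: float = 5.0 / 60.0  # h
    duration: float = 12.0  # h
    replicates: int = 3
    noise_cv: float = 0.05
    volume_relaxation_rate: float = 1.0  # per h
    glucose_mM: float = 2.5
    initial_density: float = 1e7  # cells per ml
    seed: int = 0

    def __post_init__(self) -> None:
        if self.interval <= 0 or self.duration <= 0:
            raise ValueError("interval and duration must be positive")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.volume_relaxation_rate <= 0 or self.initial_density <= 0:
            raise ValueError(
                "volume_relaxation_rate and initial_density must be positive"
            )


def _lognormal_factors(
    rng: np.random.Generator, cv: float, shape: tuple[int, ...]
) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(shape)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=shape)


def generate_timeseries(
    preset: StrainPreset,
    params: ModelParameters = ModelParameters(),
    design: SyntheticDesign = SyntheticDesign(),
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Simulate replicate batch-culture time series for one strain.

    All bookkeeping is per liter of culture.  The noise-free trajectory is
    the closed-form biphasic model sampled on the design's time grid:
    exponential growth at the preset-scaled glucose rate with proportional
    glucose drawdown and acetate accumulation (Y_ag * phi per mol consumed),
    then exponential growth on the pooled acetate, then stationary phase.
    The mean cell volume is the scaled glucose-phase volume before the
    switch and relaxes exponentially toward the scaled acetate-phase volume
    after it; OD is proportional to total biovolume.

    Returns a tidy table with columns
    (strain, replicate, time, glucose_mM, acetate_mM, od, counts_ml,
    volume_um3).  ``result.attrs["truncated"]`` flags series whose duration
    ends before carbon exhaustion.
    """
    rng = np.random.default_rng(design.seed if rng is None else rng)
    p, pre = params, preset

    glc0 = design.glucose_mM * 1e-3  # mol per liter
    n0 = design.initial_density * 1e3  # cells per liter
    mu_g = growth_rate_on_glucose(pre.phi, p) * pre.mu_g_factor
    mu_a = p.mu_a * pre.mu_a_factor
    q_g = p.Y_xg * (1 - pre.phi) / (p.rho * p.V_cg) * pre.cell_yield_factor
    q_a = p.acetate_cell_yield * pre.cell_yield_factor
    v_g = p.V_cg * pre.volume_factor
    v_a = p.V_ca * pre.volume_factor

    dN_g = q_g * glc0
    T_g = np.log1p(dN_g / n0) / mu_g
    ace_peak = p.Y_ag * pre.phi * glc0
    N_tg = n0 + dN_g
    dN_a = q_a * ace_peak
    T_a = np.log1p(dN_a / N_tg) / mu_a if ace_peak > 0 else 0.0

    t = np.arange(0.0, design.duration + design.interval / 2, design.interval)
    truncated = design.duration < T_g + T_a
    if truncated:
        warnings.warn(
            f"series duration {design.duration} h ends before carbon "
            f"exhaustion at {T_g + T_a:.2f} h; trajectories are truncated",
            stacklevel=2,
        )

    in_g = t <= T_g
    in_a = (t > T_g) & (t <= T_g + T_a)

    counts = np.where(
        in_g,
        n0 * np.exp(mu_g * t),
        np.where(in_a, N_tg * np.exp(mu_a * (t - T_g)), N_tg + dN_a),
    )
    glucose = np.where(in_g, glc0 - (counts - n0) / q_g, 0.0)
    glucose = np.clip(glucose, 0.0, None)
    acetate = np.where(
        in_g,
        p.Y_ag * pre.phi * (counts - n0) / q_g,
        np.clip(ace_peak - (counts - N_tg) / q_a, 0.0, None),
    )
    r = design.volume_relaxation_rate
    volume = np.where(
        in_g, v_g, v_a + (v_g - v_a) * np.exp(-r * np.clip(t - T_g, 0, None))
    )
    od = counts / 1e3 * volume * OD_PER_BIOVOLUME  # counts/ml * um^3 * k

    frames = []
    channels = {
        "glucose_mM": glucose * 1e3,
        "acetate_mM": acetate * 1e3,
        "od": od,
        "counts_ml": counts / 1e3,
        "volume_um3": volume,
    }
    for rep in range(1, design.replicates + 1):
        noisy = {
            name: vals * _lognormal_factors(rng, design.noise_cv, t.shape)
            for name, vals in channels.items()
        }
        frames.append(
            pd.DataFrame(
                {"strain": pre.name, "replicate": rep, "time": t, **noisy}
            )
        )
    out = pd.concat(frames, ignore_index=True)[TIMESERIES_COLUMNS]
    out.attrs["truncated"] = bool(truncated)
    return out
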