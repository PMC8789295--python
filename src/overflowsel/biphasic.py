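"""Closed-form biphasic (glucose -> acetate) growth model.

A population starts from ``N0`` cells and a finite amount of glucose.  A
fraction ``phi`` of the glucose flux is diverted to acetate (overflow
metabolism); the remainder is converted to biomass at yield ``Y_xg``.  When
the glucose is gone the cells switch to the accumulated acetate, which they
consume at the slower rate ``mu_a`` with yield ``Y_xa`` and a smaller cell
volume.  Fitness is the time-averaged exponential growth rate over the full
feast-famine cycle, F = ln(N_final / N0) / (T_g + T_a), which a serial
batch-transfer regime selects on.

Everything here is closed form; :func:`ode_oracle` provides an independent
forward-integration cross-check of the same dynamics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import minimize_scalar

from .parameters import ModelParameters

__all__ = [
    "BiphasicOutcome",
    "growth_rate_on_glucose",
    "cells_from_glucose",
    "glucose_phase_duration",
    "acetate_from_glucose",
    "cells_from_acetate",
    "acetate_phase_duration",
    "simulate_biphasic",
    "fitness",
    "fitness_landscape",
    "optimal_phi",
    "ode_oracle",
]

LANDSCAPE_COLUMNS = [
    "phi",
    "mu_g",
    "dN_g",
    "T_g",
    "acetate",
    "dN_a",
    "T_a",
    "N_final",
    "growth_factor",
    "fitness",
]


@dataclass(frozen=True)
class BiphasicOutcome:
    """Derived quantities of one evaluation of the biphasic model.

    ``N_final`` satisfies both bookkeeping identities
    ``N0 + dN_g + dN_a`` and ``N0 * exp(mu_g T_g) * exp(mu_a T_a)``.
    """

    phi: float
    mu_g: float
    dN_g: float
    T_g: float
    acetate: float
    dN_a: float
    T_a: float
    N_final: float
    growth_factor: float
    fitness: float


def _check_phi(phi: float, upper_open: bool = False) -> None:
    if not 0.0 <= phi <= 1.0:
        raise ValueError(f"phi must lie in [0, 1], got {phi}")
    if upper_open and phi == 1.0:
        raise ValueError(
            "phi=1 is singular: mu_g(1)=0 while all glucose is converted to "
            "acetate, so the model assigns no finite glucose-phase duration"
        )


def growth_rate_on_glucose(phi: float, params: ModelParameters) -> float:
    """Growth rate on glucose as a function of the overflow fraction.

    mu_g(phi) = (1 - phi) * (alpha + delta * exp(-(beta - phi)^2 / gamma^2)),
    in 1/h.  Zero at phi=1, positive on [0, 1), with an interior peak: cells
    that overflow moderately grow faster on glucose than fully respiring
    ones.
    """
    _check_phi(phi)
    p = params
    return (1.0 - phi) * (
        p.alpha + p.delta * math.exp(-((p.beta - phi) ** 2) / p.gamma**2)
    )


def cells_from_glucose(phi: float, params: ModelParameters) -> float:
    """Cells produced during the glucose phase (Delta N_g).

    The (1 - phi) fraction of glucose not overflowed is converted to biomass
    at yield Y_xg and packaged into cells of volume V_cg and density rho:
    Delta N_g = Y_xg (1 - phi) glc0 / (rho V_cg).
    """
    _check_phi(phi)
    return params.Y_xg * (1.0 - phi) * params.glc0 / (params.rho * params.V_cg)


def glucose_phase_duration(dN_g: float, N0: float, mu_g: float) -> float:
    """Duration of exponential growth needed to add ``dN_g`` cells.

    T_g = ln(dN_g / N0 + 1) / mu_g.
    """
    if dN_g < 0:
        raise ValueError(f"dN_g must be >= 0, got {dN_g}")
    if N0 <= 0:
        raise ValueError(f"N0 must be > 0, got {N0}")
    if dN_g == 0.0:
        return 0.0
    if mu_g <= 0:
        raise ValueError(
            f"mu_g must be > 0 when cells are produced (dN_g={dN_g}); "
            "mu_g=0 makes the phase duration singular"
        )
    return math.log1p(dN_g / N0) / mu_g


def acetate_from_glucose(phi: float, params: ModelParameters) -> float:
    """Acetate accumulated by the end of the glucose phase, mol.

    ace(T_g) = Y_ag * phi * glc0.
    """
    _check_phi(phi)
    return params.Y_ag * phi * params.glc0


def cells_from_acetate(acetate: float, params: ModelParameters) -> float:
    """Cells produced during the acetate phase (Delta N_a).

    Delta N_a = Y_xa * ace / (rho * V_ca).
    """
    if acetate < 0:
        raise ValueError(f"acetate must be >= 0, got {acetate}")
    return params.Y_xa * acetate / (params.rho * params.V_ca)


def acetate_phase_duration(dN_a: float, N_at_Tg: float, mu_a: float) -> float:
    """Duration of the acetate phase: T_a = ln(dN_a / N(T_g) + 1) / mu_a."""
    if dN_a < 0:
        raise ValueError(f"dN_a must be >= 0, got {dN_a}")
    if N_at_Tg <= 0:
        raise ValueError(f"N_at_Tg must be > 0, got {N_at_Tg}")
    if mu_a <= 0:
        raise ValueError(f"mu_a must be > 0, got {mu_a}")
    if dN_a == 0.0:
        return 0.0
    return math.log1p(dN_a / N_at_Tg) / mu_a


def simulate_biphasic(phi: float, params: ModelParameters) -> BiphasicOutcome:
    """Evaluate the full biphasic model at one overflow fraction.

    Chains the five closed-form pieces: glucose-phase cell gain and duration,
    acetate accumulation, acetate-phase cell gain and duration; then the
    growth factor G = N_final / N0 and fitness F = ln(G) / (T_g + T_a).

    Raises
    ------
    ValueError
        If ``phi`` is outside [0, 1), or if ``glc0 = 0`` (no growth, so no
        finite fitness is defined).
    """
    _check_phi(phi, upper_open=True)
    p = params
    mu_g = growth_rate_on_glucose(phi, p)
    dN_g = cells_from_glucose(phi, p)
    T_g = glucose_phase_duration(dN_g, p.N0, mu_g)
    ace = acetate_from_glucose(phi, p)
    N_at_Tg = p.N0 + dN_g
    dN_a = cells_from_acetate(ace, p)
    T_a = acetate_phase_duration(dN_a, N_at_Tg, p.mu_a)
    N_final = N_at_Tg + dN_a
    G = N_final / p.N0
    T = T_g + T_a
    if T == 0.0:
        raise ValueError(
            "fitness undefined: no growth occurred (glc0 = 0 gives "
            "T_g + T_a = 0)"
        )
    F = math.log(G) / T
    return BiphasicOutcome(
        phi=phi,
        mu_g=mu_g,
        dN_g=dN_g,
        T_g=T_g,
        acetate=ace,
        dN_a=dN_a,
        T_a=T_a,
        N_final=N_final,
        growth_factor=G,
        fitness=F,
    )


def fitness(phi: float, params: ModelParameters) -> float:
    """Geometric fitness F(phi) = ln(N_final / N0) / (T_g + T_a), per h.

    Equals the time-weighted average of the two phase growth rates, so it
    always lies between mu_a and mu_g(phi) when both phases run.
    """
    return simulate_biphasic(phi, params).fitness


def fitness_landscape(
    phi_grid: Sequence[float], params: ModelParameters
) -> pd.DataFrame:
    """Evaluate the model on a grid of overflow fractions.

    Parameters
    ----------
    phi_grid : sequence of float
        Strictly increasing overflow fractions, all in [0, 1).

    Returns
    -------
    pandas.DataFrame
        One row per grid point with columns
        (phi, mu_g, dN_g, T_g, acetate, dN_a, T_a, N_final, growth_factor,
        fitness).
    """
    grid = np.asarray(phi_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("phi_grid must not be empty")
    if grid.ndim != 1 or (grid.size > 1 and not np.all(np.diff(grid) > 0)):
        raise ValueError("phi_grid must be a strictly increasing 1-D sequence")
    rows = [asdict(simulate_biphasic(float(phi), params)) for phi in grid]
    return pd.DataFrame(rows, columns=LANDSCAPE_COLUMNS)


def optimal_phi(
    params: ModelParameters,
    tolerance: float = 1e-6,
    phi_max: float = 0.99,
    coarse_points: int = 101,
) -> tuple[float, float]:
    """Locate the fitness-maximizing overflow fraction.

    Deterministic two-stage search: a coarse grid over [0, phi_max] brackets
    the maximum, then bounded golden-section/parabolic refinement narrows it
    to ``tolerance`` in phi.

    Returns
    -------
    (phi_star, F_star)
    """
    if tolerance <= 0:
        raise ValueError(f"tolerance must be > 0, got {tolerance}")
    grid = np.linspace(0.0, phi_max, coarse_points)
    values = np.array([fitness(float(p), params) for p in grid])
    k = int(np.argmax(values))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, grid.size - 1)]
    if lo == hi:  # degenerate single-point grid
        return float(lo), float(values[k])
    res = minimize_scalar(
        lambda p: -fitness(float(p), params),
        bounds=(float(lo), float(hi)),
        method="bounded",
        options={"xatol": tolerance},
    )
    phi_star = float(res.x)
    F_star = -float(res.fun)
    # The refined value can only improve on the coarse grid.
    if values[k] > F_star:
        phi_star, F_star = float(grid[k]), float(values[k])
    return phi_star, F_star


def ode_oracle(
    phi: float,
    params: ModelParameters,
    step: float = 1e-3,
    rtol: float = 1e-12,
) -> BiphasicOutcome:
    """Forward-integration cross-check of :func:`simulate_biphasic`.

    Integrates dN/dt = mu N with explicit resource bookkeeping: phase 1 runs
    until the glucose pool (drawn down in proportion to cells produced) is
    exhausted, phase 2 until the accumulated acetate is gone.  Phase ends are
    located by integrator event detection; ``step`` bounds the maximum step
    of the adaptive integrator.

    Independent of the closed form: no phase duration or final count is taken
    from the analytic solution.
    """
    _check_phi(phi, upper_open=True)
    p = params
    if p.glc0 == 0.0:
        return BiphasicOutcome(phi, growth_rate_on_glucose(phi, p), 0.0, 0.0,
                               0.0, 0.0, 0.0, p.N0, 1.0, 0.0)

    mu_g = growth_rate_on_glucose(phi, p)
    # cells produced per mol glucose consumed (only the non-overflowed part
    # becomes biomass) and per mol acetate consumed
    q_g = p.Y_xg * (1.0 - phi) / (p.rho * p.V_cg)
    q_a = p.acetate_cell_yield

    def rhs1(t, y):  # y = [N, glucose]
        dN = mu_g * y[0]
        return [dN, -dN / q_g]

    def glucose_gone(t, y):
        return y[1]

    glucose_gone.terminal = True
    glucose_gone.direction = -1

    horizon = 10.0 * (math.log(2.0) / mu_g) * 40.0  # generous upper bound
    sol1 = solve_ivp(
        rhs1, (0.0, horizon), [p.N0, p.glc0], events=glucose_gone,
        max_step=step, rtol=rtol, atol=1e-30,
    )
    if not sol1.t_events[0].size:
        raise RuntimeError("ode_oracle: glucose never depleted within horizon")
    T_g = float(sol1.t_events[0][0])
    N_at_Tg = float(sol1.y_events[0][0][0])
    dN_g = N_at_Tg - p.N0
    ace = p.Y_ag * phi * p.glc0

    if ace <= 0.0:
        T_a, dN_a, N_final = 0.0, 0.0, N_at_Tg
    else:
        def rhs2(t, y):  # y = [N, acetate]
            dN = p.mu_a * y[0]
            return [dN, -dN / q_a]

        def acetate_gone(t, y):
            return y[1]

        acetate_gone.terminal = True
        acetate_gone.direction = -1

        horizon2 = 40.0 * math.log(2.0) / p.mu_a
        sol2 = solve_ivp(
            rhs2, (0.0, horizon2), [N_at_Tg, ace], events=acetate_gone,
            max_step=step, rtol=rtol, atol=1e-30,
        )
        if not sol2.t_events[0].size:
            raise RuntimeError(
                "ode_oracle: acetate never depleted within horizon"
            )
        T_a = float(sol2.t_events[0][0])
        N_final = float(sol2.y_events[0][0][0])
        dN_a = N_final - N_at_Tg

    G = N_final / p.N0
    T = T_g + T_a
    F = math.log(G) / T if T > 0 else 0.0
    return BiphasicOutcome(
        phi=phi, mu_g=mu_g, dN_g=dN_g, T_g=T_g, acetate=ace, dN_a=dN_a,
        T_a=T_a, N_final=N_final, growth_factor=G, fitness=F,
    )
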