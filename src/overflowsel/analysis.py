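"""Growth-curve analysis: phase rates, yields, cell sizes, strain contrasts.

Operates on tidy batch-culture tables with the same schema the synthetic
generator writes (strain, replicate, time, glucose_mM, acetate_mM, od,
counts_ml, volume_um3).  All yield arithmetic is per liter of culture so
that mol/mol and cells/mol quantities need no culture volume.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PhaseEstimates",
    "StrainComparison",
    "estimate_growth_rate",
    "detect_switch_time",
    "compute_yields",
    "analyze_replicates",
    "compare_strains",
]

#: Fraction of the initial glucose below which glucose counts as depleted.
GLUCOSE_DEPLETION_FRACTION = 0.01

#: Default sliding-window length (points) for growth-rate regression.
#: At 5-min sampling this spans ~2.4 h, i.e. two to three mass doublings of
#: the glucose phase.  Much shorter windows make the maximum over windows a
#: statistic of the measurement noise rather than of the growth curve.
DEFAULT_RATE_WINDOW = 29

#: Default moving-average length (points) applied to the log signal before
#: the window regressions.
DEFAULT_RATE_SMOOTH = 3

#: Hours after the diauxic switch at which the cell volume is considered
#: settled at its acetate/stationary value.
STATIONARY_VOLUME_OFFSET = 4.0


@dataclass(frozen=True)
class PhaseEstimates:
    """Per-replicate summary statistics of one biphasic growth curve."""

    mu_g_hat: float  # max growth rate in the glucose phase, per h
    mu_a_hat: float  # max growth rate in the acetate phase, per h
    t_switch: float  # glucose depletion time, h
    od_yield: float  # delta OD per mol glucose consumed (per liter)
    count_yield: float  # cells gained per mol glucose consumed (per liter)
    acetate_per_glucose: float  # mol acetate formed per mol glucose
    v_exp: float  # mean cell volume in the glucose-exponential window, um^3
    v_stat: float  # mean cell volume in the acetate/stationary window, um^3


@dataclass(frozen=True)
class StrainComparison:
    """Percent differences (b vs a) per metric, with Welch t-test p-values.

    percent difference = 100 * (mean_b / mean_a - 1); the standard
    deviation is that of per-replicate percent differences of b against the
    mean of a.
    """

    table: pd.DataFrame  # index: metric; columns: percent_diff, sd, p_value
    n_a: int
    n_b: int

    def __getitem__(self, metric: str) -> pd.Series:
        return self.table.loc[metric]


def _sliding_slopes(t: np.ndarray, logy: np.ndarray, window: int) -> np.ndarray:
    """OLS slope of logy vs t in every contiguous window of given length."""
    n = t.size - window + 1
    slopes = np.empty(n)
    for i in range(n):
        ts, ys = t[i : i + window], logy[i : i + window]
        slopes[i] = np.polyfit(ts, ys, 1)[0]
    return slopes


def estimate_growth_rate(
    series: pd.DataFrame,
    window: int = DEFAULT_RATE_WINDOW,
    phase_window: tuple[float, float] | None = None,
    channel: str = "counts_ml",
    smooth: int = DEFAULT_RATE_SMOOTH,
    adapt_window: bool = True,
) -> float:
    """Maximum specific growth rate within a phase, per h.

    Fits a log-linear least-squares regression of ``channel`` vs time in
    every sliding window of ``window`` consecutive points inside
    ``phase_window`` and returns the maximum slope — the standard
    maximum-specific-growth-rate readout for batch growth curves.  The log
    signal is first smoothed by a centered ``smooth``-point moving average
    (``smooth=1`` disables it).  With ``adapt_window`` (default) the window
    shrinks to the phase length when the phase holds fewer points, so short
    phases are fit with a single regression rather than rejected.
    """
    sub = series
    if phase_window is not None:
        lo, hi = phase_window
        sub = series[(series["time"] >= lo) & (series["time"] <= hi)]
    sub = sub[sub[channel] > 0]
    t = sub["time"].to_numpy(dtype=float)
    y = np.log(sub[channel].to_numpy(dtype=float))
    if smooth > 1 and t.size >= smooth + 2:
        kernel = np.full(smooth, 1.0 / smooth)
        y = np.convolve(y, kernel, mode="valid")
        t = t[(smooth - 1) // 2 : t.size - (smooth // 2)]
    if adapt_window:
        window = min(window, t.size)
    if window < 3:
        raise ValueError(f"window must span >= 3 points, got {window}")
    if t.size < window:
        raise ValueError(
            f"phase window {phase_window} holds {t.size} usable points; "
            f"at least {window} are required"
        )
    slopes = _sliding_slopes(t, y, window)
    return float(slopes.max(initial=0.0))


def detect_switch_time(
    series: pd.DataFrame,
    threshold_fraction: float = GLUCOSE_DEPLETION_FRACTION,
) -> float | None:
    """Time of glucose depletion (the diauxic switch), h.

    First time point at which glucose falls below ``threshold_fraction`` of
    its initial value.  Returns None if glucose is never depleted.
    """
    if "glucose_mM" not in series.columns:
        raise ValueError("series has no glucose_mM column")
    s = series.sort_values("time")
    g = s["glucose_mM"].to_numpy(dtype=float)
    t = s["time"].to_numpy(dtype=float)
    g0 = g[0]
    if g0 <= 0:
        return float(t[0])
    below = g < threshold_fraction * g0
    if not below.any():
        return None
    return float(t[np.argmax(below)])


def compute_yields(
    series: pd.DataFrame,
    t_switch: float | None = None,
    glucose0_mM: float | None = None,
    rate_window: int = DEFAULT_RATE_WINDOW,
    stationary_offset: float = STATIONARY_VOLUME_OFFSET,
) -> PhaseEstimates:
    """Summary statistics of one replicate's biphasic growth curve.

    Acetate per glucose is the (smoothed) peak acetate divided by the
    glucose consumed up to the same time point — at the diauxic switch, in
    practice; the numerical cell yield is the cell gain (stationary
    mean minus initial) per mol of consumed glucose.  Mean cell volumes are
    taken inside the glucose-exponential window and from
    ``stationary_offset`` hours after the switch onward, so the volume has
    settled at its acetate/stationary value.

    ``glucose0_mM`` is the known glucose concentration of the medium; in a
    defined medium this is an experimental design quantity, and supplying it
    avoids resting all per-glucose yields on a single noisy measurement at
    t=0.  When None, the first glucose sample is used instead.
    """
    s = series.sort_values("time").reset_index(drop=True)
    if t_switch is None:
        t_switch = detect_switch_time(s)
    if t_switch is None:
        raise ValueError("glucose never depleted: no diauxic switch found")
    t = s["time"].to_numpy(dtype=float)

    if glucose0_mM is None:
        glucose0_mM = float(s["glucose_mM"].iloc[0])
    g0 = glucose0_mM * 1e-3  # mol/l
    consumed_total = max(g0 - float(s["glucose_mM"].iloc[-1]) * 1e-3, 0.0)
    if consumed_total <= 0:
        raise ValueError("no glucose was consumed: yields undefined")

    # Acetate peaks at the moment of glucose depletion.  Pair acetate and
    # consumed glucose at the last sample before depletion: during the
    # glucose phase their ratio is the overflow ratio at every sample, so
    # this pairing is exact regardless of how the sampling grid falls
    # relative to the switch (the raw acetate maximum may already sit on
    # the falling, acetate-consuming side).
    ace = s["acetate_mM"].to_numpy(dtype=float)
    glc = s["glucose_mM"].to_numpy(dtype=float)
    pre_switch = np.nonzero(t < t_switch)[0]
    i_peak = int(pre_switch[-1]) if pre_switch.size else int(np.argmax(ace))
    ace_peak = float(ace[i_peak]) * 1e-3
    consumed_at_peak = max(g0 - float(glc[i_peak]) * 1e-3, 0.0)
    if consumed_at_peak <= 0:
        raise ValueError("no glucose consumed by the acetate peak")
    acetate_per_glucose = ace_peak / consumed_at_peak

    stationary = s[s["time"] >= t_switch + stationary_offset]
    if stationary.empty:
        stationary = s.tail(max(len(s) // 10, 1))
    counts0 = float(s["counts_ml"].iloc[0]) * 1e3  # per liter
    counts_final = float(stationary["counts_ml"].mean()) * 1e3
    count_yield = (counts_final - counts0) / consumed_total

    od0 = float(s["od"].iloc[0])
    od_final = float(stationary["od"].mean())
    od_yield = (od_final - od0) / consumed_total

    exp_window = s[s["time"] <= 0.8 * t_switch]
    v_exp = float(exp_window["volume_um3"].mean())
    v_stat = float(stationary["volume_um3"].mean())

    mu_g_hat = estimate_growth_rate(
        s, window=rate_window, phase_window=(0.0, t_switch)
    )
    # acetate phase: from the switch until acetate is (nearly) gone
    after = s[s["time"] > t_switch]
    ace = after["acetate_mM"].to_numpy(dtype=float)
    depleted = np.nonzero(ace < 0.01 * max(ace_peak * 1e3, 1e-12))[0]
    t_ace_end = (
        float(after["time"].to_numpy()[depleted[0]])
        if depleted.size
        else float(t[-1])
    )
    try:
        mu_a_hat = estimate_growth_rate(
            s, window=rate_window, phase_window=(t_switch, t_ace_end)
        )
    except ValueError:
        mu_a_hat = math.nan

    return PhaseEstimates(
        mu_g_hat=mu_g_hat,
        mu_a_hat=mu_a_hat,
        t_switch=float(t_switch),
        od_yield=od_yield,
        count_yield=count_yield,
        acetate_per_glucose=acetate_per_glucose,
        v_exp=v_exp,
        v_stat=v_stat,
    )


def analyze_replicates(table: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Per-replicate :func:`compute_yields` for a (possibly multi-strain) table.

    Returns one row per (strain, replicate) with the PhaseEstimates fields
    as columns.
    """
    rows = []
    for (strain, rep), sub in table.groupby(["strain", "replicate"]):
        est = compute_yields(sub, **kwargs)
        rows.append({"strain": strain, "replicate": rep, **est.__dict__})
    return pd.DataFrame(rows)


_METRICS = [f.name for f in fields(PhaseEstimates)]


def compare_strains(
    a: pd.DataFrame, b: pd.DataFrame, metrics: list[str] | None = None
) -> StrainComparison:
    """Percent differences of strain b relative to reference strain a.

    Both inputs are per-replicate estimate tables as produced by
    :func:`analyze_replicates`.  For every metric the comparison reports
    100 * (mean_b / mean_a - 1), the standard deviation of the
    per-replicate percent differences, and the two-sided Welch t-test
    p-value.  With fewer than two replicates on either side the p-value is
    NaN (flagged, not fatal).
    """
    metrics = metrics or [m for m in _METRICS if m in a.columns and m in b.columns]
    if len(a) < 1 or len(b) < 1:
        raise ValueError("each strain needs at least one replicate")
    rows = {}
    for m in metrics:
        xa = a[m].to_numpy(dtype=float)
        xb = b[m].to_numpy(dtype=float)
        ref = float(np.mean(xa))
        pct = 100.0 * (float(np.mean(xb)) / ref - 1.0)
        sd = float(np.std(100.0 * (xb / ref - 1.0), ddof=1)) if len(xb) > 1 else math.nan
        if len(xa) > 1 and len(xb) > 1:
            with warnings.catch_warnings():
                # identical samples trigger a harmless precision warning
                warnings.simplefilter("ignore", RuntimeWarning)
                p = float(stats.ttest_ind(xa, xb, equal_var=False).pvalue)
            if math.isnan(p) and np.allclose(xa, xb):
                p = 1.0
        else:
            p = math.nan
        rows[m] = {"percent_diff": pct, "sd": sd, "p_value": p}
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "metric"
    return StrainComparison(table=table, n_a=len(a), n_b=len(b))
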