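"""Growth-fitness estimation from OD600 curves and serial-transfer logs.

The per-interval rate is r_i = ln(C_{i+1}/C_i)/(t_{i+1}-t_i) between
consecutive plate-reader points; the reported rate is the mean of the best
window of three consecutive r_i (largest mean whose coefficient of variation
passes a threshold). Serial-transfer generations follow
G = log2(Nt/N0) per day, with companion rate mu = ln(Nt/N0)/dt.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "GrowthCurve",
    "GrowthEstimate",
    "TransferLog",
    "rate_segments",
    "select_rate_window",
    "carrying_capacity",
    "estimate_growth",
    "generations",
    "compare_growth",
]


@dataclass(frozen=True)
class GrowthCurve:
    """An OD600 time series for one well/replicate."""

    times: np.ndarray  # hours, strictly increasing
    od: np.ndarray  # OD600, > 0
    replicate: str = ""
    lineage: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.od, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "od", c)
        if t.ndim != 1 or c.shape != t.shape:
            raise ValueError("times and od must be 1-D arrays of equal length")
        if t.size < 4:
            raise ValueError("need at least 4 points (3 consecutive rates)")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(c <= 0):
            raise ValueError("OD values must be positive")


@dataclass(frozen=True)
class GrowthEstimate:
    rate: float  # per hour
    rate_window: tuple[int, int, int]  # indices into the rate series
    carrying_capacity: float  # OD600
    replicate: str = ""
    lineage: str = ""


@dataclass(frozen=True)
class TransferLog:
    """Per-day serial-transfer records."""

    day: np.ndarray
    dilution: np.ndarray
    od_start: np.ndarray  # N0
    od_end: np.ndarray  # Nt
    dt_hours: np.ndarray
    feasible: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.day)
        for name in ("dilution", "od_start", "od_end", "dt_hours"):
            if len(getattr(self, name)) != n:
                raise ValueError("all TransferLog columns must share one length")
        if self.feasible is None:
            object.__setattr__(self, "feasible", np.ones(n, dtype=bool))
        bad = set(np.unique(self.dilution)) - {10**3, 10**4, 10**5, 10**6}
        if bad:
            raise ValueError(f"dilution factors outside 10^3..10^6: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.day)


def rate_segments(curve: GrowthCurve) -> np.ndarray:
    """Per-interval rates r_i = ln(C_{i+1}/C_i)/(t_{i+1}-t_i).

    Length is one less than the number of points. Summing r_i*dt_i over any
    span telescopes to ln(C_end/C_start).
    """
    return np.diff(np.log(curve.od)) / np.diff(curve.times)


def select_rate_window(rates, cv_max: float = 0.2, penalty: float = 1.0):
    """Pick the best window of three consecutive rates.

    Among windows whose coefficient of variation (sample SD / mean) is at most
    *cv_max*, the one with the largest mean wins; ties go to the earliest.
    If no window passes the filter, the window maximizing mean - penalty*SD
    is used. Returns (rate, (i, i+1, i+2)) where rate is the window mean.
    """
    r = np.asarray(rates, dtype=float)
    if r.size < 3:
        raise ValueError("need at least 3 rates for a window")
    windows = np.lib.stride_tricks.sliding_window_view(r, 3)
    means = windows.mean(axis=1)
    sds = windows.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(means > 0, sds / means, np.inf)
    passing = cv <= cv_max
    if passing.any():
        idx = int(np.flatnonzero(passing)[np.argmax(means[passing])])
    else:
        idx = int(np.argmax(means - penalty * sds))
    return float(means[idx]), (idx, idx + 1, idx + 2)


def carrying_capacity(curve: GrowthCurve, top_k: int = 3) -> float:
    """Robust maximal population size: mean of the top-k OD readings."""
    od = np.asarray(curve.od, dtype=float)
    k = min(top_k, od.size)
    return float(np.sort(od)[-k:].mean())


def estimate_growth(curve: GrowthCurve, cv_max: float = 0.2,
                    penalty: float = 1.0, min_od: float = 0.0) -> GrowthEstimate:
    """Full per-curve estimate: windowed rate plus carrying capacity.

    *min_od* optionally excludes rate segments whose lower endpoint is below
    a trustworthy reading (0 keeps everything).
    """
    rates = rate_segments(curve)
    if min_od > 0:
        ok = np.minimum(curve.od[:-1], curve.od[1:]) >= min_od
        # finite sentinel keeps window statistics defined while making any
        # window touching an excluded segment unselectable
        masked = np.where(ok, rates, -1e6)
    else:
        masked = rates
    rate, window = select_rate_window(masked, cv_max=cv_max, penalty=penalty)
    return GrowthEstimate(
        rate=rate,
        rate_window=window,
        carrying_capacity=carrying_capacity(curve),
        replicate=curve.replicate,
        lineage=curve.lineage,
    )


def generations(log: TransferLog):
    """Per-day generations G = log2(Nt/N0), cumulative sum, and rates mu.

    Returns (cumulative_G, per_day_G, per_day_mu).
    """
    n0 = np.asarray(log.od_start, dtype=float)
    nt = np.asarray(log.od_end, dtype=float)
    if np.any(n0 <= 0) or np.any(nt <= 0):
        raise ValueError("OD values in the transfer log must be positive")
    ratio = nt / n0
    g = np.log2(ratio)
    mu = np.log(ratio) / np.asarray(log.dt_hours, dtype=float)
    return np.cumsum(g), g, mu


def compare_growth(group_a, group_b, paired_rates=None, paired_capacities=None):
    """Two-sided Mann-Whitney U between two groups, plus optional Spearman.

    If *paired_rates*/*paired_capacities* are given (equal-length vectors),
    also returns Spearman's rho and p for the rate-versus-capacity relation.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    u = stats.mannwhitneyu(a, b, alternative="two-sided")
    out = {"U": float(u.statistic), "p_mannwhitney": float(u.pvalue)}
    if paired_rates is not None and paired_capacities is not None:
        x = np.asarray(list(paired_rates), dtype=float)
        y = np.asarray(list(paired_capacities), dtype=float)
        if x.shape != y.shape:
            raise ValueError("paired vectors must have equal length")
        rho = stats.spearmanr(x, y)
        out["spearman_rho"] = float(rho.statistic)
        out["p_spearman"] = float(rho.pvalue)
    return out
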