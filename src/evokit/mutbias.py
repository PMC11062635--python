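"""Fixed-mutation summaries and the scar-distance randomization test.

The locational-bias test draws, for each of ``n_replicates`` replicates, as
many uniform random positions as there are observed mutations, computes the
distance from every position to the nearest deletion-scar junction, and runs
a two-sided Welch's t-test of random-versus-observed distances. The mean of
the replicate p-values (mu_p) with a normal-approximation 95% interval is the
decision statistic: mu_p > 0.05 reads as "no locational bias".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MutationRecord",
    "RandomizationResult",
    "EssentialityResult",
    "summarize_mutations",
    "distance_to_nearest_scar",
    "circular_distances",
    "welch_t",
    "randomization_test",
    "calibration_pvalues",
    "essentiality_ratio_test",
    "normalized_positions",
]

_CLASSES = {"SNP", "indel", "structural"}
_CONTEXTS = {"genic", "intergenic"}
_EFFECTS = {"nonsynonymous", "synonymous", None}

SUMMARY_COLUMNS = ["all", "intergenic", "genic_indel", "genic_snp", "N", "S"]


@dataclass(frozen=True)
class MutationRecord:
    """One fixed mutation with its classification.

    ``effect`` is only meaningful for genic SNPs and must be None otherwise.
    ``position`` is the leftmost affected coordinate (1-based).
    """

    lineage: str
    position: int
    mclass: str = "SNP"
    context: str = "genic"
    effect: str | None = None
    gene: str | None = None
    essential: bool | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position must be >= 1 (1-based coordinates)")
        if self.mclass not in _CLASSES:
            raise ValueError(f"unknown mutation class {self.mclass!r}")
        if self.context not in _CONTEXTS:
            raise ValueError(f"unknown context {self.context!r}")
        if self.effect not in _EFFECTS:
            raise ValueError(f"unknown coding effect {self.effect!r}")
        if self.effect is not None and not (
            self.mclass == "SNP" and self.context == "genic"
        ):
            raise ValueError("coding effect applies only to genic SNPs")


def summarize_mutations(records, lineages=None) -> pd.DataFrame:
    """Per-lineage counts (all / intergenic / genic indel / genic SNP / N / S)
    plus a ``Sum`` row.

    *lineages* optionally restricts and validates the admissible lineage ids;
    a record with a lineage outside the list is an error.
    """
    records = list(records)
    if lineages is None:
        lineages = sorted({r.lineage for r in records})
    else:
        lineages = list(lineages)
        known = set(lineages)
        for r in records:
            if r.lineage not in known:
                raise ValueError(f"unknown lineage id {r.lineage!r}")
    counts = {lin: dict.fromkeys(SUMMARY_COLUMNS, 0) for lin in lineages}
    for r in records:
        row = counts[r.lineage]
        row["all"] += 1
        if r.context == "intergenic":
            row["intergenic"] += 1
        elif r.mclass == "indel":
            row["genic_indel"] += 1
        elif r.mclass == "SNP":
            row["genic_snp"] += 1
            if r.effect == "nonsynonymous":
                row["N"] += 1
            elif r.effect == "synonymous":
                row["S"] += 1
        # genic structural events stay uncategorized beyond "all"
    table = pd.DataFrame.from_dict(counts, orient="index",
                                   columns=SUMMARY_COLUMNS).loc[list(lineages)]
    table.loc["Sum"] = table.sum(axis=0)
    return table


def circular_distances(positions, scars, length, circular=True) -> np.ndarray:
    """Distance from each position to its nearest scar junction.

    Circular arc distance min(|p-s|, L-|p-s|) by default; plain |p-s| when
    *circular* is False.
    """
    p = np.atleast_1d(np.asarray(positions, dtype=np.int64))
    s = np.asarray(scars, dtype=np.int64)
    if s.size == 0:
        raise ValueError("scar set must be non-empty")
    d = np.abs(p[..., None] - s)
    if circular:
        d = np.minimum(d, length - d)
    return d.min(axis=-1)


def distance_to_nearest_scar(position, layout, circular=True) -> int:
    """Distance (bp) from one position to the nearest scar of *layout*."""
    if not (1 <= position <= layout.length):
        raise ValueError(f"position {position} outside [1, {layout.length}]")
    return int(circular_distances(position, layout.scar_array, layout.length,
                                  circular=circular)[0])


def welch_t(a, b):
    """Welch's unequal-variance t-test, two-sided.

    Returns (t, df, p) with df from the Welch-Satterthwaite approximation.
    Degenerate inputs (zero variance in both samples) give p=1 when the means
    agree and p=0 otherwise.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    diff = a.mean() - b.mean()
    if se2 == 0.0:
        if diff == 0.0:
            return 0.0, float(na + nb - 2), 1.0
        return math.copysign(math.inf, diff), float(na + nb - 2), 0.0
    t = diff / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(min(p, 1.0))


@dataclass(frozen=True)
class RandomizationResult:
    observed_distances: np.ndarray
    p_values: np.ndarray
    mu_p: float
    ci95: tuple[float, float]
    n_replicates: int
    seed: int
    sidedness: str = "two-sided"

    @property
    def biased(self) -> bool:
        """Locational bias called iff mu_p <= 0.05."""
        return self.mu_p <= 0.05

    @property
    def verdict(self) -> str:
        return "locational bias" if self.biased else "no locational bias"

    def to_dict(self) -> dict:
        return {
            "mu_p": self.mu_p,
            "ci95": list(self.ci95),
            "n_replicates": self.n_replicates,
            "seed": self.seed,
            "sidedness": self.sidedness,
            "verdict": self.verdict,
            "observed_distances": [int(d) for d in self.observed_distances],
            "p_values": [float(p) for p in self.p_values],
        }


def _welch_p_rows(rows: np.ndarray, obs: np.ndarray) -> np.ndarray:
    """Vectorized two-sided Welch p-values of each row of *rows* vs *obs*."""
    na = rows.shape[1]
    nb = obs.size
    ma = rows.mean(axis=1)
    va = rows.var(axis=1, ddof=1)
    mb = obs.mean()
    vb = obs.var(ddof=1)
    se2 = va / na + vb / nb
    diff = ma - mb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(se2 == 0.0, np.where(diff == 0.0, 1.0, 0.0), p)
    return np.minimum(p, 1.0)


def randomization_test(observed, layout, n_replicates: int = 1000, seed: int = 0,
                       circular: bool = True) -> RandomizationResult:
    """Monte-Carlo test for locational bias of mutations relative to scars.

    *observed* may be MutationRecords or raw positions. Each replicate draws
    the same number of uniform positions on the genome, computes
    nearest-scar distances and a two-sided Welch's t-test against the
    observed distances; mu_p is the mean of the replicate p-values with a
    normal-approximation 95% interval.
    """
    positions = np.asarray(
        [m.position if isinstance(m, MutationRecord) else int(m) for m in observed],
        dtype=np.int64,
    )
    if positions.size < 2:
        raise ValueError("need at least 2 observed mutations")
    if not layout.scars:
        raise ValueError("layout has no scars")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")

    scars = layout.scar_array
    obs_d = circular_distances(positions, scars, layout.length, circular).astype(float)

    rng = np.random.default_rng(seed)
    rand_pos = rng.integers(1, layout.length + 1,
                            size=(n_replicates, positions.size))
    rand_d = circular_distances(rand_pos, scars, layout.length, circular).astype(float)
    p = _welch_p_rows(rand_d, obs_d)

    mu_p = float(p.mean())
    half = 1.96 * float(p.std(ddof=1)) / math.sqrt(n_replicates) if n_replicates > 1 else 0.0
    return RandomizationResult(
        observed_distances=obs_d.astype(np.int64),
        p_values=p,
        mu_p=mu_p,
        ci95=(mu_p - half, mu_p + half),
        n_replicates=int(n_replicates),
        seed=int(seed),
    )


def calibration_pvalues(layout, n_mutations: int, n_pairs: int = 2000,
                        seed: int = 0, circular: bool = True) -> np.ndarray:
    """Null calibration of the locational-bias test.

    Draws *n_pairs* independent (observed, random) pairs of uniform mutation
    sets and returns one Welch p-value per pair. When both sides come from
    the null these p-values are approximately Uniform(0, 1) — unlike the
    replicate p-values of :func:`randomization_test`, which share a single
    fixed observed sample and are therefore conservative by construction.
    """
    if n_mutations < 2:
        raise ValueError("need at least 2 mutations per draw")
    if not layout.scars:
        raise ValueError("layout has no scars")
    rng = np.random.default_rng(seed)
    scars = layout.scar_array
    shape = (n_pairs, n_mutations)
    d_obs = circular_distances(rng.integers(1, layout.length + 1, size=shape),
                               scars, layout.length, circular).astype(float)
    d_rand = circular_distances(rng.integers(1, layout.length + 1, size=shape),
                                scars, layout.length, circular).astype(float)
    res = stats.ttest_ind(d_rand, d_obs, axis=1, equal_var=False)
    return np.minimum(np.asarray(res.pvalue, dtype=float), 1.0)


@dataclass(frozen=True)
class EssentialityResult:
    ratio_mut: float  # percent
    ratio_all: float  # percent
    chi2: float
    p: float
    chi2_corrected: float
    p_corrected: float
    warnings: tuple[str, ...] = ()


def essentiality_ratio_test(k_ess_mut: int, n_mut: int, K_ess: int,
                            N_genes: int) -> EssentialityResult:
    """2x2 chi-square of essential-gene ratio in mutated vs all genes.

    Both the plain Pearson statistic and the Yates-corrected one are reported;
    ratios are percentages. Degenerate margins give chi2=0, p=1 with a
    warning, as does any expected cell below 1.
    """
    if not (0 <= k_ess_mut <= n_mut <= N_genes and k_ess_mut <= K_ess <= N_genes):
        raise ValueError("counts must satisfy k <= n <= N and k <= K <= N")
    warnings: list[str] = []
    table = np.array(
        [
            [k_ess_mut, n_mut - k_ess_mut],
            [K_ess - k_ess_mut, (N_genes - n_mut) - (K_ess - k_ess_mut)],
        ],
        dtype=float,
    )
    ratio_mut = 100.0 * k_ess_mut / n_mut if n_mut else float("nan")
    ratio_all = 100.0 * K_ess / N_genes if N_genes else float("nan")
    if np.any(table < 0):
        raise ValueError("inconsistent counts produce a negative cell")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        warnings.append("degenerate margin: chi-square undefined, p set to 1")
        return EssentialityResult(ratio_mut, ratio_all, 0.0, 1.0, 0.0, 1.0,
                                  tuple(warnings))
    expected = stats.contingency.expected_freq(table)
    if np.any(expected < 1.0):
        warnings.append("expected cell count below 1; chi-square unreliable")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    chi2c, pc, _, _ = stats.chi2_contingency(table, correction=True)
    return EssentialityResult(ratio_mut, ratio_all, float(chi2), float(p),
                              float(chi2c), float(pc), tuple(warnings))


def normalized_positions(records, layout) -> np.ndarray:
    """Positions as fractions of genome length in [0, 1)."""
    pos = np.asarray(
        [m.position if isinstance(m, MutationRecord) else int(m) for m in records],
        dtype=float,
    )
    return (pos - 1.0) / layout.length
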