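"""Synthetic input generation for the analysis pipeline.

Everything downstream (growth fitting, mutation-location tests, periodicity
analysis, enrichment) consumes plain tables; this module fabricates those
tables with the statistical structure the analyses assume: a circular reduced
genome carrying deletion-scar junctions, mutation sets placed under a uniform
null or a scar-attracted alternative, logistic plate-reader OD curves, daily
serial-transfer records, and expression profiles carrying a sinusoidal
chromosomal signal plus noise.

Coordinates are 1-based inclusive on a circular chromosome throughout.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SimConfig",
    "Gene",
    "GenomeLayout",
    "InfeasibleLayoutError",
    "gen_genome_layout",
    "gen_mutations",
    "gen_growth_curve",
    "gen_expression_profile",
    "gen_serial_transfer_log",
    "DEFAULT_CATEGORIES",
    "OD_DETECTION_FLOOR",
]

#: Plate readers have a noise floor; OD values below this are clamped so that
#: log-ratios stay defined.
OD_DETECTION_FLOOR = 1e-3

#: Fraction of genes flagged essential (286 of 3290 in the reduced genome).
ESSENTIAL_FRACTION = 286 / 3290

DEFAULT_CATEGORIES = (
    "Transporter",
    "Enzyme",
    "Unknown function",
    "Regulator",
    "Membrane",
    "Carrier",
    "Factor",
    "Structural component",
    "RNA",
    "Cell process",
    "Phenotype",
    "DNA replication",
    "Transcription",
    "Translation",
)

# Fixed offsets separating per-generator random streams derived from one seed.
_STREAM_LAYOUT = 0
_STREAM_MUTATION = 1
_STREAM_GROWTH = 2
_STREAM_EXPRESSION = 3
_STREAM_TRANSFER = 4


class InfeasibleLayoutError(ValueError):
    """Requested gene complement cannot fit on the genome."""


@dataclass(frozen=True)
class SimConfig:
    """Knobs for all generators; one seed, per-generator derived streams."""

    seed: int = 0
    genome_length: int = 3_670_000
    n_genes: int = 3290
    n_scars: int = 30
    n_mutations: int = 65
    n_lineages: int = 9
    od_interval: float = 30.0  # minutes
    od_duration: float = 48.0  # hours
    noise_sd: float = 0.2  # expression log-units
    period_count: int = 6
    amplitude: float = 0.2  # expression log-units
    bias_scale: float = 10_000.0  # bp, scar-attraction scale

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if self.n_scars < 0 or self.n_mutations < 0:
            raise ValueError("n_scars and n_mutations must be non-negative")
        if self.od_interval <= 0 or self.od_duration <= 0:
            raise ValueError("od_interval and od_duration must be positive")
        n_steps = self.od_duration * 60.0 / self.od_interval
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ValueError("od_interval must divide od_duration evenly")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng((int(self.seed), int(stream)))

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class Gene:
    gene_id: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive, start <= end
    strand: str
    essential: bool
    category: str
    regulons: tuple[str, ...] = ()

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GenomeLayout:
    """Circular genome: length, scar junction positions, gene coordinates.

    Scars are point junctions (the residual boundary of a deletion), not
    intervals — the reduced genome no longer contains the deleted span.
    """

    length: int
    circular: bool = True
    scars: tuple[int, ...] = ()
    genes: tuple[Gene, ...] = ()

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("genome length must be positive")
        for s in self.scars:
            if not (1 <= s <= self.length):
                raise ValueError(f"scar position {s} outside [1, {self.length}]")
        if list(self.scars) != sorted(self.scars):
            raise ValueError("scar list must be sorted ascending")
        seen: set[str] = set()
        for g in self.genes:
            if not (1 <= g.start <= g.end <= self.length):
                raise ValueError(f"gene {g.gene_id} outside genome bounds")
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene id {g.gene_id}")
            seen.add(g.gene_id)

    @property
    def scar_array(self) -> np.ndarray:
        return np.asarray(self.scars, dtype=np.int64)

    def gene_at(self, position: int) -> Gene | None:
        """Gene whose [start, end] interval contains *position*, else None."""
        starts = np.fromiter((g.start for g in self.genes), dtype=np.int64,
                             count=len(self.genes))
        idx = int(np.searchsorted(starts, position, side="right")) - 1
        if idx >= 0 and self.genes[idx].end >= position:
            return self.genes[idx]
        return None


def gen_genome_layout(cfg: SimConfig) -> GenomeLayout:
    """Draw a circular genome layout: uniform scars, non-overlapping genes.

    Gene lengths are uniform around 1 kb; gaps between genes are distributed
    randomly. Roughly 8.7% of genes are flagged essential.
    """
    rng = cfg.rng(_STREAM_LAYOUT)
    L = cfg.genome_length

    scars = tuple(sorted(int(p) for p in rng.integers(1, L + 1, size=cfg.n_scars)))

    n = cfg.n_genes
    genes: list[Gene] = []
    if n > 0:
        lengths = rng.integers(700, 1301, size=n)
        total = int(lengths.sum())
        if total > L:
            raise InfeasibleLayoutError(
                f"total gene span {total} bp exceeds genome length {L} bp"
            )
        slack = L - total
        # n+1 random gap sizes summing to the slack (stars and bars).
        cuts = np.sort(rng.integers(0, slack + 1, size=n))
        gaps = np.diff(np.concatenate([[0], cuts, [slack]]))
        essential = rng.random(n) < ESSENTIAL_FRACTION
        strands = rng.choice(["+", "-"], size=n)
        categories = rng.choice(DEFAULT_CATEGORIES, size=n)
        regulon_pool = [f"R{i:02d}" for i in range(1, 47)]
        n_reg = rng.integers(0, 3, size=n)
        pos = 1
        for i in range(n):
            pos += int(gaps[i])
            start = pos
            end = start + int(lengths[i]) - 1
            pos = end + 1
            regs = tuple(rng.choice(regulon_pool, size=int(n_reg[i]), replace=False))
            genes.append(
                Gene(
                    gene_id=f"g{i + 1:04d}",
                    start=start,
                    end=end,
                    strand=str(strands[i]),
                    essential=bool(essential[i]),
                    category=str(categories[i]),
                    regulons=regs,
                )
            )
    return GenomeLayout(length=L, circular=True, scars=scars, genes=tuple(genes))


def gen_mutations(layout, n, model="null", bias_scale=10_000.0, seed=0,
                  lineage="sim"):
    """Place *n* mutations on the genome and classify them against genes.

    model="null": positions i.i.d. uniform on [1, length].
    model="scar_biased": a random scar plus a signed exponential offset of
    scale *bias_scale*, wrapped on the circle — used for power checks.

    Returns a list of :class:`evokit.mutbias.MutationRecord`.
    """
    from .mutbias import MutationRecord

    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng((int(seed), _STREAM_MUTATION))
    L = layout.length
    if model == "null":
        positions = rng.integers(1, L + 1, size=n)
    elif model == "scar_biased":
        if not layout.scars:
            raise ValueError("scar_biased placement requires at least one scar")
        anchors = rng.choice(layout.scar_array, size=n)
        offsets = rng.exponential(scale=bias_scale, size=n) if bias_scale > 0 else np.zeros(n)
        signs = rng.choice([-1.0, 1.0], size=n)
        positions = ((anchors - 1 + np.rint(signs * offsets).astype(np.int64)) % L) + 1
    else:
        raise ValueError(f"unknown placement model: {model!r}")

    classes = rng.choice(["SNP", "indel"], size=n, p=[0.8, 0.2])
    # nonsynonymous fraction among genic SNPs mirrors the observed 36/45
    nonsyn = rng.random(n) < 0.8
    records = []
    for i in range(int(n)):
        pos = int(positions[i])
        gene = layout.gene_at(pos)
        context = "genic" if gene is not None else "intergenic"
        mclass = str(classes[i])
        if mclass == "SNP" and context == "genic":
            effect = "nonsynonymous" if nonsyn[i] else "synonymous"
        else:
            effect = None
        records.append(
            MutationRecord(
                lineage=lineage,
                position=pos,
                mclass=mclass,
                context=context,
                effect=effect,
                gene=gene.gene_id if gene is not None else None,
                essential=gene.essential if gene is not None else None,
            )
        )
    return records


def logistic_od(t_hours, r, K, od0):
    """Closed-form logistic trajectory od(t) = K·od0·e^{rt} / (K + od0(e^{rt}−1))."""
    t = np.asarray(t_hours, dtype=float)
    e = np.exp(r * t)
    return K * od0 * e / (K + od0 * (e - 1.0))


def gen_growth_curve(r_true, K, od0, noise_sd, cfg: SimConfig, seed=None,
                     replicate="r1", lineage="sim"):
    """Logistic OD600 trajectory sampled on the plate-reader grid plus noise.

    Gaussian noise is additive in OD units and the result is clamped at the
    detection floor (1e-3).
    """
    from .growth import GrowthCurve

    if r_true <= 0 or K <= 0 or od0 <= 0:
        raise ValueError("r_true, K and od0 must be positive")
    if K <= od0:
        raise ValueError("carrying capacity K must exceed od0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng((int(seed), _STREAM_GROWTH))
    step_h = cfg.od_interval / 60.0
    n_steps = int(round(cfg.od_duration / step_h))
    times = np.arange(n_steps + 1) * step_h
    od = logistic_od(times, r_true, K, od0)
    if noise_sd > 0:
        od = od + rng.normal(0.0, noise_sd, size=od.shape)
    od = np.maximum(od, OD_DETECTION_FLOOR)
    return GrowthCurve(times=times, od=od, replicate=replicate, lineage=lineage)


def gen_expression_profile(layout, period_count=6, amplitude=0.2, phase=0.0,
                           baseline=1.0, noise_sd=0.2, seed=0, sample="sim"):
    """Per-gene log-expression with a chromosomal sinusoid plus Gaussian noise.

    value = baseline + amplitude·sin(2π·period_count·(midpoint+phase)/L) + ε
    """
    from .periodicity import ExpressionProfile

    if period_count < 0:
        raise ValueError("period_count must be >= 0")
    rng = np.random.default_rng((int(seed), _STREAM_EXPRESSION))
    mids = np.array([g.midpoint for g in layout.genes])
    L = layout.length
    signal = baseline + amplitude * np.sin(
        2.0 * np.pi * period_count * (mids + phase) / L
    )
    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, size=signal.shape)
    return ExpressionProfile(
        gene_ids=tuple(g.gene_id for g in layout.genes),
        starts=np.array([g.start for g in layout.genes], dtype=np.int64),
        ends=np.array([g.end for g in layout.genes], dtype=np.int64),
        values=signal,
        sample=sample,
        genome_length=L,
    )


_ALLOWED_DILUTIONS = (10**3, 10**4, 10**5, 10**6)
_TRANSFER_WINDOW = (0.01, 0.1)  # target OD600 window at transfer


def gen_serial_transfer_log(r_true_schedule, dilutions=_ALLOWED_DILUTIONS,
                            cfg: SimConfig | None = None, seed=0, K=1.0,
                            interval_hours=24.0, od_init=None):
    """Daily dilute-and-regrow records emulating a serial-transfer regime.

    Each day the previous culture is diluted by one of the allowed tenfold
    factors and regrown for *interval_hours* at that day's rate; the dilution
    whose endpoint OD lands closest to the 0.01–0.1 transfer window is kept.
    Days where no dilution can reach the window are flagged infeasible, not
    fatal.

    Returns an :class:`evokit.growth.TransferLog`.
    """
    from .growth import TransferLog

    rates = np.asarray(list(r_true_schedule), dtype=float)
    if rates.size == 0:
        raise ValueError("rate schedule must be non-empty")
    dilutions = tuple(int(d) for d in dilutions)
    if not dilutions or any(d not in _ALLOWED_DILUTIONS for d in dilutions):
        raise ValueError(f"dilutions must come from {_ALLOWED_DILUTIONS}")

    lo, hi = _TRANSFER_WINDOW
    target = math.sqrt(lo * hi)
    prev_od = K if od_init is None else float(od_init)
    days, chosen, od_start, od_end, feasible = [], [], [], [], []
    for day, r in enumerate(rates, start=1):
        best = None
        for d in dilutions:
            n0 = max(prev_od / d, OD_DETECTION_FLOOR * 1e-3)
            nt = float(logistic_od(interval_hours, r, K, n0))
            score = abs(math.log(nt / target))
            if best is None or score < best[0]:
                best = (score, d, n0, nt)
        _, d, n0, nt = best
        days.append(day)
        chosen.append(d)
        od_start.append(n0)
        od_end.append(nt)
        feasible.append(lo <= nt <= hi)
        prev_od = nt
    return TransferLog(
        day=np.array(days, dtype=np.int64),
        dilution=np.array(chosen, dtype=np.int64),
        od_start=np.array(od_start),
        od_end=np.array(od_end),
        dt_hours=np.full(len(days), float(interval_hours)),
        feasible=np.array(feasible, dtype=bool),
    )
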