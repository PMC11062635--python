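"""Binomial enrichment of gene sets against annotation backgrounds.

For each label with more than ``min_label_size`` members in the background,
the over-representation p-value is the upper binomial tail
P(X >= k | n, K/N); Bonferroni correction runs over the labels actually
tested. The hypergeometric tail and Benjamini-Hochberg correction are
available behind flags for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "GeneAnnotationMap",
    "EnrichmentResult",
    "binomial_enrichment",
    "overlap_table",
]


@dataclass(frozen=True)
class GeneAnnotationMap:
    """gene id -> labels, per annotation scheme, over a background universe."""

    universe: frozenset
    schemes: dict  # scheme name -> {gene id -> frozenset of labels}

    def __post_init__(self) -> None:
        for scheme, mapping in self.schemes.items():
            stray = set(mapping) - self.universe
            if stray:
                raise ValueError(
                    f"scheme {scheme!r} labels genes outside the universe: "
                    f"{sorted(stray)[:5]}"
                )

    @classmethod
    def from_records(cls, records, universe=None) -> "GeneAnnotationMap":
        """Build from (gene_id, scheme, label) triples."""
        schemes: dict[str, dict[str, set]] = {}
        seen = set()
        for gene, scheme, label in records:
            seen.add(gene)
            schemes.setdefault(scheme, {}).setdefault(gene, set()).add(label)
        uni = frozenset(universe) if universe is not None else frozenset(seen)
        frozen = {
            s: {g: frozenset(ls) for g, ls in m.items()} for s, m in schemes.items()
        }
        return cls(universe=uni, schemes=frozen)

    def label_sets(self, scheme: str) -> dict:
        """label -> set of genes carrying it (within the universe)."""
        out: dict[str, set] = {}
        for gene, labels in self.schemes[scheme].items():
            for lab in labels:
                out.setdefault(lab, set()).add(gene)
        return out


@dataclass(frozen=True)
class EnrichmentResult:
    label: str
    k: int  # hits in query
    n: int  # query size
    K: int  # label size in background
    N: int  # universe size
    p_raw: float
    p_adjusted: float
    direction: str  # over | under

    @property
    def expected(self) -> float:
        return self.n * self.K / self.N


def binomial_enrichment(query, annot: GeneAnnotationMap, scheme: str,
                        min_label_size: int = 15, correction: str = "bonferroni",
                        test: str = "binomial"):
    """Enrichment of *query* genes for each sufficiently large label.

    Labels with background size strictly greater than *min_label_size* are
    tested; p_raw is the one-sided tail in the direction of the observed
    deviation (binomial by default, hypergeometric with ``test="hypergeom"``).
    Results come back sorted by adjusted p-value.
    """
    query = set(query)
    if not query:
        raise ValueError("query gene set is empty")
    stray = query - annot.universe
    if stray:
        raise ValueError(f"query gene(s) outside the universe: {sorted(stray)[:5]}")
    if scheme not in annot.schemes:
        raise ValueError(f"unknown annotation scheme {scheme!r}")
    if correction not in {"bonferroni", "bh"}:
        raise ValueError("correction must be 'bonferroni' or 'bh'")
    if test not in {"binomial", "hypergeom"}:
        raise ValueError("test must be 'binomial' or 'hypergeom'")

    N = len(annot.universe)
    n = len(query)
    labels = {
        lab: genes
        for lab, genes in annot.label_sets(scheme).items()
        if len(genes) > min_label_size
    }
    m_tests = len(labels)
    results = []
    for lab in sorted(labels):
        genes = labels[lab]
        K = len(genes)
        k = len(query & genes)
        if test == "binomial":
            p_over = float(stats.binom.sf(k - 1, n, K / N))
            p_under = float(stats.binom.cdf(k, n, K / N))
        else:
            p_over = float(stats.hypergeom.sf(k - 1, N, K, n))
            p_under = float(stats.hypergeom.cdf(k, N, K, n))
        if k >= n * K / N:
            direction, p_raw = "over", p_over
        else:
            direction, p_raw = "under", p_under
        results.append(
            {"label": lab, "k": k, "n": n, "K": K, "N": N,
             "p_raw": min(p_raw, 1.0), "direction": direction}
        )

    if correction == "bonferroni":
        for r in results:
            r["p_adjusted"] = min(1.0, r["p_raw"] * m_tests)
    else:  # Benjamini-Hochberg over the tested labels
        order = np.argsort([r["p_raw"] for r in results])
        adj = np.empty(m_tests)
        prev = 1.0
        for rank_rev, idx in enumerate(order[::-1]):
            rank = m_tests - rank_rev
            val = min(prev, results[idx]["p_raw"] * m_tests / rank)
            adj[idx] = val
            prev = val
        for r, a in zip(results, adj):
            r["p_adjusted"] = float(a)

    out = [EnrichmentResult(**r) for r in results]
    out.sort(key=lambda r: (r.p_adjusted, r.p_raw, r.label))
    return out


def overlap_table(sets: dict):
    """Intersection sizes for every combination of >= 2 named sets, plus a
    per-gene multiplicity histogram (how many sets each gene appears in).

    Returns (combos, multiplicity) where combos maps tuples of set names to
    the size of their common intersection and multiplicity maps each gene to
    its membership count.
    """
    from itertools import combinations

    names = list(sets)
    if len(names) < 2:
        raise ValueError("need at least 2 sets")
    sets = {k: set(v) for k, v in sets.items()}
    combos: dict[tuple, int] = {}
    for r in range(2, len(names) + 1):
        for group in combinations(names, r):
            common = set.intersection(*(sets[g] for g in group))
            combos[group] = len(common)
    multiplicity: dict = {}
    for name in names:
        for gene in sets[name]:
            multiplicity[gene] = multiplicity.get(gene, 0) + 1
    return combos, multiplicity
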