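"""Hypergeometric enrichment statistics.

Covers three related questions: is a pathway enriched for highlighted
genes; how well does the pathway/PPI candidate extension recover genes
independently reported for the same disease (coverage); and how much more
often do highlighted genes carry prior literature support than genes
picked by raw p-value ranking (enrichment ratio).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy import special, stats

from .weighting import adjust_multiple_testing

__all__ = [
    "EnrichmentResult",
    "hypergeom_upper_tail",
    "coverage_evaluation",
    "enrichment_ratio",
    "pathway_enrichment",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """Upper-tail hypergeometric test summary.

    population_N genes in total, marked_M of them flagged (e.g. reported
    in the literature), drawn_n highlighted, overlap_m in both.
    """

    population_N: int
    marked_M: int
    drawn_n: int
    overlap_m: int
    p_value: float

    def __post_init__(self) -> None:
        if self.overlap_m > min(self.marked_M, self.drawn_n):
            raise ValueError("overlap exceeds a margin")
        if self.drawn_n > self.population_N or self.marked_M > self.population_N:
            raise ValueError("margin exceeds population")


def hypergeom_upper_tail(N: int, M: int, n: int, m: int) -> float:
    """P(X >= m) for X ~ Hypergeometric(N, M, n), summed in log-space.

    N: population size; M: marked; n: drawn; m: observed overlap.
    """
    if not (0 <= m <= min(M, n) and n <= N and M <= N):
        raise ValueError(f"invalid hypergeometric arguments N={N} M={M} n={n} m={m}")
    if m == 0:
        return 1.0
    ks = np.arange(m, min(M, n) + 1)
    log_pmf = stats.hypergeom.logpmf(ks, N, M, n)
    return float(np.exp(special.logsumexp(log_pmf)))


def coverage_evaluation(
    extended: Iterable[str],
    reported: Iterable[str],
    population_N: int,
) -> tuple[float, EnrichmentResult]:
    """Coverage of independently reported genes by the extended set.

    Coverage (in percent) = |extended ∩ reported| / |extended|; the
    p-value asks whether that overlap beats random draws of the same size
    from a population of ``population_N`` genes.
    """
    ext = set(extended)
    rep = set(reported)
    if not ext:
        raise ValueError("coverage undefined for an empty extended set")
    if population_N < len(ext | rep):
        raise ValueError("population smaller than the union of gene sets")
    overlap = len(ext & rep)
    p = hypergeom_upper_tail(population_N, len(rep), len(ext), overlap)
    result = EnrichmentResult(
        population_N=population_N,
        marked_M=len(rep),
        drawn_n=len(ext),
        overlap_m=overlap,
        p_value=p,
    )
    return 100.0 * overlap / len(ext), result


def enrichment_ratio(
    hits_a: int, total_a: int, hits_b: int, total_b: int
) -> float:
    """Ratio of hit proportions, (hits_a/total_a) / (hits_b/total_b).

    Returns ``inf`` when the reference arm has zero hits.
    """
    if total_a <= 0 or total_b <= 0:
        raise ValueError("totals must be positive")
    if hits_b == 0:
        return float("inf")
    return (hits_a / total_a) / (hits_b / total_b)


def pathway_enrichment(
    highlighted: Iterable[str],
    pathways: Mapping[str, Iterable[str]],
    universe_size: int,
    q: float = 0.05,
    pathway_min: int = 2,
    pathway_max: int = 300,
) -> list[dict]:
    """Per-pathway hypergeometric enrichment with BH correction.

    Pathways outside the [pathway_min, pathway_max] size window are
    skipped before testing, mirroring the size filter of the candidate
    extension step.  ``universe_size`` is the number of genes eligible to
    be highlighted (e.g. all genes on the genotyping chip) and must be
    supplied explicitly.
    """
    hi = set(highlighted)
    rows = []
    for name in sorted(pathways):
        members = set(pathways[name])
        if not pathway_min <= len(members) <= pathway_max:
            continue
        overlap = len(hi & members)
        p = hypergeom_upper_tail(universe_size, len(members), len(hi), overlap) \
            if len(hi) <= universe_size and len(members) <= universe_size else 1.0
        rows.append({
            "pathway": name,
            "size": len(members),
            "overlap": overlap,
            "p_value": p,
        })
    if rows:
        reject, adj = adjust_multiple_testing(
            np.array([r["p_value"] for r in rows]), "bh", q
        )
        for r, flag, a in zip(rows, reject, adj):
            r["bh_adjusted_p"] = float(a)
            r["significant"] = bool(flag)
    return rows
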