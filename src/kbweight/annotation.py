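"""Functional annotation scoring and strong/weak clue-set classification.

SNPs are assigned putative disease-risk scores in three steps: a base score
from the SNP's gene-feature class (non-synonymous, splice site, intron, ...),
bonuses for promising non-gene features (cross-species conservation, positive
selection, microRNA binding sites), and a +3 candidate-gene bonus when the
SNP falls in, or near, a gene of the extended candidate set.  A cutoff
(default 4) then splits SNPs into a strong-clue set, eligible for favourable
p-value weights, and a weak-clue set.

The candidate set itself is grown from seed genes through shared biological
pathways (size-filtered) and proximity in the protein-protein interaction
(PPI) network.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureClass",
    "SnpAnnotation",
    "CandidateGeneSet",
    "RiskScoredSnp",
    "DEFAULT_BASE_SCORES",
    "DEFAULT_CUTOFF",
    "DEFAULT_CONSERVATION_THRESHOLD",
    "DEFAULT_SELECTION_THRESHOLD",
    "CANDIDATE_GENE_BONUS",
    "NON_GENE_BONUS",
    "UPSTREAM_WINDOW",
    "DOWNSTREAM_WINDOW",
    "extend_candidate_genes",
    "score_snp",
    "score_table",
    "classify_snps",
    "transfer_ld_scores",
    "assign_feature_classes",
]


class FeatureClass(str, Enum):
    """Gene-context class of a SNP."""

    NONSYNONYMOUS = "nonsynonymous"
    SPLICE_SITE = "splice_site"
    SYNONYMOUS = "synonymous"
    UTR = "utr"
    INTRON = "intron"
    UPSTREAM = "upstream"
    DOWNSTREAM = "downstream"
    INTERGENIC = "intergenic"


#: Base risk score per gene-feature class.  Coding-change classes score
#: highest; near-gene classes score 1 so that the +3 candidate-gene bonus
#: pushes any SNP in or near a candidate gene to the cutoff of 4.
DEFAULT_BASE_SCORES: dict[FeatureClass, int] = {
    FeatureClass.NONSYNONYMOUS: 3,
    FeatureClass.SPLICE_SITE: 3,
    FeatureClass.SYNONYMOUS: 2,
    FeatureClass.UTR: 2,
    FeatureClass.INTRON: 1,
    FeatureClass.UPSTREAM: 1,
    FeatureClass.DOWNSTREAM: 1,
    FeatureClass.INTERGENIC: 0,
}

DEFAULT_CUTOFF = 4
DEFAULT_CONSERVATION_THRESHOLD = 0.8
DEFAULT_SELECTION_THRESHOLD = 2.0
CANDIDATE_GENE_BONUS = 3
NON_GENE_BONUS = 2
#: 5' window (bp) upstream of a transcript still counted as near-gene.
UPSTREAM_WINDOW = 2000
#: 3' window (bp) downstream of a transcript still counted as near-gene.
DOWNSTREAM_WINDOW = 500


@dataclass(frozen=True)
class SnpAnnotation:
    """Per-SNP functional annotation record.

    ``conservation`` is a score in [0, 1] (phastCons-like); ``selection`` is
    an unbounded positive-selection score (iHS-like); both may be missing.
    ``gene`` is None exactly when the SNP is intergenic.
    """

    snp_id: str
    chrom: str
    pos: int
    feature_class: FeatureClass
    gene: str | None = None
    conservation: float | None = None
    selection: float | None = None
    mirna_site: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if (self.feature_class is FeatureClass.INTERGENIC) != (self.gene is None):
            raise ValueError(
                f"{self.snp_id}: feature_class intergenic <=> gene is None"
            )
        if self.conservation is not None and not 0.0 <= self.conservation <= 1.0:
            raise ValueError(
                f"{self.snp_id}: conservation {self.conservation} outside [0, 1]"
            )


@dataclass
class CandidateGeneSet:
    """Seed genes plus the pathway/PPI-extended candidate genes.

    ``provenance`` maps each extended gene to how it entered the set:
    ``"seed"``, ``"pathway"`` or ``"ppi"`` (seed wins on overlap).
    """

    seeds: frozenset[str]
    extended: frozenset[str]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.seeds <= self.extended:
            raise ValueError("seeds must be a subset of extended")

    def __contains__(self, gene: str) -> bool:
        return gene in self.extended


@dataclass(frozen=True)
class RiskScoredSnp:
    snp_id: str
    score: int
    clue_set: str  # "strong" | "weak"


def extend_candidate_genes(
    seeds: Iterable[str],
    pathways: Mapping[str, Iterable[str]],
    ppi_edges: Iterable[tuple[str, str]],
    ppi_depth: int = 2,
    pathway_min: int = 2,
    pathway_max: int = 300,
) -> CandidateGeneSet:
    """Grow the candidate gene set from seeds via pathways and the PPI net.

    A gene enters the extended set if it shares a pathway (of size within
    ``[pathway_min, pathway_max]``) with a seed, or lies within ``ppi_depth``
    edges of a seed in the PPI graph.  Pathways outside the size window are
    excluded entirely.  Seeds with no pathway or PPI record stay in the set
    but contribute no extension.

    Parameters
    ----------
    seeds
        Seed gene symbols (assumed disease-relevant a priori).
    pathways
        Mapping pathway name -> member gene symbols.
    ppi_edges
        Undirected gene-pair edges; duplicates and self-loops are collapsed.
    ppi_depth
        Maximum unweighted shortest-path distance from a seed (default 2,
        the two-level PPI neighbourhood).
    """
    if ppi_depth < 1:
        raise ValueError("ppi_depth must be >= 1")
    if pathway_min > pathway_max:
        raise ValueError("pathway_min must be <= pathway_max")

    seed_set = frozenset(seeds)
    provenance: dict[str, str] = {g: "seed" for g in sorted(seed_set)}
    extended: set[str] = set(seed_set)

    for name in sorted(pathways):
        members = set(pathways[name])
        if not pathway_min <= len(members) <= pathway_max:
            continue
        if members & seed_set:
            for g in sorted(members - extended):
                provenance[g] = "pathway"
            extended |= members

    graph = nx.Graph()
    for u, v in ppi_edges:
        if u != v:
            graph.add_edge(u, v)
    seeds_in_graph = seed_set & set(graph.nodes)
    if seed_set and not seeds_in_graph and graph.number_of_nodes():
        logger.warning("no seed gene appears in the PPI network")
    for seed in sorted(seeds_in_graph):
        reachable = nx.single_source_shortest_path_length(
            graph, seed, cutoff=ppi_depth
        )
        for g in sorted(set(reachable) - extended):
            provenance[g] = "ppi"
        extended |= set(reachable)

    missing = seed_set - extended  # cannot happen, seeds always kept
    if missing:  # pragma: no cover - defensive
        extended |= missing
    unknown = seed_set - (set().union(*map(set, pathways.values())) if pathways else set()) - set(graph.nodes)
    if unknown:
        logger.warning(
            "%d seed gene(s) absent from pathways and PPI: %s",
            len(unknown),
            ", ".join(sorted(unknown)[:5]),
        )
    return CandidateGeneSet(
        seeds=seed_set, extended=frozenset(extended), provenance=provenance
    )


def score_snp(
    ann: SnpAnnotation,
    candidates: CandidateGeneSet,
    cons_threshold: float = DEFAULT_CONSERVATION_THRESHOLD,
    sel_threshold: float = DEFAULT_SELECTION_THRESHOLD,
    base_scores: Mapping[FeatureClass, int] | None = None,
) -> int:
    """Three-step putative disease-risk score for one SNP.

    score = base(feature class)
          + 2 per qualifying non-gene feature (conservation >= threshold,
            selection >= threshold, miRNA binding site)
          + 3 if the SNP's gene is in the extended candidate set.

    Missing conservation/selection values never qualify.  The selection
    threshold is one-sided (large positive scores indicate selection).
    """
    table = DEFAULT_BASE_SCORES if base_scores is None else base_scores
    score = int(table[ann.feature_class])
    if ann.conservation is not None and ann.conservation >= cons_threshold:
        score += NON_GENE_BONUS
    if ann.selection is not None and ann.selection >= sel_threshold:
        score += NON_GENE_BONUS
    if ann.mirna_site:
        score += NON_GENE_BONUS
    if ann.gene is not None and ann.gene in candidates.extended:
        score += CANDIDATE_GENE_BONUS
    return score


def score_table(
    annotations: Iterable[SnpAnnotation],
    candidates: CandidateGeneSet,
    cons_threshold: float = DEFAULT_CONSERVATION_THRESHOLD,
    sel_threshold: float = DEFAULT_SELECTION_THRESHOLD,
    base_scores: Mapping[FeatureClass, int] | None = None,
) -> dict[str, int]:
    """Score every SNP; returns snp_id -> score."""
    return {
        ann.snp_id: score_snp(ann, candidates, cons_threshold, sel_threshold, base_scores)
        for ann in annotations
    }


def classify_snps(
    scores: Mapping[str, int], cutoff: int = DEFAULT_CUTOFF
) -> dict[str, set[str]]:
    """Partition SNPs into strong- (score >= cutoff) and weak-clue sets."""
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    strong = {s for s, v in scores.items() if v >= cutoff}
    weak = set(scores) - strong
    return {"strong": strong, "weak": weak}


def transfer_ld_scores(
    local: Mapping[str, int],
    proxies: pd.DataFrame,
    r2_threshold: float = 0.9,
) -> dict[str, int]:
    """Transfer risk scores from LD-proxy SNPs onto typed SNPs.

    For each local SNP, its score becomes the max of its own score and the
    scores of proxy SNPs in strong LD (r^2 strictly above the threshold).
    Monotone (scores never decrease) and idempotent.

    ``proxies`` columns: local_snp, proxy_snp, r2, proxy_score.
    """
    out = dict(local)
    if proxies.empty:
        return out
    bad = ~proxies["r2"].between(0.0, 1.0)
    if bad.any():
        raise ValueError("r2 values outside [0, 1]")
    strong_ld = proxies[proxies["r2"] > r2_threshold]
    unknown = set(strong_ld["local_snp"]) - set(local)
    if unknown:
        warnings.warn(
            f"{len(unknown)} LD proxy row(s) reference unknown local SNPs; ignored",
            stacklevel=2,
        )
    best = strong_ld.groupby("local_snp")["proxy_score"].max()
    for snp, proxy_score in best.items():
        if snp in out:
            out[snp] = max(out[snp], int(proxy_score))
    return out


def assign_feature_classes(
    snps: pd.DataFrame,
    gene_models: pd.DataFrame,
    upstream_window: int = UPSTREAM_WINDOW,
    downstream_window: int = DOWNSTREAM_WINDOW,
) -> pd.DataFrame:
    """Derive near-gene feature classes from transcript bounds.

    Used when the annotation table carries no pre-computed feature class.
    A SNP inside [txStart, txEnd] is labelled intron (the most conservative
    intragenic class); within the strand-aware 5' window it is upstream and
    within the 3' window downstream; otherwise intergenic.  Coordinates are
    1-based inclusive.

    ``snps`` columns: snp_id, chrom, pos.  ``gene_models`` columns: gene,
    chrom, strand (+/-), txStart, txEnd.
    """
    rows = []
    by_chrom = {c: g for c, g in gene_models.groupby("chrom")}
    for rec in snps.itertuples(index=False):
        feature, gene = FeatureClass.INTERGENIC, None
        models = by_chrom.get(rec.chrom)
        if models is not None:
            for gm in models.itertuples(index=False):
                if gm.txStart <= rec.pos <= gm.txEnd:
                    feature, gene = FeatureClass.INTRON, gm.gene
                    break
                if gm.strand == "+":
                    up = gm.txStart - upstream_window <= rec.pos < gm.txStart
                    down = gm.txEnd < rec.pos <= gm.txEnd + downstream_window
                else:
                    up = gm.txEnd < rec.pos <= gm.txEnd + upstream_window
                    down = gm.txStart - downstream_window <= rec.pos < gm.txStart
                if up:
                    feature, gene = FeatureClass.UPSTREAM, gm.gene
                elif down and feature is FeatureClass.INTERGENIC:
                    feature, gene = FeatureClass.DOWNSTREAM, gm.gene
        rows.append((rec.snp_id, feature.value, gene))
    return pd.DataFrame(rows, columns=["snp_id", "feature_class", "gene"])
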