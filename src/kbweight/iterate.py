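"""Iterative seed-gene refinement loop.

Each pass: seed genes -> pathway/PPI candidate extension -> SNP risk
scoring and strong/weak classification -> signal estimation and weight
optimisation -> weighted p-values -> re-seed from the top-n genes by
weighted p.  The loop stops when the weight pair stops moving (numerically
equal between consecutive iterations) or at the iteration cap.

Pre-defined seed genes, when supplied, are used only for iteration 0 and
may be dropped by re-seeding; without them the first seeds come from the
top-n genes by original p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import annotation as ann_mod
from . import weighting

logger = logging.getLogger(__name__)

__all__ = ["IterationState", "PipelineInputs", "select_seed_genes", "run_iteration", "run_until_convergence"]

DEFAULT_TOP_N = 20
DEFAULT_MAX_ITER = 20
DEFAULT_TOL = 1e-6


@dataclass
class PipelineInputs:
    """Static inputs shared by every iteration."""

    assoc: pd.DataFrame  # columns: snp_id, p (chisq optional)
    annotations: list[ann_mod.SnpAnnotation]
    pathways: Mapping[str, set[str]]
    ppi_edges: list[tuple[str, str]]
    ld_proxies: pd.DataFrame | None = None
    cutoff: int = ann_mod.DEFAULT_CUTOFF
    cons_threshold: float = ann_mod.DEFAULT_CONSERVATION_THRESHOLD
    sel_threshold: float = ann_mod.DEFAULT_SELECTION_THRESHOLD
    ppi_depth: int = 2
    q: float = 0.05
    exclude_significant: bool = True

    def snp_gene_map(self) -> dict[str, str]:
        return {a.snp_id: a.gene for a in self.annotations if a.gene is not None}


@dataclass
class IterationState:
    iteration: int = 0
    seed_genes: frozenset[str] = frozenset()
    weights: tuple[float, float] | None = None
    converged: bool = False
    trace: list[weighting.WeightSolution] = field(default_factory=list)
    table: pd.DataFrame | None = None
    candidates: ann_mod.CandidateGeneSet | None = None


def select_seed_genes(
    pvalues: Mapping[str, float],
    snp_gene: Mapping[str, str],
    top_n: int = DEFAULT_TOP_N,
) -> frozenset[str]:
    """Top-n genes ranked by their minimum SNP p-value.

    Ties broken lexicographically by gene symbol, so the selection is
    deterministic.  Raises if no SNP maps to a gene.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    best: dict[str, float] = {}
    for snp, p in pvalues.items():
        gene = snp_gene.get(snp)
        if gene is None:
            continue
        if gene not in best or p < best[gene]:
            best[gene] = p
    if not best:
        raise ValueError("no seedable genes: no SNP maps to a gene")
    ranked = sorted(best.items(), key=lambda kv: (kv[1], kv[0]))
    return frozenset(g for g, _ in ranked[:top_n])


def run_iteration(
    state: IterationState,
    inputs: PipelineInputs,
    top_n: int = DEFAULT_TOP_N,
) -> IterationState:
    """Execute one extend -> score -> classify -> weight -> re-seed pass."""
    snp_gene = inputs.snp_gene_map()
    p_map = dict(zip(inputs.assoc["snp_id"], inputs.assoc["p"]))
    seeds = state.seed_genes
    if not seeds:
        seeds = select_seed_genes(p_map, snp_gene, top_n)
        logger.info("auto-selected %d seed genes from original p-values", len(seeds))

    candidates = ann_mod.extend_candidate_genes(
        seeds, inputs.pathways, inputs.ppi_edges, ppi_depth=inputs.ppi_depth
    )
    scores = ann_mod.score_table(
        inputs.annotations,
        candidates,
        cons_threshold=inputs.cons_threshold,
        sel_threshold=inputs.sel_threshold,
    )
    if inputs.ld_proxies is not None and not inputs.ld_proxies.empty:
        scores = ann_mod.transfer_ld_scores(scores, inputs.ld_proxies)
    partition = ann_mod.classify_snps(scores, inputs.cutoff)

    snp_ids = inputs.assoc["snp_id"].to_numpy()
    p = inputs.assoc["p"].to_numpy(dtype=float)
    strong_mask = np.fromiter(
        (s in partition["strong"] for s in snp_ids), dtype=bool, count=snp_ids.size
    )
    result = weighting.weighted_analysis(
        p,
        strong_mask,
        q=inputs.q,
        exclude_significant=inputs.exclude_significant,
    )
    reject, _ = weighting.adjust_multiple_testing(result.weighted_p, "bh", inputs.q)
    table = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "p": p,
            "score": [scores[s] for s in snp_ids],
            "clue_set": np.where(strong_mask, "strong", "weak"),
            "weight": result.weights,
            "weighted_p": result.weighted_p,
            "bh_flag": reject,
        }
    )
    new_seeds = select_seed_genes(
        dict(zip(snp_ids, result.weighted_p)), snp_gene, top_n
    )
    sol = result.solution
    return IterationState(
        iteration=state.iteration + 1,
        seed_genes=new_seeds,
        weights=(sol.w_strong, sol.w_weak),
        converged=False,
        trace=state.trace + [sol],
        table=table,
        candidates=candidates,
    )


def run_until_convergence(
    inputs: PipelineInputs,
    seeds: frozenset[str] | None = None,
    top_n: int = DEFAULT_TOP_N,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
) -> IterationState:
    """Iterate until the weight pair changes by at most ``tol``."""
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    state = IterationState(seed_genes=seeds or frozenset())
    prev: tuple[float, float] | None = None
    for _ in range(max_iter):
        state = run_iteration(state, inputs, top_n=top_n)
        w = state.weights
        logger.info(
            "iteration %d: w_S=%.4f w_W=%.6f seeds=%d",
            state.iteration, w[0], w[1], len(state.seed_genes),
        )
        if prev is not None and abs(w[0] - prev[0]) <= tol and abs(w[1] - prev[1]) <= tol:
            state.converged = True
            break
        prev = w
    return state
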