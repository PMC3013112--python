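"""Case-control GWAS simulator and power evaluation.

Genotypes at each causal SNP follow Hardy-Weinberg proportions in the
population; the three penetrances are solved from (model, genotype relative
risk, prevalence) with the baseline penetrance f0 as the free parameter
(dominant: f1 = f2 = GRR * f0; multiplicative: f1 = GRR * f0,
f2 = GRR^2 * f0).  Case and control genotype distributions follow by
Bayes' rule.  Null SNPs are drawn with identical allele frequencies in
both groups and no linkage disequilibrium, so Bonferroni family-wise error
control is exact in theory.

The association test is the basic allelic test: Pearson chi-square on the
2x2 allele-count table of cases versus controls, 1 df.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from . import weighting

__all__ = [
    "SimulationConfig",
    "PowerResult",
    "penetrances",
    "case_control_allele_freqs",
    "allelic_test_ncp",
    "simulate_case_control",
    "simulate_null_allele_counts",
    "allelic_test",
    "allelic_test_counts",
    "estimate_power_mc",
    "pipeline_power_mc",
    "theoretical_gain_curve",
    "sample_size_for_power",
]

#: Minor allele frequencies of the three planted susceptibility SNPs.
DEFAULT_CAUSAL_MAFS = (0.0750, 0.2167, 0.4167)
DEFAULT_N_NULL_SNPS = 28370


@dataclass(frozen=True)
class SimulationConfig:
    maf: float
    model: str  # "dominant" | "multiplicative"
    grr: float
    prevalence: float
    n_cases: int
    n_controls: int
    n_null_snps: int = 0
    null_maf_range: tuple[float, float] = (0.05, 0.5)
    replicates: int = 1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.maf < 1.0:
            raise ValueError("maf must be in (0, 1)")
        if self.model not in ("dominant", "multiplicative"):
            raise ValueError(f"unknown model {self.model!r}")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        if self.grr < 0:
            raise ValueError("grr must be >= 0")
        penetrances(self.maf, self.model, self.grr, self.prevalence)  # feasibility


@dataclass(frozen=True)
class PowerResult:
    power_weighted: float
    power_unweighted: float
    gain: float  # percentage points
    mean_false_positives: float
    mc_se: float
    replicates: int
    rng_seed: int


def penetrances(
    maf: float, model: str, grr: float, prevalence: float
) -> np.ndarray:
    """Penetrance vector (f0, f1, f2) solved from the disease model.

    f0 is chosen so the population prevalence matches; raises if any
    implied penetrance exceeds 1.
    """
    p = maf
    g = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    if model == "dominant":
        rel = np.array([1.0, grr, grr])
    elif model == "multiplicative":
        rel = np.array([1.0, grr, grr**2])
    else:
        raise ValueError(f"unknown model {model!r}")
    f0 = prevalence / float(g @ rel)
    f = f0 * rel
    if np.any(f > 1.0):
        raise ValueError("infeasible config: implied penetrance > 1")
    return f


def _genotype_dists(
    maf: float, model: str, grr: float, prevalence: float
) -> tuple[np.ndarray, np.ndarray]:
    """(P(g|case), P(g|control)) under HWE + penetrance model."""
    p = maf
    g = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    f = penetrances(maf, model, grr, prevalence)
    k = float(g @ f)
    case = g * f / k
    control = g * (1 - f) / (1 - k)
    return case, control


def case_control_allele_freqs(
    maf: float, model: str, grr: float, prevalence: float
) -> tuple[float, float]:
    """Expected risk-allele frequency in cases and controls."""
    case, control = _genotype_dists(maf, model, grr, prevalence)
    dose = np.array([0.0, 0.5, 1.0])
    return float(case @ dose), float(control @ dose)


def allelic_test_ncp(
    maf: float, model: str, grr: float, prevalence: float,
    n_cases: int, n_controls: int,
) -> float:
    """Non-centrality of the allelic test under the disease model.

    Pearson chi-square on the 2x2 allele table with expected frequencies
    p1 (cases) and p2 (controls) and 2n alleles per group has NCP equal to
    the chi-square statistic evaluated at the expected counts.
    """
    p1, p2 = case_control_allele_freqs(maf, model, grr, prevalence)
    k1, k2 = 2 * n_cases, 2 * n_controls
    pbar = (k1 * p1 + k2 * p2) / (k1 + k2)
    return (k1 * k2 / (k1 + k2)) * (p1 - p2) ** 2 / (pbar * (1 - pbar))


def simulate_case_control(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> dict[str, np.ndarray]:
    """Genotype counts for one replicate at the causal SNP plus null SNPs.

    Returns ``{"causal_cases": (3,), "causal_controls": (3,),
    "null_case_alleles": (n_null,), "null_control_alleles": (n_null,),
    "null_mafs": (n_null,)}`` — null SNPs are summarised directly by their
    minor-allele counts since the allelic test only needs allele tallies.
    """
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    case_dist, control_dist = _genotype_dists(
        config.maf, config.model, config.grr, config.prevalence
    )
    causal_cases = rng.multinomial(config.n_cases, case_dist)
    causal_controls = rng.multinomial(config.n_controls, control_dist)
    lo, hi = config.null_maf_range
    null_mafs = rng.uniform(lo, hi, size=config.n_null_snps)
    null_case = rng.binomial(2 * config.n_cases, null_mafs)
    null_control = rng.binomial(2 * config.n_controls, null_mafs)
    return {
        "causal_cases": causal_cases,
        "causal_controls": causal_controls,
        "null_case_alleles": null_case,
        "null_control_alleles": null_control,
        "null_mafs": null_mafs,
    }


def simulate_null_allele_counts(
    n_snps: int, n_cases: int, n_controls: int,
    mafs: np.ndarray, rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Allele counts for independent null SNPs, identical in both groups."""
    case = rng.binomial(2 * n_cases, mafs, size=n_snps)
    control = rng.binomial(2 * n_controls, mafs, size=n_snps)
    return case, control


def allelic_test(a: float, b: float, c: float, d: float) -> tuple[float, float]:
    """Pearson chi-square (1 df) on the 2x2 allele table [[a, b], [c, d]].

    Rows are cases/controls, columns the two alleles.
    """
    stat = allelic_test_counts(
        np.atleast_1d(np.asarray(a, float)), np.atleast_1d(np.asarray(b, float)),
        np.atleast_1d(np.asarray(c, float)), np.atleast_1d(np.asarray(d, float)),
    )[0]
    return float(stat), float(stats.chi2.sf(stat, 1))


def allelic_test_counts(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray
) -> np.ndarray:
    """Vectorised allelic chi-square; raises on any degenerate margin."""
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    if np.any((a < 0) | (b < 0) | (c < 0) | (d < 0)):
        raise ValueError("allele counts must be >= 0")
    n = a + b + c + d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if np.any((r1 == 0) | (r2 == 0)):
        raise ValueError("degenerate table: zero row margin")
    denom = r1 * r2 * c1 * c2
    out = np.zeros_like(n)
    ok = denom > 0
    out[ok] = n[ok] * (a[ok] * d[ok] - b[ok] * c[ok]) ** 2 / denom[ok]
    return out


def _replicate_stats(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[float, np.ndarray]:
    """(causal chi-square, null chi-square vector) for one replicate."""
    data = simulate_case_control(config, rng)
    dose = np.array([0.0, 1.0, 2.0])
    a = float(data["causal_cases"] @ dose)
    b = 2.0 * config.n_cases - a
    c = float(data["causal_controls"] @ dose)
    d = 2.0 * config.n_controls - c
    causal_stat = allelic_test_counts(
        np.atleast_1d(a), np.atleast_1d(b), np.atleast_1d(c), np.atleast_1d(d)
    )[0]
    nc, ncl = data["null_case_alleles"], data["null_control_alleles"]
    null_stats = allelic_test_counts(
        nc, 2.0 * config.n_cases - nc, ncl, 2.0 * config.n_controls - ncl
    )
    return float(causal_stat), null_stats


def estimate_power_mc(
    config: SimulationConfig,
    w_causal: float = 1.0,
    w_null: np.ndarray | float = 1.0,
    alpha_fw: float = 0.05,
) -> PowerResult:
    """Monte-Carlo power of the (weighted) Bonferroni allelic test.

    The causal SNP rejects when its weighted p-value falls below
    alpha_fw / m over the m = 1 + n_null_snps tests; null rejections are
    counted the same way with their weights.
    """
    rng = np.random.default_rng(config.rng_seed)
    m = 1 + config.n_null_snps
    threshold = alpha_fw / m
    hits_w = hits_u = 0
    fp_total = 0
    w_null_arr = np.broadcast_to(
        np.asarray(w_null, dtype=float), (config.n_null_snps,)
    )
    for _ in range(config.replicates):
        causal_stat, null_stats = _replicate_stats(config, rng)
        p_causal = stats.chi2.sf(causal_stat, 1)
        hits_u += p_causal < threshold
        hits_w += np.minimum(p_causal / w_causal, 1.0) < threshold
        if config.n_null_snps:
            p_null = stats.chi2.sf(null_stats, 1)
            fp_total += int((np.minimum(p_null / w_null_arr, 1.0) < threshold).sum())
    r = config.replicates
    pw, pu = hits_w / r, hits_u / r
    se = float(np.sqrt(max(pw * (1 - pw), pu * (1 - pu)) / r)) if r > 1 else 0.0
    return PowerResult(
        power_weighted=pw,
        power_unweighted=pu,
        gain=100.0 * (pw - pu),
        mean_false_positives=fp_total / r,
        mc_se=se,
        replicates=r,
        rng_seed=config.rng_seed,
    )


def pipeline_power_mc(
    config: SimulationConfig,
    strong_fraction: float = 0.03,
    alpha_fw: float = 0.05,
    causal_in_strong: bool = True,
) -> PowerResult:
    """Full-pipeline Monte-Carlo power: re-estimate weights per replicate.

    Each replicate simulates the genome, places the causal SNP in the
    strong-clue set (together with a random ``strong_fraction`` of the null
    SNPs, mimicking the functional classification) or in the weak set,
    runs the signal estimation and weight optimisation on the replicate's
    own p-values, and tests the causal SNP against the weighted and
    unweighted Bonferroni thresholds.
    """
    rng = np.random.default_rng(config.rng_seed)
    m = 1 + config.n_null_snps
    threshold = alpha_fw / m
    hits_w = hits_u = 0
    fp_total = 0
    for _ in range(config.replicates):
        causal_stat, null_stats = _replicate_stats(config, rng)
        stats_all = np.concatenate([[causal_stat], null_stats])
        p_all = stats.chi2.sf(stats_all, 1)
        strong = np.zeros(m, dtype=bool)
        strong[0] = causal_in_strong
        n_strong_null = int(round(strong_fraction * config.n_null_snps))
        idx = rng.choice(config.n_null_snps, size=n_strong_null, replace=False)
        strong[1 + idx] = True
        try:
            res = weighting.weighted_analysis(
                p_all, strong, stats_vec=stats_all, q=alpha_fw,
                exclude_significant=True, grid_points=400,
            )
            wp = res.weighted_p
        except ValueError:  # a set emptied by exclusion: fall back to w=1
            wp = p_all
        hits_u += p_all[0] < threshold
        hits_w += wp[0] < threshold
        fp_total += int((wp[1:] < threshold).sum())
    r = config.replicates
    pw, pu = hits_w / r, hits_u / r
    se = float(np.sqrt(max(pw * (1 - pw), pu * (1 - pu)) / r)) if r > 1 else 0.0
    return PowerResult(
        power_weighted=pw,
        power_unweighted=pu,
        gain=100.0 * (pw - pu),
        mean_false_positives=fp_total / r,
        mc_se=se,
        replicates=r,
        rng_seed=config.rng_seed,
    )


def theoretical_gain_curve(
    w_s: float,
    w_w: float,
    alpha: float,
    delta_grid: Sequence[float],
) -> np.ndarray:
    """Closed-form per-NCP power gain and loss of the weighted test.

    Returns a structured array with fields (delta, gain, loss):
    gain(d) = P(w_s; d) - P(1; d) for a strong-set alternative and
    loss(d) = P(1; d) - P(w_w; d) for a weak-set alternative, both from
    the non-central chi-square tail.
    """
    d = np.asarray(delta_grid, dtype=float)
    p1 = weighting.single_test_power(np.ones_like(d) * 1.0, alpha, d)
    ps = weighting.single_test_power(np.full_like(d, w_s), alpha, d)
    pw = weighting.single_test_power(np.full_like(d, w_w), alpha, d)
    out = np.zeros(d.size, dtype=[("delta", float), ("gain", float), ("loss", float)])
    out["delta"] = d
    out["gain"] = ps - p1
    out["loss"] = p1 - pw
    return out


def sample_size_for_power(
    target_power: float,
    maf: float,
    model: str,
    grr: float,
    prevalence: float,
    alpha: float,
) -> int:
    """Equal cases/controls per group so the allelic test reaches the target.

    Solves the closed-form power equation power(NCP(n)) = target for n by
    bisection on the analytic non-centrality.
    """
    def gap(n: float) -> float:
        ncp = allelic_test_ncp(maf, model, grr, prevalence, int(n), int(n))
        return weighting.single_test_power(1.0, alpha, ncp) - target_power

    n = optimize.brentq(gap, 10, 10**7, xtol=1)
    return int(round(n))
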