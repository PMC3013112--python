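"""Signal-structure estimation and optimal p-value weighting.

The model: association chi-square statistics (1 df) in each clue set are a
two-component mixture — a proportion pi0 of null tests following central
chi2_1, and the rest following a common non-central chi2_1 with
non-centrality parameter (NCP) delta, the set's "signal strength".

From the p-values of each set we estimate pi0 (Storey-Tibshirani), the
alternative count m1 = (1 - pi0) * m, and delta (first-moment matching on
the truncated mixture).  Given these, the average genome-wide power of a
weighted Bonferroni procedure is an explicit function of the two set
weights (w_S, w_W); we maximise it subject to the weight budget
m_S * w_S + m_W * w_W = m_S + m_W (mean weight one, which preserves
family-wise error control) and the ordering w_S >= w_W.  A weighted p-value
is the original p divided by its set's weight, capped at 1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "SetSignalEstimate",
    "WeightSolution",
    "estimate_pi0",
    "estimate_signal",
    "estimate_ncp",
    "single_test_power",
    "average_power",
    "optimize_weights",
    "weight_pvalues",
    "WeightedAnalysis",
    "weighted_analysis",
    "adjust_multiple_testing",
    "genomic_inflation",
    "chisq_from_pvalues",
]

#: Central chi2_1 median, the denominator of the genomic inflation factor.
_CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))

DEFAULT_LAMBDA_GRID = np.round(np.arange(0.05, 0.951, 0.05), 2)
_PI0_FLOOR = 1e-4


@dataclass(frozen=True)
class SetSignalEstimate:
    """Estimated signal structure of one clue set."""

    m: int
    pi0_hat: float
    m1_hat: int
    ncp_hat: float
    no_signal: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi0_hat <= 1.0:
            raise ValueError(f"pi0_hat {self.pi0_hat} outside [0, 1]")
        if not 0 <= self.m1_hat <= self.m:
            raise ValueError("m1_hat outside [0, m]")
        if self.ncp_hat < 0:
            raise ValueError("ncp_hat must be >= 0")


@dataclass(frozen=True)
class WeightSolution:
    """Optimal weight pair for the strong/weak clue sets."""

    w_strong: float
    w_weak: float
    avg_power: float
    alpha: float
    budget_residual: float
    grid_resolution: float
    uninformative: bool = False

    def as_dict(self) -> dict:
        return {
            "w_strong": self.w_strong,
            "w_weak": self.w_weak,
            "avg_power": self.avg_power,
            "alpha": self.alpha,
            "budget_residual": self.budget_residual,
            "grid_resolution": self.grid_resolution,
            "uninformative": self.uninformative,
        }


def chisq_from_pvalues(pvalues: np.ndarray) -> np.ndarray:
    """Invert two-sided p-values to chi2_1 statistics."""
    return stats.chi2.isf(np.asarray(pvalues, dtype=float), 1)


def estimate_pi0(
    pvalues: np.ndarray,
    lambda_grid: np.ndarray | None = None,
) -> float:
    """Storey-Tibshirani estimate of the null-hypothesis proportion.

    Computes pi0(lambda) = #{p > lambda} / ((1 - lambda) m) over the grid,
    fits a cubic smoother and takes its value at the largest lambda (the
    lambda -> 1 limit), clipped to [1e-4, 1].  If every p-value lies below
    the smallest lambda there is no mass to estimate from: returns 0.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    lam = DEFAULT_LAMBDA_GRID if lambda_grid is None else np.asarray(lambda_grid)
    if np.any((lam <= 0) | (lam >= 1)):
        raise ValueError("lambda grid must lie in (0, 1)")
    lam = np.sort(lam)
    if p.max() < lam.min():
        warnings.warn("all p-values below the lambda grid; pi0 set to 0", stacklevel=2)
        return 0.0
    pi0_lam = np.array([(p > x).sum() / ((1.0 - x) * p.size) for x in lam])
    if lam.size >= 4:
        coeffs = np.polyfit(lam, pi0_lam, 3)
        pi0 = float(np.polyval(coeffs, lam.max()))
    else:
        pi0 = float(pi0_lam[-1])
    return float(np.clip(pi0, _PI0_FLOOR, 1.0))


def _truncated_moment_parts(t: float, df: int, ncp: float) -> tuple[float, float]:
    """(E[X 1{X>t}], P(X>t)) for (non-)central chi-square with ``df`` df.

    Uses the exact identity x f_k(x; d) = k f_{k+2}(x; d) + d f_{k+4}(x; d),
    so E[X 1{X>t}] = k S_{k+2}(t; d) + d S_{k+4}(t; d).
    """
    if ncp == 0.0:
        sf = stats.chi2.sf
        return df * sf(t, df + 2), sf(t, df)
    sf = stats.ncx2.sf
    return df * sf(t, df + 2, ncp) + ncp * sf(t, df + 4, ncp), sf(t, df, ncp)


def _mixture_truncated_mean(t: float, pi0: float, ncp: float) -> float:
    """E[X | X > t] for the pi0-central / (1-pi0)-noncentral chi2_1 mixture."""
    num0, den0 = _truncated_moment_parts(t, 1, 0.0)
    num1, den1 = _truncated_moment_parts(t, 1, ncp)
    num = pi0 * num0 + (1.0 - pi0) * num1
    den = pi0 * den0 + (1.0 - pi0) * den1
    return num / den


def estimate_ncp(
    stats_vec: np.ndarray,
    m1_hat: int,
    truncation: float | None = None,
    max_ncp: float = 1e4,
    tol: float = 1e-6,
) -> tuple[float, bool]:
    """Moment estimate of the NCP from truncated chi-square statistics.

    Matches the observed mean of the statistics above the truncation point
    to the expected truncated mean of the mixture (implied null proportion
    pi0 = 1 - m1_hat / m), solving for delta by bisection — the truncated
    mean is strictly increasing in delta.

    Returns ``(ncp_hat, no_signal)``; ``no_signal`` is True when m1_hat = 0
    or when the observed truncated mean does not exceed the all-null
    truncated mean (no evidence of signal; ncp_hat = 0).

    The default truncation point is the central chi2_1 quantile at p = 0.05
    (3.841), so only the informative upper tail enters the moment equation.
    """
    x = np.asarray(stats_vec, dtype=float)
    if m1_hat < 0:
        raise ValueError("m1_hat must be >= 0")
    if truncation is None:
        truncation = float(stats.chi2.isf(0.05, 1))
    if truncation < 0:
        raise ValueError("truncation must be >= 0")
    if m1_hat == 0:
        return 0.0, True
    tail = x[x > truncation]
    if tail.size == 0:
        return 0.0, True
    observed = float(tail.mean())
    pi0 = 1.0 - m1_hat / x.size
    null_mean = _mixture_truncated_mean(truncation, 1.0, 0.0)
    if observed <= null_mean:
        return 0.0, True

    def gap(delta: float) -> float:
        return _mixture_truncated_mean(truncation, pi0, delta) - observed

    if gap(max_ncp) < 0:  # observed mean beyond the search bracket
        return max_ncp, False
    ncp = optimize.brentq(gap, 0.0, max_ncp, xtol=tol)
    return float(ncp), False


def estimate_signal(
    pvalues: np.ndarray,
    stats_vec: np.ndarray | None = None,
    lambda_grid: np.ndarray | None = None,
    truncation: float | None = None,
) -> SetSignalEstimate:
    """Full signal-structure estimate of one clue set from its p-values."""
    p = np.asarray(pvalues, dtype=float)
    if stats_vec is None:
        stats_vec = chisq_from_pvalues(p)
    pi0 = estimate_pi0(p, lambda_grid)
    m1 = int(round((1.0 - pi0) * p.size))
    ncp, no_signal = estimate_ncp(stats_vec, m1, truncation)
    return SetSignalEstimate(
        m=p.size, pi0_hat=pi0, m1_hat=m1, ncp_hat=ncp, no_signal=no_signal
    )


def single_test_power(w, alpha: float, ncp) -> np.ndarray | float:
    """Power of a single chi2_1 test rejected at the weighted level w*alpha.

    power = P(chi2_1(ncp) > q) with q the upper w*alpha quantile of central
    chi2_1.  At ncp = 0 this equals w*alpha exactly; it is strictly
    increasing in both w and ncp.  Accepts array ``w`` or ``ncp``.
    """
    w = np.asarray(w, dtype=float)
    ncp = np.asarray(ncp, dtype=float)
    level = w * alpha
    if np.any(level <= 0):
        raise ValueError("w * alpha must be positive")
    if np.any(level >= 1):
        warnings.warn("w * alpha >= 1: power saturates at 1", stacklevel=2)
    level = np.minimum(level, 1.0)
    q = stats.chi2.isf(level, 1)
    power = np.where(
        ncp == 0.0,
        level,  # exact null identity, avoids ncx2 at nc=0
        stats.ncx2.sf(q, 1, np.where(ncp == 0.0, 1.0, ncp)),
    )
    if power.ndim == 0:
        return float(power)
    return power


def average_power(
    w_s,
    w_w: float,
    alpha: float,
    est_s: SetSignalEstimate,
    est_w: SetSignalEstimate,
) -> np.ndarray | float:
    """Genome-wide average power over the m1 = m1_S + m1_W alternatives."""
    m1 = est_s.m1_hat + est_w.m1_hat
    if m1 == 0:
        raise ValueError("no alternatives estimated in either clue set")
    p_s = single_test_power(w_s, alpha, est_s.ncp_hat) if est_s.m1_hat else 0.0
    p_w = single_test_power(w_w, alpha, est_w.ncp_hat) if est_w.m1_hat else 0.0
    return (est_s.m1_hat * p_s + est_w.m1_hat * p_w) / m1


def optimize_weights(
    m_s: int,
    m_w: int,
    est_s: SetSignalEstimate,
    est_w: SetSignalEstimate,
    alpha: float,
    grid_points: int = 1000,
) -> WeightSolution:
    """Find the budget-feasible weight pair maximising average power.

    The budget m_S w_S + m_W w_W = m_S + m_W makes the problem
    one-dimensional: w_W is determined by w_S, and w_S ranges over
    [1, (m_S + m_W)/m_S] (so w_S >= 1 >= w_W >= 0 and the ordering
    constraint holds automatically).  A uniform grid locates the optimum;
    golden-section refinement sharpens it.  Deterministic.
    """
    if m_s < 1 or m_w < 1:
        raise ValueError("both clue sets must be non-empty")
    m = m_s + m_w
    if est_s.ncp_hat == 0.0 and est_w.ncp_hat == 0.0:
        logger.info("no signal in either set; weights stay at 1")
        return WeightSolution(1.0, 1.0, 0.0, alpha, 0.0, 0.0, uninformative=True)

    def w_weak_of(w_s):
        return (m - m_s * np.asarray(w_s, dtype=float)) / m_w

    # keep w_W * alpha > 0 strictly: stop a hair short of the upper bound
    hi = m / m_s
    eps = (hi - 1.0) / (grid_points * 10.0)
    lo = 1.0
    hi_search = hi - eps

    def objective(w_s: float) -> float:
        w_w = max(float(w_weak_of(w_s)), 1e-12)
        return -float(average_power(w_s, w_w, alpha, est_s, est_w))

    grid = np.linspace(lo, hi_search, grid_points)
    w_w_grid = np.maximum(w_weak_of(grid), 1e-12)
    m1 = est_s.m1_hat + est_w.m1_hat
    if m1 == 0:
        raise ValueError("no alternatives estimated in either clue set")
    p_s = single_test_power(grid, alpha, est_s.ncp_hat) if est_s.m1_hat else np.zeros_like(grid)
    p_w = single_test_power(w_w_grid, alpha, est_w.ncp_hat) if est_w.m1_hat else np.zeros_like(grid)
    avg = (est_s.m1_hat * p_s + est_w.m1_hat * p_w) / m1
    best = int(np.argmax(avg))
    step = grid[1] - grid[0]
    bracket_lo = grid[max(best - 1, 0)]
    bracket_hi = grid[min(best + 1, grid_points - 1)]
    res = optimize.minimize_scalar(
        objective, bounds=(bracket_lo, bracket_hi), method="bounded",
        options={"xatol": 1e-10},
    )
    w_s = float(res.x) if -res.fun >= avg[best] else float(grid[best])
    w_w = max(float(w_weak_of(w_s)), 0.0)
    power = float(average_power(w_s, max(w_w, 1e-12), alpha, est_s, est_w))
    residual = m_s * w_s + m_w * w_w - m
    return WeightSolution(
        w_strong=w_s,
        w_weak=w_w,
        avg_power=power,
        alpha=alpha,
        budget_residual=residual,
        grid_resolution=float(step),
    )


def weight_pvalues(pvalues: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted p-values: p / w, capped at 1; w = 0 fully down-weights."""
    p = np.asarray(pvalues, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be >= 0")
    if np.any(w == 0):
        warnings.warn("zero weight: affected p-values set to 1", stacklevel=2)
    with np.errstate(divide="ignore"):
        out = np.where(w > 0, p / np.where(w > 0, w, 1.0), np.inf)
    return np.minimum(out, 1.0)


def adjust_multiple_testing(
    pvalues: np.ndarray, method: str = "bh", q: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Bonferroni or Benjamini-Hochberg correction.

    Returns (reject flags, adjusted p-values).  Valid on weighted p-values
    because the mean-one weight budget preserves the error-rate guarantee.
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    key = {"bh": "fdr_bh", "bonferroni": "bonferroni"}[method]
    reject, adjusted = multipletests(p, alpha=q, method=key)[:2]
    return reject, adjusted


@dataclass
class WeightedAnalysis:
    """Per-SNP weighting result for one genome-wide pass."""

    weights: np.ndarray
    weighted_p: np.ndarray
    est_strong: SetSignalEstimate
    est_weak: SetSignalEstimate
    solution: WeightSolution
    excluded: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))


def weighted_analysis(
    pvalues: np.ndarray,
    strong_mask: np.ndarray,
    stats_vec: np.ndarray | None = None,
    q: float = 0.05,
    alpha: float | None = None,
    exclude_significant: bool = True,
    truncation: float | None = None,
    grid_points: int = 1000,
) -> WeightedAnalysis:
    """One full weighting pass: estimate both sets, optimise, weight.

    SNPs already significant by Bonferroni at ``q`` on the original
    p-values (where weighting can add nothing) keep weight 1 and are left
    out of both the signal estimation and the weight budget; disable with
    ``exclude_significant=False``.  ``alpha`` defaults to the per-test
    Bonferroni level q / m over the SNPs in the budget.
    """
    p = np.asarray(pvalues, dtype=float)
    strong = np.asarray(strong_mask, dtype=bool)
    if p.shape != strong.shape:
        raise ValueError("pvalues and strong_mask must align")
    x = chisq_from_pvalues(p) if stats_vec is None else np.asarray(stats_vec, float)
    excluded = np.zeros(p.size, dtype=bool)
    if exclude_significant:
        excluded = p < q / p.size
    active = ~excluded
    m_s = int((strong & active).sum())
    m_w = int((~strong & active).sum())
    if m_s == 0 or m_w == 0:
        raise ValueError("one clue set is empty after exclusion")
    if alpha is None:
        alpha = q / (m_s + m_w)
    est_s = estimate_signal(p[strong & active], x[strong & active], truncation=truncation)
    est_w = estimate_signal(p[~strong & active], x[~strong & active], truncation=truncation)
    sol = optimize_weights(m_s, m_w, est_s, est_w, alpha, grid_points=grid_points)
    weights = np.ones(p.size)
    weights[strong & active] = sol.w_strong
    weights[~strong & active] = sol.w_weak
    return WeightedAnalysis(
        weights=weights,
        weighted_p=weight_pvalues(p, weights),
        est_strong=est_s,
        est_weak=est_w,
        solution=sol,
        excluded=excluded,
    )


def genomic_inflation(stats_vec: np.ndarray) -> float:
    """Genomic inflation factor: median chi2_1 statistic / 0.4549."""
    x = np.asarray(stats_vec, dtype=float)
    if x.size == 0:
        raise ValueError("empty statistic vector")
    return float(np.median(x) / _CHI2_1_MEDIAN)
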