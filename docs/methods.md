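# Methods

## Model

Association test statistics are χ² with 1 degree of freedom (the basic
allelic test, or any 1-df test supplied through a PLINK-style `.assoc`
table; p-values are inverted to χ²₁ statistics when the statistic column is
absent). Within each clue set *G* ∈ {strong, weak} the statistics are
modelled as independent draws from the two-component mixture

    π₀,G · χ²₁  +  (1 − π₀,G) · χ²₁(δ_G)

with a single common non-centrality δ_G per set — the set's signal
strength. This "one δ per set" assumption is deliberately coarse: it makes
the average-power objective a smooth one-dimensional function of the weight
split and keeps the optimisation deterministic. It is wrong in detail for
real genomes (effect sizes vary), but the weighting only needs the relative
ordering of evidence between the two sets, not per-SNP effect sizes.

## Risk scoring

Base scores per gene-feature class: nonsynonymous and splice site 3,
synonymous and UTR 2, intron and up/downstream 1, intergenic 0. Non-gene
bonuses are +2 each for conservation ≥ 0.8 (score in [0,1]), one-sided
positive-selection score ≥ 2.0 (iHS-like, unbounded), and presence of a
microRNA binding site; missing values never qualify. SNPs whose gene is in
the extended candidate set get +3. The table is configurable; its defaults
are pinned by two structural constraints: any SNP in or within the 2 kb 5′ /
500 bp 3′ window of a candidate gene must reach the strong-clue cutoff of
4, and an intergenic SNP must need at least two qualifying non-gene
features to reach it. LD-proxy score transfer (r² > 0.9 by default) can
only raise scores, never lower them, and is idempotent.

Candidate extension unions three sources: the seeds themselves, co-members
of any pathway of size 2–300 containing a seed, and genes within 2 edges of
a seed in the PPI graph (self-loops and duplicate edges collapsed).
Pathway/PPI record order never affects the result.

## Estimation

**π₀ (Storey–Tibshirani).** π₀(λ) = #{p > λ}/((1 − λ)m) on the grid
λ = 0.05, 0.10, …, 0.95; a cubic polynomial is fitted to (λ, π₀(λ)) and
evaluated at λ = 0.95, then clipped to [10⁻⁴, 1]. If every p-value lies
below the smallest λ there is no null mass to estimate from and the
estimate is 0 (flagged by a warning). For sets of a few hundred SNPs the
estimator is noisy (the λ = 0.95 bin holds ~5% of the set); this is the
binding limitation in small-set simulations, discussed below.

**δ (truncated first-moment matching).** With m₁ = round((1 − π₀)m) fixed,
δ solves

    mean of statistics above t  =  E[X | X > t],
    X ~ π₀·χ²₁ + (1 − π₀)·χ²₁(δ),

where t is the truncation point (default: the central χ²₁ quantile at
p = 0.05, i.e. 3.841; configurable). The truncated moments are computed
exactly via x·f_k(x; δ) = k·f_{k+2}(x; δ) + δ·f_{k+4}(x; δ), i.e.
E[X·1{X>t}] = k·S_{k+2}(t; δ) + δ·S_{k+4}(t; δ) with S the survival
function — no quadrature. The right-hand side is strictly increasing in δ,
so Brent root-finding on δ ∈ [0, 10⁴] (tolerance 10⁻⁶) is reliable. If
m₁ = 0, or the observed truncated mean does not exceed the all-null
truncated mean, the estimate is 0 with a no-signal flag.

## Weight optimisation

Power of one weighted test: P(w; δ) = P(χ²₁(δ) > q) with q the upper
w·α quantile of central χ²₁ — computed from the exact non-central χ² tail
rather than the asymptotically equivalent one-sided normal form (the two
agree to better than 10⁻⁹ relative at genome-wide α; the exact form makes
the δ = 0 identity P = w·α hold to machine precision).

The budget m_S·w_S + m_W·w_W = m_S + m_W (mean weight one) reduces the
search to w_S ∈ [1, (m_S + m_W)/m_S]; the ordering w_S ≥ 1 ≥ w_W then
holds automatically. A 1,000-point uniform grid locates the optimum of the
average power and bounded golden-section refinement sharpens it; there is
no randomness. With the published set sizes 1194/8088 and the weak weight
at its floor 0.001, the budget pins the high weight at 7.77.

SNPs already significant by Bonferroni on the *original* p-values gain
nothing from up-weighting (power gain peaks at mid-size signals and
vanishes for very strong ones), so they keep weight 1 and are excluded
from estimation and the budget; this is configurable off.

## Iteration

Seeds → extension → scoring/classification → estimation/optimisation →
weighted p-values → new seeds = top-20 genes by minimum weighted SNP
p-value (gene assignment includes the up/downstream windows; ties break
lexicographically). Convergence: both weights move ≤ 10⁻⁶ between
consecutive iterations; cap 20 iterations. Because every stage is
deterministic, a repeated weight pair is a fixed point. Pre-defined seed
genes only enter iteration 0 and may be dropped by re-seeding, which
avoids hard-wiring the prior into the final ranking.

## Simulator

One causal SNP per configuration: population genotypes in Hardy–Weinberg
proportions at the given minor allele frequency; penetrances
(f₀, f₁, f₂) solved from the model — dominant f₁ = f₂ = GRR·f₀,
multiplicative f₁ = GRR·f₀, f₂ = GRR²·f₀ — with f₀ set by the prevalence
(configurations implying a penetrance above 1 are rejected). Case and
control genotype distributions follow by Bayes' rule; null SNPs are
simulated directly as binomial allele counts with identical frequencies
(uniform MAF in [0.05, 0.5]) in both groups. Default causal MAFs mirror
the three planted susceptibility SNPs (0.0750, 0.2167, 0.4167). All
randomness flows through one seeded `numpy` generator and every result
records its seed.

Null SNPs are independent — no linkage disequilibrium — so weighted
Bonferroni FWER control is exact in theory; the slight false-positive
inflation that LD produces in real panels is therefore *not* reproduced
here, and passing FWER tests say nothing about LD-structured data.
Likewise the classification stage of the simulated pipeline assigns a
random 3% of null SNPs to the strong-clue set rather than re-deriving
annotation, which preserves the statistical structure (one true signal
among mostly-null strong-clue SNPs) but none of the biological texture.

**Scaled-down Monte-Carlo conditions.** The full-pipeline power
experiment uses 5,000 null SNPs plus one causal SNP (MAF 0.0750, dominant,
GRR 1.55, prevalence 0.10 — a late-onset-Alzheimer-like configuration),
1,000 replicates, and the per-group sample size solved analytically from
the allelic-test non-centrality so that unweighted Bonferroni power is
50%. Per replicate the pipeline re-estimates π₀, δ and the weights from
that replicate's own p-values. Observed gain is ~13–16 percentage points
across seeds. The limiting factor is π₀ estimation on the 151-SNP strong
set: its sampling noise swamps the true (1 − π₀) ≈ 0.007, so m̂₁ = 0 and
the weights stay at 1 in roughly two-thirds of replicates; when m̂₁ ≥ 1
the optimizer correctly pushes the whole budget onto the strong set. At
genome scale (hundreds of thousands of SNPs, thousands of strong-clue
SNPs) the estimator noise shrinks and the weighting activates far more
reliably — the scaled-down gain is a conservative reading.

## Enrichment

Upper-tail cumulative hypergeometric probabilities are summed in log space
(logpmf + logsumexp) for stability at very small p. Coverage of a
reported-gene list by the extended candidate set is the overlap fraction
with the same upper-tail p-value; pathway enrichment applies the test per
pathway (size filter 2–300 first) with Benjamini–Hochberg across pathways
at 5%. The gene-universe size N is always an explicit argument — it is a
property of the genotyping platform and annotation vintage, not of the
method.

## Numerical notes and edge cases

- Genomic inflation λ_GC = median(χ²)/0.45494 (exact central χ²₁ median).
- Weighted p-values are capped at 1; weight 0 maps p to 1 with a warning.
- `optimize_weights` returns (1, 1) flagged uninformative when neither set
  shows signal; `average_power` refuses m₁,S = m₁,W = 0.
- The weight search stops a grid-hair short of the upper budget boundary
  so w_W·α stays strictly positive; boundary optima are reported to ~10⁻³
  relative.
- BED gene models are converted to 1-based inclusive coordinates on read;
  everything internal is 1-based inclusive.

## Known limitations

- Two clue sets only; no per-SNP continuous weights.
- No LD-aware simulation or enrichment correction.
- The small-set π₀/δ estimators are high-variance below ~1,000 tests per
  set; interpret per-set estimates on small panels with care.
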