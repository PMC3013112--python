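# kbweight

Knowledge-based p-value weighting to boost the power of genome-wide
association studies (GWAS).

Marker-by-marker GWAS are underpowered for susceptibility loci of modest
effect: at genome-wide significance thresholds (α ≈ 0.05/300,000 per test)
a SNP with a moderately non-central test statistic is usually missed.
`kbweight` raises the power for the SNPs most likely to matter by combining
two ingredients:

1. **Bioinformatics classification.** Every SNP receives an integer risk
   score from its gene-feature class (non-synonymous, splice site, UTR,
   intron, up/downstream, intergenic), bonuses for promising non-gene
   features (cross-species conservation ≥ 0.8, positive-selection score
   ≥ 2.0, microRNA binding site; +2 each) and a +3 bonus when it lies in or
   near a candidate gene. Candidate genes are grown from seed genes through
   shared pathways (GMT, sizes 2–300) and the two-level protein–protein
   interaction (PPI) neighbourhood. Scores ≥ 4 define the **strong-clue
   set**; the rest form the **weak-clue set**. Near-candidate-gene SNPs
   always reach the cutoff; intergenic SNPs need at least two qualifying
   non-gene features.

2. **Statistical exploration.** Within each set *G* ∈ {S, W} the χ²₁
   association statistics follow the mixture
   π₀,G · χ²₁ + (1 − π₀,G) · χ²₁(δ_G). π₀ is estimated by the
   Storey–Tibshirani smoother, the signal strength δ by first-moment
   matching on the truncated mixture, and the per-set weights (w_S, w_W)
   maximise the average power of the weighted Bonferroni test

   m₁ᴬᵛᵍ power = (m₁,S·P(w_S; δ_S) + m₁,W·P(w_W; δ_W)) / (m₁,S + m₁,W),
   P(w; δ) = P(χ²₁(δ) > χ²₁⁻¹(1 − wα)),

   subject to the mean-one budget m_S·w_S + m_W·w_W = m_S + m_W (which
   preserves family-wise error control) and the ordering w_S ≥ w_W.
   Weighted p-values are p/w (capped at 1) and remain valid inputs to
   Bonferroni and Benjamini–Hochberg corrections.

The two parts iterate: the top-*n* genes by weighted p-value become the
next round's seed genes, until the weight pair converges.

A case-control simulator (Hardy–Weinberg genotypes, penetrances solved
from the disease model, allelic χ² tests) and hypergeometric enrichment
statistics round out the toolkit.

## Worked example

Generate a synthetic input bundle, score it, and run one weighting pass:

```bash
kbweight fixture --out-dir demo --n-snps 2000 --n-genes 250 --planted-signals 8 --seed 5
kbweight annotate --annotation demo/annotation.tsv --pathways demo/pathways.gmt \
    --ppi demo/ppi.tsv --seeds demo/seeds.txt --out demo/scores.tsv
kbweight weight --assoc demo/assoc.tsv --scores demo/scores.tsv --out demo/weighted.tsv
```

which prints

```
strong: 426  weak: 1574
w_strong=4.7383 w_weak=0.000100 avg_power=0.0108
lambda_GC=0.93457
```

426 of 2,000 SNPs carry strong functional clues; the optimizer pushed
essentially the whole weight budget onto them (w_S ≈ 4.7, the weak-set
weight floored near 0), because the planted association signals all sit
in the strong-clue set and the weak set shows no evidence of signal. The
genomic inflation factor λ_GC ≈ 0.93 confirms the null SNPs are well
calibrated.
`demo/weighted.tsv` lists each SNP's original p, clue set, weight and
weighted p. The same loop with iterative re-seeding runs via
`kbweight iterate`, and `kbweight simulate` / `kbweight enrich` expose the
power simulator and pathway enrichment.

From Python:

```python
from kbweight import hypergeom_upper_tail
hypergeom_upper_tail(15300, 219, 555, 32)   # 1.64e-11
```

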