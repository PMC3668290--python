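# Methods

## The screening procedure

`mbmdr-robust` implements Model-Based Multifactor Dimensionality Reduction
(MB-MDR) for quantitative traits. For each unordered pair of bi-allelic SNPs
the n individuals are partitioned into the nine two-locus genotype cells
(minor-allele counts 0/1/2 at each SNP). The analysis has two steps:

1. **Cell labeling (dimensionality reduction).** Each cell is compared with
   the pooled remaining individuals by a two-group test — the pooled-variance
   Student's t (default) or Welch's unequal-variance t. A cell is labeled
   **H** when the test is significant at `alpha_label` (two-sided) with the
   cell mean above the rest, **L** when significantly below, and **O**
   otherwise. Any cell contributing fewer than `min_cell` individuals to
   either side of the comparison is labeled O without testing.
2. **Association on the reduced construct.** The pooled H individuals are
   tested against all others, likewise the pooled L individuals, with the
   same two-group test; the per-pair evidence is the larger of the two
   squared statistics, reported as an ANOVA F value. A branch with no
   labeled cells, or failing the `min_cell` rule, contributes F = 0, so every
   pair always has a well-defined statistic.

Because the step-2 statistic is a maximum of two data-selected comparisons,
its null distribution is stochastically larger than the nominal
F(1, n − 2); no parametric reference is used. Instead the familywise error
rate over all m(m−1)/2 pairs is controlled by the **Westfall–Young step-down
maxT** permutation procedure: the trait vector is permuted across
individuals B times (genotypes fixed), the *entire* two-step analysis —
including relabeling — is re-run per permutation, and for hypotheses ranked
by decreasing observed F the adjusted p-value at rank r is
(1 + #{permutations whose successive maximum over ranks ≥ r is ≥ the
observed value}) / (B + 1), with monotonicity enforced down the ranking.
The +1 convention keeps adjusted p-values in [1/(B+1), 1]. Ties among
observed statistics are broken by the stable lexicographic pair order;
permutation comparisons use ≥.

Relabeling inside every permutation is what makes the permutation null
honest: the selection step is part of the statistic being calibrated.

### Why Welch's t collapses inside MB-MDR

Welch's statistic for a small cell against a large remainder has few
effective degrees of freedom, so its null distribution has heavy tails. The
maxT correction compares raw F values across pairs, and the permutation
maxima are dominated by these heavy-tailed unbalanced comparisons; a true
signal in a balanced comparison (the causal checkerboard pools ~n/2 vs
~n/2) cannot compete. The package reproduces this conservativeness; it is a
property of the max-statistic construction, not a defect of the test.

## The simulator

Traits follow a pure-epistasis two-locus "checkerboard" model: the trait
mean is raised by β for individuals heterozygous at exactly one causal locus
and homozygous at the other (cells (0,1), (1,0), (1,2), (2,1) of the 3×3
grid). With both causal MAFs at 0.5 under Hardy–Weinberg equilibrium these
four cells carry probability p_high = 0.5 and neither SNP has a marginal
effect. Genotypes are Binomial(2, maf) per SNP (HWE) with independent
columns (linkage equilibrium); noise-SNP MAFs are redrawn per replicate from
U(0.05, 0.5).

Residuals, conditional on the causal-pair cell, come from one of three
families × {equal, unequal} variances:

| family | homoscedastic | heteroscedastic |
|---|---|---|
| normal | variance = average of one U(1,10)⁹ draw | nine variances ~ U(1,10) |
| chi-square | central χ²(2) (mean 2, var 4) | noncentral χ²(df, ncp), df ~ U(2,10), ncp = 10 − df → constant mean 10, var 2·df + 4·ncp ∈ (20, 36] |
| Student's t | t(3) (var 3) | t(3) rescaled to per-cell variances ~ U(3,10) |

Per-cell parameters are redrawn for every replicate; df draws are
continuous. For the heteroscedastic t family an alternative reading —
per-cell df ~ U(3,10) instead of per-cell variances — is plausible, so it is
exposed as `SimulationConfig(t_hetero_mode="df")`; the variance reading is
the default because it parallels the normal family's construction and
actually perturbs homoscedasticity by a controlled amount.

**Signal injection and calibration.** The epistatic signal is an additive
mean shift β on the high cells on top of the family's residual draw — the
one mechanism that defines "fraction of phenotypic variance that is
epistatic" uniformly across all three families. Writing σ² for the expected
residual variance (the average of the nine per-cell variances) and p for
p_high, the genetic variance of β·I(high) is β²p(1−p), so

    β = sqrt( g²/(1−g²) · σ² / (p(1−p)) )

yields Var(genetic)/Var(total) = g². `g2 = 0` gives β = 0 exactly, so the
null settings are untouched by this choice. Large-sample tests confirm the
realized variance fraction matches the configured g² for every family.

**What the generator does not emulate:** linkage disequilibrium, related
individuals, missing genotypes, main effects, covariates, and more than two
causal loci. Passing tests therefore demonstrate the method's operating
characteristics under clean, complete, unlinked data — not robustness to
the correlated-SNP settings where subset pivotality of maxT is in doubt.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `n_individuals` | 500 | unrelated individuals per replicate |
| `n_noise_snps` | 98 | noise SNPs (plus 2 causal → m = 100) |
| `causal_maf` | 0.5 | makes the checkerboard purely epistatic |
| `g2` | 0 / 0.05 / 0.1 | epistatic fraction of trait variance |
| `alpha_label` | 0.1 | two-sided level of the H/L labeling tests |
| `min_cell` | 10 | minimum group size, enforced on **both** sides of every comparison |
| `n_permutations` (B) | 999 | maxT permutations (199 in the reduced presets) |
| `alpha_overall` | 0.05 | level applied to adjusted p-values |

`alpha_label = 0.1` is the conventional MB-MDR labeling threshold; it is a
config knob, and power (not error control — the permutation null absorbs the
labeling rule) is mildly sensitive to it.

## Numerical choices

- The vectorized engine computes every two-group statistic from per-cell
  counts, trait sums and sums of squares, obtained for all pairs and all
  permutations at once through genotype-grouped matrix products. Labeling
  significance for Student's t is decided by comparing t² against the
  critical value at `alpha_label` (df = n − 2 is constant), avoiding p-value
  evaluation; Welch labeling evaluates the t tail probability only where the
  statistic exceeds the normal-approximation lower bound of the critical
  region. Step 2 needs no p-values at all — maxT works on raw F values.
- Degenerate comparisons (zero pooled variance, undersized groups) are never
  errors inside a scan: the cell is O, the branch contributes F = 0.
- The engine agrees with a naive loop-based re-implementation to relative
  1e-9 on statistics and exactly on adjusted p-values; bit-identity is not
  expected because BLAS and sequential summation round differently.
- Transformations: the log transform shifts non-positive traits by
  −min + 1 before taking logs (the arm must be defined for Gaussian traits;
  any order-preserving policy leaves rank-based downstream results
  unchanged). Rank-to-normality uses the plotting position (r − 0.5)/n
  (symmetric, never 0 or 1); r/(n+1) is available as an option. Ties receive
  average ranks, matching the Mann–Whitney equivalence of the rank-t test.
- Per-replicate random streams derive from
  `SeedSequence([master_seed, setting_code, replicate_index])`, so every
  replicate, and every full study, is reproducible bit-for-bit from one
  integer seed; permutation indices derive analogously and are shared across
  analysis arms, pairing arm contrasts replicate-by-replicate.
- Replicates run sequentially; the study grid writes per-setting JSON
  checkpoints so interrupted runs resume. Sequential execution keeps the
  determinism story trivial, and single-replicate scans are already
  vectorized enough (~1 s at n = 500, m = 100, B = 199) that a study is
  practical without a worker pool.

## False-positive rate definition

For g² > 0 settings the reported false-positive rate is the fraction of
replicates in which **at least one non-causal pair** is significant (a
familywise-style rate, matching the ~α magnitude of the reference results).
The per-replicate indicator triple (causal, any non-causal, any) is exposed,
so a mean-count-per-replicate definition can be computed from the same runs
if preferred.

## Problem sizes used by the shipped checks

Full scale is R = 1000 replicates × B = 999 permutations per setting. The
package's own test suite and the acceptance script use reduced scales chosen
as the smallest runs that remain decisive under binomial error: the
acceptance script uses B = 199 with R = 200 (rate estimates, m = 25 for the
null run) or R = 100 (power estimates, m = 100); the test suite uses R of
40–150 with assertions widened by three combined binomial standard errors.
At B = 199 the adjusted-p granularity is 1/200, which adds ±0.005-level
jitter to rate estimates against the α = 0.05 threshold.

## Known limitations

- maxT's strong FWER control relies on subset pivotality; under LD or
  highly variable MAFs that assumption can fail, and this package makes no
  attempt to correct for it (bootstrap-based nulls are out of scope).
- Only two-locus models, quantitative complete-data traits, and unadjusted
  (no main effect / covariate) screens are supported.
- Welch labeling uses the Welch–Satterthwaite approximation, which is poor
  for cells near the `min_cell` floor; this is intrinsic to the method
  variant being studied, not worked around.
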