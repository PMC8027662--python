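# Methods

## Setting and notation

A single SNP *g* instruments an exposure *x* against a trait *y* using
summary statistics from two independent GWAS. All association strength is
carried on the 1-df chi-square scale, W = (b̂/SE)²; every p-value is the
1-df chi-square upper tail (equivalently a two-sided normal tail). The
instrument is selected because its exposure association passes a p-value
threshold (default 5×10⁻⁸, the genome-wide convention), which on the
chi-square scale is W_gx ≥ 29.71679 and, through the simple-regression
identity |ρ̂| = 1/√(1 + (n−2)/W), imposes a floor on the attainable
|sample correlation| (0.4823663, 0.1700451, 0.05443772 at n = 100, 1000,
10,000) and hence on its Fisher-Z transform (`SelectionDesign` bundles
these conversions).

## The tests

**SMR.** T_SMR = W_gx·W_gy/(W_gx + W_gy), referred to a 1-df chi-square.
Algebraically T_SMR is half the harmonic mean of the two Wald statistics,
so T_SMR < min{W_gx, W_gy} whenever both are positive: the test is
intrinsically conservative for its effective null "b_gx = 0 or b_gy = 0",
before any selection effect is added. The degenerate both-zero input is
defined as (0, p = 1), the limit along W_gx = W_gy → 0, to keep pipelines
total.

**Min-test.** min{W_gx, W_gy} with p = max of the marginal p-values:
rejects iff both marginals reject, and its rejection set strictly contains
SMR's at every level.

**Conditional test.** Selection guarantees b_gx ≠ 0, so under instrument
validity (no pleiotropy — assumed, not checked) the causal null reduces to
b_gy = 0, tested by W_gy alone. W_gy comes from the independent trait GWAS
and is untouched by exposure-side selection, so the test is exactly
calibrated. Multiplicity is corrected only over the m genes that carry a
selected instrument (strict inequality p < α/m; m = 9639 genes gives
5.18726×10⁻⁶ at α = 0.05). Bonferroni is the only correction implemented.

**MR Steiger.** T = (z_gx − z_gy)/√(1/(n_x−3) + 1/(n_y−3)) with
z = arctanh(|ρ̂|), referred to N(0,1); significant-and-positive orients
x → y, significant-and-negative y → x, otherwise undetermined. The
absolute-value transform is the convention of the directionality test; a
signed variant (`fisher_z_signed`) is exposed separately. Under selection
the z's are left-truncated normals — mean shifted up, variance shrunk —
and with n_x ≠ n_y the two truncations bite unequally, so the realized
size at nominal 5% ranges from ~3% (mild selection) to ~10% (severe
selection) in the shipped experiments.

**Truncated-normal LRT.** The remedy models each selected z as a normal
with known scale 1/√(n−3) left-truncated at its known cutoff c, and tests
equal means by 2·log(L1/L0): L1 maximizes each study's conditional
likelihood separately, L0 under a common mean. Numerics: each
maximization is a bounded Brent search (xatol 1e-10) on the single shared
interval [min(z) − 10·max(sd), max(z) + 10·max(sd)]; sharing one interval
between the constrained and unconstrained fits guarantees the statistic is
non-negative by construction. The conditional likelihood of an observation
landing near its cutoff peaks far to the left (approximately
c − sd²/(z − c)), and exactly at z = c it increases without bound as the
mean decreases; a maximizer pinned at the interval boundary is therefore
reported with `converged = False`, never silently. The log-density uses
`norm.logsf` for the truncation denominator so deep truncation stays
finite.

The reference distribution for the LRT p-value is a genuinely open choice:
with one observation per likelihood term the usual chi-square asymptotics
have no n to grow. The default is the 1-df chi-square (standard LRT
practice); a parametric bootstrap (simulate pairs under the fitted common
mean with the same truncation, recompute, add-one p-value) is available
and recommended when the decision is close. A related caveat: the
single-observation conditional MLE is heavy-tailed to the left, so it
corrects the winner's curse in median but its mean overcorrects; the test
suite checks median bias reduction.

## Simulation engines

**Chi-square selection.** Wald draws are generated as (Z + √ncp)², Z
standard normal — exactly noncentral chi-square(1, ncp) while keeping a
single normal RNG dependency. With ncp = 13 and the genome-wide cutoff,
the analytic exceedance probability (normal-tail identity, cross-checked
against `scipy.stats.ncx2`) is 0.03246, so ≈ 325 of 10,000 draws survive.

**Wald-ratio selection.** b̂_gx ~ N(b_gx, 1), b̂_gy ~ N(0, 1) independent;
the unselected ratio b̂_gy/b̂_gx is fat-tailed (Cauchy-like as the
denominator mean shrinks), while conditioning on b̂_gx² ≥ cutoff pins the
denominator away from zero and the selected ratios pass normality checks.

**Steiger selection.** z_gx ~ N(arctanh ρ, 1/(n_x−3)) and independently
z_gy ~ N(arctanh ρ, 1/(n_y−3)); a replicate is retained iff both z's clear
their Fisher-Z cutoffs (selection on z, not |z| — the rule actually
applied when rows are kept by p-value with a concordant sign convention).
Draw order is fixed (all z_gx, then all z_gy) and one seeded generator
serves each experiment, so a seed reproduces results bit-exactly. The
shipped configurations are (ρ, n_x, n_y) = (0.15, 10³, 10⁴),
(0.19, 10³, 10⁴), (0.015, 10⁵, 3×10⁵), (0.015, 1.5×10⁵, 4×10⁵) at 10,000
replicates each — seconds of work. The closed-form selection probability
(product of two normal upper tails) bounds every simulated count; with an
unknown external seed, simulated quantities match published ones in
distribution, within Monte-Carlo error, not bit-exactly.

**Synthetic eQTL study.** Genotypes: per-SNP MAF uniform on [0.05, 0.5],
two haplotypes from a latent AR(1) Gaussian (adjacent correlation 0.5 by
default, 200 cis-SNPs per gene) thresholded at the MAF quantile — HWE
marginals with first-order LD. These synthetic genotypes stand in for a
real reference cohort; they reproduce the selection mechanism, which is
what drives the calibration results, but not real LD block structure,
allele-frequency spectra or population stratification, so passing tests
speak to the selection effect, not to any specific cohort. Expression:
n_causal SNPs chosen uniformly, standard-normal effects, then the realized
genetic component rescaled to sample variance h² and the residual to
1 − h² — the variance partition is exact by construction, removing a
nuisance source of Monte-Carlo noise from calibration checks. The scan is
closed-form per-SNP OLS (vectorised); p-values come from the chi-square of
the Wald statistic so they are exactly consistent with the package's
chi-square-scale convention (at the sample sizes used the difference from
the exact t reference is negligible). Constant genotype columns are
flagged and skipped, not fatal; top-SNP ties break to the lowest index.
Null GWAS signals are independent standard-normal z's, so W_gy is exactly
1-df chi-square and the conditional test must be calibrated — the
experiment's internal control. The default experiment in the test suite
uses 2,000 genes at N = 1000, five causal eQTLs, h² = 0.4 (about half a
minute); the per-gene SNP count (200) and LD (0.5) are fixed design
choices, not tuned.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| p_threshold | 5×10⁻⁸ | p-value | genome-wide convention; sets all cutoffs |
| n_x, n_y | — | individuals | Fisher-Z variance is 1/(n−3); asymmetry drives Steiger miscalibration |
| ρ | — | correlation | true SNP–trait correlation; with the cutoffs, determines selection severity |
| n_reps | 10,000 | replicates | matches the shipped experiments; binomial MC error ≈ 4·√(p(1−p)/n) |
| h², n_causal, N | 0.4, 5, 1000 | — | eQTL architecture; per-SNP noncentrality ≈ N·h²/n_causal governs selection rate |
| ld_rho, n_snps | 0.5, 200 | — | cis-window LD and density; affect the top-SNP maximum, not the null GWAS side |

Monte-Carlo tolerance convention throughout the tests: 4·√(p(1−p)/n) for
proportions and 4·sd/√n for means (≲10⁻⁴ false-failure rate), multiplied
by √2 when the comparison value is itself a Monte-Carlo draw from an
unknown seed.

## Limitations

- Single-instrument inference only; no multi-SNP estimators, no
  heterogeneity/pleiotropy diagnostics. The conditional test inherits the
  no-pleiotropy assumption outright.
- The truncated LRT treats the cutoff as the only selection event; real
  pipelines select the *most significant* of many correlated SNPs, a
  harder conditioning event that none of the closed forms capture.
- The synthetic genotype model is exchangeable across genes and has no
  population structure; calibration conclusions transfer to real cohorts
  only insofar as the selection mechanism, not genotype realism, is the
  driver.
- p-values on the chi-square scale assume the large-sample normal
  approximation of the underlying estimates; very small studies (n < 30)
  are outside the intended regime.
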