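# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the design decisions behind `tsmr`, in the order data flows
through the pipeline.

## Data model and harmonization

A `SummaryStats` table holds one GWAS's per-SNP statistics (variant id,
effect/other allele, effect-allele frequency, beta, SE, p, N). Betas are
per-effect-allele effects: log odds ratios for binary traits, SD or native
units for continuous ones. The reader drops malformed rows (non-positive SE,
p outside (0,1], bad alleles) and counts them; the constructor enforces the
invariants strictly.

Harmonization aligns every dataset to the **first exposure's effect allele**.
Swapped alleles flip the beta sign and replace eaf with 1−eaf; strand
complements are recognized for non-palindromic SNPs. Strand-ambiguous (A/T,
C/G) SNPs cannot be resolved by letters: by default they are dropped
(`palindrome_policy="drop"`, conservative and reproducible when frequencies
are missing); `infer_by_eaf` orients them by allele frequency when both
frequencies lie outside 0.5 ± `eaf_window` (default 0.08). Matching is by
variant id only — all intended sources share rsID space, so no coordinates or
liftover are needed. Every shared SNP is either retained or logged with a
drop reason, so retained + dropped always equals the intersection.

## Instrument selection

Four filters in order, each recorded per SNP: genome-wide significance
(strict p < 5×10⁻⁸), greedy LD clumping, the weak-instrument filter
F = β²/SE² ≥ 10 (retained at equality), and an explicit exclusion list for
variants known to act through confounders (Phenoscanner-style lookups are
out of scope; their result enters as the list). Clumping repeatedly takes
the remaining SNP with the smallest p as an index and discards SNPs with
r² > 0.001 against it or within 10,000 kb on the same chromosome; p-value
ties break lexicographically by SNP id so the output is independent of row
order. Clumping consumes a user-supplied LD matrix rather than a reference
panel, keeping the package download-free; with no matrix the step is skipped
with a logged warning (pre-clumped input). A SNP missing from the matrix is
a hard error — silently keeping it would bias the panel toward dependence.

## Univariable estimators

All estimators consume the harmonized arrays; p-values are two-sided normal
(consistent with the Wald CIs, z = Φ⁻¹(0.975) ≈ 1.96), and odds-scale output
is exp(β ∓ z·se), rounded only at presentation. The random-effects IVW uses
multiplicative overdispersion with a max(1,·) floor — the random-effects fit
can never be more precise than the fixed-effects one. MR-Egger orients all
exposure effects non-negative before fitting (the identification convention
for its intercept) and scales both SEs by max(1, √(Q′/(k−2))).

Weighted-median and mode SEs come from a parametric bootstrap (β̂ resampled
from normal(β̂, se), default 1000 draws, seed required by the pipeline
config). The mode uses a 2048-point grid spanning [min θ̂ − 3h, max θ̂ + 3h];
the grid argmax (lowest index on exact ties) is the estimate. Degenerate
case: when the MAD of the ratios is exactly zero, a strict majority of the
(weighted) mass ties at the median value, and the estimator returns that
value — the zero-bandwidth limit of the kernel mode. An SD-based fallback
bandwidth was rejected: with, say, ratios (0.5, 0.5, 0.5, 5.0) it
over-smooths and drags the mode a dozen grid steps off the dominant cluster.

## Sensitivity analyses

Cochran's Q is computed against the IVW fit (df k−1) and the Egger fit
(df k−2). When the IVW Q test rejects at 0.05 the pipeline labels the IVW
row random-effects, mirroring the main-analysis convention. Leave-one-out
refits IVW without each SNP; a SNP is flagged when its exclusion flips the
estimate's sign or moves it by more than a configurable multiple (default
1.0) of the **reduced-set** SE. The reduced-set yardstick is deliberate: a
full-set random-effects SE is inflated by the very outlier being probed
(self-masking), while the full-set fixed-effects SE flags everything once
any outlier is present.

The outlier test follows the residual-sum-of-squares simulation recipe:
RSS_obs uses leave-one-out IVW slopes; the null distribution draws
β′_X ~ N(β̂_X, se_X) and β′_Y ~ N(θ̂₋ⱼβ̂_X, se_Y) and recomputes RSS
(including the leave-one-out slopes) per draw. Empirical p-values carry the
+1/(n+1) correction so they are never zero. Per-SNP outlier p-values are
Bonferroni-adjusted by k; SNPs below 0.05 are removed and IVW refit. Note
Bonferroni makes the smallest achievable adjusted p equal k/(n_sim+1), so
n_sim must exceed ~20·k for the test to be able to reject at all (default
n_sim = 1000). The distortion test is intentionally not implemented — the
pipeline reports detect/remove/refit only.

## Multivariable MR and the lasso

MVMR-IVW is weighted least squares of β̂_Y on the k×M exposure-effect matrix
without intercept, SEs scaled by max(1, √(Q_A/(k−M))); a rank check names the
offending collinear pair. MVMR-Egger adds an intercept after orienting rows
by a chosen exposure. The weighted median variant is 0.5-quantile regression:
the check loss is positively homogeneous, so scaling each row by its weight
reduces the weighted problem to plain quantile regression (statsmodels
QuantReg), with parametric-bootstrap SEs. Conditional instrument strength is
reported per exposure as the mean of squared weighted-residualized effects
over se², but never filtered on — only the univariable F > 10 rule gates
instruments.

The lasso variant minimizes Σ w_j(β_Yj − α_j − x_jθ)² + λΣ|α_j|: every SNP
gets its own intercept, and a nonzero α̂_j marks it invalid. The objective is
jointly convex, solved by alternating the closed-form WLS update for θ with
the per-SNP soft-threshold α_j = soft(r_j, λ/(2w_j)), warm-started along a
50-point geometric λ grid from λ_max (where all α = 0) downward. λ is chosen
as the largest valid set whose IVW heterogeneity Q is below the χ² 0.95
critical value (df = set size − M), and the reported estimate is the IVW
refit on that set (post-lasso, so estimates stay comparable to IVW). With
λ → ∞ the fit equals MVMR-IVW; with λ = 0 the model interpolates and the
valid set is empty. A known behavioural limit, visible in the acceptance
simulations: a contaminated SNP whose post-fit residual is ≲3.5 z-units can
ride inside a set that still passes the Q gate, so "exact identification" of
5-se outliers plateaus around 60–75% — the Q-slack, not the optimizer,
binds. Larger offsets (the 10-se outlier-test scenario) are identified
essentially always.

## Multiple testing

Two Benjamini–Hochberg conventions are provided. The default is the
rank-scaled form adj_j = p_j·m/rank_j (ties share the largest rank), which is
the convention behind this analysis's reported adjusted values; `monotone=True`
gives the textbook step-up with the cummin pass (identical to R's `p.adjust`
and statsmodels `fdr_bh`). The two differ only where a rank-scaled value
exceeds a later one — for the six-test family here, only at the smallest p.
Tiers: significant (adjusted < 0.05), suggestive (raw < 0.05 ≤ adjusted),
null. Families are declared explicitly in the pipeline config; the
univariable family has m = 6 (3 exposures × 2 outcomes), the protein screen
m = 91.

## Mediation

Two-step product of coefficients with first-order delta-method SEs,
assuming the two steps come from independent samples (sample overlap across
biobank-derived sources is a documented caveat, not modeled). The direct
effect is β_TE − β_IE with SE √(se²_TE + se²_IE) under the same independence
caveat. The mediated proportion CI defaults to dividing the indirect-effect
CI by the total effect (`ie_ci_over_te`); `full_delta` additionally
propagates the total effect's uncertainty, and the Monte-Carlo check in the
tests shows the full-delta half-width within 10% of the simulated quantile
interval at the worked example's values. Step 2 uses the univariable
mediator→outcome estimate (matching the published layout); an MVMR-adjusted
step 2 can be assembled from the MVMR module when the mediator's instruments
overlap the exposure's. A mediator is reported as mediating when the normal
test of β_IE has p < 0.05.

## Synthetic data generator

Statistics are generated directly at the summary level — the estimators see
only summary data, so no individual-level genotypes are simulated. Per SNP:
maf ~ U(maf_range); instrument effect γ_j drawn **half-normal**(gamma_sd),
i.e. the effect allele is the exposure-increasing allele. The non-negative
orientation is load-bearing: with sign-symmetric γ, a "directional"
pleiotropy mean would cancel under the β_X ≥ 0 orientation and could bias
nothing, which contradicts what directional pleiotropy must do. Standard
errors use the standardized-trait approximation 1/√(2·maf(1−maf)·n)
(binary-outcome scaling absorbed into θ's interpretation); observed effects
are normal draws around truth, p-values from z = β/se (floored at 10⁻³⁰⁰),
and each dataset's file-level allele orientation is randomized per SNP so the
harmonizer always has real work. Pleiotropy α_j applies to a random
`prop_invalid` fraction: balanced N(0,τ), directional N(μ,τ), or correlated
δ·γ_j + N(0,τ) (violating instrument-strength-independent-of-direct-effect).

Defaults emulate the source-study scale: n ≈ 4–4.5×10⁵ per trait,
gamma_sd = 0.03, maf ∈ (0.05, 0.5) — giving post-selection F statistics
spanning roughly 30–700, the published instrument-strength band. The
statistical tests use an explicitly stronger scenario (n_exposure = 2×10⁶,
n_outcome = 5×10⁵, gamma_sd = 0.1) declared in the test fixtures, so that
finite-sample weak-instrument bias (order θ/F̄) is negligible against
Monte-Carlo error at the replication counts used.

Under mediation, β_M has mean b_EM·γ + η and β_Y mean
(θ_dir + b_EM·b_MY)·γ + b_MY·η + α, with η optional mediator-specific
instrument effects (sign-symmetric; without them the exposure and mediator
effect columns are exactly collinear and MVMR is unidentified). The
study-level composer `simulate_mediation_study` concatenates two panels —
the exposure's instruments and the mediator's own instruments (null exposure
effects) — reproducing the disjoint-instrument structure real two-step MR
relies on; with a single shared panel, step 2 would be confounded by the
exposure's direct effect.

What the generator does **not** emulate: realistic LD (the block model is
synthetic), sample overlap between the two samples, winner's curse at the
selection threshold beyond what the p-filter itself induces, allele-frequency
differences between populations, and binary-trait non-collapsibility. Passing
tests therefore demonstrate correctness of the estimators under the stated
generative assumptions, not robustness to those real-data complications.

## Calibration notes

- Cochran's Q and the global outlier test are exactly calibrated only when
  exposure-side noise is negligible (the NOME approximation): the residual
  variance is se_Y² + θ²se_X², so Q's rejection rate sits slightly above
  nominal (≈0.05–0.06 in the test scenario, which keeps se_X ≪ se_Y by
  giving the exposure the larger sample).
- The weighted median under one-sided contamination carries a finite-sample
  quantile-shift bias of ≈0.57·σ_ratio (the 0.5 weight quantile falls at the
  0.71 quantile of the valid ratios when 30% of weight is displaced one
  way). The bias-to-MC-error ratio is invariant to sample size, so the
  robustness test asserts the breakdown property itself — median bias an
  order of magnitude below IVW's and below 10% of the true effect — rather
  than strict unbiasedness.
- Problem sizes in tests and the acceptance script (100–500 replicates,
  k = 30–150, n_sim = 400–1000) were chosen so each property is measured
  with Monte-Carlo error well inside its assertion margin.

## Interfaces

The pipeline is a YAML-configured orchestration (trait files and roles,
instrument settings, estimator settings with mandatory seed, FDR family,
MVMR models, mediation triples). Every suite writes TSV tables shaped like
the study's published tables, a JSON bundle, and a manifest of inputs and
seeds; outputs contain no timestamps, so a rerun with the same config is
byte-identical. The CLI (`tsmr simulate|uvmr|mvmr|mediate|report`) is a thin
wrapper; `--threads` is accepted for interface compatibility and never
affects results. Whether the MVMR adjusts each sarcopenia trait for the
others, the confounders, or both is a config choice (each `mvmr:` entry
lists its own exposure set) — both readings of the source design are
expressible.
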