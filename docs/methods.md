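# Methods

## Model and estimators

The data are an abundance matrix X = (x_ij), p metabolites × n samples,
with a two-group design (g₁ control, n − g₁ disease samples).  The
classical volcano plot tests H₀: μᵢᶜ = μᵢᴰ per metabolite with the
two-sample t statistic and combines the p-value with the log₂ fold
change; the robust variant replaces the classical moments with
kernel-weighted ones.

**Kernel weights.** w_ij = exp(−λ (x_ij − m)² / (2 s²)), where m and s
are the median and the raw MAD (no 1.4826 normal-consistency factor) of
metabolite i's values within sample j's own group.  The weights lie in
(0, 1]; λ = 0 gives all-ones weights and the exact classical analysis.

*Scope of the median/MAD.*  The weight formula could also be read with
per-sample-column statistics.  We compute weights per metabolite within
each group (`weight_scope="row_group"`, the default) because the weights
multiply entries inside group-specific means; pooling the groups would
flag genuine between-group signal as outlying, and pooling metabolites
would compare incommensurable intensity scales.  The column-wise variant
remains available (`weight_scope="column"`).

*Degenerate scales.*  When the within-group MAD is 0 (more than half the
group identical) the mean absolute deviation is used instead; if that is
also 0 the group is constant, there are no outliers, and all weights are
1.  Computed weights are floored at 1e−300 so that float underflow
cannot produce an exact zero.

**Weighted moments.**  The default estimators are the standard weighted
mean X̄ = Σ w x / Σ w and the reliability-weighted variance
S² = Σ w (x − X̄)² / (Σw − Σw²/Σw), which reduce exactly to the
classical mean and n−1 variance when every weight is 1.  Dividing by the
raw group size instead (`weight_denominator="group_size"`) is offered
for comparison, but it shrinks the moments toward zero by the
down-weighted mass: under contamination that injects noise proportional
to μᵢ into the t numerator and destroys the robustness the weighting is
meant to buy, so it is not the default.

**Test statistic.**  Pooled variance with df = n − 2 by default; a
Welch-type unequal-variance statistic with Welch–Satterthwaite df is
selectable.  The test is two-sided (H₁: μᵢᶜ ≠ μᵢᴰ); a one-sided
upper-tail option exists.  Degenerate rows (both weighted variances 0)
give t = 0 when the means agree and ±∞ otherwise.  Note that the
kernel-weighted variance carries no consistency correction: at large λ
it underestimates the clean-data variance (the kernel suppresses exactly
the large deviations), so t values at λ > 0 are comparable *within* an
analysis (rankings, and hence ROC behaviour, are unaffected) but are not
calibrated against the nominal t distribution as finely as at λ = 0.
Since λ = 0 is selected whenever the data are clean, calibration holds
where it matters.

**Calling rule.**  differential ⇔ p < α and |log₂FC| > threshold
(strict; defaults α = 0.05, threshold 1).  Bonferroni-adjusted p-values
are always reported; the rule uses raw p-values by default and adjusted
ones with `adjusted_calling=True`.  An undefined fold change is never
called.

**Fold change and data scale.**  For raw intensity data,
log₂FC = log₂(X̄ᴰ/X̄ᶜ), undefined (NaN, with a logged warning) when a
group mean is non-positive — which is why fold changes should not be
computed on auto-scaled data.  For data already on the log₂ scale
(`data_scale="log2"`) the log₂ fold change is the difference of group
means.  The simulated benchmark uses the log₂ scale: its additive group
effects of ±2 are log₂-units, i.e. four-fold concentration changes,
which is the regime the |log₂FC| > 1 rule is designed for.

## Cross-validated λ selection

Samples are split into k group-stratified folds (shuffled with a seeded
generator, dealt round-robin, fold sizes within a group differing by at
most 1).  For each candidate λ and each fold, weights and weighted group
means are computed from the training samples only and every held-out
entry contributes |x_ij − X̄ᵢ^{G(j),train}|.  The fold loss is the
*median* of these absolute errors and the candidate's loss is the mean
over folds.  A median loss is essential: a mean (or squared) loss is
dominated by the held-out outliers themselves and cannot distinguish a
robust fit from a contaminated one.  Training predictions use
Σw-normalized means for the same reason the analysis does.

The chosen λ is the smallest candidate whose loss is within one standard
error (over the k fold losses, at the minimizing candidate) of the
minimum — the usual one-standard-error rule.  On clean data the loss
differences among small λ are orders of magnitude below the fold-to-fold
noise, so the rule deterministically prefers the classical λ = 0; under
contamination the λ = 0 loss exceeds the minimum by a large multiple of
the SE and a positive λ is selected.  A strict arg-min would instead
pick essentially at random among the near-equivalent small candidates on
clean data.

Defaults: grid {0, 0.01, 0.05, 0.1, 0.2, 0.5, 1, 2, 5} (from "classical"
to aggressive down-weighting), k = 5 (fits the 30-sample smaller group
of the benchmark design while leaving ≥ 3 training samples per group),
ties and near-ties resolved toward smaller λ by construction.

## Synthetic data generator

One-way ANOVA on the log₂ scale: y_ijk = μᵢ + g_ij + ε_ijk with
μᵢ ~ Uniform(10, 20) per metabolite and ε ~ N(0, 1) per entry.  Group
effects are drawn once per (metabolite, group): up-regulated metabolites
from N(4, 1) (disease) and N(2, 1) (control), down-regulated ones
swapped, so the expected disease − control difference is ±2 with
between-metabolite spread √2.  Non-differential metabolites draw a
*single* N(0, 1) effect shared by both groups: they are "equal
concentration" rows, and giving the two groups independent effect draws
would build a mean difference of SD √2 into rows labelled null — far
above the sampling error (≈ 0.24 at 40 + 30 samples) — so that no method
could separate truth from noise.  Defaults: 130 null + 10 up + 10 down
metabolites, 40 control + 30 disease samples.

Outliers: ⌊rate·p·n + 0.5⌋ distinct cells drawn uniformly over the whole
matrix; cell (i, j) is replaced by a draw from N(factor·μ̂ᵢ, σ̂ᵢ²) with
μ̂ᵢ, σ̂ᵢ² the mean and sample variance of row i of the
*pre-contamination* matrix (the only self-consistent choice when several
rates are applied to one base dataset).  Factor 3 for the synthetic
benchmark, factor 4 for contaminating measured matrices.  Everything is
bit-reproducible from (design, seed).

What the generator does *not* emulate: metabolite–metabolite
correlation, missing values, batch effects, heteroscedastic or
multiplicative noise, and heavy-tailed baseline error.  Passing
benchmarks therefore demonstrate robustness to gross entry-wise
contamination under an idealized independent-Gaussian background, not
performance on every pathology of real data.

## Evaluation suite

Confusion counts against the simulation truth with MER = (FP + FN)/p,
power = TPR, and FDR = FP/(FP + TP) (0 at zero discoveries).  ROC curves
sweep −log₁₀(p) (p floored at 1e−300), the one monotone score both
methods share — the binary volcano rule has no natural sweep, and at
λ = 0 this ranking is exactly the classical t-test's.  AUC is
trapezoidal; partial AUC integrates FPR ∈ [0, 0.2] with linear
interpolation at the cut and is reported unnormalized (maximum 0.2), a
normalized variant behind a flag.  Set stability between a clean and a
contaminated analysis is the symmetric difference of the two
differential id sets.

## Benchmark problem sizes

The replicated benchmark (tests and `scripts/acceptance.py`) uses 50
replicates per contamination level and 20 paired datasets for the
stability comparison, with full cross-validated λ selection per
replicate.  These sizes give paired sign tests and Monte-Carlo checks
ample resolution — the observed gaps (e.g. mean AUC ≈ 0.95 vs ≈ 0.55 at
15% contamination) are enormous relative to replicate noise — while
keeping the whole suite at the scale of seconds.

## Known limitations

Two groups only; no missing values (impute upstream); no moderated or
Bayesian variance shrinkage; no permutation p-values; per-metabolite λ is
not supported (one λ per dataset); the weighted variance is uncorrected
at λ > 0 (see above).
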