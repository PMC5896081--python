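# rvolcano

Outlier-robust volcano plots for differential metabolite identification in
two-group metabolomics studies.

## The problem

A volcano plot calls a metabolite *differential* between a disease and a
control group when its two-sample t-test gives p < α and its
|log₂ fold-change| exceeds a threshold (defaults: α = 0.05, threshold 1).
Both ingredients are built from group means and variances, which a single
aberrant measurement — instrument error, overlapping peaks, a mislabelled
sample — can wreck.  Metabolomics matrices routinely contain such outliers.

`rvolcano` implements a kernel-weighted variant (the *robust volcano plot*,
RVP) next to the classical one (CVP).  For the abundance matrix
X = (x_ij), p metabolites × n samples (g₁ control, n − g₁ disease), every
entry receives the weight

    w_ij = exp( −λ (x_ij − median)² / (2 · mad²) )

with the median and the (raw, unscaled) median absolute deviation computed
over the metabolite's values within the sample's own group.  Weighted group
means X̄ᵢᶜ, X̄ᵢᴰ and weighted variances S²_iC, S²_iD replace the classical
moments in

    log₂(FCᵢ) = log₂(X̄ᵢᴰ / X̄ᵢᶜ),
    t = (X̄ᵢᶜ − X̄ᵢᴰ) / sqrt( S²ᵢ (1/g₁ + 1/(n−g₁)) ),   df = n − 2,

(Welch-type unequal-variance t optional).  An entry at its group median
keeps weight 1; a gross outlier is driven toward weight 0 and loses its
influence.  At λ = 0 all weights are 1 and RVP *is* CVP, exactly.

λ is chosen by k-fold cross-validation: folds are stratified by group, each
held-out entry is predicted by its training-group weighted mean, the fold
loss is the median absolute prediction error (a robust loss — a mean loss
would be dominated by the very outliers the kernel suppresses), and the
smallest λ within one standard error of the minimal loss wins.  On clean
data this selects λ = 0 and the analysis reduces to the classical one.

The package also ships the simulation benchmark used to validate the
method: a one-way ANOVA generator on the log₂ scale
(y_ijk = μᵢ + g_ij + ε_ijk, μᵢ ~ U(10, 20), ε ~ N(0, 1); 130 null + 10
up- + 10 down-regulated metabolites × 40 + 30 samples; differential group
effects from N(4, 1) vs N(2, 1)), entry-wise outlier injection from
N(3 μᵢ, σᵢ²), and an evaluation suite (MER, ROC/AUC, pAUC at FPR ≤ 0.2,
power, FDR, differential-set stability).

## Worked example

Simulate a contaminated dataset, analyze it with cross-validated λ, and
score the calls against the simulation truth:

```sh
rvolcano simulate --out data.tsv --design-out design.tsv \
    --truth-out truth.tsv --outlier-rate 0.15 --seed 1
rvolcano run --data data.tsv --design design.tsv --lam auto \
    --data-scale log2 --seed 1 --out results.tsv --lambda-out cv.tsv
rvolcano evaluate --results results.tsv --truth truth.tsv --out report.tsv
```

The run log reports `RVP: lambda=0.05, 16/150 metabolites called
differential`.  The sidecar `cv.tsv` shows why λ = 0.05 was chosen — the
classical candidate λ = 0 predicts held-out entries poorly once 15% of the
cells are outliers:

```
lambda  cv_loss              chosen
0.0     4.8312703996789015   False
0.01    0.8876120021033559   False
0.05    0.8463079598518514   True
0.1     0.8476127254690052   False
...
```

and `report.tsv` scores the calls against the ground truth:

```
tp  fp  tn   fn  tpr  fpr  ...  mer      power  fdr  auc    pauc
16  0   130  4   0.8  0.0  ...  0.02667  0.8    0.0  0.965  0.18
```

16 of the 20 truly differential metabolites are recovered with zero false
positives despite the contamination; the same data analyzed with
`--method cvp` collapse (AUC ≈ 0.55, MER ≈ 0.16 on average).  Fold
changes here are differences of means because the simulated abundances are
log₂-scale (`--data-scale log2`); for raw intensity tables the default
ratio fold change applies.  Add `--plot volcano.png` for the figure.

The same operations are available as library functions
(`rvolcano.simulate_dataset`, `rvolcano.analyze`,
`rvolcano.evaluate_table`, ...).

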