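"""Scoring of differential calls against ground truth.

Confusion metrics (TPR/FPR/TNR/FNR), the misclassification error rate
MER = (FP + FN) / p, power and FDR of the calling rule, ROC curves with
(partial) AUC, and the stability of differential sets under
contamination.  For the volcano methods the ROC ranking score is
-log10(p-value): the binary volcano rule itself has no natural sweep,
and the p-ranking is the monotone score both CVP and RVP share (at
lambda = 0 it reproduces the classical t-test ranking exactly).  The
fold-change criterion enters MER/power/FDR through the calling rule but
not the ROC ranking.

The module also hosts the replicate drivers used by the benchmark: the
simulate -> select lambda -> analyze -> score loop, and the paired
clean/contaminated stability experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from sklearn import metrics as _skm

from .data import AbundanceMatrix, GroupDesign
from .simulate import SimulationDesign, TruthLabels, inject_outliers, simulate_dataset
from .stats import VolcanoTable, analyze
from .weights import DEFAULT_LAMBDA_GRID, KernelParams


@dataclass(frozen=True)
class EvalReport:
    """Confusion counts and derived rates for one set of calls."""

    tp: int
    fp: int
    tn: int
    fn: int
    tpr: float
    fpr: float
    tnr: float
    fnr: float
    mer: float
    power: float
    fdr: float
    auc: Optional[float] = None
    pauc: Optional[float] = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


@dataclass(frozen=True)
class RocCurve:
    """ROC points from (0, 0) to (1, 1), both coordinates nondecreasing."""

    fpr: np.ndarray
    tpr: np.ndarray

    @property
    def points(self):
        return list(zip(self.fpr, self.tpr))


def _truth_array(truth) -> np.ndarray:
    if isinstance(truth, TruthLabels):
        return truth.differential
    return np.asarray(truth, dtype=bool)


def confusion(flags, truth) -> EvalReport:
    """Standard 2x2 confusion of calls vs truth with MER, power, and FDR.

    FDR is defined as 0 when nothing is called (0/0 convention); rates
    with a zero denominator are reported as NaN.
    """
    flags = np.asarray(flags, dtype=bool)
    t = _truth_array(truth)
    if flags.shape != t.shape:
        raise ValueError(f"flags length {flags.size} != truth length {t.size}")
    tp = int(np.sum(flags & t))
    fp = int(np.sum(flags & ~t))
    fn = int(np.sum(~flags & t))
    tn = int(np.sum(~flags & ~t))
    pos, neg = tp + fn, fp + tn
    tpr = tp / pos if pos else float("nan")
    fnr = fn / pos if pos else float("nan")
    fpr = fp / neg if neg else float("nan")
    tnr = tn / neg if neg else float("nan")
    mer = (fp + fn) / flags.size
    fdr = fp / (fp + tp) if (fp + tp) else 0.0
    return EvalReport(tp=tp, fp=fp, tn=tn, fn=fn, tpr=tpr, fpr=fpr, tnr=tnr,
                      fnr=fnr, mer=mer, power=tpr, fdr=fdr)


def roc_curve(scores, truth) -> RocCurve:
    """ROC curve sweeping thresholds over the unique scores, ties grouped."""
    t = _truth_array(truth)
    scores = np.asarray(scores, dtype=float)
    if scores.shape != t.shape:
        raise ValueError("scores and truth lengths differ")
    if t.all() or not t.any():
        raise ValueError("ROC needs at least one positive and one negative")
    fpr, tpr, _ = _skm.roc_curve(t.astype(int), scores, drop_intermediate=False)
    return RocCurve(fpr=fpr, tpr=tpr)


def auc(curve: RocCurve) -> float:
    """Trapezoidal area under the full ROC curve."""
    return float(np.trapezoid(curve.tpr, curve.fpr))


def pauc(curve: RocCurve, fpr_max: float = 0.2, normalized: bool = False) -> float:
    """Partial AUC over FPR in [0, fpr_max], linear interpolation at the cut.

    Unnormalized by default (maximum value fpr_max); ``normalized=True``
    divides by fpr_max.
    """
    if not 0 < fpr_max <= 1:
        raise ValueError(f"fpr_max must lie in (0, 1], got {fpr_max}")
    keep = curve.fpr <= fpr_max
    xs = curve.fpr[keep]
    ys = curve.tpr[keep]
    if xs[-1] < fpr_max:
        j = int(np.argmax(curve.fpr > fpr_max))
        x0, x1 = curve.fpr[j - 1], curve.fpr[j]
        y0, y1 = curve.tpr[j - 1], curve.tpr[j]
        y_cut = y0 + (y1 - y0) * (fpr_max - x0) / (x1 - x0)
        xs = np.append(xs, fpr_max)
        ys = np.append(ys, y_cut)
    area = float(np.trapezoid(ys, xs))
    return area / fpr_max if normalized else area


def volcano_scores(table: VolcanoTable) -> np.ndarray:
    """ROC ranking score for a volcano table: -log10(p), p floored at 1e-300."""
    return -np.log10(np.clip(table.p_values, 1e-300, None))


def stability_overlap(set_a: Iterable, set_b: Iterable) -> tuple[int, int]:
    """(|A intersect B|, |A symmetric-difference B|) of two id sets."""
    a, b = set(set_a), set(set_b)
    return len(a & b), len(a ^ b)


def evaluate_table(table: VolcanoTable, truth, fpr_max: float = 0.2) -> EvalReport:
    """Score one volcano table: calling-rule confusion plus p-ranked AUC/pAUC."""
    report = confusion(table.differential, truth)
    curve = roc_curve(volcano_scores(table), truth)
    return replace(report, auc=auc(curve), pauc=pauc(curve, fpr_max=fpr_max))


def _replicate_seeds(seed: int, count: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=count)


def benchmark_replicates(
    n_replicates: int,
    outlier_rate: float,
    seed: int,
    design: Optional[SimulationDesign] = None,
    lambda_grid: tuple = DEFAULT_LAMBDA_GRID,
    k_folds: int = 5,
    data_scale: str = "log2",
    alpha: float = 0.05,
    fc_threshold: float = 1.0,
) -> pd.DataFrame:
    """Simulate -> select lambda -> analyze (RVP and CVP) -> score, repeated.

    Each replicate redraws the whole dataset (mu_i, group effects, noise,
    outliers).  RVP uses the CV-chosen lambda of its own replicate; CVP is
    the lambda = 0 analysis of the same data.  The simulated abundances
    are log2-scale, hence ``data_scale="log2"``.  Returns one row per
    (replicate, method) with AUC, pAUC, MER, power, FDR, the lambda used,
    and the number of calls.
    """
    base = design or SimulationDesign()
    rows = []
    for r, s in enumerate(_replicate_seeds(seed, n_replicates)):
        des = replace(base, seed=int(s), outlier_rate=outlier_rate)
        m, d, truth, _ = simulate_dataset(des)
        params = KernelParams(lambda_grid=lambda_grid, k_folds=k_folds, seed=int(s))
        tables = {
            "RVP": analyze(m, d, "auto", params=params, data_scale=data_scale,
                           alpha=alpha, fc_threshold=fc_threshold),
            "CVP": analyze(m, d, 0.0, data_scale=data_scale,
                           alpha=alpha, fc_threshold=fc_threshold),
        }
        for tag, table in tables.items():
            rep = evaluate_table(table, truth)
            rows.append({
                "replicate": r, "method": tag, "lambda": table.lambda_used,
                "auc": rep.auc, "pauc": rep.pauc, "mer": rep.mer,
                "power": rep.power, "fdr": rep.fdr,
                "n_called": int(table.differential.sum()),
            })
    return pd.DataFrame(rows)


def stability_experiment(
    n_pairs: int,
    outlier_rate: float,
    seed: int,
    design: Optional[SimulationDesign] = None,
    lambda_grid: tuple = DEFAULT_LAMBDA_GRID,
    k_folds: int = 5,
    data_scale: str = "log2",
    alpha: float = 0.05,
    fc_threshold: float = 1.0,
) -> pd.DataFrame:
    """Paired clean / contaminated runs: how much does the differential set move?

    For each pair, a clean dataset is simulated and a contaminated copy is
    produced by outlier injection at ``outlier_rate``.  Both versions are
    analyzed with RVP (lambda CV-chosen per version) and CVP, and the
    non-overlap (symmetric difference) of the two differential sets is
    recorded per method.  An outlier-robust method should keep its calls
    nearly unchanged.
    """
    base = design or SimulationDesign()
    rows = []
    seeds = _replicate_seeds(seed, 2 * n_pairs).reshape(n_pairs, 2)
    for r, (s_data, s_outl) in enumerate(seeds):
        des = replace(base, seed=int(s_data), outlier_rate=0.0)
        m_clean, d, truth, _ = simulate_dataset(des)
        m_cont, _ = inject_outliers(m_clean, outlier_rate,
                                    factor=base.outlier_factor, seed=int(s_outl))
        row = {"pair": r}
        for tag, lam in (("RVP", "auto"), ("CVP", 0.0)):
            sets = []
            for m in (m_clean, m_cont):
                params = KernelParams(lambda_grid=lambda_grid, k_folds=k_folds,
                                      seed=int(s_data))
                table = analyze(m, d, lam, params=params, data_scale=data_scale,
                                alpha=alpha, fc_threshold=fc_threshold)
                sets.append(table.called_ids)
            n_common, n_nonoverlap = stability_overlap(*sets)
            row[f"common_{tag.lower()}"] = n_common
            row[f"nonoverlap_{tag.lower()}"] = n_nonoverlap
        rows.append(row)
    return pd.DataFrame(rows)
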