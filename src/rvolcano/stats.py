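"""Weighted fold change, weighted t-statistics, p-values, and the volcano
calling rule.

The classical volcano plot (CVP) calls a metabolite differential when its
two-sample t-test gives p < alpha and |log2 fold-change| exceeds a
threshold.  The robust volcano plot (RVP) computes the same quantities
from kernel-weighted means and variances, so outlying entries lose
influence; at lambda = 0 all weights are 1 and RVP reduces exactly to
CVP.

Two denominator conventions exist for the weighted moments:

``sum_weights`` (default)
    X-bar = sum(w x) / sum(w) and the variance uses the reliability-weight
    Bessel correction sum(w) - sum(w^2)/sum(w).  This is the standard
    weighted estimator: it stays centred when outliers are down-weighted
    and reduces exactly to the classical mean/variance at lambda = 0.
``group_size``
    X-bar = sum(w x) / g and variance divisor g - 1, with g the raw group
    size.  Down-weighting then shrinks the moments toward zero, which
    cancels in the fold-change ratio but biases the t numerator; the
    option is provided for comparison.

The t statistic keeps the classical orientation (control minus disease);
the pooled form is referred to Student's t with n - 2 degrees of
freedom, the unequal-variance (Welch) form uses Welch-Satterthwaite
degrees of freedom.  The test is two-sided by default (H1: means
differ); a one-sided upper-tail option is available.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .data import AbundanceMatrix, GroupDesign
from .weights import KernelParams, WeightMatrix, kernel_weights

logger = logging.getLogger("rvolcano")

VARIANCE_MODES = ("pooled", "welch")
TAILS = ("two-sided", "upper")
DATA_SCALES = ("intensity", "log2")
WEIGHT_DENOMINATORS = ("sum_weights", "group_size")


@dataclass(frozen=True)
class GroupStats:
    """Per-metabolite weighted group moments (arrays of length p)."""

    mean_control: np.ndarray
    mean_disease: np.ndarray
    var_control: np.ndarray
    var_disease: np.ndarray
    pooled_var: np.ndarray


def weighted_group_stats(m: AbundanceMatrix, w: WeightMatrix, d: GroupDesign,
                         weight_denominator: str = "sum_weights") -> GroupStats:
    """Weighted means, variances, and the pooled variance per metabolite."""
    if weight_denominator not in WEIGHT_DENOMINATORS:
        raise ValueError(f"weight_denominator must be one of {WEIGHT_DENOMINATORS}")
    if w.weights.shape != m.values.shape:
        raise ValueError(
            f"weight matrix shape {w.weights.shape} does not match data {m.values.shape}"
        )
    ctrl, dis = d.indices(m.sample_ids)
    out = {}
    for key, idx in (("control", ctrl), ("disease", dis)):
        x = m.values[:, idx]
        ww = w.weights[:, idx]
        g = len(idx)
        if weight_denominator == "group_size":
            mean = (ww * x).sum(axis=1) / g
            var = (ww * (x - mean[:, None]) ** 2).sum(axis=1) / (g - 1)
        else:
            v1 = ww.sum(axis=1)
            v2 = (ww**2).sum(axis=1)
            mean = (ww * x).sum(axis=1) / v1
            denom = v1 - v2 / v1
            num = (ww * (x - mean[:, None]) ** 2).sum(axis=1)
            var = np.where(denom > 1e-12, num / np.where(denom > 1e-12, denom, 1.0), 0.0)
        out[f"mean_{key}"] = mean
        out[f"var_{key}"] = var
    g1, g2 = len(ctrl), len(dis)
    pooled = ((g1 - 1) * out["var_control"] + (g2 - 1) * out["var_disease"]) / (g1 + g2 - 2)
    return GroupStats(pooled_var=pooled, **out)


def log2_fold_change(mean_disease, mean_control, data_scale: str = "intensity"):
    """log2 fold change of disease over control.

    ``intensity``: log2(mean_disease / mean_control); undefined (NaN) when
    either mean is non-positive.  ``log2``: the data are already log2
    intensities, so the log2 fold change is the difference of means.
    """
    if data_scale not in DATA_SCALES:
        raise ValueError(f"data_scale must be one of {DATA_SCALES}")
    md = np.asarray(mean_disease, dtype=float)
    mc = np.asarray(mean_control, dtype=float)
    scalar = md.ndim == 0 and mc.ndim == 0
    md, mc = np.atleast_1d(md), np.atleast_1d(mc)
    if data_scale == "log2":
        out = md - mc
    else:
        ok = (md > 0) & (mc > 0)
        out = np.full(np.broadcast(md, mc).shape, np.nan)
        out[ok] = np.log2(md[ok] / mc[ok])
    return float(out[0]) if scalar else out


def t_statistic(stats: GroupStats, d: GroupDesign,
                variance_mode: str = "pooled") -> tuple[np.ndarray, np.ndarray]:
    """Two-sample t statistic (control minus disease) and degrees of freedom.

    ``pooled``: t = (X̄C - X̄D) / sqrt(S²(1/g1 + 1/g2)) with df = n - 2.
    ``welch``: unequal-variance statistic with Welch-Satterthwaite df.
    Degenerate rows (both variances zero): t = 0 when the means agree,
    +/- inf otherwise.
    """
    if variance_mode not in VARIANCE_MODES:
        raise ValueError(f"variance_mode must be one of {VARIANCE_MODES}")
    g1, g2 = d.control_count, d.disease_count
    num = stats.mean_control - stats.mean_disease
    if variance_mode == "pooled":
        se2 = stats.pooled_var * (1.0 / g1 + 1.0 / g2)
        df = np.full_like(num, float(g1 + g2 - 2))
    else:
        a = stats.var_control / g1
        b = stats.var_disease / g2
        se2 = a + b
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2**2 / (a**2 / (g1 - 1) + b**2 / (g2 - 1))
        df = np.where(se2 > 0, df, float(g1 + g2 - 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = num / np.sqrt(se2)
    zero_se = se2 == 0
    if np.any(zero_se):
        with np.errstate(invalid="ignore"):
            t = np.where(zero_se & (num == 0), 0.0, t)
            t = np.where(zero_se & (num != 0), np.sign(num) * np.inf, t)
    return t, df


def p_value(t, df, tail: str = "two-sided"):
    """Tail probability of Student's t.

    Two-sided by default, 2 P(T_df > |t|), matching the alternative
    H1: mu_C != mu_D and the p < alpha calling rule; ``upper`` gives the
    one-sided integral from t to infinity.
    """
    if tail not in TAILS:
        raise ValueError(f"tail must be one of {TAILS}")
    t = np.asarray(t, dtype=float)
    df = np.asarray(df, dtype=float)
    if np.any(df <= 0):
        raise ValueError("degrees of freedom must be positive")
    if tail == "two-sided":
        p = 2.0 * sps.t.sf(np.abs(t), df)
        p = np.minimum(p, 1.0)
    else:
        p = sps.t.sf(t, df)
    return float(p) if p.ndim == 0 else p


def bonferroni(p) -> np.ndarray:
    """Bonferroni family-wise adjustment: min(1, p * m) element-wise."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, p * p.size)


def call_differential(p_values, log2_fc, alpha: float = 0.05,
                      fc_threshold: float = 1.0) -> np.ndarray:
    """The volcano calling rule: p < alpha AND |log2FC| > fc_threshold.

    Strict inequalities; an undefined (NaN) fold change is never called.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if fc_threshold < 0:
        raise ValueError(f"fc_threshold must be nonnegative, got {fc_threshold}")
    p = np.asarray(p_values, dtype=float)
    fc = np.asarray(log2_fc, dtype=float)
    with np.errstate(invalid="ignore"):
        return (p < alpha) & (np.abs(fc) > fc_threshold) & ~np.isnan(fc)


@dataclass(frozen=True)
class MetaboliteResult:
    """Per-metabolite volcano statistics."""

    metabolite_id: str
    mean_control: float
    mean_disease: float
    var_control: float
    var_disease: float
    pooled_var: float
    log2_fc: float          # NaN when undefined
    t_stat: float
    df: float
    p_value: float
    p_adjusted: float
    differential: bool


@dataclass(frozen=True)
class VolcanoTable:
    """Per-metabolite results in input row order, plus the rule applied.

    ``method_tag`` is CVP exactly when ``lambda_used == 0`` (the classical
    volcano plot); any positive lambda marks the robust variant (RVP).
    """

    results: tuple
    alpha: float
    fc_threshold: float
    lambda_used: float
    cv_result: Optional[object] = None

    @property
    def method_tag(self) -> str:
        return "CVP" if self.lambda_used == 0 else "RVP"

    @property
    def metabolite_ids(self) -> tuple:
        return tuple(r.metabolite_id for r in self.results)

    @property
    def p_values(self) -> np.ndarray:
        return np.array([r.p_value for r in self.results])

    @property
    def log2_fc(self) -> np.ndarray:
        return np.array([r.log2_fc for r in self.results])

    @property
    def t_stats(self) -> np.ndarray:
        return np.array([r.t_stat for r in self.results])

    @property
    def differential(self) -> np.ndarray:
        return np.array([r.differential for r in self.results])

    @property
    def called_ids(self) -> frozenset:
        return frozenset(r.metabolite_id for r in self.results if r.differential)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "metabolite_id": [r.metabolite_id for r in self.results],
                "mean_control": [r.mean_control for r in self.results],
                "mean_disease": [r.mean_disease for r in self.results],
                "log2_fc": [r.log2_fc for r in self.results],
                "t_stat": [r.t_stat for r in self.results],
                "df": [r.df for r in self.results],
                "p_value": [r.p_value for r in self.results],
                "p_adjusted": [r.p_adjusted for r in self.results],
                "differential": ["TRUE" if r.differential else "FALSE" for r in self.results],
            }
        )

    def write(self, target, delimiter: str = "\t") -> None:
        self.to_frame().to_csv(target, sep=delimiter, index=False)


def analyze(m: AbundanceMatrix, d: GroupDesign, lam=0.0, *,
            params: Optional[KernelParams] = None,
            variance_mode: str = "pooled",
            alpha: float = 0.05,
            fc_threshold: float = 1.0,
            tail: str = "two-sided",
            data_scale: str = "intensity",
            weight_scope: str = "row_group",
            weight_denominator: str = "sum_weights",
            adjusted_calling: bool = False) -> VolcanoTable:
    """Run the full volcano pipeline and return one result per metabolite.

    Parameters
    ----------
    lam
        The kernel tuning parameter, or the string ``"auto"`` to select it
        by k-fold cross-validation (configured through ``params``).
        ``lam=0`` is the classical volcano plot.
    adjusted_calling
        Apply the calling rule to the Bonferroni-adjusted p-values instead
        of the raw ones (the default rule uses raw p < alpha).
    """
    cv = None
    if isinstance(lam, str):
        if lam != "auto":
            raise ValueError(f"lam must be a number or 'auto', got {lam!r}")
        from .crossval import select_lambda

        params = params or KernelParams()
        cv = select_lambda(m, d, params, weight_scope=weight_scope)
        lam = cv.chosen_lambda
    lam = float(lam)
    w = kernel_weights(m, d, lam, weight_scope=weight_scope)
    stats = weighted_group_stats(m, w, d, weight_denominator=weight_denominator)
    fc = log2_fold_change(stats.mean_disease, stats.mean_control, data_scale=data_scale)
    n_undefined = int(np.isnan(np.atleast_1d(fc)).sum())
    if n_undefined:
        logger.warning(
            "%d metabolites have undefined log2 fold change (non-positive group "
            "mean); pass raw intensities for fold changes", n_undefined,
        )
    t, df = t_statistic(stats, d, variance_mode=variance_mode)
    p = p_value(t, df, tail=tail)
    p_adj = bonferroni(p)
    flags = call_differential(p_adj if adjusted_calling else p, fc,
                              alpha=alpha, fc_threshold=fc_threshold)
    results = tuple(
        MetaboliteResult(
            metabolite_id=m.metabolite_ids[i],
            mean_control=float(stats.mean_control[i]),
            mean_disease=float(stats.mean_disease[i]),
            var_control=float(stats.var_control[i]),
            var_disease=float(stats.var_disease[i]),
            pooled_var=float(stats.pooled_var[i]),
            log2_fc=float(np.atleast_1d(fc)[i]),
            t_stat=float(t[i]),
            df=float(df[i]),
            p_value=float(np.atleast_1d(p)[i]),
            p_adjusted=float(p_adj[i]),
            differential=bool(flags[i]),
        )
        for i in range(m.p)
    )
    return VolcanoTable(results=results, alpha=alpha, fc_threshold=fc_threshold,
                        lambda_used=lam, cv_result=cv)
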