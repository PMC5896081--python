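"""Synthetic two-group metabolomics data with entry-wise outlier
contamination.

The generator follows a one-way ANOVA model on the log2 intensity scale:

    y_ijk = mu_i + g_ij + eps_ijk

where ``mu_i ~ Uniform(10, 20)`` is the overall intensity of metabolite
i, ``g_ij`` is the group effect (drawn once per metabolite and group),
and ``eps_ijk ~ N(0, 1)`` is per-entry noise.  Up-regulated metabolites
draw their disease effect from N(4, 1) and their control effect from
N(2, 1); down-regulated metabolites swap the two; non-differential
("equal concentration") metabolites draw a single N(0, 1) effect shared
by both groups, so their group means are genuinely equal.  The default
design is 150 metabolites (130 null + 10 up + 10 down) by 70 samples
(40 control + 30 disease).

Outliers are injected entry-wise: round(rate * p * n) distinct cells are
chosen uniformly over the whole matrix and cell (i, j) is replaced by a
draw from N(factor * mu_hat_i, sigma_hat_i^2), where mu_hat_i and
sigma_hat_i^2 are the mean and sample variance of row i of the
pre-contamination matrix (the only self-consistent choice when several
rates are applied to the same base data).  The synthetic benchmark uses
factor 3; contamination of real matrices uses factor 4.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .data import CONTROL, DISEASE, AbundanceMatrix, GroupDesign

UP, DOWN, NULL = "up", "down", "null"


@dataclass(frozen=True)
class SimulationDesign:
    """Generative parameters for the artificial dataset.

    Effect parameters are (mean, sd) pairs of the normal distributions the
    per-(metabolite, group) effects are drawn from.
    """

    n_null: int = 130
    n_up: int = 10
    n_down: int = 10
    n_control: int = 40
    n_disease: int = 30
    mu_low: float = 10.0
    mu_high: float = 20.0
    effect_up_disease: tuple = (4.0, 1.0)
    effect_up_control: tuple = (2.0, 1.0)
    effect_down_disease: tuple = (2.0, 1.0)
    effect_down_control: tuple = (4.0, 1.0)
    effect_null: tuple = (0.0, 1.0)
    noise_sd: float = 1.0
    outlier_rate: float = 0.0
    outlier_factor: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_null", "n_up", "n_down", "n_control", "n_disease"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.outlier_rate <= 1:
            raise ValueError(f"outlier_rate must lie in [0, 1], got {self.outlier_rate}")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for name in ("effect_up_disease", "effect_up_control", "effect_down_disease",
                     "effect_down_control", "effect_null"):
            mean, sd = getattr(self, name)
            if sd <= 0:
                raise ValueError(f"{name} sd must be positive")
        if self.mu_high <= self.mu_low:
            raise ValueError("mu_high must exceed mu_low")

    @property
    def p(self) -> int:
        return self.n_null + self.n_up + self.n_down

    @property
    def n(self) -> int:
        return self.n_control + self.n_disease

    @property
    def n_differential(self) -> int:
        return self.n_up + self.n_down


@dataclass(frozen=True)
class TruthLabels:
    """Ground-truth differential indicator and direction per metabolite."""

    differential: np.ndarray
    direction: tuple

    def __post_init__(self) -> None:
        diff = np.asarray(self.differential, dtype=bool)
        object.__setattr__(self, "differential", diff)
        object.__setattr__(self, "direction", tuple(self.direction))
        if len(self.direction) != diff.size:
            raise ValueError("direction and differential lengths differ")
        if any((d == NULL) == f for d, f in zip(self.direction, diff)):
            raise ValueError("differential flags must match non-null directions")

    def to_frame(self, metabolite_ids):
        import pandas as pd

        return pd.DataFrame({
            "metabolite_id": list(metabolite_ids),
            "differential": ["TRUE" if f else "FALSE" for f in self.differential],
            "direction": list(self.direction),
        })


def _inject(values: np.ndarray, rate: float, factor: float,
            rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    if not 0 <= rate <= 1:
        raise ValueError(f"outlier rate must lie in [0, 1], got {rate}")
    p, n = values.shape
    count = int(np.floor(rate * p * n + 0.5))
    mask = np.zeros((p, n), dtype=bool)
    out = values.copy()
    if count == 0:
        return out, mask
    flat = rng.choice(p * n, size=count, replace=False)
    rows, cols = np.unravel_index(flat, (p, n))
    mu_hat = values.mean(axis=1)
    sd_hat = values.std(axis=1, ddof=1)
    out[rows, cols] = rng.normal(factor * mu_hat[rows], sd_hat[rows])
    mask[rows, cols] = True
    return out, mask


def inject_outliers(m: AbundanceMatrix, rate: float, factor: float = 3.0,
                    seed: int = 0) -> tuple[AbundanceMatrix, np.ndarray]:
    """Replace a random fraction of cells by outlying values.

    round(rate * p * n) distinct cells are drawn without replacement over
    the whole matrix; cell (i, j) is replaced by N(factor * mu_hat_i,
    sigma_hat_i^2) with row moments from the input matrix.  Returns the
    contaminated matrix and the boolean mask of replaced cells.
    """
    rng = np.random.default_rng(seed)
    out, mask = _inject(m.values, rate, factor, rng)
    return AbundanceMatrix(out, m.metabolite_ids, m.sample_ids), mask


def contaminate_real(m: AbundanceMatrix, rate: float,
                     seed: int = 0) -> tuple[AbundanceMatrix, np.ndarray]:
    """Contaminate an experimentally measured matrix: outliers from
    N(4 * mu_hat_i, sigma_hat_i^2)."""
    return inject_outliers(m, rate, factor=4.0, seed=seed)


def simulate_dataset(
    design: SimulationDesign,
) -> tuple[AbundanceMatrix, GroupDesign, TruthLabels, np.ndarray]:
    """Generate one artificial dataset under ``design``.

    Returns the (possibly contaminated) abundance matrix, the group
    design (control samples first), the truth labels, and the boolean
    outlier mask.  Bit-identical output for identical (design, seed).
    """
    rng = np.random.default_rng(design.seed)
    p, n = design.p, design.n
    mu = rng.uniform(design.mu_low, design.mu_high, size=p)

    direction = [UP] * design.n_up + [DOWN] * design.n_down + [NULL] * design.n_null
    g_control = np.empty(p)
    g_disease = np.empty(p)
    up = slice(0, design.n_up)
    down = slice(design.n_up, design.n_up + design.n_down)
    null = slice(design.n_up + design.n_down, p)
    g_control[up] = rng.normal(*design.effect_up_control, size=design.n_up)
    g_disease[up] = rng.normal(*design.effect_up_disease, size=design.n_up)
    g_control[down] = rng.normal(*design.effect_down_control, size=design.n_down)
    g_disease[down] = rng.normal(*design.effect_down_disease, size=design.n_down)
    shared = rng.normal(*design.effect_null, size=design.n_null)
    g_control[null] = shared
    g_disease[null] = shared  # equal concentration: no between-group effect

    group_effect = np.concatenate([
        np.repeat(g_control[:, None], design.n_control, axis=1),
        np.repeat(g_disease[:, None], design.n_disease, axis=1),
    ], axis=1)
    noise = rng.normal(0.0, design.noise_sd, size=(p, n))
    values = mu[:, None] + group_effect + noise

    width = max(3, len(str(p)))
    metabolite_ids = tuple(f"M{i + 1:0{width}d}" for i in range(p))
    sample_ids = tuple(
        [f"C{j + 1:02d}" for j in range(design.n_control)]
        + [f"D{j + 1:02d}" for j in range(design.n_disease)]
    )
    values, mask = _inject(values, design.outlier_rate, design.outlier_factor, rng)

    m = AbundanceMatrix(values, metabolite_ids, sample_ids)
    d = GroupDesign.from_labels(
        sample_ids, [CONTROL] * design.n_control + [DISEASE] * design.n_disease
    )
    truth = TruthLabels(np.array([dirn != NULL for dirn in direction]), direction)
    return m, d, truth, mask
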