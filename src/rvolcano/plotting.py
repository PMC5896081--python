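"""Volcano-plot rendering (matplotlib, headless-safe)."""

from __future__ import annotations

import logging

import numpy as np

from .stats import VolcanoTable

logger = logging.getLogger("rvolcano")


def render_volcano(table: VolcanoTable, path, alpha: float | None = None,
                   fc_threshold: float | None = None) -> None:
    """Scatter of log2 fold change against -log10(p) with threshold guides.

    Differential metabolites are highlighted; metabolites with undefined
    fold change are omitted (their count is logged).  Output format is
    chosen by the file extension (PNG, SVG, PDF, ...).
    """
    import matplotlib

    if matplotlib.get_backend().lower() not in ("agg", "svg", "pdf"):
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not table.results:
        raise ValueError("cannot render an empty volcano table")
    alpha = table.alpha if alpha is None else alpha
    fc_threshold = table.fc_threshold if fc_threshold is None else fc_threshold

    fc = table.log2_fc
    logp = -np.log10(np.clip(table.p_values, 1e-300, None))
    flags = table.differential
    defined = ~np.isnan(fc)
    dropped = int((~defined).sum())
    if dropped:
        logger.info("omitting %d metabolites with undefined log2 fold change", dropped)

    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(fc[defined & ~flags], logp[defined & ~flags], s=12, c="0.6",
               label="not differential")
    if np.any(defined & flags):
        ax.scatter(fc[defined & flags], logp[defined & flags], s=16, c="crimson",
                   label="differential")
    ax.axhline(-np.log10(alpha), ls="--", lw=0.8, c="k")
    ax.axvline(fc_threshold, ls="--", lw=0.8, c="k")
    ax.axvline(-fc_threshold, ls="--", lw=0.8, c="k")
    ax.set_xlabel(r"$\log_2$ fold change")
    ax.set_ylabel(r"$-\log_{10}$ p-value")
    ax.set_title(f"{table.method_tag} (lambda = {table.lambda_used:g})")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
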