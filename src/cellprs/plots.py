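"""Scatter-with-regression presentation of one association cell.

The x-axis is the standardized polygenic score; the y-axis is the volume
change residualized on the covariates, so positive values indicate a volume
gain over the intervention after covariate adjustment.  The fitted line
carries the 95% confidence band of the predicted means.
"""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import statsmodels.api as sm

from .assoc import AssocConfig, residualize, usable_covariates


def plot_regression_scatter(
    x: np.ndarray, y: np.ndarray, path: str | Path,
    xlabel: str = "standardized PRS",
    ylabel: str = "volume change (corrected residuals)",
    title: str = "",
) -> None:
    """Scatter plus OLS line and 95% CI band of the predicted means."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    design = sm.add_constant(x)
    fit = sm.OLS(y, design).fit()
    grid = np.linspace(x.min(), x.max(), 100)
    pred = fit.get_prediction(sm.add_constant(grid))
    band = pred.conf_int(alpha=0.05)

    fig, ax = plt.subplots(figsize=(4.5, 4.0))
    ax.scatter(x, y, s=22, color="#3b6ea5", alpha=0.85, edgecolor="none")
    ax.plot(grid, pred.predicted_mean, color="#222222", lw=1.5)
    ax.fill_between(grid, band[:, 0], band[:, 1], color="#999999", alpha=0.3,
                    linewidth=0)
    ax.axhline(0.0, color="#bbbbbb", lw=0.8, zorder=0)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    if title:
        ax.set_title(title, fontsize=10)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_association(
    cell: pd.Series,
    prs_table: pd.DataFrame,
    outcomes: pd.DataFrame,
    covariates: pd.DataFrame,
    cfg: AssocConfig,
    path: str | Path,
) -> None:
    """Render the scatter for one result row of the association table."""
    group = cell["group"]
    threshold = float(cell["threshold"])
    col = f"pt_{threshold:g}"
    merged = (
        outcomes[outcomes["group"] == group]
        .merge(prs_table[["subject_id", col]], on="subject_id")
        .merge(covariates, on="subject_id")
    )
    y = merged[f"z_{cell['hemisphere']}_{cell['subfield']}"].to_numpy()
    x = merged[col].to_numpy()
    sd = x.std(ddof=1)
    if sd > 0:
        x = (x - x.mean()) / sd
    y_resid = residualize(y, usable_covariates(merged[list(cfg.covariates)]))
    title = (
        f"{cell['gene_set']} PRS (Pt={threshold:g}) vs {cell['hemisphere']} "
        f"{cell['subfield']} change, {group}"
    )
    plot_regression_scatter(x, y_resid, path, title=title)
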