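"""Bland-Altman and agreement-regression figures."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt

from gaitspeed.evaluation import AgreementRegression, bland_altman
from gaitspeed.model import TestPrediction


def bland_altman_plot(preds: Sequence[TestPrediction], path: str | Path) -> Path:
    """Error vs mean-of-methods scatter with bias and LOA lines."""
    est = np.array([p.median_estimate for p in preds])
    truth = np.array([p.truth for p in preds])
    d = est - truth
    mean = (est + truth) / 2
    bias, lo, hi = bland_altman(preds)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(mean, d, s=18, alpha=0.7)
    ax.axhline(bias, color="black", lw=1.2)
    for y in (lo, hi):
        ax.axhline(y, color="red", ls="--", lw=1.0)
    ax.set_xlabel("mean of estimated and true speed (m/s)")
    ax.set_ylabel("estimate $-$ truth (m/s)")
    ax.set_title("Bland-Altman")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def regression_plot(preds: Sequence[TestPrediction], reg: AgreementRegression,
                    path: str | Path) -> Path:
    """Truth-on-estimate scatter with OLS line and bootstrap band."""
    est = np.array([p.median_estimate for p in preds])
    truth = np.array([p.truth for p in preds])
    grid = np.linspace(est.min(), est.max(), 100)
    lo, hi = reg.band(grid)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.fill_between(grid, lo, hi, color="grey", alpha=0.4,
                    label="95% bootstrap band")
    ax.scatter(est, truth, s=18, alpha=0.7)
    ax.plot(grid, reg.slope * grid + reg.intercept, color="black", lw=1.2,
            label=f"y = {reg.slope:.2f} x + {reg.intercept:.2f}")
    ax.plot(grid, grid, color="red", ls="--", lw=1.0, label="identity")
    ax.set_xlabel("estimated speed (m/s)")
    ax.set_ylabel("true speed (m/s)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
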