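"""Trajectory curves, model-selection tables and figures.

Curves are computed at covariate reference values (all model covariates at
zero, i.e. the reference configuration) and mapped back to the 0-15 score
scale through the inverse of the fitted monotone link, so they are directly
comparable to the clinical cutoff of 5.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .fit import FittedModel
from .link import invert_link
from .survival import cumulative_incidence
from .trajectory import class_mean

CLINICAL_CUTOFF = 5.0

__all__ = [
    "estimated_trajectories",
    "selection_report",
    "cif_table",
    "plot_trajectories",
    "plot_cif",
]


def estimated_trajectories(fitted: FittedModel, t_grid) -> pd.DataFrame:
    """Model-implied mean score per class over ``t_grid``.

    Returns a tidy frame ``class, t, h_mean, gds_hat`` where ``h_mean`` is
    the mean on the transformed scale and ``gds_hat`` its back-transformed
    value (bounded by the score range by construction).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    params = fitted.params
    x_ref = np.zeros(params.common.gamma.size)
    frames = []
    for g, cp in enumerate(params.classes):
        h = class_mean(t_grid, x_ref, cp, params.common)
        if params.link is not None:
            gds = invert_link(h, params.link)
        else:
            gds = h
        frames.append(pd.DataFrame(
            {"class": g, "t": t_grid, "h_mean": h, "gds_hat": gds}))
    return pd.concat(frames, ignore_index=True)


def selection_report(table: pd.DataFrame) -> pd.DataFrame:
    """Format a class-enumeration table; the minimum-BIC row is flagged.

    Accepts the table from ``enumerate_classes`` (with or without its own
    ``selected`` column) and returns a copy with percentage-scaled class
    share and the selection flag recomputed from the BIC column.
    """
    out = table.copy()
    ok = out["bic"].notna()
    best = out.loc[ok, "bic"].idxmin()
    out["selected"] = False
    out.loc[best, "selected"] = True
    if "min_class_share" in out:
        out["min_class_share_pct"] = 100.0 * out["min_class_share"]
    return out


def cif_table(fitted: FittedModel, t_grid) -> pd.DataFrame:
    """Tidy per-class cumulative incidence curves: class, cause, t, cif."""
    t_grid = np.asarray(t_grid, dtype=float)
    params = fitted.params
    w_ref = np.zeros(params.survival.omega.shape[1])
    rows = []
    for g in range(fitted.G):
        cif = cumulative_incidence(t_grid, g, w_ref, params.survival)
        for k, cause in enumerate(("dementia", "death")):
            rows.append(pd.DataFrame(
                {"class": g, "cause": cause, "t": t_grid, "cif": cif[:, k]}))
    return pd.concat(rows, ignore_index=True)


def plot_trajectories(curves: pd.DataFrame, path=None, class_names=None):
    """Mean-score curves per class with the clinical cutoff dashed."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for g, sub in curves.groupby("class"):
        label = class_names[g] if class_names else f"class {g + 1}"
        ax.plot(sub["t"], sub["gds_hat"], label=label)
    ax.axhline(CLINICAL_CUTOFF, ls="--", color="grey", lw=1)
    ax.set_xlabel("years from late-study baseline")
    ax.set_ylabel("estimated GDS-15")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_cif(cif: pd.DataFrame, path=None, cause="dementia",
             class_names=None):
    """Cumulative incidence of one cause by latent class."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for g, sub in cif[cif["cause"] == cause].groupby("class"):
        label = class_names[g] if class_names else f"class {g + 1}"
        ax.plot(sub["t"], sub["cif"], label=label)
    ax.set_xlabel("years from late-study baseline")
    ax.set_ylabel(f"cumulative incidence of {cause}")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
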