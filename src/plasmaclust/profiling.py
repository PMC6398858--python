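"""Blood-marker profiles per cluster.

Kernel weights learned by the similarity model are summed per marker into an
importance score; the top-ranked markers define each cluster's profile, which
is described by per-cluster means/SDs of the scaled values and a direction
(higher/lower) relative to the population mean.  One-way ANOVA across clusters
validates that the top markers actually separate the clusters; following the
single-screen design, the 0.001 significance threshold is applied without
additional multiple-testing correction.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .cimlr import SimilarityModel
from .kernels import KernelBank

__all__ = ["marker_importance", "anova_by_cluster", "ANOVA_ALPHA"]

#: significance threshold used to call a marker's cluster separation real
ANOVA_ALPHA = 1e-3


def marker_importance(model: SimilarityModel, bank: KernelBank) -> pd.DataFrame:
    """Sum each marker's kernel weights into an importance score and rank.

    Returns a DataFrame (marker_id, importance, rank) sorted by descending
    importance; ties break by marker id so ranking is deterministic.  The
    importances inherit the simplex constraint on w: nonnegative, summing
    to 1.
    """
    w = np.asarray(model.w, dtype=float)
    if w.shape != (bank.n_kernels,):
        raise ValueError("model weights do not match the kernel bank")
    importance = np.zeros(bank.n_markers)
    np.add.at(importance, bank.marker_of_kernel, w)
    table = pd.DataFrame({"marker_id": bank.marker_ids, "importance": importance})
    table = table.sort_values(
        ["importance", "marker_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def anova_by_cluster(X, labels, marker_ids=None) -> pd.DataFrame:
    """Per-marker one-way ANOVA across clusters plus profile descriptives.

    Parameters
    ----------
    X : MarkerMatrix or DataFrame of (scaled) marker values
    labels : per-subject cluster labels
    marker_ids : markers to test (default: all)

    Returns
    -------
    Tidy DataFrame with one row per (cluster, marker): mean, sd, direction
    ('higher'/'lower' vs the population mean), anova_p (the marker-level
    p-value repeated across its rows) and significant (p < 0.001).  Markers
    whose test involves a cluster with fewer than 2 members are reported with
    NaN p and a warning.
    """
    if hasattr(X, "to_frame"):
        frame = X.to_frame()
    else:
        frame = pd.DataFrame(X)
    labels = np.asarray(labels)
    if labels.shape[0] != frame.shape[0]:
        raise ValueError("labels must align with X rows")
    clusters = np.unique(labels)
    if clusters.size < 2:
        raise ValueError("need at least 2 clusters for ANOVA")
    if marker_ids is None:
        marker_ids = list(frame.columns)

    small = [int(c) for c in clusters if (labels == c).sum() < 2]
    if small:
        warnings.warn(
            f"cluster(s) {small} have < 2 members; ANOVA p-values skipped",
            stacklevel=2,
        )

    rows = []
    for marker in marker_ids:
        col = frame[marker].to_numpy(float)
        groups = [col[labels == c] for c in clusters]
        if small:
            pval = np.nan
        else:
            with np.errstate(invalid="ignore"):
                pval = float(stats.f_oneway(*groups).pvalue)
        grand = col.mean()
        for c, g in zip(clusters, groups):
            rows.append(
                {
                    "cluster": int(c),
                    "marker": marker,
                    "mean": float(g.mean()) if g.size else np.nan,
                    "sd": float(g.std(ddof=1)) if g.size > 1 else np.nan,
                    "direction": "higher" if g.size and g.mean() > grand else "lower",
                    "anova_p": pval,
                    "significant": bool(pval < ANOVA_ALPHA) if np.isfinite(pval) else False,
                }
            )
    return pd.DataFrame(rows)
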