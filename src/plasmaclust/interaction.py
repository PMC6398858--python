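"""Cluster x diagnosis interaction analysis on brain phenotypes.

Three comparison schemes probe how a blood-marker subtype relates to a
numeric phenotype (ICV-normalised regional volume, region-averaged thickness,
or any other per-subject measure):

* ``whole_cluster`` — members of a cluster vs the rest of the population,
  ignoring diagnosis;
* ``diagnostic_group`` — two diagnostic groups (e.g. CN vs AD) within one
  cluster;
* ``diagnostic_interaction`` — subjects of one diagnosis inside a cluster vs
  subjects of the same diagnosis outside it (the probe for profile x stage
  interactions).

Group differences are tested with a two-sided Mann-Whitney U test.  Because
clusters and diagnostic groups have unequal sizes, the raw p-value is
corrected against a permutation null: cluster membership is shuffled within
each diagnostic stratum — which preserves every cluster size and every
cluster x diagnosis cell count exactly — and the observed p is called
significant only if it falls below the alpha-quantile (default 5%) of the
permuted p distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ComparisonSpec",
    "PermutationResult",
    "mannwhitney",
    "permute_membership",
    "run_comparison",
    "run_all",
    "SCHEMES",
]

SCHEMES = ("whole_cluster", "diagnostic_group", "diagnostic_interaction")

#: combined sample size at or below which the exact U distribution is used
#: (when the pooled values are tie-free); larger samples use the normal
#: approximation with tie correction.
EXACT_CUTOFF = 25


@dataclass(frozen=True)
class ComparisonSpec:
    """One comparison: scheme, cluster, phenotype and (scheme-dependent)
    diagnosis or ordered diagnosis pair."""

    scheme: str
    cluster_id: int
    phenotype_id: str
    diagnosis: str | None = None
    diagnosis_pair: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}, got {self.scheme!r}")
        if self.scheme == "diagnostic_group" and self.diagnosis_pair is None:
            raise ValueError("diagnostic_group requires diagnosis_pair")
        if self.scheme == "diagnostic_interaction" and self.diagnosis is None:
            raise ValueError("diagnostic_interaction requires diagnosis")

    def describe(self) -> str:
        extra = self.diagnosis or (
            "/".join(self.diagnosis_pair) if self.diagnosis_pair else ""
        )
        return f"{self.scheme}(cluster={self.cluster_id}, {extra}, {self.phenotype_id})"


@dataclass
class PermutationResult:
    """Observed Mann-Whitney p with its strata-preserving permutation null."""

    spec: ComparisonSpec
    observed_p: float
    null_ps: np.ndarray
    alpha: float
    n_perm: int
    seed: int
    n_a: int
    n_b: int
    percentile_threshold: float = field(init=False)
    significant: bool = field(init=False)

    def __post_init__(self) -> None:
        self.null_ps = np.asarray(self.null_ps, float)
        self.percentile_threshold = float(np.quantile(self.null_ps, self.alpha))
        self.significant = bool(self.observed_p <= self.percentile_threshold)


def mannwhitney(values_a, values_b, *, axis: int = -1):
    """Two-sided Mann-Whitney U p-value.

    Uses the exact U distribution when the combined sample is small
    (<= EXACT_CUTOFF) and tie-free, otherwise the normal approximation with
    tie correction and continuity correction.  Accepts stacked groups for a
    vectorised test along ``axis``.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty for the Mann-Whitney test")
    n = a.shape[axis] + b.shape[axis]
    if n < 4:
        raise ValueError(f"combined sample size {n} < 4")
    pooled = np.concatenate([a, b], axis=axis)
    has_ties = np.unique(pooled).size < pooled.size if pooled.ndim == 1 else True
    method = "exact" if (n <= EXACT_CUTOFF and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method, axis=axis)
    return np.minimum(res.pvalue, 1.0)


def permute_membership(cluster_labels, diagnosis_labels, seed=None, rng=None):
    """Shuffle cluster labels within each diagnostic stratum.

    Preserves every cluster size and every cluster x diagnosis cell count
    exactly, and is uniform over the assignments reachable that way.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    cl = np.asarray(cluster_labels)
    dg = np.asarray(diagnosis_labels)
    if cl.shape != dg.shape:
        raise ValueError("label vectors must align")
    out = cl.copy()
    for d in np.unique(dg):
        idx = np.flatnonzero(dg == d)
        out[idx] = cl[idx][rng.permutation(idx.size)]
    return out


def _permuted_label_matrix(cl, dg, n_perm, rng, stratified=True):
    """(n_perm, N) matrix of permuted cluster labels."""
    n = cl.size
    perm = np.tile(cl, (n_perm, 1))
    if stratified:
        for d in np.unique(dg):
            idx = np.flatnonzero(dg == d)
            perm[:, idx] = rng.permuted(perm[:, idx], axis=1)
    else:
        perm = rng.permuted(perm, axis=1)
    return perm


def _group_masks(spec: ComparisonSpec, cl, dg):
    if spec.scheme == "whole_cluster":
        a = cl == spec.cluster_id
        b = ~a
    elif spec.scheme == "diagnostic_group":
        d1, d2 = spec.diagnosis_pair
        a = (cl == spec.cluster_id) & (dg == d1)
        b = (cl == spec.cluster_id) & (dg == d2)
    else:  # diagnostic_interaction
        a = (cl == spec.cluster_id) & (dg == spec.diagnosis)
        b = (cl != spec.cluster_id) & (dg == spec.diagnosis)
    return a, b


def _phenotype_vector(phenotypes, phenotype_id):
    if hasattr(phenotypes, "to_frame") and hasattr(phenotypes, "region_ids"):
        frame = phenotypes.to_frame()
    elif isinstance(phenotypes, pd.DataFrame):
        frame = phenotypes
    elif isinstance(phenotypes, pd.Series):
        return phenotypes.to_numpy(float)
    else:
        return np.asarray(phenotypes, float)
    return frame[phenotype_id].to_numpy(float)


def run_comparison(spec: ComparisonSpec, phenotypes, cluster_labels,
                   diagnosis_labels, n_perm: int = 1000, seed: int = 0,
                   alpha: float = 0.05, stratified: bool = True,
                   _perm_labels: np.ndarray | None = None) -> PermutationResult:
    """Observed Mann-Whitney p for one comparison plus its permutation null.

    ``_perm_labels`` lets a caller (``run_all``) share one permuted-label
    matrix across phenotypes; by default it is generated here from ``seed``.
    """
    cl = np.asarray(cluster_labels)
    dg = np.asarray(diagnosis_labels)
    values = _phenotype_vector(phenotypes, spec.phenotype_id)
    if not (cl.shape == dg.shape == values.shape):
        raise ValueError("labels and phenotype must align")

    mask_a, mask_b = _group_masks(spec, cl, dg)
    n_a, n_b = int(mask_a.sum()), int(mask_b.sum())
    if n_a == 0 or n_b == 0:
        raise ValueError(f"empty comparison group in {spec.describe()}")
    observed_p = float(mannwhitney(values[mask_a], values[mask_b]))

    if _perm_labels is None:
        rng = np.random.default_rng(seed)
        _perm_labels = _permuted_label_matrix(cl, dg, n_perm, rng, stratified)
    null_ps = _null_pvalues(spec, values, _perm_labels, dg, n_a, n_b)

    return PermutationResult(spec=spec, observed_p=observed_p, null_ps=null_ps,
                             alpha=alpha, n_perm=len(null_ps), seed=seed,
                             n_a=n_a, n_b=n_b)


def _null_pvalues(spec, values, perm_labels, dg, n_a, n_b):
    """p-values under each permuted labelling.

    With strata-preserving permutations the group sizes are constant across
    replicates, so the groups stack into rectangular arrays and one vectorised
    Mann-Whitney call covers all replicates.  Degenerate replicates (an empty
    group, only possible with unstratified shuffles) are recorded as p = 1.
    """
    n_perm = perm_labels.shape[0]
    rows_a, rows_b = [], []
    fallback = []
    for r in range(n_perm):
        a, b = _group_masks(spec, perm_labels[r], dg)
        if a.sum() == n_a and b.sum() == n_b:
            rows_a.append(values[a])
            rows_b.append(values[b])
            fallback.append(None)
        else:
            fallback.append((values[a], values[b]))
    ps = np.empty(n_perm)
    if rows_a:
        stacked = mannwhitney(np.asarray(rows_a), np.asarray(rows_b), axis=-1)
        stacked = np.atleast_1d(stacked)
        it = iter(stacked)
        for r in range(n_perm):
            if fallback[r] is None:
                ps[r] = next(it)
    n_empty = 0
    for r, fb in enumerate(fallback):
        if fb is None:
            continue
        va, vb = fb
        if va.size == 0 or vb.size == 0:
            ps[r] = 1.0
            n_empty += 1
        else:
            ps[r] = float(mannwhitney(va, vb))
    if n_empty:
        logger.warning("%d permutation replicate(s) had an empty group (p set to 1) in %s",
                       n_empty, spec.describe())
    return ps


def run_all(phenotypes, cluster_labels, diagnosis_labels,
            schemes=SCHEMES, n_perm: int = 1000, seed: int = 0,
            alpha: float = 0.05, min_group: int = 2,
            stratified: bool = True) -> pd.DataFrame:
    """All comparisons of the requested schemes over clusters x phenotypes.

    Returns a tidy DataFrame with one row per comparison: scheme, cluster,
    diagnosis_or_pair, phenotype, n_a, n_b, observed_p, null_p05, significant,
    n_perm, seed, note.  Comparisons whose observed groups are smaller than
    ``min_group`` are kept as rows with NaN p-values and an explanatory note.
    One permuted-label matrix per run is shared by all comparisons, so the
    result is reproducible for a fixed seed regardless of iteration order.
    """
    cl = np.asarray(cluster_labels)
    dg = np.asarray(diagnosis_labels)
    if isinstance(schemes, str):
        schemes = (schemes,)
    for s in schemes:
        if s not in SCHEMES:
            raise ValueError(f"unknown scheme {s!r}")
    if hasattr(phenotypes, "to_frame"):
        frame = phenotypes.to_frame()
    else:
        frame = pd.DataFrame(phenotypes)
    clusters = sorted(int(c) for c in np.unique(cl))
    diags = sorted(str(d) for d in np.unique(dg))
    rng = np.random.default_rng(seed)
    perm_labels = _permuted_label_matrix(cl, dg, n_perm, rng, stratified)

    rows = []
    for scheme in schemes:
        for c in clusters:
            if scheme == "whole_cluster":
                combos = [(None, None)]
            elif scheme == "diagnostic_group":
                combos = [(None, (d1, d2)) for i, d1 in enumerate(diags)
                          for d2 in diags[i + 1:]]
            else:
                combos = [(d, None) for d in diags]
            for diag, pair in combos:
                for phenotype in frame.columns:
                    spec = ComparisonSpec(scheme=scheme, cluster_id=c,
                                          phenotype_id=str(phenotype),
                                          diagnosis=diag, diagnosis_pair=pair)
                    mask_a, mask_b = _group_masks(spec, cl, dg)
                    n_a, n_b = int(mask_a.sum()), int(mask_b.sum())
                    base = {
                        "scheme": scheme,
                        "cluster": c,
                        "diagnosis_or_pair": diag or (":".join(pair) if pair else ""),
                        "phenotype": str(phenotype),
                        "n_a": n_a,
                        "n_b": n_b,
                        "n_perm": n_perm,
                        "seed": seed,
                    }
                    if min(n_a, n_b) < min_group:
                        rows.append({**base, "observed_p": np.nan,
                                     "null_p05": np.nan, "significant": False,
                                     "note": f"skipped: group size < {min_group}"})
                        continue
                    res = run_comparison(spec, frame, cl, dg, n_perm=n_perm,
                                         seed=seed, alpha=alpha,
                                         stratified=stratified,
                                         _perm_labels=perm_labels)
                    rows.append({**base, "observed_p": res.observed_p,
                                 "null_p05": res.percentile_threshold,
                                 "significant": res.significant, "note": ""})
    return pd.DataFrame(rows)
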