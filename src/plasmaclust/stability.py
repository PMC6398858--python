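"""Bootstrap cluster-stability assessment with Jaccard matching.

A clustering is refitted on bootstrap resamples of the cohort (same size,
with replacement); each resample's clusters are matched one-to-one to the
reference clusters by maximising total Jaccard overlap, and the per-reference-
cluster mean Jaccard over replicates quantifies stability.  Baselines:
k-means on the raw (scaled) marker space with Euclidean distance, and uniform
random labels.

Jaccard overlap is computed on *sets* of unique subject ids (a subject drawn
twice counts once), and reference clusters are restricted to subjects present
in the resample so that out-of-sample subjects do not mechanically depress the
overlap.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .cimlr import Hyperparams, embed_and_cluster, fit_cimlr
from .kernels import DEFAULT_K_GRID, DEFAULT_SIGMA_GRID, build_kernel_bank

logger = logging.getLogger(__name__)

__all__ = ["StabilityReport", "jaccard", "match_clusters", "bootstrap_stability"]

METHODS = ("cimlr", "kmeans_euclidean", "random")


@dataclass
class StabilityReport:
    """Per-cluster Jaccard stability of one method over bootstrap replicates."""

    method: str
    n_boot: int
    seed: int
    per_replicate_jaccard: np.ndarray  # n_boot x C
    per_cluster_mean_jaccard: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.per_replicate_jaccard = np.asarray(self.per_replicate_jaccard, float)
        self.per_cluster_mean_jaccard = self.per_replicate_jaccard.mean(axis=0)


def jaccard(set_a, set_b) -> float:
    """Intersection over union of two subject-id sets; J(empty, empty) = 0."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        warnings.warn("Jaccard of two empty sets defined as 0", stacklevel=2)
        return 0.0
    return len(a & b) / len(union)


def _label_sets(labels, ids, n_clusters: int) -> list[set]:
    labels = np.asarray(labels)
    ids = np.asarray(ids)
    return [set(ids[labels == c]) for c in range(n_clusters)]


def match_clusters(reference_labels, candidate_labels, subject_ids=None):
    """One-to-one matching of candidate clusters to reference clusters.

    Maximises the total Jaccard overlap with an optimal bipartite assignment;
    labelings with different cluster counts are padded with empty
    pseudo-clusters.  Ties are broken deterministically (lowest reference
    index first).

    Returns
    -------
    mapping : dict candidate label -> reference label
    per_reference_jaccard : ndarray over reference labels (padded entries
        excluded)
    """
    ref = np.asarray(reference_labels)
    cand = np.asarray(candidate_labels)
    if ref.shape != cand.shape:
        raise ValueError("labelings must cover the same subjects")
    ids = np.arange(ref.size) if subject_ids is None else np.asarray(subject_ids)
    c_ref = int(ref.max()) + 1 if ref.size else 0
    c_cand = int(cand.max()) + 1 if cand.size else 0
    c = max(c_ref, c_cand)
    ref_sets = _label_sets(ref, ids, c)
    cand_sets = _label_sets(cand, ids, c)
    overlap = np.zeros((c, c))
    for i, rs in enumerate(ref_sets):
        for j, cs in enumerate(cand_sets):
            if rs or cs:
                overlap[i, j] = len(rs & cs) / len(rs | cs)
    row, col = linear_sum_assignment(-overlap)
    mapping = {int(cj): int(ri) for ri, cj in zip(row, col)}
    per_ref = np.zeros(c_ref)
    for ri, cj in zip(row, col):
        if ri < c_ref:
            per_ref[ri] = overlap[ri, cj]
    return mapping, per_ref


def bootstrap_stability(
    X,
    reference_labels,
    method: str = "cimlr",
    n_boot: int = 100,
    seed: int = 0,
    *,
    n_clusters: int | None = None,
    k_grid=DEFAULT_K_GRID,
    sigma_grid=DEFAULT_SIGMA_GRID,
    hyperparams: Hyperparams | None = None,
    resample_indices=None,
    max_redraws: int = 100,
) -> StabilityReport:
    """Bootstrap the chosen clustering method and report per-cluster Jaccard.

    Parameters
    ----------
    X : ndarray or MarkerMatrix (scaled subjects x markers)
    reference_labels : labels fitted on the full cohort
    method : 'cimlr' (kernel bank + similarity learning + embedding +
        k-means), 'kmeans_euclidean' (k-means on the marker rows), or
        'random' (uniform labels)
    resample_indices : optional (n_boot, N) integer array overriding the
        resampling — a test hook, e.g. the identity resample.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    values = np.asarray(getattr(X, "values", X), dtype=float)
    ref = np.asarray(reference_labels)
    n = values.shape[0]
    if ref.shape != (n,):
        raise ValueError("reference_labels must align with X rows")
    c = n_clusters if n_clusters is not None else int(ref.max()) + 1
    rng = np.random.default_rng(seed)

    per_rep = np.zeros((n_boot, c))
    for b in range(n_boot):
        if resample_indices is not None:
            idx = np.asarray(resample_indices[b])
        else:
            idx = rng.integers(0, n, size=n)
            redraws = 0
            while np.unique(idx).size < c:
                redraws += 1
                if redraws > max_redraws:
                    raise RuntimeError("could not draw a resample with >= C distinct subjects")
                logger.info("replicate %d redrawn (fewer than %d distinct subjects)", b, c)
                idx = rng.integers(0, n, size=n)

        sub_seed = int(rng.integers(0, 2**31 - 1))
        labels_b = _fit_labels(values[idx], method, c, sub_seed,
                               k_grid, sigma_grid, hyperparams)
        present = np.unique(idx)
        cand_sets = [set(idx[labels_b == cl]) for cl in range(c)]
        ref_sets = [set(np.flatnonzero(ref == cl)) & set(present) for cl in range(c)]
        overlap = np.zeros((c, c))
        for i, rs in enumerate(ref_sets):
            for j, cs in enumerate(cand_sets):
                if rs or cs:
                    overlap[i, j] = len(rs & cs) / len(rs | cs)
        row, col = linear_sum_assignment(-overlap)
        for ri, cj in zip(row, col):
            per_rep[b, ri] = overlap[ri, cj]

    return StabilityReport(method=method, n_boot=n_boot, seed=seed,
                           per_replicate_jaccard=per_rep)


def _fit_labels(values, method, c, seed, k_grid, sigma_grid, hyperparams):
    if method == "random":
        return np.random.default_rng(seed).integers(0, c, size=values.shape[0])
    if method == "kmeans_euclidean":
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=c, n_init=10, random_state=seed % (2**31))
        return km.fit_predict(values)
    hp = hyperparams if hyperparams is not None else Hyperparams(n_clusters=c)
    if hp.n_clusters != c:
        from dataclasses import replace

        hp = replace(hp, n_clusters=c)
    bank = build_kernel_bank(values, k_grid, sigma_grid)
    model = fit_cimlr(bank, hp)
    embed_and_cluster(model, seed=seed % (2**31))
    return model.labels
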