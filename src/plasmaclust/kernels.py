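"""Per-marker Gaussian kernel bank with KNN-adaptive bandwidths.

Each blood marker ``m`` contributes P = len(k_grid) * len(sigma_grid) Gaussian
kernels.  The bandwidth of kernel ``(m, k, sigma)`` between subjects ``i`` and
``j`` is

    eps_ijm = sigma * (mu_im + mu_jm) / 2

where ``mu_im`` is the mean absolute distance from subject ``i`` to its ``k``
nearest neighbours in marker ``m`` (self excluded), and the kernel value is the
normal density

    K_mp(i, j) = exp(-(x_im - x_jm)^2 / (2 eps_ijm^2)) / (eps_ijm sqrt(2 pi)).

The density normalisation makes kernels from tight neighbourhoods (small mu)
larger in absolute value; the weight-learning step downstream sees both the
shape and the scale of each kernel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KernelParams",
    "KernelBank",
    "build_kernel_bank",
    "DEFAULT_K_GRID",
    "DEFAULT_SIGMA_GRID",
    "REFERENCE_SIGMA_GRID",
]

#: Neighbour counts and bandwidth multipliers of the canonical grid
#: (15 kernels per marker).  Values this large assume a cohort of a few
#: hundred subjects; ``build_kernel_bank`` clamps k to N-1 for smaller ones.
DEFAULT_K_GRID = (30, 45, 50)
DEFAULT_SIGMA_GRID = (30, 35, 40, 45, 50)

#: Alternative multipliers in the range typical of reference multi-kernel
#: implementations; on min-max scaled data these give sharper, more
#: discriminative kernels than the canonical grid.
REFERENCE_SIGMA_GRID = (1.0, 1.25, 1.5, 1.75, 2.0)


@dataclass(frozen=True)
class KernelParams:
    """(k, sigma) pair parameterising one kernel."""

    k: int
    sigma: float

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")


@dataclass
class KernelBank:
    """The M*P Gaussian kernels over one cohort.

    Attributes
    ----------
    kernels : ndarray, shape (Q, N, N)
        Stacked kernel matrices, Q = M * P.
    params : list of KernelParams, length Q
    marker_of_kernel : ndarray of int, shape (Q,)
        Index of the marker each kernel was built from.
    marker_ids : list of str
    mu : ndarray, shape (n_k, N, M)
        Mean KNN distance per k-grid entry, subject and marker.
    k_grid, sigma_grid : grids actually used (after clamping).
    """

    kernels: np.ndarray
    params: list[KernelParams]
    marker_of_kernel: np.ndarray
    marker_ids: list[str]
    mu: np.ndarray
    k_grid: tuple[int, ...]
    sigma_grid: tuple[float, ...]
    subject_ids: list[str] = field(default_factory=list)

    @property
    def n_kernels(self) -> int:
        return self.kernels.shape[0]

    @property
    def n_subjects(self) -> int:
        return self.kernels.shape[1]

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def kernels_2d(self) -> np.ndarray:
        """View of the bank as (Q, N*N) for fast inner products."""
        q, n, _ = self.kernels.shape
        return self.kernels.reshape(q, n * n)


def build_kernel_bank(
    X,
    k_grid=DEFAULT_K_GRID,
    sigma_grid=DEFAULT_SIGMA_GRID,
    *,
    clamp_k: bool = True,
    dtype=np.float64,
) -> KernelBank:
    """Build the Gaussian kernel bank for a scaled marker matrix.

    Parameters
    ----------
    X : MarkerMatrix or ndarray (N subjects x M markers)
        Min-max scaled values without missing entries.
    k_grid : iterable of int
        Neighbour counts for the adaptive bandwidth.  Each k must be < N;
        with ``clamp_k`` (default) oversized values are clamped to N-1 and a
        warning is emitted, otherwise they raise.
    sigma_grid : iterable of float
        Bandwidth multipliers.

    Returns
    -------
    KernelBank with exactly ``len(k_grid) * len(sigma_grid)`` kernels per
    marker, each symmetric, finite and positive.
    """
    values, subject_ids, marker_ids = _as_matrix(X)
    n, m = values.shape
    if n < 2:
        raise ValueError("need at least 2 subjects to build kernels")
    if np.isnan(values).any():
        raise ValueError("marker matrix contains missing values")

    k_grid = tuple(int(k) for k in k_grid)
    sigma_grid = tuple(float(s) for s in sigma_grid)
    if not k_grid or not sigma_grid:
        raise ValueError("k_grid and sigma_grid must be non-empty")
    clamped = []
    for k in k_grid:
        if k < 1:
            raise ValueError(f"k must be >= 1, got {k}")
        if k >= n:
            if not clamp_k:
                raise ValueError(f"k={k} must be < number of subjects N={n}")
            clamped.append(k)
    if clamped:
        warnings.warn(
            f"k values {clamped} >= N={n}; clamped to N-1={n - 1}",
            stacklevel=2,
        )
        k_grid = tuple(min(k, n - 1) for k in k_grid)

    p = len(k_grid) * len(sigma_grid)
    q = m * p
    kernels = np.empty((q, n, n), dtype=dtype)
    params: list[KernelParams] = []
    marker_of_kernel = np.empty(q, dtype=np.intp)
    mu_all = np.empty((len(k_grid), n, m))

    sqrt_2pi = np.sqrt(2.0 * np.pi)
    idx = 0
    for mi in range(m):
        col = values[:, mi]
        d = np.abs(col[:, None] - col[None, :])
        # sorted distances to others; column 0 is the self-distance (0)
        d_sorted = np.sort(d, axis=1)
        d2 = d * d
        for ki, k in enumerate(k_grid):
            mu_i = d_sorted[:, 1 : k + 1].mean(axis=1)
            mu_all[ki, :, mi] = mu_i
            base = 0.5 * (mu_i[:, None] + mu_i[None, :])
            for sigma in sigma_grid:
                eps = sigma * base
                eps = _guard_zero_bandwidth(eps, marker_ids[mi])
                kernels[idx] = np.exp(-d2 / (2.0 * eps * eps)) / (eps * sqrt_2pi)
                params.append(KernelParams(k=k, sigma=sigma))
                marker_of_kernel[idx] = mi
                idx += 1

    return KernelBank(
        kernels=kernels,
        params=params,
        marker_of_kernel=marker_of_kernel,
        marker_ids=list(marker_ids),
        mu=mu_all,
        k_grid=k_grid,
        sigma_grid=sigma_grid,
        subject_ids=list(subject_ids),
    )


def _guard_zero_bandwidth(eps: np.ndarray, marker_id: str) -> np.ndarray:
    """Replace zero bandwidths (duplicate marker values) by the smallest
    positive bandwidth of that marker; a fully constant marker gets a unit
    bandwidth, making its kernels flat and uninformative."""
    zero = eps <= 0.0
    if not zero.any():
        return eps
    eps = eps.copy()
    positive = eps[~zero]
    if positive.size:
        eps[zero] = positive.min()
    else:
        warnings.warn(
            f"marker {marker_id!r} is constant; its kernels are uniform",
            stacklevel=3,
        )
        eps[zero] = 1.0
    return eps


def _as_matrix(X):
    """Accept a MarkerMatrix, DataFrame or ndarray; return (values, ids, cols)."""
    if hasattr(X, "values") and hasattr(X, "marker_ids"):  # MarkerMatrix
        return (
            np.asarray(X.values, dtype=float),
            list(X.subject_ids),
            list(X.marker_ids),
        )
    if hasattr(X, "columns"):  # DataFrame
        return (
            X.to_numpy(dtype=float),
            [str(i) for i in X.index],
            [str(c) for c in X.columns],
        )
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D subjects x markers array")
    n, m = arr.shape
    return arr, [str(i) for i in range(n)], [f"m{j}" for j in range(m)]
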