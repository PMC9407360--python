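"""Kernel density estimation on a pooled two-group sample.

The central object is the pairwise :class:`KernelMatrix`: scaled kernel
evaluations between every pair of pooled observations at a fixed bandwidth.
The matrix never sees group labels, so every permutation of labels reuses it —
each permuted statistic is just a different row/column bookkeeping over the
same entries.  Leave-one-out log-densities are computed from the matrix by
log-sum-exp, which keeps heavy-tailed kernels at tiny bandwidths stable.

Bivariate data use a product kernel (one bandwidth per coordinate).  For data
supported on the unit square, a reflection correction augments each point with
its three mirror images across the axes; each leave-one-out estimate then
leaves out the evaluation point together with its reflections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .kernels import KernelSpec

__all__ = [
    "CombinedSample",
    "KernelMatrix",
    "kde_eval",
    "kde_eval_bivariate",
    "build_kernel_matrix",
    "loo_log_density",
    "reflect_unit_square",
    "loo_log_density_reflected",
]

_REFLECTION_SIGNS = np.array([[1, 1], [1, -1], [-1, -1], [-1, 1]], dtype=float)


@dataclass(frozen=True)
class CombinedSample:
    """The pooled sample Z with group sizes; first ``m`` points are group X.

    Both leave-one-out sub-samples must be non-empty, hence ``m > 1`` and
    ``n > 1``.  All statistics downstream depend on the data only through the
    pooled observations and the labels, so relabeling never touches ``z``.
    """

    z: np.ndarray
    m: int
    n: int

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        if z.ndim == 1:
            z = z[:, None]
        if z.ndim != 2 or z.shape[1] not in (1, 2):
            raise ValueError(
                f"observations must be 1- or 2-dimensional, got shape {z.shape}"
            )
        if not np.all(np.isfinite(z)):
            raise ValueError("observations must be finite")
        if self.m < 2 or self.n < 2:
            raise ValueError(
                f"each group needs at least 2 observations (m={self.m}, n={self.n})"
            )
        if z.shape[0] != self.m + self.n:
            raise ValueError(
                f"expected {self.m + self.n} observations, got {z.shape[0]}"
            )
        object.__setattr__(self, "z", z)

    @classmethod
    def from_groups(cls, x, y) -> "CombinedSample":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.ndim != y.ndim:
            raise ValueError("both groups must have the same dimension")
        return cls(np.concatenate([x, y], axis=0), len(x), len(y))

    @property
    def size(self) -> int:
        return self.m + self.n

    @property
    def dim(self) -> int:
        return self.z.shape[1]

    @property
    def labels(self) -> np.ndarray:
        """Boolean mask, True for the X-group (first ``m`` observations)."""
        lab = np.zeros(self.size, dtype=bool)
        lab[: self.m] = True
        return lab

    @property
    def x(self) -> np.ndarray:
        return np.squeeze(self.z[: self.m], axis=-1) if self.dim == 1 else self.z[: self.m]

    @property
    def y(self) -> np.ndarray:
        return np.squeeze(self.z[self.m :], axis=-1) if self.dim == 1 else self.z[self.m :]


@dataclass
class KernelMatrix:
    """Pairwise scaled kernel evaluations on the pooled sample.

    ``log_entries[i, j]`` is the log of the scaled kernel between observations
    i and j at the stored bandwidth; the diagonal is excluded (−inf) so that
    leave-one-out sums never include the evaluation point.  ``shift`` and
    ``expm`` hold a row-wise shifted exponential of the matrix for stable,
    vectorized log-sum-exp reductions: for any index subset ``s`` not
    containing i,

        log mean_{j in s} M[i, j] = shift[i] + log(expm[i] @ 1_s) − log|s|.
    """

    log_entries: np.ndarray
    bandwidth: tuple[float, ...]
    kernel_name: str
    reflected: bool = False
    shift: np.ndarray = field(init=False, repr=False)
    expm: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        le = self.log_entries
        if le.ndim != 2 or le.shape[0] != le.shape[1]:
            raise ValueError("kernel matrix must be square")
        self.shift = np.max(le, axis=1)
        if not np.all(np.isfinite(self.shift)):
            raise ValueError("every observation needs a positive-kernel neighbor")
        with np.errstate(invalid="ignore"):
            self.expm = np.exp(le - self.shift[:, None])
        np.fill_diagonal(self.expm, 0.0)

    @property
    def size(self) -> int:
        return self.log_entries.shape[0]

    def pooled_loo(self) -> np.ndarray:
        """Leave-one-out log-density of each Z_i under the pooled estimate."""
        return (
            self.shift
            + np.log(self.expm.sum(axis=1))
            - math.log(self.size - 1)
        )

    def group_loo(self, mask: np.ndarray) -> np.ndarray:
        """LOO log-density of each observation in ``mask`` within its group.

        Returns a length-N vector; entries outside ``mask`` are NaN.
        """
        mask = np.asarray(mask, dtype=bool)
        cnt = int(mask.sum()) - 1
        if cnt < 1:
            raise ValueError("group must have at least 2 members")
        s = self.expm @ mask.astype(float)
        out = np.full(self.size, np.nan)
        with np.errstate(divide="ignore"):
            out[mask] = self.shift[mask] + np.log(s[mask]) - math.log(cnt)
        # the row shift comes from the full row; a far-away group's shifted
        # terms can underflow into subnormals — redo those rows exactly
        for i in np.flatnonzero(mask & (s < 1e-250)):
            sub = mask.copy()
            sub[i] = False
            out[i] = logsumexp(self.log_entries[i, sub]) - math.log(cnt)
        return out


def _scaled_log_kernel(diff: np.ndarray, h: float, kernel: KernelSpec) -> np.ndarray:
    if not (h > 0):
        raise ValueError(f"bandwidth must be positive, got {h}")
    return kernel.log_pdf(diff / h) - math.log(h)


def kde_eval(
    u,
    h: float,
    points: Sequence[float] | np.ndarray,
    kernel: KernelSpec,
    *,
    log: bool = False,
):
    """Univariate kernel density estimate ``(1/kh) Σ K((u − U_i)/h)``.

    The log variant is computed by log-sum-exp over the log-kernel terms.
    Vectorized over ``u``.
    """
    pts = np.asarray(points, dtype=float).ravel()
    if pts.size == 0:
        raise ValueError("kernel estimate needs at least one data point")
    u = np.asarray(u, dtype=float)
    scalar = u.ndim == 0
    terms = _scaled_log_kernel(np.atleast_1d(u)[:, None] - pts[None, :], h, kernel)
    out = logsumexp(terms, axis=1) - math.log(pts.size)
    if not log:
        out = np.exp(out)
    return float(out[0]) if scalar else out


def kde_eval_bivariate(
    u,
    h1: float,
    h2: float,
    points,
    kernel: KernelSpec,
    *,
    log: bool = False,
):
    """Bivariate product-kernel estimate ``(1/(k h1 h2)) Σ L(Δ1/h1) L(Δ2/h2)``."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"expected k×2 data points, got shape {pts.shape}")
    u = np.asarray(u, dtype=float)
    scalar = u.ndim == 1
    uu = np.atleast_2d(u)
    if uu.shape[1] != 2:
        raise ValueError(f"evaluation points must be 2-dimensional, got {u.shape}")
    terms = _scaled_log_kernel(
        uu[:, None, 0] - pts[None, :, 0], h1, kernel
    ) + _scaled_log_kernel(uu[:, None, 1] - pts[None, :, 1], h2, kernel)
    out = logsumexp(terms, axis=1) - math.log(pts.shape[0])
    if not log:
        out = np.exp(out)
    return float(out[0]) if scalar else out


def _as_bandwidth_tuple(b, dim: int) -> tuple[float, ...]:
    bt = tuple(float(v) for v in np.atleast_1d(np.asarray(b, dtype=float)))
    if len(bt) == 1 and dim == 2:
        bt = (bt[0], bt[0])
    if len(bt) != dim:
        raise ValueError(f"expected {dim} bandwidth(s), got {bt}")
    if any(v <= 0 for v in bt):
        raise ValueError(f"bandwidths must be positive, got {bt}")
    return bt


def _log_matrix_univariate(z: np.ndarray, b: float, kernel: KernelSpec) -> np.ndarray:
    d = z[:, None] - z[None, :]
    return _scaled_log_kernel(d, b, kernel)


def _log_matrix_bivariate(
    z: np.ndarray, b1: float, b2: float, kernel: KernelSpec
) -> np.ndarray:
    return _scaled_log_kernel(
        z[:, None, 0] - z[None, :, 0], b1, kernel
    ) + _scaled_log_kernel(z[:, None, 1] - z[None, :, 1], b2, kernel)


def _log_matrix_reflected(
    z: np.ndarray, b1: float, b2: float, kernel: KernelSpec
) -> np.ndarray:
    """log S_ij where S sums the product kernel over the 4 reflections of Z_j.

    Reflections across the axes turn the differences (x_i − x_j, y_i − y_j)
    into the four sign combinations of differences and sums; the kernel's own
    symmetry makes S symmetric.
    """
    if np.any(z < 0.0) or np.any(z > 1.0):
        raise ValueError("reflection correction requires data on the unit square")
    dx, sx = z[:, None, 0] - z[None, :, 0], z[:, None, 0] + z[None, :, 0]
    dy, sy = z[:, None, 1] - z[None, :, 1], z[:, None, 1] + z[None, :, 1]
    terms = np.stack(
        [
            _scaled_log_kernel(dx, b1, kernel) + _scaled_log_kernel(dy, b2, kernel),
            _scaled_log_kernel(dx, b1, kernel) + _scaled_log_kernel(sy, b2, kernel),
            _scaled_log_kernel(sx, b1, kernel) + _scaled_log_kernel(sy, b2, kernel),
            _scaled_log_kernel(sx, b1, kernel) + _scaled_log_kernel(dy, b2, kernel),
        ]
    )
    return logsumexp(terms, axis=0)


def build_kernel_matrix(
    sample: CombinedSample,
    bandwidth,
    kernel: KernelSpec,
    *,
    reflect: bool = False,
) -> KernelMatrix:
    """Pairwise scaled kernel matrix on the pooled sample; diagonal excluded.

    With ``reflect=True`` (bivariate, unit-square data) each entry sums the
    product kernel over the four reflected copies of the source point, so that
    leave-one-out estimates through this matrix automatically leave out the
    evaluation point plus its three reflections and carry the ×4 boundary
    normalization.
    """
    b = _as_bandwidth_tuple(bandwidth, sample.dim)
    if reflect:
        if sample.dim != 2:
            raise ValueError("reflection correction is only defined for bivariate data")
        le = _log_matrix_reflected(sample.z, b[0], b[1], kernel)
    elif sample.dim == 2:
        le = _log_matrix_bivariate(sample.z, b[0], b[1], kernel)
    else:
        le = _log_matrix_univariate(sample.z[:, 0], b[0], kernel)
    np.fill_diagonal(le, -np.inf)
    return KernelMatrix(le, b, kernel.name, reflected=reflect)


def loo_log_density(i: int, subset: np.ndarray, matrix: KernelMatrix) -> float:
    """Leave-one-out log-density of observation i over ``subset`` minus i.

    ``subset`` is a boolean mask over the pooled observations; observation i
    is removed internally if present.  Computed stably by log-sum-exp.
    """
    subset = np.asarray(subset, dtype=bool).copy()
    subset[i] = False
    cnt = int(subset.sum())
    if cnt == 0:
        raise ValueError(f"subset is empty after removing observation {i}")
    return float(logsumexp(matrix.log_entries[i, subset]) - math.log(cnt))


def reflect_unit_square(points) -> tuple[np.ndarray, np.ndarray]:
    """Reflect unit-square points across both axes.

    Each (x, y) produces (x, y), (x, −y), (−x, −y), (−x, y).  Returns the
    4k augmented points and a (k, 4) index map from each original point to
    its copies.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"expected k×2 points, got shape {pts.shape}")
    if np.any(pts < 0.0) or np.any(pts > 1.0):
        raise ValueError("reflection assumes support on the unit square [0,1]²")
    k = pts.shape[0]
    augmented = (pts[:, None, :] * _REFLECTION_SIGNS[None, :, :]).reshape(4 * k, 2)
    index_map = np.arange(4 * k).reshape(k, 4)
    return augmented, index_map


def loo_log_density_reflected(
    i: int,
    subset: np.ndarray,
    sample: CombinedSample,
    b1: float,
    b2: float,
    kernel: KernelSpec,
) -> float:
    """Boundary-corrected LOO log-density at Z_i (leave-out-four).

    Equals the log of 4 × the kernel estimate built from the 4 reflected
    copies of every subset point except Z_i, evaluated at the original Z_i.
    """
    matrix = build_kernel_matrix(sample, (b1, b2), kernel, reflect=True)
    return loo_log_density(i, subset, matrix)
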