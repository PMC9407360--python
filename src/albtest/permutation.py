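"""Permutation null distribution of ALB, p-values and critical values.

Conditional on the pooled order statistics, every relabeling of group
membership is equally likely under the null, so the permutation distribution
of ALB gives an exact-level test.  The LCV bandwidth is invariant to
relabeling and the kernel matrix is label-free, so both are computed once and
shared by all permutations: each permuted ALB* is a vectorized reduction of
the same matrix against a fresh label indicator.

Because ALB is negative with probability tending to one under the null, the
1−α permutation quantile t_{m,n} is eventually negative; rejecting on a
negative value of an evidence statistic would be nonsensical, so the critical
value is floored at zero: max(0, t_{m,n}).

Conventions (recorded in every report):
- t_{m,n} is the order statistic at position ceil((1−α)·N) of the N permuted
  values — the conservative standard for permutation tests.
- The p-value counts strict exceedances, #{ALB* > ALB}/N; an add-one variant
  (#{ALB* ≥ ALB}+1)/(N+1) is available for users needing guaranteed validity
  but is not the default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .alb import alb_upper_bound
from .kde import CombinedSample, KernelMatrix, build_kernel_matrix
from .kernels import KernelSpec

__all__ = [
    "PermutationResult",
    "alb_for_labels",
    "permutation_distribution",
    "p_value",
    "critical_value",
    "conditional_level",
]

_CHUNK = 2048  # permutations per vectorized block; bounds peak memory


@dataclass(frozen=True)
class PermutationResult:
    """Observed ALB with its sampled permutation null."""

    observed: float
    alb_star: np.ndarray
    p_value: float
    t_quantile: float
    critical_value: float
    alpha: float
    n_permutations: int
    seed: int | None

    @property
    def reject(self) -> bool:
        return self.observed >= self.critical_value


def _alb_batch(matrix: KernelMatrix, indicators: np.ndarray) -> np.ndarray:
    """ALB* for each column of a boolean (N_obs × N_perm) X-group indicator.

    Uses the row-shifted exponential form of the kernel matrix: for each
    observation the own-group LOO log-density is shift + log(row-sum over the
    group) − log(group size − 1); the pooled term is permutation-invariant.
    """
    expm, shift = matrix.expm, matrix.shift
    n_obs = matrix.size
    m = int(indicators[:, 0].sum())
    n = n_obs - m
    pooled_sum = float(matrix.pooled_loo().sum())
    out = np.empty(indicators.shape[1])
    for start in range(0, indicators.shape[1], _CHUNK):
        block = indicators[:, start : start + _CHUNK]
        fx = block.astype(float)
        sx = expm @ fx
        sy = expm @ (1.0 - fx)
        with np.errstate(divide="ignore"):
            own = np.where(
                block,
                np.log(sx) - math.log(m - 1),
                np.log(sy) - math.log(n - 1),
            )
        own_sum = own.sum(axis=0) + shift.sum()
        out[start : start + block.shape[1]] = (own_sum - pooled_sum) / n_obs
    return out


def alb_for_labels(matrix: KernelMatrix, labels: np.ndarray) -> float:
    """ALB of the pooled sample under an arbitrary X-group label mask."""
    labels = np.asarray(labels, dtype=bool)
    return float(_alb_batch(matrix, labels[:, None])[0])


def _random_indicators(
    n_obs: int, m: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    base = np.zeros(n_obs, dtype=bool)
    base[:m] = True
    mat = np.tile(base, (n_perm, 1))
    return rng.permuted(mat, axis=1).T


def p_value(observed: float, alb_star: np.ndarray, *, add_one: bool = False) -> float:
    """Permutation p-value: the proportion of ALB* strictly above the observed.

    Ties count as non-exceedances.  ``add_one`` switches to the
    (#{ALB* ≥ obs}+1)/(N+1) variant.
    """
    alb_star = np.asarray(alb_star, dtype=float)
    if alb_star.size == 0:
        raise ValueError("need at least one permuted value")
    if add_one:
        return (int(np.sum(alb_star >= observed)) + 1) / (alb_star.size + 1)
    return float(np.mean(alb_star > observed))


def _quantile(values: np.ndarray, level: float) -> float:
    """Order statistic at position ceil(level · N) (1-indexed)."""
    v = np.sort(np.asarray(values, dtype=float))
    k = min(max(int(math.ceil(level * v.size)), 1), v.size)
    return float(v[k - 1])


def critical_value(alb_star: np.ndarray, alpha: float) -> float:
    """max(0, empirical 1−α quantile of the permuted values)."""
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    return max(0.0, _quantile(alb_star, 1.0 - alpha))


def permutation_distribution(
    sample: CombinedSample,
    bandwidth,
    kernel: KernelSpec,
    n_permutations: int,
    *,
    alpha: float = 0.05,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    reflect: bool = False,
    matrix: KernelMatrix | None = None,
) -> PermutationResult:
    """Sample the permutation null of ALB and summarize it.

    Permutations are drawn uniformly with replacement from the relabeling
    group.  The bandwidth must already be the pooled-sample LCV value (or any
    fixed value): it is shared across permutations by construction.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    if rng is None:
        rng = np.random.default_rng(seed)
    if matrix is None:
        matrix = build_kernel_matrix(sample, bandwidth, kernel, reflect=reflect)
    observed = alb_for_labels(matrix, sample.labels)
    indicators = _random_indicators(sample.size, sample.m, n_permutations, rng)
    alb_star = _alb_batch(matrix, indicators)
    bound = alb_upper_bound(sample.m, sample.n)
    if np.any(alb_star > bound + 1e-9):
        raise AssertionError("permuted ALB exceeded its theoretical upper bound")
    return PermutationResult(
        observed=observed,
        alb_star=alb_star,
        p_value=p_value(observed, alb_star),
        t_quantile=_quantile(alb_star, 1.0 - alpha),
        critical_value=critical_value(alb_star, alpha),
        alpha=alpha,
        n_permutations=n_permutations,
        seed=seed,
    )


def conditional_level(
    sample: CombinedSample,
    bandwidth,
    kernel: KernelSpec,
    n_first: int,
    n_second: int,
    *,
    alpha: float = 0.05,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    reflect: bool = False,
    matrix: KernelMatrix | None = None,
) -> float:
    """Conditional level of the test whose critical value uses n_first permutations.

    Draws n_first permutations and takes their 1−α quantile, then draws
    n_second further permutations and returns the proportion strictly
    exceeding that quantile — the actual rejection probability, given the
    data, of the finite-permutation test.
    """
    if n_first < 1 or n_second < 1:
        raise ValueError("both permutation counts must be at least 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    if matrix is None:
        matrix = build_kernel_matrix(sample, bandwidth, kernel, reflect=reflect)
    first = _alb_batch(
        matrix, _random_indicators(sample.size, sample.m, n_first, rng)
    )
    t = _quantile(first, 1.0 - alpha)
    second = _alb_batch(
        matrix, _random_indicators(sample.size, sample.m, n_second, rng)
    )
    return float(np.mean(second > t))
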