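"""The ALB statistic: the average of leave-one-out log-Bayes factors.

For each pooled observation Z_i, a Bayes factor B_i compares two kernel-
estimate models of the held-out datum: the numerator estimates the density
from the rest of Z_i's *own group*, the denominator from the rest of the
*pooled* sample.  With a scale-family bandwidth prior both marginal
likelihoods collapse to kernel estimates with the induced kernel L, so

    log B_i = log f̂_L(Z_i | b, own group − i) − log f̂_L(Z_i | b, Z_{-i}),

and ALB is the mean of the m+n values.  Equivalently (m+n)·ALB is the sum of
the two within-group cross-validation log-likelihoods minus the pooled one —
the log of a likelihood ratio of "different densities" to "equal densities".

ALB is sharply bounded above.  With p_{m,n} = (m−1)/(m+n−1), the pooled LOO
estimate is the mixture p·(own-group LOO) + (1−p)·(other group), so each
X-group log B_i ≤ −log p_{m,n}, giving

    ALB ≤ −(m/(m+n))·log p_{m,n} − (n/(m+n))·log((n−1)/(m+n−1))
        ≤ log 2 · max(m/(m−1), n/(n−1)).

Unless a group is tiny the effective bound is log 2: no single Bayes factor
can ever carry compelling evidence, which is why the statistic is used with a
permutation null rather than on the Bayes scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .kde import CombinedSample, KernelMatrix, build_kernel_matrix
from .kernels import KernelSpec

__all__ = ["ALBResult", "log_bayes_factor", "alb_statistic", "alb_upper_bound"]


@dataclass(frozen=True)
class ALBResult:
    """ALB value with its per-observation log-Bayes factors."""

    alb: float
    log_bf: np.ndarray
    bandwidth: tuple[float, ...]
    kernel_name: str
    m: int
    n: int

    @property
    def upper_bound(self) -> float:
        return alb_upper_bound(self.m, self.n)


def log_bayes_factor(i: int, sample: CombinedSample, matrix: KernelMatrix) -> float:
    """log B_i for a single pooled observation, from the kernel matrix."""
    labels = sample.labels
    own = labels if labels[i] else ~labels
    if int(own.sum()) < 2:
        raise ValueError("each group needs at least 2 members for leave-one-out")
    pooled = np.ones(sample.size, dtype=bool)
    from .kde import loo_log_density

    return loo_log_density(i, own, matrix) - loo_log_density(i, pooled, matrix)


def alb_statistic(
    sample: CombinedSample,
    bandwidth,
    kernel: KernelSpec,
    *,
    reflect: bool = False,
    matrix: KernelMatrix | None = None,
) -> ALBResult:
    """ALB and the per-observation log-Bayes factors at a fixed bandwidth.

    A prebuilt :class:`KernelMatrix` may be passed to avoid recomputation;
    kernels are never re-evaluated per permutation elsewhere for the same
    reason.
    """
    if matrix is None:
        matrix = build_kernel_matrix(sample, bandwidth, kernel, reflect=reflect)
    labels = sample.labels
    own = np.where(
        labels, matrix.group_loo(labels), matrix.group_loo(~labels)
    )
    log_bf = own - matrix.pooled_loo()
    return ALBResult(
        alb=float(log_bf.mean()),
        log_bf=log_bf,
        bandwidth=matrix.bandwidth,
        kernel_name=matrix.kernel_name,
        m=sample.m,
        n=sample.n,
    )


def alb_upper_bound(m: int, n: int) -> float:
    """Sharp upper bound on ALB for group sizes (m, n).

    Returns the smaller of the exact mixture bound
    −(m/(m+n))·log((m−1)/(m+n−1)) − (n/(m+n))·log((n−1)/(m+n−1))
    and its entropy relaxation log 2 · max(m/(m−1), n/(n−1)).
    """
    if m < 2 or n < 2:
        raise ValueError(f"bound requires m > 1 and n > 1, got m={m}, n={n}")
    total = m + n
    exact = -(m / total) * math.log((m - 1) / (total - 1)) - (n / total) * math.log(
        (n - 1) / (total - 1)
    )
    relaxed = math.log(2.0) * max(m / (m - 1), n / (n - 1))
    return min(exact, relaxed)
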