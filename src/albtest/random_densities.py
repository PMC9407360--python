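"""Random normal-mixture densities and the size/power simulation harness.

The random-mixture mechanism draws a normal mixture whose component count M
lies in {2, …, 20} with probability proportional to 1/M, mixture weights from
a Dirichlet(1/2, …, 1/2), component variances i.i.d. inverse-gamma with shape
and scale both 1/2 (density ∝ x^{−3/2} e^{−1/(2x)}), and component means
μ_j | σ_j ~ N(0, σ_j²).  The heavy-tailed variance prior produces densities
ranging from near-normal to sharply multimodal, a stress benchmark for
nonparametric two-sample tests.

The harness runs the two standard experiments:

- *conditional levels*: how well a critical value estimated from a small
  permutation set (N1 draws, 95th percentile) holds its nominal level,
  measured against a larger permutation set (N2 draws) from the same data;
- *power comparison*: permutation p-values of ALB against the two-sample
  Kolmogorov–Smirnov test (and optionally a kernel-L2 permutation test) on
  the normal scale alternative N(0,1) vs N(0,2²).

Every replicate gets an independent child seed spawned from the master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .bandwidth import select_bandwidth
from .baselines import bowman_l2_test, ks_two_sample
from .kde import CombinedSample, build_kernel_matrix
from .kernels import KernelSpec, hall_kernel
from .permutation import conditional_level, permutation_distribution

__all__ = [
    "NormalMixture",
    "ExperimentConfig",
    "draw_random_mixture",
    "mixture_pdf",
    "mixture_sample",
    "sampler_for_design",
    "run_level_experiment",
    "run_power_comparison",
    "summarize_levels",
    "summarize_power",
]

_M_SUPPORT = np.arange(2, 21)
_M_PROBS = (1.0 / _M_SUPPORT) / np.sum(1.0 / _M_SUPPORT)


@dataclass(frozen=True)
class NormalMixture:
    """A finite normal mixture Σ w_j N(μ_j, σ_j²)."""

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        mu = np.asarray(self.means, dtype=float)
        sd = np.asarray(self.sds, dtype=float)
        if not (w.shape == mu.shape == sd.shape and w.ndim == 1):
            raise ValueError("weights, means and sds must be equal-length vectors")
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("weights must be nonnegative and sum to 1")
        if np.any(sd <= 0):
            raise ValueError("component standard deviations must be positive")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "means", mu)
        object.__setattr__(self, "sds", sd)

    @property
    def n_components(self) -> int:
        return len(self.weights)

    @property
    def mean(self) -> float:
        return float(np.sum(self.weights * self.means))


def draw_random_mixture(rng: np.random.Generator) -> NormalMixture:
    """Draw a random normal mixture from the benchmark prior.

    M ∝ 1/m on {2..20}; weights ~ Dirichlet(1/2,…,1/2); σ_j² ~ IG(1/2, 1/2)
    (shape/scale); μ_j | σ_j ~ N(0, σ_j²).
    """
    m = int(rng.choice(_M_SUPPORT, p=_M_PROBS))
    weights = rng.dirichlet(np.full(m, 0.5))
    # sigma^2 ~ inverse-gamma(1/2, scale 1/2)  <=>  1/sigma^2 ~ Gamma(1/2, scale 2)
    sigma2 = 1.0 / rng.gamma(shape=0.5, scale=2.0, size=m)
    sds = np.sqrt(sigma2)
    means = rng.normal(0.0, sds)
    return NormalMixture(weights, means, sds)


def mixture_pdf(x, mixture: NormalMixture) -> np.ndarray:
    """Density Σ w_j φ((x − μ_j)/σ_j)/σ_j, vectorized over x."""
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    xv = np.atleast_1d(x)
    dens = np.sum(
        mixture.weights[None, :]
        * stats.norm.pdf(xv[:, None], mixture.means[None, :], mixture.sds[None, :]),
        axis=1,
    )
    return float(dens[0]) if scalar else dens


def mixture_sample(k: int, mixture: NormalMixture, rng: np.random.Generator) -> np.ndarray:
    """k i.i.d. draws: pick a component by weight, then draw the normal."""
    idx = rng.choice(mixture.n_components, size=k, p=mixture.weights)
    return rng.normal(mixture.means[idx], mixture.sds[idx])


@dataclass(frozen=True)
class ExperimentConfig:
    """Settings shared by the simulation experiments.

    ``design`` names the sampling scheme for each replicate's pair of samples:
    ``"null"`` (both N(0,1)), ``"scale-alt"`` (N(0,1) vs N(0,2²)) or
    ``"random-mixtures"`` (two independent draws from the mixture prior;
    ``null_mixtures=True`` reuses a single draw for both groups).
    """

    design: str = "null"
    m: int = 50
    n: int = 50
    replicates: int = 500
    n_permutations: int = 3845
    n_first: int = 338
    n_second: int = 3845
    alpha: float = 0.05
    seed: int = 0
    null_mixtures: bool = False
    kernel: KernelSpec = field(default_factory=hall_kernel)


def sampler_for_design(
    cfg: ExperimentConfig,
) -> Callable[[np.random.Generator], tuple[np.ndarray, np.ndarray]]:
    """Per-replicate (X, Y) sampler for the configured design."""
    if cfg.design == "null":
        return lambda rng: (
            rng.standard_normal(cfg.m),
            rng.standard_normal(cfg.n),
        )
    if cfg.design == "scale-alt":
        return lambda rng: (
            rng.standard_normal(cfg.m),
            2.0 * rng.standard_normal(cfg.n),
        )
    if cfg.design == "random-mixtures":

        def draw(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
            fx = draw_random_mixture(rng)
            fy = fx if cfg.null_mixtures else draw_random_mixture(rng)
            return mixture_sample(cfg.m, fx, rng), mixture_sample(cfg.n, fy, rng)

        return draw
    raise ValueError(
        f"unknown design {cfg.design!r}; expected 'null', 'scale-alt' or 'random-mixtures'"
    )


def _child_rngs(seed: int, count: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(count)]


def run_level_experiment(cfg: ExperimentConfig) -> pd.DataFrame:
    """Conditional level of the N1-permutation test, per replicate.

    For each replicate: draw the pair of samples, select the pooled LCV
    bandwidth once, estimate the critical value from ``n_first`` permutations
    and measure the share of ``n_second`` further permuted ALBs exceeding it.
    """
    sampler = sampler_for_design(cfg)
    rows = []
    for rep, rng in enumerate(_child_rngs(cfg.seed, cfg.replicates)):
        x, y = sampler(rng)
        sample = CombinedSample.from_groups(x, y)
        fit = select_bandwidth(sample, cfg.kernel)
        matrix = build_kernel_matrix(sample, fit.bandwidth, cfg.kernel)
        level = conditional_level(
            sample,
            fit.bandwidth,
            cfg.kernel,
            cfg.n_first,
            cfg.n_second,
            alpha=cfg.alpha,
            rng=rng,
            matrix=matrix,
        )
        rows.append(
            {"replicate": rep, "conditional_level": level, "bandwidth": fit.b}
        )
    return pd.DataFrame(rows)


def summarize_levels(
    levels: pd.DataFrame, band: tuple[float, float] = (0.03, 0.07)
) -> dict[str, float]:
    """Mean conditional level and the share falling inside ``band``."""
    v = levels["conditional_level"].to_numpy()
    inside = np.mean((v >= band[0]) & (v <= band[1]))
    return {
        "mean_level": float(v.mean()),
        "share_in_band": float(inside),
        "replicates": int(v.size),
    }


def run_power_comparison(
    cfg: ExperimentConfig, *, methods: tuple[str, ...] = ("alb", "ks")
) -> pd.DataFrame:
    """Per-replicate p-values for ALB and the baseline tests.

    The ALB p-value uses ``cfg.n_permutations`` label permutations with the
    pooled LCV bandwidth; KS is the classical two-sample test; ``"bowman"``
    adds the kernel-L2 permutation test (same permutation budget).
    """
    sampler = sampler_for_design(cfg)
    rows = []
    for rep, rng in enumerate(_child_rngs(cfg.seed, cfg.replicates)):
        x, y = sampler(rng)
        row: dict[str, float] = {"replicate": rep}
        if "alb" in methods:
            sample = CombinedSample.from_groups(x, y)
            fit = select_bandwidth(sample, cfg.kernel)
            perm = permutation_distribution(
                sample,
                fit.bandwidth,
                cfg.kernel,
                cfg.n_permutations,
                alpha=cfg.alpha,
                rng=rng,
            )
            row["alb"] = perm.observed
            row["p_alb"] = perm.p_value
            row["bandwidth"] = fit.b
        if "ks" in methods:
            row["p_ks"] = ks_two_sample(x, y).p_value
        if "bowman" in methods:
            row["p_bowman"] = bowman_l2_test(
                x, y, cfg.n_permutations, rng=rng
            ).p_value
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_power(table: pd.DataFrame, alpha: float = 0.05) -> dict[str, float]:
    """Rejection counts per method and pairwise p-value comparisons."""
    out: dict[str, float] = {"replicates": int(len(table))}
    for col in table.columns:
        if col.startswith("p_"):
            out[f"reject_{col[2:]}"] = int((table[col] < alpha).sum())
    if {"p_alb", "p_ks"} <= set(table.columns):
        out["share_ks_above_alb"] = float((table["p_ks"] > table["p_alb"]).mean())
    if {"p_alb", "p_bowman"} <= set(table.columns):
        out["share_bowman_geq_alb"] = float(
            (table["p_bowman"] >= table["p_alb"]).mean()
        )
    return out
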