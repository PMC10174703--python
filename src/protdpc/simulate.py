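"""Synthetic two-group proteomics datasets with intensity-dependent missingness.

The generative model: each feature (protein) draws a mean log2 intensity
uniformly on ``mean_range``; replicate values are normal around the group
mean with standard deviation ``replicate_sd``; a random subset of
``n_de`` features is differentially expressed with log2 fold change
``log2_fc`` split evenly up/down between the two groups (and split
symmetrically about the feature mean, +/- half the fold change per group).
Each entry is then detected independently with probability
``logistic(dpc_beta0 + dpc_beta1 * y)`` of its own log2 value — the
logit-linear detection probability curve — and undetected entries are
masked as missing.

All randomness flows from one seed through a single generator consumed in
a fixed order (feature means -> DE selection -> replicate noise ->
detection), so a dataset is fully reproducible from its config.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

from .matrix import IntensityMatrix


__all__ = ["SimConfig", "SimDataset", "simulate_complete", "inject_missingness",
           "simulate_dataset"]


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters; defaults reproduce the reference design of
    10 000 proteins in two groups of 6, means uniform on [5, 12], replicate
    SD 0.3, 1000 two-fold DE proteins and a DPC with slope 0.8 and
    intercept -6."""

    n_features: int = 10_000
    n_samples_per_group: int = 6
    mean_range: tuple[float, float] = (5.0, 12.0)
    replicate_sd: float = 0.3
    n_de: int = 1000
    log2_fc: float = 1.0
    dpc_beta0: float = -6.0
    dpc_beta1: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if self.n_samples_per_group < 1:
            raise ValueError("n_samples_per_group must be >= 1")
        if self.n_de < 0 or self.n_de > self.n_features:
            raise ValueError("n_de must satisfy 0 <= n_de <= n_features")
        if self.replicate_sd < 0:
            raise ValueError("replicate_sd must be non-negative")
        if not self.mean_range[0] < self.mean_range[1]:
            raise ValueError("mean_range must be an increasing pair")
        if self.dpc_beta1 < 0:
            raise ValueError("dpc_beta1 must be non-negative")


@dataclass
class SimDataset:
    """A simulated dataset: the complete matrix, the observed (post-missingness)
    matrix, per-feature DE labels (+1 up in group 2, -1 down, 0 null), the
    per-sample group labels (1/2) and the config that generated it."""

    complete: IntensityMatrix
    observed: IntensityMatrix | None
    de_labels: np.ndarray
    group_labels: np.ndarray
    true_means: np.ndarray
    truth: SimConfig

    @property
    def groups(self) -> np.ndarray:
        return self.group_labels


def _generate_complete(config: SimConfig, rng: np.random.Generator):
    m, k = config.n_features, config.n_samples_per_group
    n = 2 * k
    means = rng.uniform(*config.mean_range, size=m)
    de_labels = np.zeros(m, dtype=int)
    if config.n_de:
        de_idx = rng.choice(m, size=config.n_de, replace=False)
        n_up = config.n_de // 2
        de_labels[de_idx[:n_up]] = 1       # up in group 2
        de_labels[de_idx[n_up:]] = -1
    group_labels = np.repeat([1, 2], k)
    # symmetric split: group means are feature mean -/+ half the fold change
    half = 0.5 * config.log2_fc * de_labels
    mu = means[:, None] + np.where(group_labels[None, :] == 2, half[:, None],
                                   -half[:, None])
    values = mu + rng.normal(0.0, config.replicate_sd, size=(m, n))
    mat = IntensityMatrix(values, np.ones((m, n), dtype=np.int8),
                          sample_ids=[f"g{g}_s{j % k + 1}" for j, g in
                                      enumerate(group_labels)])
    return mat, de_labels, group_labels, means


def simulate_complete(config: SimConfig) -> SimDataset:
    """Generate the complete (no-missingness) dataset for a config."""
    rng = np.random.default_rng(config.seed)
    mat, de, groups, means = _generate_complete(config, rng)
    return SimDataset(complete=mat, observed=None, de_labels=de,
                      group_labels=groups, true_means=means, truth=config)


def inject_missingness(data: IntensityMatrix, beta0: float, beta1: float,
                       seed: int | np.random.Generator = 0) -> IntensityMatrix:
    """Apply logit-linear DPC missingness to a complete matrix.

    Each entry is detected independently with probability
    ``logistic(beta0 + beta1 * y)``; undetected entries keep their value
    array slot but are masked (and set NaN).  Bit-identical masks for a
    given seed.
    """
    if np.any(data.mask == 0):
        raise ValueError("input matrix must be complete (no missing entries)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p_detect = expit(beta0 + beta1 * data.values)
    mask = (rng.random(data.values.shape) < p_detect).astype(np.int8)
    values = np.where(mask == 1, data.values, np.nan)
    return IntensityMatrix(values, mask, list(data.feature_ids), list(data.sample_ids))


def simulate_dataset(config: SimConfig) -> SimDataset:
    """Full simulation: complete data plus DPC missingness, one RNG stream."""
    rng = np.random.default_rng(config.seed)
    mat, de, groups, means = _generate_complete(config, rng)
    observed = inject_missingness(mat, config.dpc_beta0, config.dpc_beta1, rng)
    return SimDataset(complete=mat, observed=observed, de_labels=de,
                      group_labels=groups, true_means=means, truth=config)
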