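"""Synthetic-data generators with recorded ground truth.

Every downstream stage gets a download-free test surface: lag/exponential/
stationary(/death) cell-density curves with multiplicative log-normal
counting noise at sparse (12–24 h) sampling; genome × sample count tables
with a known log-normal abundance structure, genome lengths, library sizes
and an optional group effect observed through a Poisson (optionally
gamma-overdispersed) counting layer; and random coalescent-style genome
trees.  All generators are deterministic under a recorded seed and return
their truth alongside the data, so parameter-recovery tests close the loop.

Defaults mirror the culturing study conditions the package analyzes:
inocula near 10⁴ cells·ml⁻¹ growing to maxima near 2×10⁶ cells·ml⁻¹,
triplicate cultures counted every 12 h over ~3 days, and ~10% proportional
flow-cytometry counting error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .growth import GrowthCurve
from .recruit import AbundanceMatrix

__all__ = [
    "GrowthSimSpec",
    "CommunitySimSpec",
    "simulate_growth",
    "simulate_counts",
    "simulate_tree",
]


@dataclass
class GrowthSimSpec:
    """Ground truth for simulated cell-density curves."""

    true_rate: float = 0.2          # doublings/h during exponential phase
    lag: float = 0.0                # h of flat density before growth
    initial_density: float = 1e4    # cells/ml
    carrying_capacity: float = 2e6  # cells/ml
    death_rate: float = 0.0         # doublings/h, <= 0; decay after capacity
    sampling_interval: float = 12.0  # h
    horizon: float = 72.0           # h
    noise_cv: float = 0.10          # multiplicative log-normal CV
    n_replicates: int = 3
    seed: int | None = None

    def __post_init__(self):
        if self.carrying_capacity <= self.initial_density:
            raise ValueError("carrying capacity must exceed initial density")
        if self.initial_density <= 0:
            raise ValueError("initial density must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise CV must be nonnegative")
        if self.death_rate > 0:
            raise ValueError("death_rate must be <= 0")
        if self.sampling_interval <= 0 or self.horizon <= 0:
            raise ValueError("sampling interval and horizon must be positive")
        if self.true_rate <= 0:
            raise ValueError("true_rate must be positive")


def _expected_density(spec: GrowthSimSpec, t: np.ndarray) -> np.ndarray:
    """Noise-free piecewise density: lag, exponential, cap, optional decay."""
    n0, k = spec.initial_density, spec.carrying_capacity
    t_cap = spec.lag + np.log2(k / n0) / spec.true_rate
    dens = np.where(
        t < spec.lag,
        n0,
        n0 * 2.0 ** (spec.true_rate * np.clip(t - spec.lag, 0.0, None)),
    )
    dens = np.minimum(dens, k)
    if spec.death_rate < 0:
        decay = k * 2.0 ** (spec.death_rate * (t - t_cap))
        dens = np.where(t > t_cap, np.minimum(dens, decay), dens)
    return dens


def simulate_growth(spec: GrowthSimSpec):
    """Simulate replicate growth curves; returns (curves, truth dict).

    Noise is multiplicative log-normal with the given CV, mean-preserving
    (σ² = ln(1 + CV²), log-mean −σ²/2).
    """
    rng = np.random.default_rng(spec.seed)
    times = np.arange(0.0, spec.horizon + 1e-9, spec.sampling_interval)
    expected = _expected_density(spec, times)
    sigma = np.sqrt(np.log1p(spec.noise_cv**2))
    curves = []
    for r in range(spec.n_replicates):
        if sigma > 0:
            noise = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=len(times)))
        else:
            noise = np.ones(len(times))
        curves.append(
            GrowthCurve(
                replicate_id=f"rep{r + 1}",
                times=times.copy(),
                densities=expected * noise,
            )
        )
    truth = {
        "true_rate": spec.true_rate,
        "lag": spec.lag,
        "carrying_capacity": spec.carrying_capacity,
        "death_rate": spec.death_rate,
        "expected_densities": expected,
        "times": times,
    }
    return curves, truth


@dataclass
class CommunitySimSpec:
    """Ground truth for simulated genome × sample recruitment counts.

    Base genome abundances are log-normal (log₁₀ scale); samples are split
    into two groups and ``effect_size`` (log₁₀ units) is added to the
    designated fraction of genomes in the second group.  Genome lengths are
    uniform on [1.5, 3.0] Mbp, library sizes log-uniform on [10⁵, 10⁷], and
    counts are Poisson around expected reads ∝ abundance × length ×
    (mapped fraction × library size), with an optional gamma overdispersion
    knob.
    """

    n_genomes: int = 20
    n_samples: int = 30
    effect_size: float = 0.0        # log10 shift on affected genomes, group B
    affected_fraction: float = 0.5
    abundance_sigma: float = 0.5    # SD of base log10 abundance
    length_range_mbp: tuple = (1.5, 3.0)
    libsize_range: tuple = (1e5, 1e7)
    mapped_fraction: float = 0.05   # fraction of the library these genomes recruit
    overdispersion: float = 0.0     # 0 = pure Poisson
    seed: int | None = None

    def __post_init__(self):
        if self.n_genomes < 2 or self.n_samples < 4:
            raise ValueError("need >= 2 genomes and >= 4 samples")
        if not 0 <= self.affected_fraction <= 1:
            raise ValueError("affected_fraction must be in [0, 1]")
        if self.overdispersion < 0:
            raise ValueError("overdispersion must be nonnegative")


def simulate_counts(spec: CommunitySimSpec):
    """Simulate a count table; returns (AbundanceMatrix, grouping, truth)."""
    rng = np.random.default_rng(spec.seed)
    genomes = [f"G{i:03d}" for i in range(spec.n_genomes)]
    samples = [f"S{j:03d}" for j in range(spec.n_samples)]

    lengths = rng.uniform(*spec.length_range_mbp, size=spec.n_genomes) * 1e6
    lo, hi = np.log10(spec.libsize_range[0]), np.log10(spec.libsize_range[1])
    libsizes = np.round(10 ** rng.uniform(lo, hi, size=spec.n_samples))

    half = spec.n_samples // 2
    group = np.array(["A"] * half + ["B"] * (spec.n_samples - half))
    n_affected = int(round(spec.affected_fraction * spec.n_genomes))
    affected = np.zeros(spec.n_genomes, dtype=bool)
    affected[rng.choice(spec.n_genomes, size=n_affected, replace=False)] = True

    base_log10 = rng.normal(0.0, spec.abundance_sigma, size=spec.n_genomes)
    log10_ab = np.tile(base_log10[:, None], (1, spec.n_samples))
    log10_ab[np.ix_(affected, group == "B")] += spec.effect_size
    abundance = 10.0**log10_ab

    weight = abundance * lengths[:, None]
    share = weight / weight.sum(axis=0, keepdims=True)
    lam = share * (spec.mapped_fraction * libsizes)[None, :]
    if spec.overdispersion > 0:
        shape = 1.0 / spec.overdispersion
        lam = lam * rng.gamma(shape, 1.0 / shape, size=lam.shape)
    counts = rng.poisson(lam)

    matrix = AbundanceMatrix(
        counts=pd.DataFrame(counts, index=genomes, columns=samples),
        genome_lengths=pd.Series(lengths, index=genomes),
        library_sizes=pd.Series(libsizes, index=samples),
    )
    grouping = pd.Series(group, index=samples, name="group")
    truth = {
        "abundance": pd.DataFrame(abundance, index=genomes, columns=samples),
        "affected_genomes": [g for g, a in zip(genomes, affected) if a],
        "effect_size": spec.effect_size,
        "expected_counts": pd.DataFrame(lam, index=genomes, columns=samples),
    }
    return matrix, grouping, truth


def simulate_tree(n_tips: int, seed: int | None = None, labels=None) -> TreeNode:
    """Random coalescent-style genome tree with exponential waiting times.

    Tips default to the ``G000``-style labels that :func:`simulate_counts`
    uses, so simulated count tables drop straight onto simulated trees.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    if labels is None:
        labels = [f"G{i:03d}" for i in range(n_tips)]
    elif len(labels) != n_tips:
        raise ValueError("labels length must equal n_tips")

    nodes = [TreeNode(name=name) for name in labels]
    heights = [0.0] * n_tips
    t = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        t += rng.exponential(1.0 / (k * (k - 1) / 2.0))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        right, h_right = nodes.pop(j), heights.pop(j)
        left, h_left = nodes.pop(i), heights.pop(i)
        left.length = t - h_left
        right.length = t - h_right
        parent = TreeNode(children=[left, right])
        nodes.append(parent)
        heights.append(t)
    root = nodes[0]
    root.length = None
    return root
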