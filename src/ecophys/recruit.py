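"""Recruitment-derived abundance and community statistics.

Genome × sample read-count tables (reads already mapped and filtered
upstream) are normalized to RPKM (reads per kilobase of genome per million
library reads) or TPM (length-normalized rates rescaled to sum to 10⁶ per
sample), optionally log₁₀-transformed.  Community structure across samples
is compared with weighted UniFrac distances over a genome phylogeny,
ordinated by classical PCoA, and tested against sample groupings with the
rank-based ANOSIM permutation statistic.  Per-genome abundance–environment
relationships use ordinary least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import permutations as _all_permutations
from math import factorial

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity
from skbio.stats.ordination import pcoa as _skbio_pcoa
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AbundanceMatrix",
    "AnosimResult",
    "RegressionResult",
    "rpkm",
    "tpm",
    "log_transform",
    "weighted_unifrac",
    "pcoa",
    "anosim",
    "abundance_regression",
    "regress_all",
]

_EXACT_MAX_N = 9  # n! label permutations; 9! = 362,880 is the practical cap


@dataclass
class AbundanceMatrix:
    """Genome × sample read counts with the lengths and depths to normalize them.

    ``counts`` is a genomes × samples DataFrame of filtered mapped-read
    counts, ``genome_lengths`` bp per genome, ``library_sizes`` total reads
    per sample, and ``sample_metadata`` an optional per-sample table
    (latitude, depth, temperature, salinity, region, ...).
    """

    counts: pd.DataFrame
    genome_lengths: pd.Series
    library_sizes: pd.Series
    sample_metadata: pd.DataFrame | None = None

    def __post_init__(self):
        self.counts = self.counts.astype(float)
        self.genome_lengths = self.genome_lengths.astype(float).reindex(
            self.counts.index
        )
        self.library_sizes = self.library_sizes.astype(float).reindex(
            self.counts.columns
        )
        if self.genome_lengths.isna().any():
            missing = list(self.genome_lengths.index[self.genome_lengths.isna()])
            raise ValueError(f"missing genome lengths for {missing}")
        if self.library_sizes.isna().any():
            missing = list(self.library_sizes.index[self.library_sizes.isna()])
            raise ValueError(f"missing library sizes for {missing}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        if (self.genome_lengths <= 0).any():
            raise ValueError("genome lengths must be positive")
        if np.any(self.library_sizes.to_numpy() < self.counts.sum(axis=0).to_numpy()):
            raise ValueError("library sizes must be >= column sums of counts")

    @property
    def genomes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns


def rpkm(matrix: AbundanceMatrix) -> pd.DataFrame:
    """Reads per kilobase of genome per million library reads.

    RPKM[g, s] = counts[g, s] / (length_kb[g] × libsize_millions[s]).
    """
    if (matrix.library_sizes == 0).any():
        bad = list(matrix.library_sizes.index[matrix.library_sizes == 0])
        raise ValueError(f"zero library size for samples {bad}")
    length_kb = matrix.genome_lengths / 1e3
    lib_m = matrix.library_sizes / 1e6
    return matrix.counts.div(length_kb, axis=0).div(lib_m, axis=1)


def tpm(matrix: AbundanceMatrix) -> pd.DataFrame:
    """Transcripts-per-million-style normalization of recruitment counts.

    Per sample, length-normalized rates counts/length_kb are rescaled to sum
    to 10⁶; all-zero samples stay all-zero.
    """
    length_kb = matrix.genome_lengths / 1e3
    rate = matrix.counts.div(length_kb, axis=0)
    colsum = rate.sum(axis=0)
    out = rate.div(colsum.where(colsum > 0, 1.0), axis=1) * 1e6
    return out


def log_transform(table: pd.DataFrame, pseudocount: float | None = None) -> pd.DataFrame:
    """log₁₀(x + pseudocount), monotone in x.

    The default pseudocount is half the smallest nonzero entry of the table.
    """
    arr = table.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("table entries must be nonnegative")
    if pseudocount is None:
        nonzero = arr[arr > 0]
        if nonzero.size == 0:
            raise ValueError(
                "all-zero table: supply an explicit pseudocount"
            )
        pseudocount = float(nonzero.min()) / 2.0
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    return np.log10(table + pseudocount)


def _as_rooted_tree(tree) -> TreeNode:
    if isinstance(tree, str):
        tree = TreeNode.read([tree])
    if len(tree.children) > 2:  # unrooted input: midpoint-root by default
        tree = tree.root_at_midpoint()
    return tree


def weighted_unifrac(
    tree,
    abundances: pd.DataFrame,
    normalized: bool = True,
) -> DistanceMatrix:
    """Weighted UniFrac distances between samples over a genome phylogeny.

    ``abundances`` is a genomes × samples table (counts or any abundance
    units; tip proportions are formed per sample).  Each branch contributes
    its length times the absolute difference in descendant proportional
    abundance; the normalized variant divides by Σ l_b (P_A(b) + P_B(b)) and
    lies in [0, 1].  Unrooted input trees are midpoint-rooted.  A genome with
    nonzero abundance that is not a tip of the tree is an error naming it.
    """
    tree = _as_rooted_tree(tree)
    tips = {t.name for t in tree.tips()}
    present = abundances.index[(abundances != 0).any(axis=1)]
    missing = [g for g in present if g not in tips]
    if missing:
        raise ValueError(f"genomes absent from the tree: {missing}")
    in_tree = [g for g in abundances.index if g in tips]
    table = abundances.loc[in_tree]
    return beta_diversity(
        "weighted_unifrac",
        table.T.to_numpy(),
        ids=list(table.columns),
        taxa=list(table.index),
        tree=tree,
        normalized=normalized,
        validate=True,
    )


def pcoa(distances: DistanceMatrix, n_axes: int = 3):
    """Classical principal-coordinate analysis (metric MDS).

    Double-centers −½D², eigendecomposes, and returns the top coordinates
    ordered by eigenvalue together with the full eigenvalue series.  Axes
    with non-positive eigenvalues are reported in the eigenvalues but never
    returned as coordinates; asking for more axes than available truncates
    with a warning.
    """
    if not isinstance(distances, DistanceMatrix):
        distances = DistanceMatrix(distances)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # skbio warns about negative eigenvalues
        res = _skbio_pcoa(distances, method="eigh")
    eigvals = res.eigvals
    positive = eigvals[eigvals > max(1e-12 * abs(eigvals.iloc[0]), 0.0)]
    available = len(positive)
    if n_axes > available:
        warnings.warn(
            f"requested {n_axes} axes but only {available} have positive "
            "eigenvalues; truncating",
            stacklevel=2,
        )
        n_axes = available
    coords = res.samples.iloc[:, :n_axes]
    coords.index = pd.Index(distances.ids, name="sample")
    return coords, eigvals


@dataclass(frozen=True)
class AnosimResult:
    """ANOSIM statistic and permutation p-value."""

    R: float
    p_value: float
    n_permutations: int
    method: str = "monte-carlo"  # or "exact"
    seed: int | None = None


def _anosim_r(ranks: np.ndarray, within: np.ndarray, denom: float) -> float:
    mean_within = ranks[within].mean()
    mean_between = ranks[~within].mean()
    return (mean_between - mean_within) / denom


def anosim(
    distances: DistanceMatrix,
    grouping,
    n_permutations: int = 999,
    seed: int | None = None,
    exact: bool = False,
) -> AnosimResult:
    """Analysis of similarities over a distance matrix.

    R = (mean between-group rank − mean within-group rank) / (n(n−1)/4) on
    the ranked pairwise distances; R ∈ [−1, 1], with 0 meaning no separation
    between groups and 1 complete separation.  The p-value is
    (1 + #{permuted R ≥ observed}) / (1 + n_permutations) for the seeded
    Monte-Carlo test, or the exact fraction over all n! label permutations
    (identity included) when ``exact=True`` (n ≤ 9).

    ``grouping`` maps each sample to one group label (mapping, Series, or a
    sequence aligned with the distance-matrix ids); ANOSIM needs ≥ 2 groups,
    each with ≥ 2 samples.
    """
    if not isinstance(distances, DistanceMatrix):
        distances = DistanceMatrix(distances)
    ids = list(distances.ids)
    n = len(ids)
    if isinstance(grouping, (dict, pd.Series)):
        labels = np.asarray([grouping[i] for i in ids])
    else:
        labels = np.asarray(list(grouping))
        if len(labels) != n:
            raise ValueError("grouping length does not match distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("ANOSIM needs at least 2 groups")
    if (counts < 2).any():
        small = list(uniq[counts < 2])
        raise ValueError(f"groups with fewer than 2 samples: {small}")

    iu, ju = np.triu_indices(n, k=1)
    ranks = stats.rankdata(distances.data[iu, ju])
    denom = n * (n - 1) / 4.0
    codes = pd.factorize(labels)[0]
    observed = _anosim_r(ranks, codes[iu] == codes[ju], denom)

    if exact:
        if n > _EXACT_MAX_N:
            raise ValueError(
                f"exact enumeration limited to n <= {_EXACT_MAX_N} samples"
            )
        total = factorial(n)
        hits = 0
        for perm in _all_permutations(range(n)):
            p = np.asarray(perm)
            c = codes[p]
            if _anosim_r(ranks, c[iu] == c[ju], denom) >= observed - 1e-12:
                hits += 1
        return AnosimResult(
            R=float(observed),
            p_value=hits / total,
            n_permutations=total,
            method="exact",
            seed=None,
        )

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        c = codes[rng.permutation(n)]
        if _anosim_r(ranks, c[iu] == c[ju], denom) >= observed - 1e-12:
            hits += 1
    return AnosimResult(
        R=float(observed),
        p_value=(1 + hits) / (1 + n_permutations),
        n_permutations=n_permutations,
        method="monte-carlo",
        seed=seed,
    )


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of abundance on an environmental covariate."""

    slope: float
    intercept: float
    p_value: float     # two-sided t-test on the slope
    r_squared: float
    n: int


def abundance_regression(values, covariate) -> RegressionResult:
    """Ordinary least squares of per-sample abundance on a covariate."""
    y = np.asarray(values, dtype=float)
    x = np.asarray(covariate, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("values and covariate must be 1-D and equal length")
    if len(y) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("covariate has zero variance")
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        p_value=float(res.pvalue),
        r_squared=float(res.rvalue**2),
        n=len(y),
    )


def regress_all(
    table: pd.DataFrame,
    covariate,
    adjust: bool = False,
) -> pd.DataFrame:
    """Per-genome OLS of abundance (table rows) on a covariate.

    Raw p-values are reported by default, matching common practice for
    per-genome recruitment regressions; ``adjust=True`` adds
    Benjamini–Hochberg q-values.
    """
    rows = []
    for genome, values in table.iterrows():
        r = abundance_regression(values.to_numpy(), covariate)
        rows.append(
            {
                "genome": genome,
                "slope": r.slope,
                "intercept": r.intercept,
                "p_value": r.p_value,
                "r_squared": r.r_squared,
                "n": r.n,
            }
        )
    out = pd.DataFrame(rows).set_index("genome")
    if adjust:
        out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out
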