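"""Independent brute-force oracles used by the test suite.

These deliberately re-derive quantities from first principles (explicit
branch sums, explicit rank averaging, exhaustive enumeration) without going
through the package's implementation paths.
"""

from itertools import permutations

import numpy as np


def unifrac_brute_force(tree, prop_a: dict, prop_b: dict):
    """Raw and normalized weighted UniFrac by explicit branch-by-branch sums.

    ``tree`` is a rooted skbio TreeNode; ``prop_a``/``prop_b`` map tip name →
    proportional abundance (missing tips are zero).
    """
    raw = 0.0
    denom = 0.0
    for node in tree.traverse(include_self=False):
        length = node.length or 0.0
        tips = [t.name for t in node.tips()] or [node.name]
        pa = sum(prop_a.get(t, 0.0) for t in tips)
        pb = sum(prop_b.get(t, 0.0) for t in tips)
        raw += length * abs(pa - pb)
        denom += length * (pa + pb)
    return raw, (raw / denom if denom > 0 else 0.0)


def _average_ranks(values):
    """Average ranks (1-based, ties averaged) without scipy."""
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values))
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def anosim_r_brute_force(dist: np.ndarray, labels) -> float:
    """ANOSIM R from its definition, with independent rank averaging."""
    labels = list(labels)
    n = len(labels)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    ranks = _average_ranks([dist[i, j] for i, j in pairs])
    within = [k for k, (i, j) in enumerate(pairs) if labels[i] == labels[j]]
    between = [k for k in range(len(pairs)) if k not in within]
    mean_w = float(np.mean(ranks[within]))
    mean_b = float(np.mean(ranks[between]))
    return (mean_b - mean_w) / (n * (n - 1) / 4.0)


def anosim_exact_p_brute_force(dist: np.ndarray, labels) -> tuple:
    """Exact permutation p by exhaustive enumeration of all n! relabelings."""
    labels = list(labels)
    n = len(labels)
    observed = anosim_r_brute_force(dist, labels)
    hits = 0
    total = 0
    for perm in permutations(range(n)):
        total += 1
        if anosim_r_brute_force(dist, [labels[k] for k in perm]) >= observed - 1e-12:
            hits += 1
    return observed, hits / total
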