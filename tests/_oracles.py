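"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's vectorized code paths: pairwise
correlations via scipy.stats.pearsonr loops, k-cores via exhaustive
repeated scanning, NACC via explicit pair enumeration.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats


def kcore_nodes(edges: list[tuple[str, str]], k: int) -> set[str]:
    """Nodes of the k-core by repeated full scans over an edge list."""
    nodes = {n for e in edges for n in e}
    edges = set(map(frozenset, edges))
    changed = True
    while changed:
        changed = False
        degree = {n: 0 for n in nodes}
        for e in edges:
            for n in e:
                degree[n] += 1
        low = {n for n in nodes if degree[n] < k}
        if low:
            nodes -= low
            edges = {e for e in edges if not (e & low)}
            changed = True
    return nodes


def pair_fraction_above(genes, weight_of, cutoff: float) -> float:
    """NACC by explicit enumeration; ``weight_of(a, b)`` may return NaN."""
    genes = sorted(genes)
    n_pairs = 0
    n_above = 0
    for a, b in itertools.combinations(genes, 2):
        n_pairs += 1
        w = weight_of(a, b)
        if np.isfinite(w) and w > cutoff:
            n_above += 1
    return n_above / n_pairs


def pearson_loop(x: np.ndarray) -> np.ndarray:
    """Full pairwise Pearson matrix via scipy.stats.pearsonr, pair by pair."""
    m = x.shape[0]
    out = np.eye(m)
    for i, j in itertools.combinations(range(m), 2):
        r, _ = stats.pearsonr(x[i], x[j])
        out[i, j] = out[j, i] = r
    return out


def loo_min_loop(pools: list[np.ndarray]) -> np.ndarray:
    """Elementwise minimum of per-pool pairwise correlations.

    ``pools`` holds one genes x samples array per leave-one-out run.
    """
    mats = [pearson_loop(p) for p in pools]
    return np.minimum.reduce(mats)


def max_corr_loop(x: np.ndarray) -> float:
    """Maximum absolute off-diagonal pairwise correlation via pearsonr loop."""
    best = 0.0
    for i, j in itertools.combinations(range(x.shape[0]), 2):
        r, _ = stats.pearsonr(x[i], x[j])
        best = max(best, abs(r))
    return best
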