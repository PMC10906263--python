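"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (enumeration, resampling,
from-scratch recomputation) and shares no code with the implementation
paths it checks.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np


# ---------------------------------------------------------------------------
# subsampling expectations


def exhaustive_subsample_expectations(counts, m):
    """Exact E[distinct taxa] and E[coverage] of a size-m subsample, m < n.

    Enumerates every one of the C(n, m) equally likely subsets of the n
    occurrence tokens.  Coverage of a subset is the probability that the
    next without-replacement draw belongs to a taxon already in the subset,
    i.e. the share of the remaining n-m tokens whose taxon is seen.
    """
    tokens = []
    for sp, c in enumerate(counts):
        tokens.extend([sp] * int(c))
    n = len(tokens)
    counts = np.asarray(counts, dtype=float)
    total_rich = 0.0
    total_cov = 0.0
    count = 0
    for subset in combinations(range(n), m):
        seen = {tokens[i] for i in subset}
        total_rich += len(seen)
        total_cov += (sum(counts[sp] for sp in seen) - m) / (n - m)
        count += 1
    return total_rich / count, total_cov / count


def mc_subsample_curves(counts, draws, rng):
    """Monte-Carlo E[distinct] and E[coverage] curves for m = 1..n-1.

    Each draw is a uniform random permutation of the occurrence tokens;
    prefix m of a permutation is a uniform without-replacement subsample.
    Coverage after m tokens is the share of the remaining n-m tokens whose
    taxon has been seen (probability the next draw is an already-seen
    taxon); it is undefined at m = n, so curves stop at n-1.
    """
    counts = np.asarray(counts, dtype=int)
    n = int(counts.sum())
    tokens = np.repeat(np.arange(len(counts)), counts)
    perms = np.argsort(rng.random((draws, n)), axis=1)
    sp = tokens[perms]
    order = np.argsort(sp, axis=1, kind="stable")
    sp_sorted = np.take_along_axis(sp, order, axis=1)
    new_sorted = np.ones_like(sp_sorted, dtype=bool)
    new_sorted[:, 1:] = sp_sorted[:, 1:] != sp_sorted[:, :-1]
    new = np.empty_like(new_sorted)
    np.put_along_axis(new, order, new_sorted, axis=1)
    richness = np.cumsum(new, axis=1).mean(axis=0)[: n - 1]
    m = np.arange(1, n)
    seen_tokens = np.cumsum(new * counts[sp], axis=1).mean(axis=0)[: n - 1]
    coverage = (seen_tokens - m) / (n - m)
    return richness, coverage


def mc_richness_at_coverage(counts, quorum, draws, rng):
    """Richness at the subsample size where the MC coverage curve hits quorum.

    Returns None when the curve never reaches the quorum (the
    without-replacement oracle cannot extrapolate past n).
    """
    richness, coverage = mc_subsample_curves(counts, draws, rng)
    if coverage[0] >= quorum:
        return float(richness[0])
    above = np.nonzero(coverage >= quorum)[0]
    if len(above) == 0:
        return None
    hi = int(above[0])
    lo = hi - 1
    t = (quorum - coverage[lo]) / (coverage[hi] - coverage[lo])
    return float(richness[lo] + t * (richness[hi] - richness[lo]))


# ---------------------------------------------------------------------------
# clustering


def brute_average_linkage_heights(dist):
    """Merge heights of UPGMA agglomeration, recomputed from scratch.

    Cluster-to-cluster distances are recalculated each step as the plain
    mean over all cross pairs of the base matrix (no Lance-Williams
    updates).  Returns the sorted list of merge heights.
    """
    dist = np.asarray(dist, dtype=float)
    clusters = [[i] for i in range(dist.shape[0])]
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in combinations(range(len(clusters)), 2):
            d = float(
                np.mean([dist[i, j] for i in clusters[a] for j in clusters[b]])
            )
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        heights.append(d)
        merged = clusters[a] + clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
        clusters.append(merged)
    return sorted(heights)


# ---------------------------------------------------------------------------
# spanning trees


def _decode_pruefer(seq, n):
    degree = [1] * n
    for v in seq:
        degree[v] += 1
    edges = []
    seq = list(seq)
    for v in seq:
        for leaf in range(n):
            if degree[leaf] == 1:
                edges.append((leaf, v))
                degree[leaf] -= 1
                degree[v] -= 1
                break
    u, w = [i for i in range(n) if degree[i] == 1]
    edges.append((u, w))
    return edges

def brute_force_mst_total(dist):
    """Minimum total weight over all labelled spanning trees (Cayley).

    Enumerates all n^(n-2) Pruefer sequences; practical for n <= 7.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if n < 2:
        return 0.0
    if n == 2:
        return float(dist[0, 1])
    best = np.inf
    for seq in product(range(n), repeat=n - 2):
        total = sum(dist[a, b] for a, b in _decode_pruefer(seq, n))
        if total < best:
            best = total
    return float(best)
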