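"""Independent brute-force oracles used to cross-check the implementations.

Everything here is written from the textbook definitions with plain loops,
deliberately sharing no code with the package.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_local_moran(values, neighbor_lists, center=None):
    """Local Moran's I from the definition, looped per vertex."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    mean = values.mean() if center is None else center
    z = values - mean
    m2 = sum(zi**2 for zi in z) / n
    out = []
    for i in range(n):
        nb = neighbor_lists[i]
        lag = sum(z[j] for j in nb) / len(nb)
        out.append(z[i] / m2 * lag)
    return np.array(out)


def brute_global_moran(values, neighbor_lists, center=None):
    """Textbook global Moran's I with row-standardized weights:
    (n / S0) * sum_ij w_ij z_i z_j / sum_i z_i^2."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    mean = values.mean() if center is None else center
    z = values - mean
    s0 = 0.0
    num = 0.0
    for i in range(n):
        w = 1.0 / len(neighbor_lists[i])
        for j in neighbor_lists[i]:
            num += w * z[i] * z[j]
            s0 += w
    return (n / s0) * num / (z @ z)


def brute_variogram(values, coords, bin_width, zscore=True):
    """Matheron semivariance per distance bin, looped over all pairs.
    Returns (centers, gamma, counts) for nonempty bins."""
    values = np.asarray(values, dtype=float)
    if zscore:
        values = (values - values.mean()) / values.std()
    n = len(values)
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for i in range(n):
        for j in range(i + 1, n):
            d = math.dist(coords[i], coords[j])
            b = int(d // bin_width)
            sums[b] = sums.get(b, 0.0) + (values[i] - values[j]) ** 2
            counts[b] = counts.get(b, 0) + 1
    bs = sorted(counts)
    centers = np.array([(b + 0.5) * bin_width for b in bs])
    gamma = np.array([sums[b] / (2.0 * counts[b]) for b in bs])
    return centers, gamma, np.array([counts[b] for b in bs])


def brute_kendall_tau_b(x, y):
    """Tau-b by explicit pair counting."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nc = nd = tx = ty = 0
    for i, j in itertools.combinations(range(len(x)), 2):
        dx, dy = x[i] - x[j], y[i] - y[j]
        if dx == 0 and dy == 0:
            tx += 1
            ty += 1
        elif dx == 0:
            tx += 1
        elif dy == 0:
            ty += 1
        elif dx * dy > 0:
            nc += 1
        else:
            nd += 1
    n0 = len(x) * (len(x) - 1) // 2
    denom = math.sqrt((n0 - tx) * (n0 - ty))
    return (nc - nd) / denom


def brute_ols(x, y):
    """Simple-regression slope/intercept/t from the closed forms."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    xc, yc = x - x.mean(), y - y.mean()
    slope = (xc @ yc) / (xc @ xc)
    intercept = y.mean() - slope * x.mean()
    resid = y - intercept - slope * x
    s2 = (resid @ resid) / (n - 2)
    se = math.sqrt(s2 / (xc @ xc))
    return slope, intercept, slope / se if se > 0 else math.inf


def brute_complete_linkage(dist):
    """Exhaustive complete-linkage agglomeration.

    Returns the merge history as a list of (frozenset_a, frozenset_b, height)
    in merge order.
    """
    dist = np.asarray(dist, dtype=float)
    clusters = [frozenset([i]) for i in range(len(dist))]
    history = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(clusters, 2):
            h = max(dist[i, j] for i in a for j in b)
            if best is None or h < best[2]:
                best = (a, b, h)
        a, b, h = best
        history.append(best)
        clusters = [c for c in clusters if c not in (a, b)] + [a | b]
    return history


def brute_partition_at(history, n_items, n_clusters):
    """Flat partition (set of frozensets) after cutting the brute-force
    merge history at n_clusters clusters."""
    clusters = {frozenset([i]) for i in range(n_items)}
    for a, b, _ in history:
        if len(clusters) <= n_clusters:
            break
        clusters.discard(a)
        clusters.discard(b)
        clusters.add(a | b)
    return clusters
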