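"""Local and global Moran's I for duration-preference fields.

The local Moran statistic at vertex i is::

    I_i = (z_i / m2) * sum_j w_ij z_j,      m2 = sum_i z_i^2 / n

where ``z`` are the preferences centered on a scope mean (hemisphere mean for
the local analysis, ROI mean for the global one) and ``w`` are
row-standardized spatial weights.  The global statistic is the average of the
local ones, which with row-standardized weights equals the textbook global
Moran's I.

Significance uses permutation nulls: the local statistic uses a conditional
permutation scheme (the focal vertex's value is held fixed while its
neighbors' values are redrawn without replacement from all other vertices in
scope); the global statistic shuffles all values jointly.  Pseudo p-values
are (R + 1) / (n_perm + 1).  Significant local statistics are classified into
HH / LL / HL / LH quadrants from the signs of z_i and its spatial lag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from chronotopo.synthetic_data import SurfacePatch

QUADRANTS = ("HH", "LL", "HL", "LH", "ns")


@dataclass
class SpatialWeights:
    """Row-standardized neighbor structure.

    ``neighbors[i]`` holds the neighbor indices of vertex i (positional
    indices into the vertex set the weights were built on); each neighbor of
    vertex i carries weight ``1 / len(neighbors[i])``.
    """

    neighbors: list  # list of int arrays
    k: int | None  # uniform neighbor count, None if variable

    @property
    def n(self) -> int:
        return len(self.neighbors)

    def lag(self, z: np.ndarray) -> np.ndarray:
        """Row-standardized spatial lag: mean of each vertex's neighbors."""
        return np.array([z[nb].mean() for nb in self.neighbors])

    def row_sums(self) -> np.ndarray:
        return np.ones(self.n)

    @classmethod
    def from_neighbor_lists(cls, neighbors) -> "SpatialWeights":
        neighbors = [np.asarray(nb, dtype=int) for nb in neighbors]
        for i, nb in enumerate(neighbors):
            if len(nb) == 0:
                raise ValueError(f"vertex {i} has no neighbors")
            if i in nb:
                raise ValueError(f"vertex {i} lists itself as a neighbor")
        ks = {len(nb) for nb in neighbors}
        return cls(neighbors, ks.pop() if len(ks) == 1 else None)


def moran_neighborhood_size(roi_sizes) -> int:
    """Neighborhood size rule for the local analysis: one-fourth of the
    vertex count of the smallest ROI in scope."""
    return max(1, min(int(s) for s in roi_sizes) // 4)


def knn_weights(
    patch: SurfacePatch,
    k: int,
    restrict: str = "all",
    subset: np.ndarray | None = None,
) -> tuple[SpatialWeights, np.ndarray]:
    """k-nearest-neighbor weights on a patch.

    ``restrict`` limits candidate neighbors to the same hemisphere
    (``"hemisphere"``), the same ROI (``"roi"``) or the whole patch
    (``"all"``).  ``subset`` (boolean mask over patch vertices, e.g. the
    valid-fit mask) drops vertices entirely before neighborhoods are built.
    Distance ties are broken by ascending vertex_id.  Returns the weights and
    the array of patch vertex ids they cover (positional index -> vertex_id).
    """
    if restrict not in ("all", "hemisphere", "roi"):
        raise ValueError("restrict must be one of 'all', 'hemisphere', 'roi'")
    mask = np.ones(patch.n_vertices, bool) if subset is None else np.asarray(subset, bool)
    ids = patch.vertex_id[mask]
    coords = patch.coords[mask]
    if restrict == "all":
        groups = np.zeros(len(ids), dtype=object)
    elif restrict == "hemisphere":
        groups = patch.hemisphere[mask]
    else:
        groups = patch.roi[mask]

    n = len(ids)
    neighbors: list = [None] * n
    for gval in pd.unique(groups):
        gi = np.flatnonzero(groups == gval)
        m = len(gi)
        if k >= m:
            raise ValueError(f"k={k} must be < group size {m} (group {gval!r})")
        d = np.linalg.norm(coords[gi, None, :] - coords[None, gi, :], axis=2)
        for a in range(m):
            order = np.lexsort((ids[gi], d[a]))
            order = order[order != a][:k]  # drop self, keep k nearest
            neighbors[gi[a]] = gi[order]
    return SpatialWeights(neighbors, k), ids


@dataclass
class MoranResult:
    """Local Moran's I with permutation pseudo p-values and quadrants."""

    vertex_id: np.ndarray
    local_i: np.ndarray
    pseudo_p: np.ndarray
    quadrant: np.ndarray
    z: np.ndarray
    lag: np.ndarray
    global_i: float
    global_p: float | None
    n_perm: int
    alpha: float
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "vertex_id": self.vertex_id,
                "local_i": self.local_i,
                "pseudo_p": self.pseudo_p,
                "quadrant": self.quadrant,
            }
        )


def _check_values(z: np.ndarray) -> None:
    if len(z) < 3:
        raise ValueError("need at least 3 vertices")
    if np.allclose(z, 0.0) or z.var() == 0:
        raise ValueError("degenerate input: centered values have zero variance")


def local_morans_i(
    values: np.ndarray,
    weights: SpatialWeights,
    center: str | float = "scope_mean",
    n_perm: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
    alternative: str = "two-sided",
) -> MoranResult:
    """Local Moran's I with conditional permutation significance.

    ``values`` aligns with the weights' vertex set (one scope, e.g. the
    valid vertices of one hemisphere).  ``center`` is the scope mean by
    default; pass a float to center on an externally computed mean (e.g. the
    hemisphere mean when analyzing one ROI at a time).

    The permutation null redraws, for each vertex, its k neighbor values
    without replacement from all *other* vertices in scope, holding the focal
    value fixed.  The tail count R takes permuted statistics at least as
    extreme on the observed side; the default ``two-sided`` pseudo p doubles
    that tail (so its false-positive rate at alpha is alpha under an i.i.d.
    null), while ``one-sided`` reports the raw observed-side tail.
    """
    if alternative not in ("two-sided", "one-sided"):
        raise ValueError("alternative must be 'two-sided' or 'one-sided'")
    values = np.asarray(values, dtype=float)
    n = weights.n
    if len(values) != n:
        raise ValueError("values and weights are misaligned")
    mean = values.mean() if center == "scope_mean" else float(center)
    z = values - mean
    _check_values(z)
    m2 = (z @ z) / n
    lag = weights.lag(z)
    local = z / m2 * lag

    rng = np.random.default_rng(seed)
    # one shared set of permutations of the (n-1) "other" slots, as in
    # standard conditional-randomization implementations
    kmax = max(len(nb) for nb in weights.neighbors)
    perm_idx = np.empty((n_perm, kmax), dtype=int)
    for r in range(n_perm):
        perm_idx[r] = rng.permutation(n - 1)[:kmax]

    pseudo_p = np.empty(n)
    others = np.empty(n - 1)
    for i in range(n):
        others[:i] = z[:i]
        others[i:] = z[i + 1 :]
        ki = len(weights.neighbors[i])
        lag_perm = others[perm_idx[:, :ki]].mean(axis=1)
        i_perm = z[i] / m2 * lag_perm
        if local[i] >= i_perm.mean():
            r_count = int(np.count_nonzero(i_perm >= local[i]))
        else:
            r_count = int(np.count_nonzero(i_perm <= local[i]))
        p_side = (r_count + 1) / (n_perm + 1)
        pseudo_p[i] = min(1.0, 2.0 * p_side) if alternative == "two-sided" else p_side

    quadrant = np.full(n, "ns", dtype=object)
    sig = pseudo_p < alpha
    hi_z, hi_lag = z > 0, lag > 0
    quadrant[sig & hi_z & hi_lag] = "HH"
    quadrant[sig & ~hi_z & ~hi_lag] = "LL"
    quadrant[sig & hi_z & ~hi_lag] = "HL"
    quadrant[sig & ~hi_z & hi_lag] = "LH"

    return MoranResult(
        vertex_id=np.arange(n),
        local_i=local,
        pseudo_p=pseudo_p,
        quadrant=quadrant,
        z=z,
        lag=lag,
        global_i=float(local.mean()),
        global_p=None,
        n_perm=n_perm,
        alpha=alpha,
        seed=seed,
    )


def global_morans_i(
    values: np.ndarray,
    weights: SpatialWeights,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Global Moran's I (mean of local statistics) with a two-sided
    permutation test that shuffles all values jointly."""
    values = np.asarray(values, dtype=float)
    n = weights.n
    if len(values) != n:
        raise ValueError("values and weights are misaligned")
    z = values - values.mean()
    _check_values(z)
    m2 = (z @ z) / n

    def global_i(zv: np.ndarray) -> float:
        return float((zv * weights.lag(zv)).sum() / (n * m2))

    obs = global_i(z)
    rng = np.random.default_rng(seed)
    perms = np.empty(n_perm)
    for r in range(n_perm):
        perms[r] = global_i(rng.permutation(z))
    center = perms.mean()
    r_count = int(np.count_nonzero(np.abs(perms - center) >= np.abs(obs - center)))
    return obs, (r_count + 1) / (n_perm + 1)


def summarize_quadrants(
    result: MoranResult,
    roi_labels: np.ndarray,
) -> pd.DataFrame:
    """Per-ROI fractions of LL/HH/HL/LH/ns vertices and the LL - HH
    difference.  ``roi_labels`` aligns with the result's vertex set."""
    roi_labels = np.asarray(roi_labels)
    if len(roi_labels) != len(result.quadrant):
        raise ValueError("roi_labels misaligned with Moran result")
    rows = []
    for roi in pd.unique(roi_labels):
        sel = result.quadrant[roi_labels == roi]
        n = len(sel)
        fracs = {q: np.count_nonzero(sel == q) / n for q in QUADRANTS}
        rows.append({"roi": roi, "n_vertices": n, **{f"frac_{q.lower()}": fracs[q] for q in QUADRANTS}, "ll_minus_hh": fracs["LL"] - fracs["HH"]})
    return pd.DataFrame(rows)
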