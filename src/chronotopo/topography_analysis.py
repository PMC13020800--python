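"""Duration-preference categories, ROI summaries, hierarchy gradients, maps.

Duration preferences are grouped into five categories spanning the tested
range — short (0.2-0.32 s), mid-short (0.32-0.44 s), medium (0.44-0.56 s),
mid-long (0.56-0.68 s) and long (0.68-0.8 s).  Per-ROI summaries collect the
median preference, the category fractions and (when supplied) the LL - HH
spatial-association difference; ordinary least-squares regressions of such
summaries on an explicit occipital-to-frontal hierarchy rank quantify
cortical gradients.  A kernel-weighted resampler renders preference fields
onto a flat 2 mm grid for map display.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from chronotopo.prf_model import TuningField

CATEGORY_LABELS = ("short", "mid-short", "medium", "mid-long", "long")
CATEGORY_EDGES = (0.2, 0.32, 0.44, 0.56, 0.68, 0.8)
UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class CategoryScheme:
    """Five preference categories over strictly increasing bin edges.

    Intervals are left-closed/right-open; the final interval is closed on
    both ends so the top design duration is assigned (edge values do occur
    in fitted data, so the closure convention is fixed and documented).
    """

    labels: tuple[str, ...] = CATEGORY_LABELS
    edges: tuple[float, ...] = CATEGORY_EDGES

    def __post_init__(self) -> None:
        if len(self.edges) != len(self.labels) + 1:
            raise ValueError("need len(labels) + 1 edges")
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("edges must be strictly increasing")


def categorize(mu_d, scheme: CategoryScheme | None = None) -> np.ndarray:
    """Assign each preference to a category label.

    Out-of-range preferences are flagged ``"unassigned"`` rather than
    silently binned.
    """
    scheme = scheme or CategoryScheme()
    mu = np.atleast_1d(np.asarray(mu_d, dtype=float))
    edges = np.asarray(scheme.edges)
    idx = np.digitize(mu, edges, right=False) - 1  # left-closed bins
    idx[mu == edges[-1]] = len(scheme.labels) - 1  # final bin closed
    out = np.full(mu.shape, UNASSIGNED, dtype=object)
    ok = (idx >= 0) & (idx < len(scheme.labels))
    out[ok] = np.asarray(scheme.labels, dtype=object)[idx[ok]]
    return out


def summarize_roi(
    field: TuningField,
    quadrants: pd.DataFrame | None = None,
    scheme: CategoryScheme | None = None,
    ordering: dict | None = None,
) -> pd.DataFrame:
    """Per-ROI summary over valid vertices: median preference, category
    fractions and, when a quadrant summary is given, the LL - HH difference.

    ``ordering`` maps ROI name -> hierarchy rank (occipital-to-frontal); ROIs
    absent from the mapping get rank NaN.  ROIs with no valid vertices are
    reported with missing values and counted in the returned frame.
    """
    scheme = scheme or CategoryScheme()
    fits = field.fits
    patch = field.patch
    rows = []
    for roi in pd.unique(patch.roi):
        sel = (patch.roi == roi) & field.valid_mask
        stream = patch.stream[patch.roi == roi][0]
        row = {
            "roi": roi,
            "stream": stream,
            "hierarchy_rank": (ordering or {}).get(roi, np.nan),
            "n_valid": int(np.count_nonzero(sel)),
        }
        if row["n_valid"] == 0:
            row.update({"median_mu": np.nan, "n_unassigned": 0})
            row.update({f"frac_{lb}": np.nan for lb in scheme.labels})
        else:
            mu = fits.loc[sel, "mu_d"].to_numpy()
            cats = categorize(mu, scheme)
            assigned = cats != UNASSIGNED
            denom = max(int(assigned.sum()), 1)
            row["median_mu"] = float(np.median(mu))
            row["n_unassigned"] = int(np.count_nonzero(~assigned))
            for lb in scheme.labels:
                row[f"frac_{lb}"] = float(np.count_nonzero(cats == lb) / denom)
        rows.append(row)
    out = pd.DataFrame(rows)
    if quadrants is not None:
        out = out.merge(quadrants[["roi", "ll_minus_hh"]], on="roi", how="left")
    return out.sort_values("hierarchy_rank", na_position="last").reset_index(drop=True)


@dataclass
class GradientFit:
    """OLS fit of a per-ROI scalar on hierarchy rank."""

    slope: float
    intercept: float
    t_stat: float
    p_value: float
    n: int


def hierarchy_regression(values, ranks) -> GradientFit:
    """Ordinary least squares of a regional summary on its
    occipital-to-frontal hierarchy rank."""
    values = np.asarray(values, dtype=float)
    ranks = np.asarray(ranks, dtype=float)
    ok = np.isfinite(values) & np.isfinite(ranks)
    values, ranks = values[ok], ranks[ok]
    if len(values) < 3:
        raise ValueError("need at least 3 regions")
    if np.ptp(values) == 0:  # flat outcome: slope 0 by convention
        return GradientFit(0.0, float(values[0]), 0.0, 1.0, len(values))
    res = sm.OLS(values, sm.add_constant(ranks)).fit()
    return GradientFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        t_stat=float(res.tvalues[1]),
        p_value=float(res.pvalues[1]),
        n=len(values),
    )


def render_preference_map(
    field: TuningField,
    grid_mm: float = 2.0,
    fwhm_mm: float = 4.0,
    weight_threshold: float = 1e-3,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render valid duration preferences onto a flat isotropic grid.

    Each grid cell holds the Gaussian-kernel-weighted mean preference of the
    valid vertices (kernel sigma = fwhm / 2.355); cells whose total kernel
    weight falls below ``weight_threshold`` are masked as NaN (locations
    outside the sampled patch).  Returns ``(map, x_centers, y_centers)``
    with ``map[iy, ix]``.
    """
    mask = field.valid_mask
    if not mask.any():
        raise ValueError("no valid vertices to render")
    coords = field.patch.coords[mask]
    mu = field.mu_d[mask]
    sigma = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))

    x0, x1 = coords[:, 0].min(), coords[:, 0].max()
    y0, y1 = coords[:, 1].min(), coords[:, 1].max()
    xc = np.arange(x0, x1 + grid_mm / 2, grid_mm)
    yc = np.arange(y0, y1 + grid_mm / 2, grid_mm)
    gx, gy = np.meshgrid(xc, yc)
    cells = np.column_stack([gx.ravel(), gy.ravel()])
    d2 = ((cells[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    w = np.exp(-d2 / (2.0 * sigma**2))
    totals = w.sum(axis=1)
    vals = np.where(totals > weight_threshold, (w @ mu) / np.where(totals > 0, totals, 1.0), np.nan)
    return vals.reshape(gy.shape), xc, yc
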