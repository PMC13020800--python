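"""Synthetic cortical patches, planted duration-preference fields, and behavior.

This module is the testing ground for the whole pipeline: it builds flat
lattice stand-ins for (flattened) cortical surface patches, plants
ground-truth duration tuning fields with controllable spatial structure,
forward-simulates condition-wise response amplitudes (beta weights) through
the Gaussian duration pRF model, and simulates logistic duration
categorization behavior with a planted point of subjective equality (PSE).

All randomness flows from one explicit integer seed per call; no global RNG
state is touched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

#: The six comparison durations of the categorization task (seconds); the
#: reference duration is 0.5 s.
DESIGN_DURATIONS: tuple[float, ...] = (0.2, 0.3, 0.4, 0.6, 0.7, 0.8)

#: Duration range inside which planted preferences are identifiable.
MU_RANGE: tuple[float, float] = (0.2, 0.8)

#: Default range for planted tuning widths (seconds).  The empirical
#: distribution of tuning widths is not constrained by the analyses this
#: package mirrors; this interval covers sharp to broad tuning within the
#: sub-second design range and is a documented free choice.
SIGMA_RANGE: tuple[float, float] = (0.05, 0.3)

FIELD_KINDS = ("gradient", "grf", "white", "boundary", "constant")


@dataclass(frozen=True)
class RoiBlock:
    """A contiguous block of vertices sharing one ROI / stream label."""

    roi: str
    n_vertices: int
    stream: str = "none"
    hemisphere: str = "L"


@dataclass
class SurfacePatch:
    """A flat stand-in for a cortical surface patch.

    Vertices carry 2-D coordinates in millimetres plus ROI, stream and
    hemisphere labels.  Inter-vertex distances are Euclidean by default; a
    precomputed distance matrix (e.g. geodesic) may be attached.
    """

    vertex_id: np.ndarray
    coords: np.ndarray  # (n, 2) mm
    roi: np.ndarray
    stream: np.ndarray
    hemisphere: np.ndarray
    _distances: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        n = len(self.vertex_id)
        if not np.array_equal(self.vertex_id, np.arange(n)):
            raise ValueError("vertex_ids must be unique and contiguous from 0")
        if self.coords.shape != (n, 2):
            raise ValueError("coords must be (n_vertices, 2)")
        for name in ("roi", "stream", "hemisphere"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} labels must have one entry per vertex")

    @property
    def n_vertices(self) -> int:
        return len(self.vertex_id)

    def distance_matrix(self) -> np.ndarray:
        """Pairwise inter-vertex distances in mm (cached)."""
        if self._distances is None:
            self._distances = cdist(self.coords, self.coords)
        return self._distances

    def set_distance_matrix(self, d: np.ndarray) -> None:
        """Attach a precomputed (e.g. geodesic) distance matrix."""
        d = np.asarray(d, dtype=float)
        n = self.n_vertices
        if d.shape != (n, n) or not np.all(np.isfinite(d)) or np.any(d < 0):
            raise ValueError("distance matrix must be (n, n), finite and >= 0")
        self._distances = d

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "vertex_id": self.vertex_id,
                "x_mm": self.coords[:, 0],
                "y_mm": self.coords[:, 1],
                "roi": self.roi,
                "stream": self.stream,
                "hemi": self.hemisphere,
            }
        )


@dataclass
class GroundTruthField:
    """Planted per-vertex tuning parameters the pRF fit must recover."""

    mu_true: np.ndarray  # seconds
    sigma_true: np.ndarray  # seconds, > 0
    gain_true: np.ndarray  # percent signal change
    baseline_true: np.ndarray  # percent signal change
    mu_range: tuple[float, float] = MU_RANGE
    clip_fraction: float = 0.0  # fraction of vertices clipped into mu_range

    def __post_init__(self) -> None:
        if np.any(self.sigma_true <= 0):
            raise ValueError("sigma_true must be > 0 everywhere")
        lo, hi = self.mu_range
        if np.any(self.mu_true < lo - 1e-12) or np.any(self.mu_true > hi + 1e-12):
            raise ValueError("mu_true must lie within mu_range")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "vertex_id": np.arange(len(self.mu_true)),
                "mu_true": self.mu_true,
                "sigma_true": self.sigma_true,
                "gain_true": self.gain_true,
                "baseline_true": self.baseline_true,
            }
        )


def make_patch(
    n_rows: int,
    n_cols: int,
    spacing_mm: float,
    roi_blocks: Sequence[RoiBlock] | None = None,
) -> SurfacePatch:
    """Build a regular ``n_rows x n_cols`` lattice patch.

    Vertices are numbered row-major; ROI blocks are assigned to contiguous
    runs of vertex ids in the given order and must cover the lattice exactly.
    """
    if n_rows < 2 or n_cols < 2:
        raise ValueError("n_rows and n_cols must be >= 2")
    if spacing_mm <= 0:
        raise ValueError("spacing_mm must be > 0")
    n = n_rows * n_cols
    rows, cols = np.divmod(np.arange(n), n_cols)
    coords = np.column_stack([cols * spacing_mm, rows * spacing_mm]).astype(float)

    if roi_blocks is None:
        roi_blocks = [RoiBlock("roi0", n)]
    if sum(b.n_vertices for b in roi_blocks) != n:
        raise ValueError("roi_blocks must cover the lattice exactly")
    roi = np.empty(n, dtype=object)
    stream = np.empty(n, dtype=object)
    hemi = np.empty(n, dtype=object)
    start = 0
    for b in roi_blocks:
        sl = slice(start, start + b.n_vertices)
        roi[sl], stream[sl], hemi[sl] = b.roi, b.stream, b.hemisphere
        start += b.n_vertices
    return SurfacePatch(np.arange(n), coords, roi, stream, hemi)


def _gaussian_smooth(coords: np.ndarray, white: np.ndarray, length_mm: float) -> np.ndarray:
    """Kernel-smooth a white field; kernel sd = length_mm / 2."""
    d = cdist(coords, coords)
    k = np.exp(-(d**2) / (2.0 * (length_mm / 2.0) ** 2))
    smooth = k @ white
    smooth -= smooth.mean()
    sd = smooth.std()
    if sd == 0:
        raise ValueError("degenerate smoothed field (zero variance)")
    return smooth / sd


def plant_field(
    patch: SurfacePatch,
    kind: str,
    params: Mapping | None = None,
    seed: int = 0,
) -> GroundTruthField:
    """Plant a ground-truth duration-preference field on ``patch``.

    Kinds
    -----
    ``constant``  single preference everywhere (``mu``, default 0.5 s).
    ``gradient``  linear ramp of preference along one lattice axis
                  (``axis`` in {"x", "y"}, ``mu_range``).
    ``grf``       Gaussian-kernel-smoothed white noise with the requested
                  ``correlation_length_mm``, rescaled to unit variance and
                  mixed with fresh white noise at ``nugget_fraction``; scaled
                  by ``amplitude_s`` (sd in seconds, default 0.12) around
                  ``center`` (default 0.5 s).
    ``white``     i.i.d. uniform preferences over ``mu_range``.
    ``boundary``  i.i.d. normal preferences tight around ``center`` (default
                  0.5 s) with ``spread`` sd (default 0.03 s) — the
                  boundary-tuned regime.

    Preferences are clipped into ``mu_range`` after generation; the clipped
    fraction is recorded on the returned field.
    """
    if kind not in FIELD_KINDS:
        raise ValueError(f"unknown field kind {kind!r}; expected one of {FIELD_KINDS}")
    p = dict(params or {})
    rng = np.random.default_rng(seed)
    n = patch.n_vertices
    lo, hi = p.get("mu_range", MU_RANGE)

    if kind == "constant":
        mu = np.full(n, float(p.get("mu", 0.5)))
    elif kind == "gradient":
        axis = 0 if p.get("axis", "x") == "x" else 1
        c = patch.coords[:, axis]
        span = c.max() - c.min()
        mu = lo + (hi - lo) * (c - c.min()) / span
    elif kind == "white":
        mu = rng.uniform(lo, hi, size=n)
    elif kind == "boundary":
        center = float(p.get("center", 0.5))
        spread = float(p.get("spread", 0.03))
        mu = rng.normal(center, spread, size=n)
    else:  # grf
        length = float(p.get("correlation_length_mm", 6.0))
        nugget = float(p.get("nugget_fraction", 0.0))
        if length <= 0:
            raise ValueError("correlation_length_mm must be > 0")
        if not 0.0 <= nugget <= 1.0:
            raise ValueError("nugget_fraction must be in [0, 1]")
        smooth = _gaussian_smooth(patch.coords, rng.standard_normal(n), length)
        fresh = rng.standard_normal(n)
        z = np.sqrt(1.0 - nugget) * smooth + np.sqrt(nugget) * fresh
        mu = float(p.get("center", 0.5)) + float(p.get("amplitude_s", 0.12)) * z

    clipped = np.count_nonzero((mu < lo) | (mu > hi))
    mu = np.clip(mu, lo, hi)

    sigma = p.get("sigma")
    if sigma is None:
        sigma = rng.uniform(*SIGMA_RANGE, size=n)
    else:
        sigma = np.full(n, float(sigma))
    gain = np.full(n, float(p.get("gain", 1.0)))
    baseline = np.full(n, float(p.get("baseline", 0.0)))
    return GroundTruthField(
        mu, sigma, gain, baseline, mu_range=(lo, hi), clip_fraction=clipped / n
    )


def simulate_betas(
    truth: GroundTruthField,
    stim,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Forward-simulate the 24 condition-wise beta weights per vertex.

    For each vertex and each duration x position condition::

        beta = baseline + gain * exp(-(d - mu)^2 / (2 sigma^2)) + N(0, noise_sd)

    The noiseless response is identical across the four positions sharing a
    duration (position invariance).  ``stim`` is a
    :class:`chronotopo.prf_model.StimulusSpec`.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    lo, hi = truth.mu_range
    durations = np.asarray(stim.durations)
    if durations.min() < lo - 1e-12 or durations.max() > hi + 1e-12:
        raise ValueError("stimulus durations outside the truth field's design range")
    rng = np.random.default_rng(seed)
    n = len(truth.mu_true)
    # (n, 6) Gaussian tuning responses, repeated over the 4 positions.
    resp = np.exp(
        -((durations[None, :] - truth.mu_true[:, None]) ** 2)
        / (2.0 * truth.sigma_true[:, None] ** 2)
    )
    clean = truth.baseline_true[:, None] + truth.gain_true[:, None] * resp
    betas = np.repeat(clean, len(stim.positions), axis=1)
    if noise_sd > 0:
        betas = betas + rng.normal(0.0, noise_sd, size=betas.shape)
    out = pd.DataFrame(betas, columns=stim.condition_names())
    out.insert(0, "vertex_id", np.arange(n))
    return out


def simulate_behavior(
    pse: float,
    slope: float,
    n_per_duration: int,
    seed: int = 0,
    durations: Sequence[float] = DESIGN_DURATIONS,
    subject_id: str = "s01",
) -> pd.DataFrame:
    """Simulate binary "comparison longer than reference" responses.

    P(longer | d) = logistic(slope * (d - pse)); balanced trial counts per
    comparison duration.
    """
    if slope <= 0:
        raise ValueError("slope must be > 0")
    if n_per_duration < 1:
        raise ValueError("n_per_duration must be >= 1")
    rng = np.random.default_rng(seed)
    d = np.repeat(np.asarray(durations, dtype=float), n_per_duration)
    with np.errstate(over="ignore"):
        p_longer = 1.0 / (1.0 + np.exp(-slope * (d - pse)))
    responses = (rng.uniform(size=d.size) < p_longer).astype(int)
    return pd.DataFrame(
        {
            "subject": subject_id,
            "trial": np.arange(d.size),
            "duration_s": d,
            "response": responses,
        }
    )


# ---------------------------------------------------------------------------
# Writers (headered TSV, '.' decimal, UTF-8) with JSON parameter sidecars.

def write_tsv(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def write_sidecar(path: str | Path, params: Mapping) -> Path:
    path = Path(path).with_suffix(".json")
    path.write_text(json.dumps(dict(params), indent=2, sort_keys=True, default=str))
    return path


def write_patch(patch: SurfacePatch, path: str | Path, params: Mapping | None = None) -> Path:
    out = write_tsv(patch.to_frame(), path)
    if params is not None:
        write_sidecar(out, params)
    return out


def read_patch(path: str | Path) -> SurfacePatch:
    df = pd.read_csv(path, sep="\t")
    return SurfacePatch(
        vertex_id=df["vertex_id"].to_numpy(),
        coords=df[["x_mm", "y_mm"]].to_numpy(dtype=float),
        roi=df["roi"].to_numpy(dtype=object),
        stream=df["stream"].to_numpy(dtype=object),
        hemisphere=df["hemi"].to_numpy(dtype=object),
    )
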