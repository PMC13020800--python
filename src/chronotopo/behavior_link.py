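"""Psychometric fits, PSE extraction and the preference-perception link.

Per-subject psychometric curves are binomial-logit regressions of the
"comparison longer than reference" response on comparison duration; the
point of subjective equality (PSE) — the duration judged longer exactly half
the time — is ``-intercept / slope``.  Kendall tau-b correlations between
subjects' PSEs and their regional median duration preferences quantify where
preferences track the perceptual category boundary; tau values are mapped to
an unbounded scale with ``z(tau) = atanh(sin(pi/2 * tau))`` before fitting
the occipital-to-frontal gradient regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from chronotopo.topography_analysis import GradientFit, hierarchy_regression


@dataclass
class PsychometricFit:
    """Logit psychometric curve of one subject."""

    intercept: float
    slope: float  # 1/seconds
    pse: float  # seconds; -intercept/slope, valid when slope > 0
    converged: bool
    pse_valid: bool


def fit_psychometric(behavior: pd.DataFrame) -> PsychometricFit:
    """Fit a binomial-logit psychometric curve to trial-level behavior.

    ``behavior`` needs columns ``duration_s`` and binary ``response``.
    Degenerate data (a single response class, fewer than two distinct
    durations) and perfect separation yield ``converged = False``; a
    non-positive fitted slope flags the PSE invalid.
    """
    d = behavior["duration_s"].to_numpy(dtype=float)
    y = behavior["response"].to_numpy(dtype=float)
    if len(np.unique(d)) < 2:
        raise ValueError("need at least 2 distinct comparison durations")
    if len(np.unique(y)) < 2:
        return PsychometricFit(np.nan, np.nan, np.nan, False, False)
    exog = sm.add_constant(d)
    try:
        import warnings

        from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            res = sm.GLM(y, exog, family=sm.families.Binomial()).fit()
        separated = any(issubclass(w.category, PerfectSeparationWarning) for w in caught)
        params = res.params
        converged = (
            bool(res.converged) and bool(np.all(np.isfinite(params))) and not separated
        )
    except Exception:
        return PsychometricFit(np.nan, np.nan, np.nan, False, False)
    if not converged or abs(params[1]) > 1e4:
        return PsychometricFit(float(params[0]), float(params[1]), np.nan, False, False)
    intercept, slope = float(params[0]), float(params[1])
    pse = -intercept / slope if slope > 0 else np.nan
    return PsychometricFit(intercept, slope, pse, True, slope > 0)


def kendall_tau(x, y) -> tuple[float, float]:
    """Kendall tau-b with its p-value (exact for small untied samples,
    normal approximation otherwise)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need at least 3 paired values")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("tau undefined for an all-tied variable")
    has_ties = len(np.unique(x)) < len(x) or len(np.unique(y)) < len(y)
    method = "exact" if (len(x) <= 9 and not has_ties) else "asymptotic"
    res = stats.kendalltau(x, y, variant="b", method=method)
    return float(res.statistic), float(res.pvalue)


def z_transform_tau(tau, clamp: bool = False):
    """Map Kendall's tau to an unbounded scale: atanh(sin(pi/2 * tau)).

    Strictly increasing and odd on (-1, 1); |tau| = 1 maps to +/-inf and is
    rejected unless ``clamp`` pulls it to 1 - 1e-6.
    """
    tau = np.asarray(tau, dtype=float)
    if np.any(np.abs(tau) > 1):
        raise ValueError("tau must lie in [-1, 1]")
    if np.any(np.abs(tau) >= 1):
        if not clamp:
            raise ValueError("|tau| = 1 maps to infinity; pass clamp=True to squash")
        tau = np.clip(tau, -1 + 1e-6, 1 - 1e-6)
    s = np.sin(np.pi / 2.0 * tau)
    # |tau| < 1 is mathematically finite; keep it so when sin rounds to 1
    lim = np.nextafter(1.0, 0.0)
    out = np.arctanh(np.clip(s, -lim, lim))
    return float(out) if out.ndim == 0 else out


@dataclass
class PseLinkResult:
    """Per-region PSE-preference correlations and their hierarchy gradient."""

    table: pd.DataFrame  # region, tau, p_value, z_tau, n_subjects, rank
    gradient: GradientFit | None  # None when fewer than 3 ranked regions


def pse_preference_link(
    pse_per_subject: pd.Series,
    median_mu: pd.DataFrame,
    ordering: dict,
    clamp: bool = False,
) -> PseLinkResult:
    """Correlate subjects' PSEs with their regional median preferences.

    ``median_mu`` is a subject x region table of median duration preferences;
    ``pse_per_subject`` aligns on its index.  Each region gets a Kendall
    tau-b (uncorrected p), its z-transform, and the z values are regressed on
    the hierarchy rank from ``ordering`` (region -> rank).
    """
    common = median_mu.index.intersection(pse_per_subject.index)
    if len(common) < 3:
        raise ValueError("need at least 3 subjects with both PSE and medians")
    pse = pse_per_subject.loc[common].to_numpy(dtype=float)
    rows = []
    for region in median_mu.columns:
        med = median_mu.loc[common, region].to_numpy(dtype=float)
        ok = np.isfinite(med) & np.isfinite(pse)
        if ok.sum() < 3 or np.ptp(med[ok]) == 0:
            tau, p = np.nan, np.nan
        else:
            tau, p = kendall_tau(med[ok], pse[ok])
        z = np.nan
        if np.isfinite(tau):
            z = z_transform_tau(tau, clamp=clamp) if abs(tau) < 1 or clamp else np.nan
        rows.append(
            {
                "region": region,
                "tau": tau,
                "p_value": p,
                "z_tau": z,
                "n_subjects": int(ok.sum()),
                "rank": ordering.get(region, np.nan),
            }
        )
    table = pd.DataFrame(rows).sort_values("rank", na_position="last").reset_index(drop=True)
    ok = np.isfinite(table["z_tau"]) & np.isfinite(table["rank"])
    grad = hierarchy_regression(table["z_tau"], table["rank"]) if ok.sum() >= 3 else None
    return PseLinkResult(table, grad)
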