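"""Cumulative-Gaussian psychometric function (PMF) fitting and the bias /
threshold measures derived from it.

For each condition, responses "comparison toward higher hue angle" are
pooled per comparison offset and fit with a two-parameter cumulative
Gaussian by Bernoulli maximum likelihood:

    P(respond higher | offset x) = Phi((x - mu) / sigma)

``mu`` is the point of subjective equality (PSE): the comparison offset at
which test and comparison look equal.  Its displacement from the ground
truth (zero offset, the target mean) measures perceptual bias; ``sigma``
is the discrimination threshold.  A fit is flagged invalid when the curve
fails to span the 0.25-0.75 probability range within the tested comparison
offsets — such fits cannot constrain either parameter.

Bias is re-signed so that positive always means "toward the distractor",
and expressed as a fraction of the full-integration prediction (half the
target-distractor separation) where that prediction exists.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm

from . import design
from .circular import signed_diff

MU_BOUNDS = (-90.0, 90.0)
SIGMA_BOUNDS = (0.1, 500.0)


@dataclass(frozen=True)
class PMFFit:
    """Cumulative-Gaussian PMF parameters with fit diagnostics."""

    mu: float  # PSE relative to zero comparison offset, degrees
    sigma: float  # SD of the cumulative Gaussian = threshold, degrees
    nll: float
    valid: bool
    converged: bool = True


def _nll(theta, x, k, n):
    mu, sigma = theta
    p = norm.cdf((x - mu) / sigma)
    p = np.clip(p, 1e-10, 1.0 - 1e-10)
    return -float(np.sum(k * np.log(p) + (n - k) * np.log1p(-p)))


def fit_pmf(offsets, n_higher, n_total) -> PMFFit:
    """Bernoulli MLE of (mu, sigma) from per-level response counts.

    Deterministic given the data (fixed multi-start).  Degenerate data
    (all responses 0 or all 1) drive the parameters to their bounds and
    yield ``valid=False`` rather than an exception.
    """
    x = np.asarray(offsets, dtype=float)
    k = np.asarray(n_higher, dtype=float)
    n = np.asarray(n_total, dtype=float)
    if not (x.shape == k.shape == n.shape):
        raise ValueError("offsets, n_higher and n_total must align")
    if np.unique(x).size < 2:
        raise ValueError("need responses at >= 2 distinct levels")
    if np.any((k < 0) | (k > n)) or np.any(n <= 0):
        raise ValueError("counts must satisfy 0 <= n_higher <= n_total > 0")

    # data-driven start: PSE near the 50% crossing, slope from the spread
    props = k / n
    mu0 = float(np.clip(np.interp(0.5, np.clip(props, 0.01, 0.99), x,
                                  left=x[0], right=x[-1]),
                        *MU_BOUNDS))
    span = float(x.max() - x.min())
    starts = [(mu0, max(span / 4.0, 1.0)), (0.0, 5.0), (0.0, 20.0),
              (mu0, max(span, 2.0))]
    bounds = [MU_BOUNDS, SIGMA_BOUNDS]
    best = None
    for x0 in starts:
        res = minimize(_nll, np.asarray(x0, float), args=(x, k, n),
                       method="L-BFGS-B", bounds=bounds,
                       options={"ftol": 1e-12, "maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
    mu, sigma = (float(v) for v in best.x)
    fit = PMFFit(mu=mu, sigma=sigma, nll=float(best.fun), valid=True,
                 converged=bool(best.success))
    return PMFFit(mu=mu, sigma=sigma, nll=fit.nll,
                  valid=pmf_validity(fit, x), converged=fit.converged)


def pmf_validity(fit: PMFFit, comparison_offsets) -> bool:
    """True iff the fitted curve spans [0.25, 0.75] within the tested
    comparison offsets."""
    x = np.asarray(comparison_offsets, dtype=float)
    lo = norm.cdf((x.min() - fit.mu) / fit.sigma)
    hi = norm.cdf((x.max() - fit.mu) / fit.sigma)
    return bool(lo <= 0.25 and hi >= 0.75)


@dataclass(frozen=True)
class BiasMeasure:
    """Signed bias in degrees (positive = toward the distractor) and as a
    fraction of the full-integration prediction (nan where that prediction
    is undefined: baseline and the 180-deg condition)."""

    bias_deg: float
    bias_fraction: float


def bias_toward_distractor(fit: PMFFit, condition: str,
                           target_mean: float,
                           distractor_mean: Optional[float]) -> BiasMeasure:
    """Re-sign the PSE so positive bias points toward the distractor.

    A distractor at lower hue angle pulls the perceived test mean down,
    which shifts the PSE to negative offsets; so the PSE is multiplied by
    the sign of the target-to-distractor arc.  For baseline the raw PSE
    (vs. the zero-offset ground truth) is reported and the fraction is
    undefined; for the 180-deg condition the fraction is undefined.
    """
    if condition == "baseline" or distractor_mean is None:
        return BiasMeasure(bias_deg=fit.mu, bias_fraction=math.nan)
    s = 1.0 if signed_diff(distractor_mean, target_mean) > 0 else -1.0
    bias = s * fit.mu
    full = design.full_integration_bias(condition)
    fraction = bias / full if math.isfinite(full) else math.nan
    return BiasMeasure(bias_deg=bias, bias_fraction=fraction)


# ---------------------------------------------------------------------------
# response-log plumbing

def aggregate_responses(frame: pd.DataFrame) -> pd.DataFrame:
    """Collapse a trial-level response log to per-level counts
    (``comparison_offset_deg``, ``n_higher``, ``n_total``), excluding dummy
    and practice trials."""
    f = frame
    for flag in ("is_dummy", "is_practice"):
        if flag in f.columns:
            f = f[~f[flag].astype(bool)]
    g = f.groupby("comparison_offset_deg")["response"]
    out = pd.DataFrame({"n_higher": g.sum(), "n_total": g.count()})
    return out.reset_index().sort_values("comparison_offset_deg",
                                         ignore_index=True)


def fit_condition(frame: pd.DataFrame) -> PMFFit:
    """Fit one PMF to all analyzed trials of a single-condition log."""
    agg = aggregate_responses(frame)
    return fit_pmf(agg["comparison_offset_deg"], agg["n_higher"],
                   agg["n_total"])


def fit_response_table(frame: pd.DataFrame, observer_id: str = "obs0",
                       per_repetition: bool = False) -> pd.DataFrame:
    """Fit PMFs per condition (pooled over block repetitions by default)
    and derive the bias measures.

    Returns one row per observer x condition (x block when
    ``per_repetition``): mu, sigma, validity, signed bias and bias
    fraction.
    """
    rows = []
    group_cols = ["condition", "block"] if per_repetition else "condition"
    f = frame
    for flag in ("is_dummy", "is_practice"):
        if flag in f.columns:
            f = f[~f[flag].astype(bool)]
    for key, sub in f.groupby(group_cols):
        condition = key[0] if per_repetition else key
        fit = fit_condition(sub)
        d = sub["distractor_mean_deg"].iloc[0]
        measure = bias_toward_distractor(
            fit, str(condition), float(sub["target_mean_deg"].iloc[0]),
            None if pd.isna(d) else float(d))
        row = {
            "observer_id": observer_id,
            "group": sub["group"].iloc[0],
            "condition": condition,
            "mu_deg": fit.mu,
            "sigma_deg": fit.sigma,
            "nll": fit.nll,
            "valid": fit.valid,
            "bias_deg": measure.bias_deg,
            "bias_fraction": measure.bias_fraction,
        }
        if per_repetition:
            row["block"] = key[1]
        rows.append(row)
    return pd.DataFrame(rows)
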