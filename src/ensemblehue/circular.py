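"""Hue-circle arithmetic and von Mises probability machinery.

All stimulus colors live on a circle of constant lightness and chroma in
CIELUV LCh coordinates; hue angle (in degrees, counterclockwise) is the only
free coordinate.  Every other module builds on the primitives here: angle
wrapping, shortest signed arcs, weighted circular means, and arc
probabilities under the von Mises distribution (the circular analogue of the
normal, with location ``mu`` and concentration ``kappa``; ``kappa = 0`` is
the uniform distribution on the circle).

Angles are kept in degrees throughout the package — radians appear only
transiently inside density/CDF evaluation.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _sstats

#: Fixed CIELUV lightness and chroma of all stimuli (the hue circle radius).
LIGHTNESS = 70.0
CHROMA = 70.0

#: Resultant lengths below this are treated as "no defined circular mean"
#: (antipodal cancellation).  Only essentially exact cancellation is
#: meaningless; empirical response data never hit this.
UNDEFINED_MEAN_TOL = 1e-8


def wrap_hue(angle):
    """Wrap an angle (or array of angles) in degrees into ``[0, 360)``.

    Parameters
    ----------
    angle : float or array_like
        Angle(s) in degrees; must be finite.

    Returns
    -------
    float or ndarray
        ``angle mod 360`` in ``[0, 360)``; 360 maps to 0.
    """
    a = np.asarray(angle, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("hue angles must be finite")
    w = np.mod(a, 360.0)
    # guard against w == 360.0 from floating-point round-off
    w = np.where(w >= 360.0, w - 360.0, w)
    if np.ndim(angle) == 0:
        return float(w)
    return w


def signed_diff(a, b):
    """Shortest signed arc from ``b`` to ``a``, in degrees in ``(-180, 180]``.

    Positive values mean ``a`` lies counterclockwise (toward higher hue
    angle) of ``b``.  Antipodal pairs return ``+180`` (deterministic
    tie-break).  Vectorized over both arguments.
    """
    d = np.mod(np.asarray(a, float) - np.asarray(b, float), 360.0)
    out = np.where(d > 180.0, d - 360.0, d)
    if np.ndim(out) == 0:
        return float(out)
    return out


def circular_mean(angles, weights=None, tol=UNDEFINED_MEAN_TOL):
    """Weighted circular mean of hue angles.

    Parameters
    ----------
    angles : array_like of degrees
        At least one angle.
    weights : array_like, optional
        Nonnegative weights, same length as ``angles``, not all zero.
        Defaults to equal weights.
    tol : float
        Resultant-length threshold below which the mean is reported
        undefined (``nan``) — e.g. two equal-weight antipodal hues, for
        which there is no meaningful average.

    Returns
    -------
    (mean, resultant_length) : (float, float)
        ``mean`` is the angle of the weighted resultant vector in
        ``[0, 360)`` or ``nan`` if the normalized resultant length falls
        below ``tol``; ``resultant_length`` is in ``[0, 1]``.
    """
    ang = np.atleast_1d(np.asarray(angles, dtype=float))
    if ang.size == 0:
        raise ValueError("need at least one angle")
    if not np.all(np.isfinite(ang)):
        raise ValueError("angles must be finite")
    if weights is None:
        w = np.ones_like(ang)
    else:
        w = np.atleast_1d(np.asarray(weights, dtype=float))
        if w.shape != ang.shape:
            raise ValueError("weights must match angles in length")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        if not np.any(w > 0):
            raise ValueError("weights must not all be zero")
    rad = np.radians(ang)
    c = float(np.sum(w * np.cos(rad)))
    s = float(np.sum(w * np.sin(rad)))
    r = math.hypot(c, s) / float(np.sum(w))
    if r < tol:
        return math.nan, r
    return wrap_hue(math.degrees(math.atan2(s, c))), r


@dataclass(frozen=True)
class VonMisesParams:
    """Location ``mu`` (degrees) and concentration ``kappa`` (>= 0)."""

    mu: float
    kappa: float

    def __post_init__(self):
        if not math.isfinite(self.mu):
            raise ValueError("mu must be finite")
        if not (math.isfinite(self.kappa) and self.kappa >= 0):
            raise ValueError("kappa must be finite and nonnegative")


def _vm_cdf(x, kappa):
    """CDF of the centered von Mises on [-pi, pi]; input clipped to range."""
    return _sstats.vonmises.cdf(np.clip(x, -np.pi, np.pi), kappa)


def arc_probability(stimulus, kappa, lo, hi):
    """P(a von Mises measurement centered on ``stimulus`` lands in the arc
    from ``lo`` counterclockwise to ``hi``).

    Vectorized over ``stimulus``; ``lo == hi`` denotes the full circle.
    Internal workhorse of :func:`vm_interval_prob` and the category-model
    likelihood.
    """
    if kappa < 0:
        raise ValueError("kappa must be nonnegative")
    stim = np.asarray(stimulus, dtype=float)
    arc = float(np.mod(hi - lo, 360.0))
    if arc == 0.0:
        arc = 360.0
    if kappa == 0.0:
        p = np.full(stim.shape, arc / 360.0)
        return float(p) if np.ndim(stimulus) == 0 else p
    d0 = np.radians(signed_diff(lo, stim))  # arc start, measurement frame
    span = math.radians(arc)
    upper = d0 + span
    # CDF extended beyond +pi by periodicity: F(x) = 1 + F(x - 2*pi)
    p = np.where(
        upper <= np.pi,
        _vm_cdf(upper, kappa) - _vm_cdf(d0, kappa),
        1.0 - _vm_cdf(d0, kappa) + _vm_cdf(upper - 2.0 * np.pi, kappa),
    )
    p = np.clip(p, 0.0, 1.0)
    if np.ndim(stimulus) == 0:
        return float(p)
    return p


def vm_interval_prob(params: VonMisesParams, lo, hi):
    """Probability mass of a von Mises distribution on a circular arc.

    The arc runs from ``lo`` counterclockwise to ``hi``; ``lo == hi`` is
    read as the full circle (probability 1).  Probabilities of arcs forming
    a partition of the circle sum to 1.
    """
    return arc_probability(params.mu, params.kappa, lo, hi)
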