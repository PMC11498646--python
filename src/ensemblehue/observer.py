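"""Parametric model observers — the package's synthetic-data generators.

Three response-producing processes are simulated:

* 2IFC ensemble comparison.  On each trial the observer forms a weighted
  circular mean over the elements of each interval (distractor elements in
  the test interval carry ``distractor_weight`` per element, target and
  comparison elements weight 1), perturbs each interval's estimate with
  independent circular noise, optionally shrinks the test estimate toward
  the across-trials grand mean (central tendency bias), and reports which
  interval's estimate has the higher hue angle.  ``distractor_weight = 0``
  is a perfectly segmenting observer, ``1`` is full integration.

* Categorization.  A noisy von Mises measurement of the stimulus hue is
  assigned to the category whose boundary arc contains it.

* Two-choice green/blue categorization for the staircase task.

All randomness flows through ``numpy.random.Generator`` so that a seed
reproduces response vectors bit for bit.
"""
from __future__ import annotations

import io
import math
from dataclasses import dataclass, asdict
from typing import Callable, Optional

import numpy as np
import pandas as pd

from . import design
from .circular import circular_mean, signed_diff, wrap_hue


@dataclass(frozen=True)
class ObserverParams:
    """Generative parameters of a simulated 2IFC observer.

    Parameters
    ----------
    distractor_weight : float >= 0
        Per-element weight of distractor elements relative to target
        elements (which have weight 1) in the test-interval average.
    internal_noise_sd : float >= 0, degrees
        SD of the wrapped-normal noise added independently to each
        interval's ensemble estimate.  Chosen as wrapped-normal (rather
        than von Mises) so it maps directly onto the cumulative-Gaussian
        psychometric function used in analysis.
    ctb_weight : float in [0, 1]
        Central-tendency pull: linear shrinkage of the test-interval
        estimate toward the across-trials grand mean (which equals the
        nominal target mean under both designs).  0 = pure sensory
        observer.
    lapse_rate : float in [0, 0.5]
        Probability of a uniformly random response.
    subsample_size : int or None
        If set, only this many elements (drawn uniformly without
        replacement from the interval's element pool) enter the average.
    """

    distractor_weight: float = 0.0
    internal_noise_sd: float = 0.0
    ctb_weight: float = 0.0
    lapse_rate: float = 0.0
    subsample_size: Optional[int] = None

    def __post_init__(self):
        if self.distractor_weight < 0:
            raise ValueError("distractor_weight must be nonnegative")
        if self.internal_noise_sd < 0:
            raise ValueError("internal_noise_sd must be nonnegative")
        if not 0.0 <= self.ctb_weight <= 1.0:
            raise ValueError("ctb_weight must be in [0, 1]")
        if not 0.0 <= self.lapse_rate <= 0.5:
            raise ValueError("lapse_rate must be in [0, 0.5]")
        if self.subsample_size is not None and self.subsample_size < 1:
            raise ValueError("subsample_size must be positive")


def estimate_ensemble(hues, weights, params: ObserverParams,
                      rng: np.random.Generator,
                      grand_mean: Optional[float] = None) -> float:
    """One interval's internal ensemble-hue estimate.

    Weighted circular mean of the (optionally subsampled) elements, plus
    wrapped-normal noise, optionally shrunk toward ``grand_mean`` by
    ``ctb_weight``.  If the circular mean is undefined (antipodal
    cancellation) the estimate falls on one of the two perpendicular arcs,
    chosen by a fair coin.
    """
    hues = np.asarray(hues, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if hues.shape != weights.shape:
        raise ValueError("weights must align with hues")
    if params.subsample_size is not None and params.subsample_size < hues.size:
        keep = rng.choice(hues.size, size=params.subsample_size,
                          replace=False)
        hues, weights = hues[keep], weights[keep]
    mean, _ = circular_mean(hues, weights)
    if math.isnan(mean):
        # antipodal cancellation: the doubled-angle mean still gives the
        # data axis; the two candidate means are the midpoints of the two
        # arcs between the opposing clusters (perpendicular to that axis),
        # chosen by fair coin
        axis, r2 = circular_mean(wrap_hue(2.0 * hues), weights)
        if math.isnan(axis):
            mean = float(rng.uniform(0.0, 360.0))
        else:
            mean = wrap_hue(axis / 2.0 + 90.0 + 180.0 * rng.integers(2))
    if params.internal_noise_sd > 0:
        mean = mean + rng.normal(0.0, params.internal_noise_sd)
    if grand_mean is not None and params.ctb_weight > 0:
        mean = grand_mean + (1.0 - params.ctb_weight) * signed_diff(
            mean, grand_mean)
    return wrap_hue(mean)


def simulate_2ifc(schedule, params: ObserverParams, seed) -> pd.DataFrame:
    """Simulate one observer through a trial schedule.

    Returns the schedule frame with ``response`` (1 = judged the comparison
    interval to lie toward higher hue angle than the test), the two internal
    estimates, and a ``lapsed`` flag appended.  Deterministic given
    ``(schedule, params, seed)``.
    """
    rng = np.random.default_rng(seed)
    frame = design.schedule_to_frame(schedule)
    responses = np.empty(len(schedule), dtype=int)
    test_est = np.empty(len(schedule))
    comp_est = np.empty(len(schedule))
    lapsed = np.zeros(len(schedule), dtype=bool)
    for i, t in enumerate(schedule):
        target = design.EnsembleSpec(t.target_mean_nominal, t.hue_range,
                                     role="target")
        hues = design.sample_ensemble(target, t.jitter, rng)
        weights = np.ones(target.n_elements)
        if t.distractor_mean_nominal is not None:
            distractor = design.EnsembleSpec(t.distractor_mean_nominal,
                                             t.hue_range, role="distractor")
            hues = np.concatenate([
                hues, design.sample_ensemble(distractor, t.jitter, rng)])
            weights = np.concatenate([
                weights,
                np.full(distractor.n_elements, params.distractor_weight)])
        test = estimate_ensemble(hues, weights, params, rng,
                                 grand_mean=t.target_mean_nominal)
        comparison = design.EnsembleSpec(
            wrap_hue(t.target_mean_nominal + t.comparison_offset),
            t.hue_range, role="comparison")
        comp_hues = design.sample_ensemble(comparison, t.jitter, rng)
        comp = estimate_ensemble(comp_hues, np.ones(comparison.n_elements),
                                 params, rng)
        resp = 1 if signed_diff(comp, test) > 0 else 0
        if params.lapse_rate > 0 and rng.random() < params.lapse_rate:
            resp = int(rng.integers(2))
            lapsed[i] = True
        responses[i] = resp
        test_est[i] = test
        comp_est[i] = comp
    frame["response"] = responses
    frame["test_estimate_deg"] = test_est
    frame["comparison_estimate_deg"] = comp_est
    frame["lapsed"] = lapsed
    return frame


def _vm_draws(rng, mu_deg, kappa, size=None):
    """Von Mises measurement noise in degrees; kappa = 0 is uniform."""
    mu = np.radians(np.asarray(mu_deg, float))
    if kappa == 0:
        out = rng.uniform(-np.pi, np.pi, size=size if size is not None
                          else mu.shape)
    else:
        out = rng.vonmises(mu, kappa, size=size)
    return wrap_hue(np.degrees(out))


def simulate_categorization(true_model, stimulus_hues, reps: int,
                            seed) -> np.ndarray:
    """Categorization responses of a von Mises category-model observer.

    Each of ``reps`` presentations of each stimulus draws a measurement
    from a von Mises centered on the stimulus with the model's kappa and
    responds with the category whose boundary arc contains the
    measurement.  Returns a ``(n_stimuli, n_categories)`` count matrix.
    """
    rng = np.random.default_rng(seed)
    stim = np.asarray(stimulus_hues, dtype=float)
    measurements = _vm_draws(rng, stim[:, None], true_model.kappa,
                             size=(stim.size, reps))
    assigned = true_model.assign(measurements.ravel()).reshape(stim.size,
                                                               reps)
    k = len(true_model.category_names)
    counts = np.zeros((stim.size, k), dtype=int)
    for j in range(k):
        counts[:, j] = np.sum(assigned == j, axis=1)
    return counts


def staircase_responder(true_boundary: float,
                        kappa: float) -> Callable[[float, np.random.Generator], str]:
    """Two-choice green/blue responder around a fixed category boundary.

    The returned callable takes ``(stimulus_hue, rng)``, draws a von Mises
    measurement of the stimulus, and answers ``"green"`` if the measurement
    falls on the green side of the boundary (lower hue angle, within the
    half-circle below it) and ``"blue"`` otherwise.
    """
    if kappa < 0:
        raise ValueError("kappa must be nonnegative")
    boundary = wrap_hue(float(true_boundary))

    def respond(stimulus_hue: float, rng: np.random.Generator) -> str:
        m = float(_vm_draws(rng, float(stimulus_hue), kappa, size=None))
        return "green" if signed_diff(m, boundary) < 0 else "blue"

    return respond


# ---------------------------------------------------------------------------
# response-log CSV round trip

def write_responses(frame: pd.DataFrame, params: ObserverParams, path):
    """Response log CSV with the observer parameters as a '#' header block."""
    with open(path, "w") as fh:
        for key, value in asdict(params).items():
            fh.write(f"# {key}: {value}\n")
        frame.to_csv(fh, index=False)


def read_responses(path) -> tuple[pd.DataFrame, dict]:
    """Inverse of :func:`write_responses`; returns (frame, header dict)."""
    header = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for line in lines:
        if not line.startswith("#"):
            break
        body_start += 1
        key, _, value = line[1:].partition(":")
        header[key.strip()] = value.strip()
    frame = pd.read_csv(io.StringIO("".join(lines[body_start:])))
    return frame, header
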