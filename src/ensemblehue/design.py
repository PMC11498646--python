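"""Stimulus specifications and trial schedules for the two experiments.

The task is a two-interval forced choice (2IFC): one interval shows the
*test* stimulus — an 18-element target hue ensemble, in most conditions
spatially intermixed with an 18-element distractor ensemble — and the other
shows an 18-element *comparison* ensemble.  The observer judges which
interval had the higher average hue angle.  Element hues are drawn from
uniform distributions on the hue circle; the comparison mean is stepped
through 11 levels around the target mean to trace out a psychometric
function.

Experiment 1 places targets mid-category (pink group at 340 deg, green
group at 130 deg) with distractors at +/-60 deg ("60Y" toward yellow, "60B"
toward blue) or at 180 deg.  Experiment 2 anchors targets at -/+22.5 deg
from each observer's green-blue category boundary, with distractors 45 deg
away either across or within the category.

Direction conventions follow the hue circle (counterclockwise = higher hue
angle): for the pink group "yellower" is the higher hue angle, so 60Y is
+60 deg (340 -> 40) and 60B is -60 deg; for the green group "bluer" is the
higher hue angle, so 60B is +60 deg (130 -> 190) and 60Y is -60 deg.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .circular import wrap_hue

N_ELEMENTS = 18
N_COMPARISON_LEVELS = 11

EXP1_TARGET_MEANS = {"pink": 340.0, "green": 130.0}
EXP2_TARGET_OFFSET_FROM_BOUNDARY = {"green": -22.5, "blue": +22.5}

#: Signed distractor-mean offsets from the target mean, per group/condition.
DISTRACTOR_OFFSETS = {
    "exp1": {
        "pink": {"d180": 180.0, "d60Y": +60.0, "d60B": -60.0},
        "green": {"d180": 180.0, "d60Y": -60.0, "d60B": +60.0},
    },
    "exp2": {
        "green": {"across": +45.0, "within": -45.0, "d180": 180.0},
        "blue": {"across": -45.0, "within": +45.0, "d180": 180.0},
    },
}

#: Comparison-level step sizes in degrees of hue angle.
STEP_SIZES = {
    "exp1": {"baseline": 4.0, "d180": 5.0, "d60Y": 6.0, "d60B": 6.0},
    # the 180-deg block appears in Experiment 2 practice only
    "exp2": {"baseline": 4.0, "across": 7.0, "within": 7.0, "d180": 7.0},
}

HUE_RANGES = {"exp1": 30.0, "exp2": 25.0}
JITTER_LIMITS = {"exp1": 7.5, "exp2": 5.0}
BLOCK_REPEATS = {"exp1": 2, "exp2": 3}
REPS_PER_LEVEL = {"exp1": 10, "exp2": 8}
N_DUMMY_PER_BLOCK = {"exp1": 0, "exp2": 11}
MAIN_CONDITIONS = {
    "exp1": ("baseline", "d180", "d60Y", "d60B"),
    "exp2": ("baseline", "across", "within"),
}
PRACTICE_REPS_PER_LEVEL = 3

#: Half the target-distractor separation: the bias a hypothetical observer
#: averaging all 36 test elements with equal weight would show (equal
#: element counts).  Undefined (nan) at 180 deg — there is no meaningful
#: average of opposing hues.
_FULL_INTEGRATION = {
    "d60Y": 30.0,
    "d60B": 30.0,
    "across": 22.5,
    "within": 22.5,
    "d180": math.nan,
}


@dataclass(frozen=True)
class EnsembleSpec:
    """Parametric description of one 18-element hue ensemble."""

    mean_hue: float
    hue_range: float  # full width of the uniform hue distribution
    n_elements: int = N_ELEMENTS
    role: str = "target"  # target | distractor | comparison

    def __post_init__(self):
        if self.hue_range < 0:
            raise ValueError("hue_range must be nonnegative")
        if self.n_elements < 1:
            raise ValueError("n_elements must be positive")
        if self.role not in ("target", "distractor", "comparison"):
            raise ValueError(f"unknown role {self.role!r}")


@dataclass
class TrialSpec:
    """One 2IFC trial of the ensemble comparison task."""

    experiment: str  # exp1 | exp2
    group: str
    condition: str
    block_index: int
    trial_index: int  # within block, presentation order
    jitter: float  # common jitter of target+distractor means, degrees
    comparison_offset: float  # comparison mean minus (jittered) target mean
    interval_order: str  # test_first | comparison_first
    target_mean_nominal: float
    distractor_mean_nominal: Optional[float] = None
    hue_range: float = 30.0
    is_dummy: bool = False
    is_practice: bool = False


def comparison_levels(step: float) -> np.ndarray:
    """The 11 equally spaced comparison offsets, symmetric about 0."""
    return step * np.arange(-5, 6, dtype=float)


def full_integration_bias(condition: str) -> float:
    """Absolute bias (degrees) predicted by equal-weight averaging of all
    36 test elements; ``nan`` for the 180-deg condition, error for baseline.
    """
    if condition == "baseline":
        raise ValueError("baseline condition has no distractor")
    try:
        return _FULL_INTEGRATION[condition]
    except KeyError:
        raise ValueError(f"unknown condition {condition!r}") from None


def _build_block(experiment, group, condition, block_index, target_mean,
                 rng, *, reps_per_level, levels=None, n_dummy=0,
                 is_practice=False):
    step = STEP_SIZES[experiment][condition]
    if levels is None:
        levels = comparison_levels(step)
    jitter_limit = JITTER_LIMITS[experiment]
    hue_range = HUE_RANGES[experiment]
    offset = DISTRACTOR_OFFSETS[experiment][group].get(condition)
    distractor_mean = None if condition == "baseline" else wrap_hue(
        target_mean + offset)

    offsets = np.repeat(np.asarray(levels, float), reps_per_level)
    offsets = rng.permutation(offsets)
    if n_dummy:
        # dummy trials lead the block while the distractor dots grow in;
        # they reuse the block's comparison levels and are never analyzed
        dummy_offsets = rng.permutation(comparison_levels(step))[:n_dummy]
        offsets = np.concatenate([dummy_offsets, offsets])

    trials = []
    for i, comp in enumerate(offsets):
        trials.append(TrialSpec(
            experiment=experiment,
            group=group,
            condition=condition,
            block_index=block_index,
            trial_index=i,
            jitter=float(rng.uniform(-jitter_limit, jitter_limit)),
            comparison_offset=float(comp),
            interval_order=("test_first" if rng.random() < 0.5
                            else "comparison_first"),
            target_mean_nominal=float(target_mean),
            distractor_mean_nominal=(None if distractor_mean is None
                                     else float(distractor_mean)),
            hue_range=hue_range,
            is_dummy=i < n_dummy,
            is_practice=is_practice,
        ))
    return trials


def build_exp1_schedule(group: str, seed: int) -> list[TrialSpec]:
    """Main-task schedule for Experiment 1.

    8 blocks (4 conditions x 2 repeats, order shuffled by ``seed``), each
    with 10 repetitions of the 11 comparison levels in shuffled order:
    880 trials total.
    """
    if group not in EXP1_TARGET_MEANS:
        raise ValueError(f"unknown exp1 group {group!r}")
    rng = np.random.default_rng(seed)
    target = EXP1_TARGET_MEANS[group]
    order = rng.permutation(
        list(MAIN_CONDITIONS["exp1"]) * BLOCK_REPEATS["exp1"])
    trials = []
    for b, cond in enumerate(order):
        trials.extend(_build_block(
            "exp1", group, str(cond), b, target, rng,
            reps_per_level=REPS_PER_LEVEL["exp1"]))
    return trials


def build_exp2_schedule(group: str, green_blue_boundary: float,
                        seed: int) -> list[TrialSpec]:
    """Main-task schedule for Experiment 2.

    The target mean sits 22.5 deg from the observer's green-blue boundary
    (green group below, blue group above).  9 blocks (3 conditions x 3
    repeats, shuffled), each with 8 repetitions of the 11 levels (88
    analyzed trials) preceded by 11 dummy trials flagged ``is_dummy``:
    792 analyzed trials total.
    """
    if group not in EXP2_TARGET_OFFSET_FROM_BOUNDARY:
        raise ValueError(f"unknown exp2 group {group!r}")
    rng = np.random.default_rng(seed)
    target = wrap_hue(float(green_blue_boundary)
                      + EXP2_TARGET_OFFSET_FROM_BOUNDARY[group])
    order = rng.permutation(
        list(MAIN_CONDITIONS["exp2"]) * BLOCK_REPEATS["exp2"])
    trials = []
    for b, cond in enumerate(order):
        trials.extend(_build_block(
            "exp2", group, str(cond), b, target, rng,
            reps_per_level=REPS_PER_LEVEL["exp2"],
            n_dummy=N_DUMMY_PER_BLOCK["exp2"]))
    return trials


def build_practice_schedule(experiment: str, group: str, seed: int,
                            green_blue_boundary: Optional[float] = None,
                            ) -> list[TrialSpec]:
    """Practice schedule: one 18-trial block per condition.

    Only the six outermost comparison levels (three per side) are used,
    three repetitions each; the zero offset never appears.  Block order is
    baseline first, then the 180-deg block, then the remaining distractor
    conditions in random order.  Experiment 2 practice includes a 180-deg
    block on top of its three main conditions (4 blocks, 72 trials, as in
    Experiment 1).
    """
    if experiment not in MAIN_CONDITIONS:
        raise ValueError(f"unknown experiment {experiment!r}")
    rng = np.random.default_rng(seed)
    if experiment == "exp1":
        if group not in EXP1_TARGET_MEANS:
            raise ValueError(f"unknown exp1 group {group!r}")
        target = EXP1_TARGET_MEANS[group]
        remaining = ["d60Y", "d60B"]
    else:
        if group not in EXP2_TARGET_OFFSET_FROM_BOUNDARY:
            raise ValueError(f"unknown exp2 group {group!r}")
        if green_blue_boundary is None:
            raise ValueError("exp2 practice needs a green-blue boundary")
        target = wrap_hue(float(green_blue_boundary)
                          + EXP2_TARGET_OFFSET_FROM_BOUNDARY[group])
        remaining = ["across", "within"]
    order = ["baseline", "d180"] + [str(c) for c in rng.permutation(remaining)]
    trials = []
    for b, cond in enumerate(order):
        levels = comparison_levels(STEP_SIZES[experiment][cond])
        outer = np.concatenate([levels[:3], levels[-3:]])
        trials.extend(_build_block(
            experiment, group, cond, b, target, rng,
            reps_per_level=PRACTICE_REPS_PER_LEVEL, levels=outer,
            is_practice=True))
    return trials


def build_condition_trials(experiment: str, group: str, condition: str,
                           n_per_level: int, seed: int,
                           green_blue_boundary: Optional[float] = None,
                           ) -> list[TrialSpec]:
    """A single-condition block with ``n_per_level`` repetitions of the 11
    comparison levels — the workhorse for targeted simulations that need
    more trials per condition than one experiment provides."""
    rng = np.random.default_rng(seed)
    if experiment == "exp1":
        if group not in EXP1_TARGET_MEANS:
            raise ValueError(f"unknown exp1 group {group!r}")
        target = EXP1_TARGET_MEANS[group]
    elif experiment == "exp2":
        if group not in EXP2_TARGET_OFFSET_FROM_BOUNDARY:
            raise ValueError(f"unknown exp2 group {group!r}")
        if green_blue_boundary is None:
            raise ValueError("exp2 trials need a green-blue boundary")
        target = wrap_hue(float(green_blue_boundary)
                          + EXP2_TARGET_OFFSET_FROM_BOUNDARY[group])
    else:
        raise ValueError(f"unknown experiment {experiment!r}")
    return _build_block(experiment, group, condition, 0, target, rng,
                        reps_per_level=n_per_level)


def sample_ensemble(spec: EnsembleSpec, trial_jitter: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Draw the element hues of one ensemble on one trial.

    Hues are i.i.d. uniform on ``mean + jitter +/- range/2``, wrapped to
    the hue circle.
    """
    center = spec.mean_hue + trial_jitter
    half = spec.hue_range / 2.0
    return wrap_hue(rng.uniform(center - half, center + half,
                                spec.n_elements))


def sample_dot_positions(rng: np.random.Generator,
                         n: int = 36) -> np.ndarray:
    """Spatial metadata: dot centers in degrees of visual angle.

    A 6-by-6 grid with 1-deg spacing, the whole grid jittered up to 1 deg
    and each dot up to 0.2 deg in a random direction.  Recorded for
    completeness only; no analysis uses position.
    """
    gx, gy = np.meshgrid(np.arange(6, dtype=float), np.arange(6, dtype=float))
    pos = np.column_stack([gx.ravel(), gy.ravel()])[:n]
    theta = rng.uniform(0, 2 * np.pi)
    r = rng.uniform(0, 1.0)
    pos += r * np.array([np.cos(theta), np.sin(theta)])
    th = rng.uniform(0, 2 * np.pi, n)
    rr = rng.uniform(0, 0.2, n)
    pos += np.column_stack([rr * np.cos(th), rr * np.sin(th)])
    return pos


# ---------------------------------------------------------------------------
# serialization

_FRAME_COLUMNS = [
    "experiment", "group", "block", "trial", "condition", "jitter_deg",
    "comparison_offset_deg", "interval_order", "target_mean_deg",
    "distractor_mean_deg", "comparison_mean_deg", "hue_range_deg",
    "is_dummy", "is_practice",
]


def schedule_to_frame(trials: list[TrialSpec]) -> pd.DataFrame:
    """One row per trial.  ``comparison_mean_deg`` records the absolute
    comparison mean (target + jitter + offset) so that offsets re-anchored
    to the nominal rather than the jittered target mean stay recoverable.
    """
    rows = []
    for t in trials:
        rows.append({
            "experiment": t.experiment,
            "group": t.group,
            "block": t.block_index,
            "trial": t.trial_index,
            "condition": t.condition,
            "jitter_deg": t.jitter,
            "comparison_offset_deg": t.comparison_offset,
            "interval_order": t.interval_order,
            "target_mean_deg": t.target_mean_nominal,
            "distractor_mean_deg": (math.nan if t.distractor_mean_nominal
                                    is None else t.distractor_mean_nominal),
            "comparison_mean_deg": wrap_hue(t.target_mean_nominal + t.jitter
                                            + t.comparison_offset),
            "hue_range_deg": t.hue_range,
            "is_dummy": t.is_dummy,
            "is_practice": t.is_practice,
        })
    return pd.DataFrame(rows, columns=_FRAME_COLUMNS)


def frame_to_schedule(frame: pd.DataFrame) -> list[TrialSpec]:
    trials = []
    for _, r in frame.iterrows():
        d = r["distractor_mean_deg"]
        trials.append(TrialSpec(
            experiment=str(r["experiment"]),
            group=str(r["group"]),
            condition=str(r["condition"]),
            block_index=int(r["block"]),
            trial_index=int(r["trial"]),
            jitter=float(r["jitter_deg"]),
            comparison_offset=float(r["comparison_offset_deg"]),
            interval_order=str(r["interval_order"]),
            target_mean_nominal=float(r["target_mean_deg"]),
            distractor_mean_nominal=None if pd.isna(d) else float(d),
            hue_range=float(r["hue_range_deg"]),
            is_dummy=bool(r["is_dummy"]),
            is_practice=bool(r["is_practice"]),
        ))
    return trials


def default_config() -> dict:
    """Every design constant in one serializable mapping."""
    return {
        "n_elements": N_ELEMENTS,
        "n_comparison_levels": N_COMPARISON_LEVELS,
        "exp1": {
            "target_means": dict(EXP1_TARGET_MEANS),
            "hue_range": HUE_RANGES["exp1"],
            "jitter_limit": JITTER_LIMITS["exp1"],
            "step_sizes": dict(STEP_SIZES["exp1"]),
            "distractor_offsets": {g: dict(v) for g, v in
                                   DISTRACTOR_OFFSETS["exp1"].items()},
            "block_repeats": BLOCK_REPEATS["exp1"],
            "reps_per_level": REPS_PER_LEVEL["exp1"],
        },
        "exp2": {
            "target_offset_from_boundary":
                dict(EXP2_TARGET_OFFSET_FROM_BOUNDARY),
            "hue_range": HUE_RANGES["exp2"],
            "jitter_limit": JITTER_LIMITS["exp2"],
            "step_sizes": dict(STEP_SIZES["exp2"]),
            "distractor_offsets": {g: dict(v) for g, v in
                                   DISTRACTOR_OFFSETS["exp2"].items()},
            "block_repeats": BLOCK_REPEATS["exp2"],
            "reps_per_level": REPS_PER_LEVEL["exp2"],
            "dummy_trials_per_block": N_DUMMY_PER_BLOCK["exp2"],
        },
        "practice": {
            "reps_per_level": PRACTICE_REPS_PER_LEVEL,
            "outer_levels_per_side": 3,
        },
    }


def write_config(path, config=None):
    config = default_config() if config is None else config
    text = (json.dumps(config, indent=2) if str(path).endswith(".json")
            else yaml.safe_dump(config, sort_keys=False))
    with open(path, "w") as fh:
        fh.write(text)


def read_config(path) -> dict:
    with open(path) as fh:
        if str(path).endswith(".json"):
            return json.load(fh)
        return yaml.safe_load(fh)
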