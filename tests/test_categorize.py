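import numpy as np
import pytest

from ensemblehue import categorize, observer
from ensemblehue.categorize import (
    CategoryDataset,
    category_centroids,
    clean_category_data,
    fit_boundary_model,
    run_staircase,
)
from ensemblehue.circular import signed_diff, wrap_hue
from .conftest import STIM_GRID, two_category_model, vector_sum_mean


def toy_dataset(cells, names, stim=None):
    """Counts from {(stim_hue, category): n} mapping."""
    stim = STIM_GRID if stim is None else np.asarray(stim, float)
    counts = np.zeros((stim.size, len(names)), dtype=int)
    index = {h: i for i, h in enumerate(stim)}
    for (hue, cat), n in cells.items():
        counts[index[hue], names.index(cat)] = n
    return CategoryDataset(stim, counts, list(names))


def test_sparse_category_dropped():
    data = toy_dataset({(100.0, "green"): 2, (105.0, "green"): 2,
                        (110.0, "green"): 2,
                        (30.0, "red"): 2, (35.0, "red"): 1},
                       ["green", "red"])
    cleaned, report = clean_category_data(data)
    assert report.dropped_categories == ["red"]
    assert cleaned.category_names == ["green"]


def test_isolated_response_removed():
    """A response split off the main run and >= 20 deg away is excluded;
    a response joined to the run across a short gap survives."""
    cells = {(h, "green"): 2 for h in (100.0, 105.0, 110.0, 115.0, 120.0,
                                       125.0, 130.0, 135.0, 140.0)}
    cells[(150.0, "green")] = 1  # two empty steps: still the same run, kept
    cells[(170.0, "green")] = 1  # three empty steps off, 20 deg: removed
    data = toy_dataset(cells, ["green"])
    cleaned, report = clean_category_data(data)
    assert report.removed_responses == [(170.0, "green", 1)]
    assert cleaned.counts[list(STIM_GRID).index(150.0), 0] == 1
    assert cleaned.counts[list(STIM_GRID).index(170.0), 0] == 0


def test_clean_wraps_around_the_circle():
    cells = {(h, "pink"): 2 for h in (345.0, 350.0, 355.0, 0.0, 5.0)}
    cells[(40.0, "pink")] = 1  # 35 deg beyond: removed
    data = toy_dataset(cells, ["pink"])
    cleaned, report = clean_category_data(data)
    assert report.removed_responses == [(40.0, "pink", 1)]
    assert cleaned.counts.sum() == 10


def test_clean_is_idempotent_and_preserves_clean_data(stim_grid):
    model = two_category_model(10.0)
    counts = observer.simulate_categorization(model, stim_grid, 4, seed=0)
    raw = CategoryDataset(stim_grid, counts, list(model.category_names))
    once, _ = clean_category_data(raw)
    twice, report = clean_category_data(once)
    assert np.array_equal(once.counts, twice.counts)
    assert not report.dropped_categories and not report.removed_responses


def test_clean_errors_when_everything_excluded():
    data = toy_dataset({(10.0, "red"): 1}, ["red"])
    with pytest.raises(ValueError):
        clean_category_data(data)


def test_centroid_symmetric():
    data = toy_dataset({(120.0, "g"): 1, (130.0, "g"): 1, (140.0, "g"): 1},
                       ["g"])
    assert category_centroids(data)[0] == pytest.approx(130.0)


def test_centroid_wraparound():
    data = toy_dataset({(350.0, "p"): 2, (10.0, "p"): 2}, ["p"])
    assert category_centroids(data)[0] == pytest.approx(0.0, abs=1e-9)


def test_centroid_matches_vector_sum_oracle():
    rng = np.random.default_rng(7)
    counts = rng.integers(0, 4, size=STIM_GRID.size)
    data = CategoryDataset(STIM_GRID, counts[:, None], ["x"])
    expected = vector_sum_mean(STIM_GRID, counts.astype(float))
    assert category_centroids(data)[0] == pytest.approx(expected, abs=1e-9)


def test_centroid_empty_category_errors():
    data = toy_dataset({(10.0, "a"): 1}, ["a", "b"])
    with pytest.raises(ValueError):
        category_centroids(data)


def _dataset_nll(model, data):
    """Independent NLL evaluation from the model's probability matrix."""
    p = model.response_probabilities(data.stimulus_hues)
    order = [model.category_names.index(n) for n in data.category_names]
    return -np.sum(data.counts * np.log(np.clip(p[:, order], 1e-300, None)))


def test_boundary_fit_noiseless_recovery(stim_grid):
    true = two_category_model(1e6)
    counts = observer.simulate_categorization(true, stim_grid, 4, seed=1)
    raw = CategoryDataset(stim_grid, counts, list(true.category_names))
    cleaned, _ = clean_category_data(raw)
    fit = fit_boundary_model(cleaned)
    gb = fit.model.boundary_between("green", "other")
    yg = fit.model.boundary_between("other", "green")
    assert abs(signed_diff(gb, 168.1)) < 5.0  # within one stimulus step
    assert abs(signed_diff(yg, 78.1)) < 5.0


def test_boundary_fit_nll_not_worse_than_truth(stim_grid):
    true = two_category_model(10.0)
    counts = observer.simulate_categorization(true, stim_grid, 4, seed=2)
    raw = CategoryDataset(stim_grid, counts, list(true.category_names))
    cleaned, _ = clean_category_data(raw)
    fit = fit_boundary_model(cleaned)
    assert fit.nll <= _dataset_nll(true, cleaned) + 1e-6
    assert fit.converged


def test_boundary_fit_rotation_equivariant(stim_grid):
    rotation = 40.0
    true = two_category_model(10.0)
    counts = observer.simulate_categorization(true, stim_grid, 4, seed=3)
    base = fit_boundary_model(CategoryDataset(
        stim_grid, counts, list(true.category_names)))
    rotated = fit_boundary_model(CategoryDataset(
        wrap_hue(stim_grid + rotation), counts,
        list(true.category_names)))
    for name_pair in [("green", "other"), ("other", "green")]:
        b0 = base.model.boundary_between(*name_pair)
        b1 = rotated.model.boundary_between(*name_pair)
        assert abs(signed_diff(b1, b0 + rotation)) < 1e-3
    assert rotated.model.kappa == pytest.approx(base.model.kappa, rel=1e-4)


def test_boundary_fit_requires_two_categories():
    data = toy_dataset({(100.0, "g"): 4, (105.0, "g"): 4}, ["g"])
    with pytest.raises(ValueError):
        fit_boundary_model(data)


def test_staircase_deterministic_responder_converges():
    respond = observer.staircase_responder(168.0, 1e6)
    result = run_staircase(respond, 168.0, seed=0)
    assert abs(signed_diff(result.estimate, 168.0)) < 1.0
    assert len(result.trace) == 100  # 4 staircases x 25 trials


def test_staircase_step_shrinks_by_one_fourth():
    respond = observer.staircase_responder(168.0, 1e6)
    trace = run_staircase(respond, 168.0, seed=0).trace
    sc = trace[trace["staircase_id"] == 0]
    first_rev = sc[sc["is_reversal"]].iloc[0]
    assert first_rev["step_deg"] == pytest.approx(3.0)
    assert sc["step_deg"].iloc[0] == pytest.approx(4.0)
    assert trace["step_deg"].min() >= 0.25


def test_staircase_starts_interleaved_round_robin():
    respond = observer.staircase_responder(168.0, 1e6)
    trace = run_staircase(respond, 168.0, seed=0).trace
    assert trace["staircase_id"].iloc[:4].tolist() == [0, 1, 2, 3]
    starts = trace.groupby("staircase_id")["stimulus_hue_deg"].first()
    assert sorted(starts) == [148.0, 148.0, 188.0, 188.0]


def test_staircase_without_reversals_warns_then_errors():
    stuck = lambda stim, rng: "green"  # noqa: E731 — never reverses
    with pytest.warns(UserWarning):
        with pytest.raises(ValueError):
            run_staircase(stuck, 168.0, seed=0)


def test_staircase_mean_error_small_at_moderate_noise():
    errors = []
    for seed in range(40):
        respond = observer.staircase_responder(168.0, 20.0)
        errors.append(signed_diff(run_staircase(respond, 168.0,
                                                seed=seed).estimate, 168.0))
    assert abs(np.mean(errors)) < 1.0
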