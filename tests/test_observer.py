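import numpy as np
import pytest
from scipy import stats as sstats

from ensemblehue import design, observer
from ensemblehue.circular import arc_probability, signed_diff
from ensemblehue.observer import ObserverParams, estimate_ensemble
from .conftest import two_category_model, vector_sum_mean


def noiseless(w=0.0, **kw):
    return ObserverParams(distractor_weight=w, internal_noise_sd=0.0, **kw)


def test_estimate_mean_of_pair():
    rng = np.random.default_rng(0)
    est = estimate_ensemble([338.0, 342.0], [1.0, 1.0], noiseless(), rng)
    assert est == pytest.approx(340.0)


def test_estimate_full_integration_midpoint():
    rng = np.random.default_rng(0)
    hues = np.concatenate([np.full(18, 340.0), np.full(18, 40.0)])
    weights = np.concatenate([np.ones(18), np.ones(18)])
    est = estimate_ensemble(hues, weights, noiseless(w=1.0), rng)
    assert est == pytest.approx(10.0)


def test_estimate_downweighted_matches_vector_sum_oracle():
    rng = np.random.default_rng(0)
    hues = np.concatenate([np.full(18, 340.0), np.full(18, 40.0)])
    weights = np.concatenate([np.ones(18), np.full(18, 1.0 / 3.0)])
    est = estimate_ensemble(hues, weights, noiseless(w=1 / 3), rng)
    assert est == pytest.approx(vector_sum_mean(hues, weights), abs=1e-9)


def test_estimate_antipodal_resolved_by_coin():
    rng = np.random.default_rng(3)
    draws = {round(estimate_ensemble([0.0, 180.0], [1.0, 1.0],
                                     noiseless(), rng))
             for _ in range(50)}
    assert draws <= {90.0, 270.0}
    assert len(draws) == 2  # both arcs occur


def test_estimate_ctb_shrinks_toward_grand_mean():
    rng = np.random.default_rng(0)
    params = ObserverParams(ctb_weight=0.5)
    est = estimate_ensemble([20.0], [1.0], params, rng, grand_mean=0.0)
    assert est == pytest.approx(10.0)


def test_estimate_subsample_uses_requested_count():
    rng = np.random.default_rng(0)
    params = ObserverParams(subsample_size=1)
    hues = np.array([10.0, 50.0])
    seen = {estimate_ensemble(hues, np.ones(2), params, rng)
            for _ in range(30)}
    assert seen == {10.0, 50.0}


def test_observer_params_validation():
    with pytest.raises(ValueError):
        ObserverParams(distractor_weight=-0.1)
    with pytest.raises(ValueError):
        ObserverParams(lapse_rate=0.9)
    with pytest.raises(ValueError):
        ObserverParams(ctb_weight=1.5)


def _zero_range_trials(condition="baseline", n_per_level=2):
    trials = design.build_condition_trials("exp1", "pink", condition,
                                           n_per_level, seed=0)
    for t in trials:
        t.hue_range = 0.0
    return trials


def test_noiseless_segregating_observer_follows_offset_sign():
    """With no hue scatter and no internal noise, responses equal the
    comparison-offset sign exactly."""
    trials = [t for t in _zero_range_trials(n_per_level=3)
              if t.comparison_offset != 0.0]
    frame = observer.simulate_2ifc(trials, noiseless(), seed=1)
    expected = (frame["comparison_offset_deg"] > 0).astype(int)
    assert (frame["response"] == expected).all()


def test_simulate_2ifc_deterministic():
    trials = design.build_exp1_schedule("green", seed=2)[:120]
    params = ObserverParams(distractor_weight=0.5, internal_noise_sd=3.0,
                            lapse_rate=0.05)
    a = observer.simulate_2ifc(trials, params, seed=9)
    b = observer.simulate_2ifc(trials, params, seed=9)
    assert a.equals(b)
    c = observer.simulate_2ifc(trials, params, seed=10)
    assert not a["response"].equals(c["response"])


def test_lapse_rate_flags_expected_fraction():
    trials = _zero_range_trials(n_per_level=100)
    params = ObserverParams(lapse_rate=0.4)
    frame = observer.simulate_2ifc(trials, params, seed=5)
    assert frame["lapsed"].mean() == pytest.approx(0.4, abs=0.03)


def test_response_log_round_trip(tmp_path):
    trials = design.build_exp1_schedule("pink", seed=0)[:50]
    params = ObserverParams(distractor_weight=0.25, internal_noise_sd=2.0)
    frame = observer.simulate_2ifc(trials, params, seed=3)
    path = tmp_path / "responses.csv"
    observer.write_responses(frame, params, path)
    back, header = observer.read_responses(path)
    assert header["distractor_weight"] == "0.25"
    assert len(back) == len(frame)
    assert (back["response"].to_numpy()
            == frame["response"].to_numpy()).all()


def test_categorization_noiseless_matches_arcs(stim_grid):
    model = two_category_model(1e6)
    counts = observer.simulate_categorization(model, stim_grid, reps=4,
                                              seed=0)
    assigned = model.assign(stim_grid)
    for i, cat in enumerate(assigned):
        assert counts[i, cat] == 4 and counts[i].sum() == 4


def test_categorization_uniform_limit_proportional_to_arcs():
    model = two_category_model(0.0)
    counts = observer.simulate_categorization(model, [200.0], reps=10_000,
                                              seed=1)[0]
    arcs = np.array([90.0, 270.0]) / 360.0  # green arc 78.1 -> 168.1
    _, p = sstats.chisquare(counts, arcs * counts.sum())
    assert p > 0.01


def test_categorization_frequencies_match_vm_interval_oracle(stim_grid):
    model = two_category_model(10.0)
    reps = 2000
    counts = observer.simulate_categorization(model, stim_grid, reps,
                                              seed=2)
    freq = counts / reps
    expected = model.response_probabilities(stim_grid)
    assert np.max(np.abs(freq - expected)) < 0.04


def test_staircase_responder_deterministic_limit():
    respond = observer.staircase_responder(168.0, 1e6)
    rng = np.random.default_rng(0)
    assert all(respond(163.0, rng) == "green" for _ in range(20))
    assert all(respond(173.0, rng) == "blue" for _ in range(20))


def test_staircase_responder_is_fair_at_boundary():
    respond = observer.staircase_responder(168.0, 25.0)
    rng = np.random.default_rng(1)
    greens = sum(respond(168.0, rng) == "green" for _ in range(10_000))
    assert greens / 10_000 == pytest.approx(0.5, abs=0.02)


def test_staircase_responder_psychometric_matches_vm_cdf():
    kappa, boundary, reps = 20.0, 168.0, 10_000
    respond = observer.staircase_responder(boundary, kappa)
    rng = np.random.default_rng(2)
    for stim in (158.0, 163.0, 168.0, 173.0):
        greens = sum(respond(stim, rng) == "green" for _ in range(reps))
        expected = arc_probability(stim, kappa, boundary - 180.0, boundary)
        assert greens / reps == pytest.approx(expected, abs=0.02)


def test_parameter_recovery_of_distractor_weight():
    """Fitted bias matches the weighted-vector-sum prediction for the
    mixing observer across segmentation regimes (0 = perfect segmentation,
    1 = full integration)."""
    from ensemblehue import psychometrics

    for w, seed in [(0.0, 10), (1.0 / 3.0, 11), (1.0, 12)]:
        trials = design.build_condition_trials("exp1", "pink", "d60Y",
                                               n_per_level=500, seed=seed)
        params = ObserverParams(distractor_weight=w, internal_noise_sd=4.0)
        frame = observer.simulate_2ifc(trials, params, seed=seed)
        fit = psychometrics.fit_condition(frame)
        measure = psychometrics.bias_toward_distractor(fit, "d60Y", 340.0,
                                                       40.0)
        predicted_shift = signed_diff(
            vector_sum_mean([0.0, 60.0], [1.0, w]), 0.0)
        predicted_fraction = predicted_shift / 30.0
        assert measure.bias_fraction == pytest.approx(predicted_fraction,
                                                      abs=0.05)


def test_threshold_monotone_in_internal_noise():
    from ensemblehue import psychometrics

    sigmas = []
    for noise in (1.0, 4.0, 10.0):
        trials = design.build_condition_trials("exp1", "pink", "baseline",
                                               n_per_level=500, seed=21)
        params = ObserverParams(internal_noise_sd=noise)
        frame = observer.simulate_2ifc(trials, params, seed=22)
        sigmas.append(psychometrics.fit_condition(frame).sigma)
    assert sigmas[0] < sigmas[1] < sigmas[2]
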