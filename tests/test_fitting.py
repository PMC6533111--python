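"""Tests of z-scoring, likelihood arithmetic, the optimizer against a
brute-force grid oracle, model comparison and split-half reliability."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from priorweight import (
    BaselineParams,
    FitConfig,
    ModelVariant,
    ObserverParams,
    TaskConfig,
    bic,
    compare_models,
    fit_subject,
    generate_cohort,
    generate_session,
    grid_mle_oracle,
    mcfadden_pseudo_r2,
    negative_log_likelihood,
    simulate_responses,
    split_half_reliability,
    zscore_vg,
)
from conftest import make_responses, make_trials

FAST = FitConfig(n_starts=6, seed=0)


# ---- z-scoring ----

def test_zscore_mean_zero_sd_one(experiment):
    vgp, tf = zscore_vg(experiment)
    assert np.mean(vgp) == pytest.approx(0.0, abs=1e-12)
    assert np.std(vgp) == pytest.approx(1.0, abs=1e-12)
    # stored transform reapplies identically
    assert np.allclose(tf(experiment["v_g"]), vgp)


def test_zscore_two_values_map_to_unit():
    vgp, _ = zscore_vg(np.array([2.0, 6.0]))
    assert np.allclose(sorted(vgp), [-1.0, 1.0])


def test_zscore_affine_invariance(experiment):
    vgp, _ = zscore_vg(experiment)
    scaled, _ = zscore_vg(3.5 * experiment["v_g"].to_numpy() + 2.0)
    assert np.allclose(scaled, vgp)


def test_zscore_constant_errors():
    with pytest.raises(ValueError):
        zscore_vg(np.array([3.0, 3.0, 3.0]))


# ---- likelihood arithmetic ----

def _two_trial_fixture():
    """Two trials where the posterior mean is analytically known:
    v_bar=0, a_g=0 gives w=1/2 exactly, b_g=0 gives s=omega."""
    trials = make_trials([15, 15], ["low", "low"], [18, 16], [24, 18])
    params = ObserverParams(0.0, 0.0, 0.0, 1.0, 1.0, 0.0)
    mu_hat = 0.5 * trials["mu_g"].to_numpy() + 0.5 * 15
    responses = make_responses(trials, mu_hat)
    return trials, responses, params


def test_nll_at_posterior_mode():
    trials, responses, params = _two_trial_fixture()
    nll = negative_log_likelihood(params, ModelVariant.FULL, trials, responses)
    assert nll == pytest.approx(2 * 0.9189385332046727, abs=1e-9)


def test_nll_additivity():
    trials, responses, params = _two_trial_fixture()
    doubled_t = pd.concat([trials, trials], ignore_index=True)
    doubled_t["trial_index"] = np.arange(len(doubled_t))
    doubled_r = pd.concat([responses, responses], ignore_index=True)
    doubled_r["trial_index"] = np.arange(len(doubled_r))
    one = negative_log_likelihood(params, ModelVariant.FULL, trials, responses)
    two = negative_log_likelihood(params, ModelVariant.FULL, doubled_t, doubled_r)
    assert two == pytest.approx(2 * one, abs=1e-9)


def test_nll_infinite_when_sd_nonpositive():
    trials, responses, _ = _two_trial_fixture()
    bad = ObserverParams(0.0, 0.0, 0.0, 0.5, 0.5, 2.0)  # s = 0.5 - 2 at vg'=-1
    assert negative_log_likelihood(bad, ModelVariant.FULL, trials, responses) == np.inf


def test_nll_misaligned_inputs_error(experiment, subject):
    _, responses = subject
    with pytest.raises(ValueError):
        negative_log_likelihood(
            ObserverParams(0, 0, 0, 1, 1, 0), ModelVariant.FULL,
            experiment.iloc[:100], responses.iloc[:99],
        )


def test_baseline_nll_ignores_trial_structure():
    trials, responses, _ = _two_trial_fixture()
    shuffled = trials.iloc[::-1].reset_index(drop=True)
    shuffled[["session_index", "trial_index"]] = trials[["session_index", "trial_index"]]
    p = BaselineParams(17.0, 2.0)
    a = negative_log_likelihood(p, ModelVariant.BASELINE, trials, responses)
    b = negative_log_likelihood(p, ModelVariant.BASELINE, shuffled, responses)
    assert a == pytest.approx(b)


# ---- information criteria ----

def test_bic_arithmetic():
    assert bic(800.0, 6, 480) == pytest.approx(1600 + 6 * np.log(480), abs=1e-9)
    assert bic(800.0, 0, 480) == 1600.0
    assert bic(800.0, 6, 1) == 1600.0
    with pytest.raises(ValueError):
        bic(800.0, 6, 0)


def test_pseudo_r2_edges():
    assert mcfadden_pseudo_r2(100.0, 100.0) == 0.0
    with pytest.warns(UserWarning):
        assert mcfadden_pseudo_r2(120.0, 100.0) < 0
    with pytest.raises(ValueError):
        mcfadden_pseudo_r2(1.0, 0.0)


# ---- optimizer vs grid oracle ----

@pytest.fixture(scope="module")
def small_subject():
    cfg = TaskConfig(n_sessions=1, trials_per_session=160, seed=42)
    trials = generate_session(cfg, 0)
    params = ObserverParams(-0.1, 1.0, 0.5, 1.5, 2.5, 0.4)
    responses = simulate_responses(trials, params, rng=np.random.default_rng(6))
    return trials, responses, params


def test_optimizer_matches_grid_on_baseline(small_subject):
    trials, responses, _ = small_subject
    r = responses["R"].to_numpy(dtype=float)
    m_axis = np.linspace(r.mean() - 1, r.mean() + 1, 81)
    s_axis = np.linspace(max(r.std() - 1, 0.1), r.std() + 1, 81)
    grid_x, grid_nll = grid_mle_oracle(
        trials, responses, ModelVariant.BASELINE, {"m": m_axis, "s": s_axis}
    )
    fit = fit_subject(trials, responses, ModelVariant.BASELINE, FAST)
    # grid resolution slack: the oracle cannot beat the optimizer by more
    # than the local curvature over one grid step
    assert fit.nll <= grid_nll + 1e-6
    assert grid_nll - fit.nll < 0.05
    assert np.allclose(grid_x, fit.x, atol=0.05)


def test_optimizer_not_worse_than_full_model_grid(small_subject):
    trials, responses, truth = small_subject
    grid = {
        "v_bar_L": np.linspace(-1, 1, 9),
        "v_bar_H": np.linspace(0, 2, 9),
        "a_g": np.array([truth.a_g]),
        "omega_L": np.linspace(0.5, 3, 6),
        "omega_H": np.linspace(0.5, 4, 6),
        "b_g": np.array([truth.b_g]),
    }
    _, grid_nll = grid_mle_oracle(trials, responses, ModelVariant.FULL, grid)
    fit = fit_subject(trials, responses, ModelVariant.FULL, FAST)
    assert fit.nll <= grid_nll + 1e-6


def test_grid_oracle_contracts(small_subject):
    trials, responses, _ = small_subject
    x, nll = grid_mle_oracle(
        trials, responses, ModelVariant.BASELINE,
        {"m": np.array([17.0]), "s": np.array([2.0])},
    )
    assert np.allclose(x, [17.0, 2.0])
    coarse = {"m": np.linspace(14, 20, 7), "s": np.linspace(1, 4, 7)}
    fine = {"m": np.linspace(14, 20, 25), "s": np.linspace(1, 4, 25)}
    _, nll_coarse = grid_mle_oracle(trials, responses, ModelVariant.BASELINE, coarse)
    _, nll_fine = grid_mle_oracle(trials, responses, ModelVariant.BASELINE, fine)
    assert nll_fine <= nll_coarse + 1e-12
    with pytest.raises(ValueError):
        grid_mle_oracle(trials, responses, ModelVariant.BASELINE,
                        {"m": np.zeros(2000), "s": np.zeros(2000)})
    with pytest.raises(ValueError):
        grid_mle_oracle(trials, responses, ModelVariant.BASELINE, {"m": np.array([17.0])})


# ---- fit_subject behaviour ----

def test_fit_beats_generating_parameters(small_subject):
    trials, responses, truth = small_subject
    fit = fit_subject(trials, responses, ModelVariant.FULL, FAST)
    nll_truth = negative_log_likelihood(truth, ModelVariant.FULL, trials, responses)
    assert fit.nll <= nll_truth + 1e-6
    assert fit.bic == pytest.approx(bic(fit.nll, 6, len(trials)))


def test_fit_observation_dominant_limit():
    """Data generated with w ~ 1 should drive the fitted v_bar strongly
    negative (weight saturating toward the observations)."""
    cfg = TaskConfig(n_sessions=1, trials_per_session=120, seed=8)
    trials = generate_session(cfg, 0)
    params = ObserverParams(-6.0, -6.0, 0.0, 0.5, 0.5, 0.0)
    responses = simulate_responses(trials, params, rng=np.random.default_rng(1))
    fit = fit_subject(trials, responses, ModelVariant.TIED_VBAR, FAST)
    assert fit.free_dict()["v_bar"] < -2.0


def test_fit_deterministic_given_seed(small_subject):
    trials, responses, _ = small_subject
    f1 = fit_subject(trials, responses, ModelVariant.ZERO_AG, FAST)
    f2 = fit_subject(trials, responses, ModelVariant.ZERO_AG, FAST)
    assert np.array_equal(f1.x, f2.x) and f1.nll == f2.nll
    assert f1.best_start_index == f2.best_start_index


def test_fit_requires_enough_trials():
    trials = make_trials([15, 15, 20], ["low", "high", "low"], [14, 16, 19], [16, 22, 21])
    responses = make_responses(trials, [15, 16, 20])
    with pytest.raises(ValueError):
        fit_subject(trials, responses, ModelVariant.FULL, FAST)


# ---- cohort-level comparison ----

@pytest.fixture(scope="module")
def tiny_cohort():
    cfg = TaskConfig(n_sessions=1, trials_per_session=240, seed=77)
    return generate_cohort(cfg, n_subjects=3)


def test_compare_models_structure(tiny_cohort):
    comp = compare_models(
        tiny_cohort, (ModelVariant.FULL, ModelVariant.BASELINE), FAST
    )
    t = comp.table
    assert t.loc["full", "nll"] < t.loc["baseline", "nll"]
    assert t["n_best"].sum() == len(tiny_cohort)
    assert t.loc["baseline", "pseudo_r2"] == pytest.approx(0.0)
    assert 0 < t.loc["full", "pseudo_r2"] < 1


def test_compare_models_prefers_simpler_truth():
    """Data generated with b_g = 0: the complexity penalty should hand the
    win to the reduced variant."""
    cfg = TaskConfig(n_sessions=1, trials_per_session=240, seed=55)

    from priorweight import sample_observer_params

    def sampler(rng):
        p = sample_observer_params(rng)
        return ObserverParams(p.v_bar_L, p.v_bar_H, p.a_g, p.omega_L, p.omega_H, 0.0)

    cohort = generate_cohort(cfg, sampler, n_subjects=3)
    comp = compare_models(cohort, (ModelVariant.FULL, ModelVariant.ZERO_BG), FAST)
    assert comp.table["bic"].idxmin() == "zero_bg"


def test_compare_models_empty_cohort_errors():
    from priorweight import Cohort

    with pytest.raises(ValueError):
        compare_models(Cohort(), (ModelVariant.FULL,))


# ---- split-half reliability ----

def test_split_half_identity_when_split_disabled(tiny_cohort):
    rel = split_half_reliability(
        tiny_cohort, ModelVariant.FULL, FAST, split=False
    )
    assert np.allclose(rel["r"], 1.0, atol=1e-9)


def test_split_half_recovers_heterogeneity():
    cfg = TaskConfig(seed=31)
    cohort = generate_cohort(cfg, n_subjects=5)
    rel = split_half_reliability(cohort, ModelVariant.ZERO_AG, FAST,
                                 rng=np.random.default_rng(2))
    # omega intercepts are the best-identified parameters
    omega_rows = rel[rel["parameter"].str.startswith("omega")]
    assert (omega_rows["r"] > 0.7).all()


def test_split_half_input_validation(tiny_cohort):
    with pytest.raises(ValueError):
        split_half_reliability(tiny_cohort.subjects[:2], ModelVariant.FULL, FAST)
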