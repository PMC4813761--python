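"""Trial classification, screening rules, SSRT estimators, drift model,
psychometric fit, post-signal slowing, complexity contrast."""

import numpy as np
import pandas as pd
import pytest

from countermand.behavior import (
    DegeneratePerformanceError,
    InsufficientDataError,
    classify_trials,
    complexity_contrast,
    corrected_post_signal_rt,
    deviance_statistic,
    estimate_rt_drift,
    estimate_ssrt,
    fit_psychometric,
    interaction_contrast,
    median_go_rt,
    screen_values,
    ssrt_average_difference,
    ssrt_integration,
)
from countermand.sim.race import (
    RaceParams,
    SessionBehavior,
    TaskConfig,
    TrialRecord,
    simulate_behavior_session,
)


def make_session(specs, response_mode="stop"):
    """Hand-built session: specs is a list of dicts per trial."""
    trials = []
    clock = 0.0
    for i, s in enumerate(specs):
        go_dir = s.get("go_direction", "L")
        t = TrialRecord(
            index=i,
            block=0,
            go_direction=go_dir,
            is_signal_trial=s.get("soa") is not None,
            outcome="unclassified",
            soa=s.get("soa"),
            rt=s.get("rt"),
            press_direction=s.get("press"),
            onset_fixation=clock,
            onset_go=clock + 1.5,
        )
        if t.soa is not None:
            t.onset_signal = t.onset_go + t.soa
        if t.rt is not None:
            t.onset_press = t.onset_go + t.rt
        trials.append(t)
        clock += 2.7
    cfg = TaskConfig(n_trials_per_block=len(specs), n_blocks=1, response_mode=response_mode)
    return SessionBehavior(trials=trials, config=cfg)


def test_classification_counts_and_fail_fraction():
    specs = (
        [{"press": "L", "rt": 0.5}] * 5
        + [{"soa": 0.2}] * 3  # no press: stop success
        + [{"soa": 0.3, "press": "L", "rt": 0.4}] * 2  # pressed: fail
    )
    ct = classify_trials(make_session(specs))
    assert ct.counts == {"go_only": 5, "signal_success": 3, "signal_fail": 2, "unclassified": 0}
    assert ct.presented_count == 10
    assert ct.fail_fraction == pytest.approx(0.4)
    assert ct.change_fraction == pytest.approx(0.5)


def test_wrong_direction_press_is_unclassified():
    ct = classify_trials(
        make_session([{"go_direction": "R", "press": "L", "rt": 0.5}])
    )
    assert ct.labels == ["unclassified"]


def test_change_mode_classification():
    specs = [
        {"soa": 0.2, "press": "R", "rt": 0.7},  # opposite press: success
        {"soa": 0.2, "press": "L", "rt": 0.4},  # original press: fail
        {"soa": 0.2, "press": "LR", "rt": 0.4},  # double press: unclassified
    ]
    ct = classify_trials(make_session(specs, response_mode="change"))
    assert ct.labels == ["signal_success", "signal_fail", "unclassified"]


def test_all_unclassified_session_degenerates_cleanly():
    ct = classify_trials(
        make_session([{"go_direction": "R", "press": "L", "rt": 0.5}] * 4)
    )
    assert ct.classified_count == 0
    assert ct.change_fraction is None
    assert ct.fail_fraction is None


def test_empty_session_raises():
    cfg = TaskConfig(n_trials_per_block=1, n_blocks=1)
    with pytest.raises(InsufficientDataError):
        classify_trials(SessionBehavior(trials=[], config=cfg))


# --------------------------------------------------------------------------
# screening
# --------------------------------------------------------------------------

def test_screening_rules():
    # low fail fraction -> excluded, deviance never evaluated
    r = screen_values(0.20, success_soa=0.55, fail_soa=0.60, deviance=1.0)
    assert not r.rule_fail_fraction and r.rule_deviance is None and not r.retained
    # high deviance -> excluded even when behavior passes
    r = screen_values(0.33, success_soa=0.40, fail_soa=0.42, deviance=7.9)
    assert r.rule_soa_ordering and r.rule_fail_fraction and r.rule_deviance is False
    assert not r.retained
    # the printed-table mean row passes everything
    r = screen_values(0.39, success_soa=0.34, fail_soa=0.39, deviance=2.7)
    assert r.retained
    # SOA ordering violation -> excluded before the psychometric stage
    r = screen_values(0.30, success_soa=0.33, fail_soa=0.32, deviance=None)
    assert not r.rule_soa_ordering and r.rule_deviance is None and not r.retained


# --------------------------------------------------------------------------
# median go RT / traditional estimators
# --------------------------------------------------------------------------

def test_median_go_rt_constant():
    ct = classify_trials(make_session([{"press": "L", "rt": 0.5}] * 40))
    assert median_go_rt(ct, trim=0) == pytest.approx(0.5)
    assert median_go_rt(ct, trim=15) == pytest.approx(0.5)


def test_trimmed_median_reduces_drift_bias():
    ses = simulate_behavior_session(
        TaskConfig(n_trials_per_block=300, n_blocks=1),
        RaceParams(drift_slope=4e-4),
        seed=13,
    )
    ct = classify_trials(ses)
    # positive drift concentrates slow RTs at the end; trimming both ends
    # cannot increase the median beyond the untrimmed value on average
    assert median_go_rt(ct, trim=15) <= median_go_rt(ct, trim=0) + 0.01


def test_median_go_rt_insufficient_data():
    ct = classify_trials(make_session([{"press": "L", "rt": 0.5}] * 31))
    with pytest.raises(InsufficientDataError):
        median_go_rt(ct, trim=15)


def test_average_difference_by_definition():
    specs = [{"press": "L", "rt": 0.57}] * 4 + [{"soa": 0.357}] * 2 + [
        {"soa": 0.357, "press": "L", "rt": 0.5}
    ] * 2
    ct = classify_trials(make_session(specs))
    assert ssrt_average_difference(ct) == pytest.approx(0.57 - 0.357)


def test_average_difference_zero_soa():
    specs = [{"press": "L", "rt": 0.5}] * 4 + [{"soa": 0.0}] * 2
    ct = classify_trials(make_session(specs))
    assert ssrt_average_difference(ct) == pytest.approx(0.5)


def test_integration_quantile_convention():
    rts = [0.4, 0.5, 0.6, 0.7, 0.8]
    specs = [{"press": "L", "rt": r} for r in rts]
    # 5 signal trials, 2 failures -> fail fraction 0.4 -> ceil(0.4*5)=2 -> Q=0.5
    specs += [{"soa": 0.3}] * 3 + [{"soa": 0.3, "press": "L", "rt": 0.45}] * 2
    ct = classify_trials(make_session(specs))
    assert ct.fail_fraction == pytest.approx(0.4)
    assert ssrt_integration(ct) == pytest.approx(0.5 - 0.3)


def test_integration_degenerate_performance():
    specs = [{"press": "L", "rt": 0.5}] * 3 + [{"soa": 0.3, "press": "L", "rt": 0.45}] * 2
    ct = classify_trials(make_session(specs))  # fail fraction 1.0
    with pytest.raises(DegeneratePerformanceError):
        ssrt_integration(ct)


def test_estimators_recover_ssrt_under_symmetric_go_distribution():
    """With a nearly symmetric go distribution both traditional
    estimators are consistent for the true stop duration."""
    par = RaceParams(go_mu=0.45, go_sigma=0.05, go_tau=0.02, ssrt_true=0.20)
    ses = simulate_behavior_session(
        TaskConfig(n_trials_per_block=4000, n_blocks=1), par, seed=17
    )
    ct = classify_trials(ses)
    est = estimate_ssrt(ct)
    assert est.ssrt_avgdiff == pytest.approx(0.20, abs=0.02)
    assert est.ssrt_integration == pytest.approx(0.20, abs=0.02)
    assert est.ssrt_av == pytest.approx((est.ssrt_avgdiff + est.ssrt_integration) / 2)


def test_mean_method_overestimates_under_skew(long_classified):
    """Structural property of the mean method: under the skewed default
    ex-Gaussian go distribution it overestimates by roughly the
    mean-median gap less the staircase overshoot, while the integration
    method stays close."""
    est = estimate_ssrt(long_classified)
    assert 0.02 < est.ssrt_avgdiff - 0.20 < 0.045
    assert abs(est.ssrt_integration - 0.20) < 0.02


# --------------------------------------------------------------------------
# drift model
# --------------------------------------------------------------------------

def test_drift_exact_on_linear_input():
    rts = [0.4 + 0.001 * i for i in range(60)]
    ct = classify_trials(make_session([{"press": "L", "rt": r} for r in rts]))
    dm = estimate_rt_drift(ct)
    pred = dm.predict(np.arange(60))
    np.testing.assert_allclose(pred, rts, atol=1e-6)
    assert dm.residual_scale < 1e-8
    assert dm.average_slope() == pytest.approx(0.001, rel=1e-3)


def test_drift_slope_recovery_and_null():
    slopes_null, slopes_drift = [], []
    for seed in range(25):
        for slope, out in ((0.0, slopes_null), (2e-4, slopes_drift)):
            ses = simulate_behavior_session(
                TaskConfig(n_trials_per_block=400, n_blocks=1),
                RaceParams(drift_slope=slope),
                seed=1000 + seed,
            )
            dm = estimate_rt_drift(classify_trials(ses))
            out.append(dm.average_slope())
    m_null = np.mean(slopes_null)
    se_null = np.std(slopes_null, ddof=1) / np.sqrt(len(slopes_null))
    assert abs(m_null) < 3 * se_null  # CI contains zero
    assert np.mean(slopes_drift) == pytest.approx(2e-4, rel=0.3)


def test_drift_linear_fallback_below_30_points():
    rts = [0.4 + 0.002 * i for i in range(12)]
    ct = classify_trials(make_session([{"press": "L", "rt": r} for r in rts]))
    dm = estimate_rt_drift(ct)
    assert dm.kind == "linear"
    with pytest.raises(InsufficientDataError):
        estimate_rt_drift(classify_trials(make_session([{"press": "L", "rt": 0.5}] * 8)))


# --------------------------------------------------------------------------
# psychometric fit
# --------------------------------------------------------------------------

def test_psychometric_recovery_from_logistic_data(rng):
    alpha, beta = 0.2, 40.0
    z = rng.uniform(0.0, 0.4, 2000)
    p = 1.0 / (1.0 + np.exp(-beta * (z - alpha)))
    y = rng.random(2000) < p
    fit = fit_psychometric(z, y, prior_center=0.21, seed=3)
    assert fit.alpha == pytest.approx(alpha, abs=0.02)
    assert fit.converged
    assert 0 <= fit.lapse <= 0.1
    assert fit.deviance < 20.0


def test_deviance_zero_when_model_matches_bins():
    z = np.concatenate([np.full(50, 0.1), np.full(50, 0.4)])
    # success probabilities exactly 0 and 1 in the two bins, and a steep
    # logistic that reproduces them: saturated fit, zero deviance
    y = z > 0.25
    d = deviance_statistic(z, y, alpha=0.25, beta=500.0, lam=0.0)
    assert d == pytest.approx(0.0, abs=1e-6)


def test_deviance_invariant_under_bin_relabeling(rng):
    z = rng.uniform(0, 0.5, 400)
    y = rng.random(400) < 0.6
    d1 = deviance_statistic(z, y, 0.25, 10.0, 0.0)
    d2 = deviance_statistic(z[::-1], y[::-1], 0.25, 10.0, 0.0)
    assert d1 == pytest.approx(d2, rel=1e-9)
    assert d1 >= 0


def test_race_model_sessions_fit_logistic_acceptably():
    """Study-size race-model sessions typically sit below the deviance
    exclusion threshold; a strongly mis-specified (shifted-lapse) success
    rule inflates deviance well beyond it."""
    from countermand.behavior import fit_inhibition_function

    devs = []
    for seed in range(8):
        ses = simulate_behavior_session(TaskConfig(), RaceParams(), seed=seed)
        fit = fit_inhibition_function(classify_trials(ses), n_iter=2500, seed=seed)
        devs.append(fit.deviance)
    assert np.median(devs) < 7.5

    # mis-specified data: success probability non-monotone in z (bimodal
    # go distribution makes the inhibition function dip) -> deviance blows up
    rng = np.random.default_rng(0)
    z = rng.uniform(0.0, 0.6, 400)
    p = 0.5 + 0.45 * np.sin(2 * np.pi * z / 0.3)
    y = rng.random(400) < p
    bad = fit_psychometric(z, y, prior_center=0.3, n_iter=2500, seed=1)
    assert bad.deviance > 7.5
    assert bad.deviance > 3 * np.median(devs)


# --------------------------------------------------------------------------
# post-signal slowing
# --------------------------------------------------------------------------

def test_post_signal_slowing_rows():
    specs = [
        {"press": "L", "rt": 0.50},
        {"soa": 0.3, "press": "L", "rt": 0.45},  # fail
        {"press": "L", "rt": 0.56},
        {"soa": 0.3},  # success
        {"soa": 0.3, "press": "L", "rt": 0.44},  # fail -> mixed run
        {"press": "L", "rt": 0.60},
    ]
    ct = classify_trials(make_session(specs))
    tab = corrected_post_signal_rt(ct)
    assert len(tab) == 1
    row = tab.iloc[0]
    assert row["previous_outcome"] == "fail"
    assert row["corrected_rt"] == pytest.approx(0.06)


def test_post_signal_slowing_null_under_pure_drift():
    """Differencing against the preceding go trial removes drift: with no
    true slowing the mean corrected RT is ~0 across seeds."""
    vals = []
    for seed in range(10):
        ses = simulate_behavior_session(
            TaskConfig(n_trials_per_block=400, n_blocks=1),
            RaceParams(drift_slope=3e-4),
            seed=seed,
        )
        tab = corrected_post_signal_rt(classify_trials(ses))
        vals.append(tab["corrected_rt"].mean())
    m = np.mean(vals)
    se = np.std(vals, ddof=1) / np.sqrt(len(vals))
    assert abs(m) < max(3 * se, 0.01)


# --------------------------------------------------------------------------
# complexity contrast
# --------------------------------------------------------------------------

def test_interaction_contrast_null():
    cells = {k: 0.5 for k in [("bar", "stop"), ("arrow", "stop"), ("bar", "change"), ("arrow", "change")]}
    assert interaction_contrast(cells) == 0.0


def _summaries(rng, n_subjects, effect=0.0, noise=0.02):
    rows = []
    for s in range(n_subjects):
        base = 0.5 + rng.normal(0, 0.05)
        for stim in ("bar", "arrow"):
            for respm in ("stop", "change"):
                complex_cell = (stim == "arrow") == (respm == "stop")
                rt = base + effect * complex_cell + rng.normal(0, noise)
                rows.append({"subject": s, "stimulus": stim, "response": respm, "go_rt": rt})
    return pd.DataFrame(rows)


def test_complexity_contrast_detects_injected_effect(rng):
    detected = 0
    for _ in range(30):
        df = _summaries(rng, 8, effect=0.03)
        res = complexity_contrast(df, n_permutations=500, seed=rng)
        detected += res.p_value < 0.05
    assert detected >= 24  # >= 80% power


def test_complexity_contrast_type_i_calibration(rng):
    ps = []
    for _ in range(200):
        df = _summaries(rng, 8, effect=0.0)
        res = complexity_contrast(df, n_permutations=300, seed=rng)
        ps.append(res.p_value)
    rate = np.mean(np.asarray(ps) < 0.05)
    assert 0.02 <= rate <= 0.09  # binomial 95% band around 0.05 at n=200


def test_complexity_contrast_missing_cell():
    df = _summaries(np.random.default_rng(0), 3).iloc[:-1]
    with pytest.raises(InsufficientDataError):
        complexity_contrast(df, n_permutations=100)
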