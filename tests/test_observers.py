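"""Observer models: noticing processes, report noise and cohort synthesis."""

import math

import numpy as np
import pytest
from scipy import stats

from ibsim import analysis, display, observers, screening
from ibsim.observers import (
    CLEAN_COVARIATES,
    ExclusionProbs,
    NoticingModel,
    ReportNoise,
    generate_cohort,
    sample_covariates_and_counts,
    sample_feature_reports,
    sample_location_report,
    sample_noticing,
)

E1 = {c.condition_id: c for c in display.condition_catalog("E1")}
E3 = {c.condition_id: c for c in display.condition_catalog("E3")}


# ---------------------------------------------------------------------------
# Noticing processes
# ---------------------------------------------------------------------------

def test_constant_hazard_matches_exponential_cdf_across_exposures():
    """P(notice) tracks 1 - exp(-lambda T) at each condition's visible
    duration (n = 10^4 per cell, within ~3 binomial SEs)."""
    lam = 0.3
    model = NoticingModel("constant_hazard", hazard_per_s=lam)
    rng = np.random.default_rng(5)
    for cond in list(E3.values()) + [E1["E1-2.67s"]]:
        noticed, t = observers._noticing_vec(model, cond, 10_000, rng)
        expected = 1.0 - math.exp(-lam * cond.visible_duration_s)
        se = math.sqrt(expected * (1 - expected) / 10_000)
        assert noticed.mean() == pytest.approx(expected, abs=3 * se)
        tt = t[noticed]
        assert (tt >= cond.motion_start_s).all()
        assert (tt <= cond.uo_offset_time_s).all()


def test_event_triggered_rates_are_exposure_invariant():
    """Onset-anchored noticing does not change between the 1.5 s and 5 s
    exposures (chi-square on 10^4 per cell, alpha = 0.01)."""
    model = NoticingModel("onset_window", p_detect=0.45)
    rng = np.random.default_rng(17)
    counts = []
    for cond in E3.values():
        noticed, _ = observers._noticing_vec(model, cond, 10_000, rng)
        counts.append([int(noticed.sum()), int((~noticed).sum())])
    assert stats.chi2_contingency(np.array(counts)).pvalue > 0.01


def test_certain_detection_and_no_object_condition():
    rng = np.random.default_rng(0)
    model = NoticingModel("onset_window", p_detect=1.0, window_s=0.0)
    noticed, t = sample_noticing(model, E1["E1-5s"].with_direction("LtoR"), rng)
    assert noticed and t == pytest.approx(E1["E1-5s"].onset_time_s)
    for variant in observers.MODEL_VARIANTS:
        noticed, t = sample_noticing(
            NoticingModel(variant, p_detect=1.0, hazard_per_s=50.0), E1["E1-none"], rng
        )
        assert (noticed, t) == (False, None)


def test_offset_window_notices_just_before_offset():
    model = NoticingModel("offset_window", p_detect=1.0, window_s=0.5)
    rng = np.random.default_rng(2)
    _, t = observers._noticing_vec(model, E3["E3-5s"], 1000, rng)
    assert (t >= 12.5).all() and (t <= 13.0).all()


def test_fixation_model_never_fires_off_fixation_paths():
    """Edge-onset short paths never reach the fixation column, so the
    fixation-anchored account predicts zero noticing there."""
    e2 = {c.condition_id: c for c in display.condition_catalog("E2")}
    model = NoticingModel("fixation_cross", p_detect=1.0)
    rng = np.random.default_rng(3)
    noticed, _ = observers._noticing_vec(model, e2["E2-1.5s-edge"], 500, rng)
    assert not noticed.any()
    noticed, t = observers._noticing_vec(model, E3["E3-5s"], 500, rng)
    assert noticed.all()
    t_fix = E3["E3-5s"].with_direction("LtoR").fixation_cross_time_s
    assert (t >= t_fix).all()


def test_edge_boost_raises_edge_onset_rate_only():
    e2 = {c.condition_id: c for c in display.condition_catalog("E2")}
    model = NoticingModel("onset_window", p_detect=0.4, edge_boost=0.15)
    rng = np.random.default_rng(4)
    edge, _ = observers._noticing_vec(model, e2["E2-5s-edge"], 20_000, rng)
    mid, _ = observers._noticing_vec(model, e2["E2-5s-mid"], 20_000, rng)
    assert edge.mean() == pytest.approx(0.55, abs=0.015)
    assert mid.mean() == pytest.approx(0.40, abs=0.015)


# ---------------------------------------------------------------------------
# Location reports
# ---------------------------------------------------------------------------

def test_noise_free_noticer_report_lands_on_scaled_onset_point(clean_noise):
    cond = E1["E1-5s"].with_direction("LtoR")
    rng = np.random.default_rng(0)
    x, y = sample_location_report(True, cond.onset_time_s, cond, clean_noise, rng)
    assert (x, y) == (pytest.approx(2 / 3 * 70.0), pytest.approx(2 / 3 * 300.0))


def test_location_report_requires_noticing_time():
    rng = np.random.default_rng(0)
    with pytest.raises(ValueError, match="noticing time"):
        sample_location_report(True, None, E1["E1-5s"].with_direction("LtoR"),
                               ReportNoise(), rng)


def test_noticers_place_reports_on_onset_side_of_fixation():
    model = NoticingModel("onset_window", p_detect=1.0, window_s=0.5)
    noise = ReportNoise(loc_sigma_px=40.0, extrapolation_px=20.0)
    rng = np.random.default_rng(8)
    cond = E1["E1-5s"]
    noticed, t = observers._noticing_vec(model, cond, 4000, rng)
    dirs = np.where(rng.random(4000) < 0.5, "LtoR", "RtoL")
    xy = observers._location_vec(noticed, t, dirs, cond, noise, rng,
                                 display.DisplayGeometry())
    x_full = xy[:, 0] / observers.PANEL_SCALE
    onset_x = np.where(dirs == "LtoR", 70.0, 630.0)
    onset_side = np.sign(x_full - 350.0) == np.sign(onset_x - 350.0)
    assert onset_side.mean() > 0.5


def test_non_noticers_scatter_widely_about_display_centre():
    noise = ReportNoise(nonnoticer_loc_sigma_px=140.0, loc_sigma_px=40.0)
    rng = np.random.default_rng(9)
    n = 4000
    noticed = np.zeros(n, dtype=bool)
    xy = observers._location_vec(noticed, np.full(n, np.nan),
                                 np.full(n, "LtoR"), E1["E1-5s"], noise, rng,
                                 display.DisplayGeometry())
    y_full = xy[:, 1] / observers.PANEL_SCALE
    assert y_full.mean() == pytest.approx(300.0, abs=10.0)
    assert y_full.std() > 80.0  # far wider than noticer placement noise


def test_reports_stay_on_two_thirds_scale_panel():
    noise = ReportNoise(nonnoticer_loc_sigma_px=500.0)
    rng = np.random.default_rng(10)
    xy = observers._location_vec(np.zeros(2000, bool), np.full(2000, np.nan),
                                 np.full(2000, "LtoR"), E1["E1-5s"], noise, rng,
                                 display.DisplayGeometry())
    assert (xy[:, 0] >= 0).all() and (xy[:, 0] <= 700 * 2 / 3).all()
    assert (xy[:, 1] >= 0).all() and (xy[:, 1] <= 600 * 2 / 3).all()


# ---------------------------------------------------------------------------
# Feature reports
# ---------------------------------------------------------------------------

def test_non_noticer_shape_accuracy_is_at_menu_chance():
    rng = np.random.default_rng(11)
    n = 20_000
    shape, _, hue = observers._feature_vec(
        np.zeros(n, bool), np.zeros(n), "E3", ReportNoise(), rng
    )
    acc = (shape == observers.TRUE_SHAPE).mean()
    se = math.sqrt((1 / 9) * (8 / 9) / n)
    assert acc == pytest.approx(1 / 9, abs=3 * se)


def test_non_noticer_hue_errors_approach_uniform_angular_deviation():
    rng = np.random.default_rng(12)
    n = 50_000
    true = rng.uniform(0, 360, n)
    _, _, hue = observers._feature_vec(np.zeros(n, bool), true, "E3",
                                       ReportNoise(), rng)
    err = analysis.wrap_deg(hue - true)
    assert analysis.angular_deviation_deg(err) == pytest.approx(81.03, abs=1.0)


def test_infinite_concentration_gives_exact_hue_reports():
    rng = np.random.default_rng(13)
    n = 500
    true = rng.uniform(0, 360, n)
    noise = ReportNoise(colour_kappa=1e12)
    _, _, hue = observers._feature_vec(np.ones(n, bool), true, "E3", noise, rng)
    err = analysis.wrap_deg(hue - true)
    assert np.abs(err).max() < 0.5


def test_menu_colour_reports_in_menu_experiments():
    rng = np.random.default_rng(14)
    shape, colour = sample_feature_reports(
        True, E1["E1-5s"].with_direction("LtoR"), ReportNoise(q_shape=1.0), rng
    )
    assert shape == "cross"
    assert colour in observers.COLOUR_MENU


# ---------------------------------------------------------------------------
# Counts, covariates, D-15
# ---------------------------------------------------------------------------

def test_zero_count_error_reproduces_true_counts(clean_noise):
    rng = np.random.default_rng(15)
    out = sample_covariates_and_counts([10, 12, 9], clean_noise,
                                       CLEAN_COVARIATES, rng)
    assert out["reported_bounces"] == (10, 12, 9)
    assert not screening.bounce_error_rule(out["true_bounces"],
                                           out["reported_bounces"])
    assert out["age_ok"] and out["vision_corrected_ok"]
    assert not out["technical_problem"] and not out["prior_ib_experience"]


def test_sixty_percent_error_on_two_trials_triggers_exclusion():
    true = (10, 10, 10)
    reported = (16, 16, 10)  # +60% twice
    assert screening.bounce_error_rule(true, reported)


def test_identity_d15_arrangement_never_flags():
    rng = np.random.default_rng(16)
    out = sample_covariates_and_counts(
        [10, 10, 10], ReportNoise(count_error_sd=0.0),
        ExclusionProbs(0, 0, 0, 0, p_d15_deficient=0.0), rng, experiment="E3",
    )
    assert out["d15_arrangement"] == tuple(range(1, 16))
    assert not screening.d15_rule("-".join(map(str, out["d15_arrangement"])))


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def test_cohort_is_reproducible_from_seed(count_pool):
    model = NoticingModel("constant_hazard", hazard_per_s=0.3)
    a = generate_cohort("E3", model, n_per_condition=50, seed=99,
                        count_pool=count_pool)
    b = generate_cohort("E3", model, n_per_condition=50, seed=99,
                        count_pool=count_pool)
    assert a.equals(b)


def test_e1_no_object_share_is_one_in_five(count_pool):
    model = NoticingModel("onset_window")
    cohort = generate_cohort("E1", model, n_per_condition=2000, seed=7,
                             count_pool=count_pool)
    share = (cohort["condition_id"] == "E1-none").mean()
    se = math.sqrt(0.2 * 0.8 / len(cohort))
    assert share == pytest.approx(0.2, abs=3.5 * se)


def test_perfect_detection_noise_free_cohort_all_noticers(count_pool, clean_noise):
    model = NoticingModel("onset_window", p_detect=1.0)
    cohort = generate_cohort("E1", model, noise=clean_noise, n_per_condition=200,
                             seed=3, exclusion_probs=CLEAN_COVARIATES,
                             count_pool=count_pool)
    cohort = analysis.add_noticer_column(cohort)
    uo = cohort[cohort["onset_type"] != "none"]
    assert uo["noticer"].all()
    assert not cohort.loc[cohort["onset_type"] == "none", "noticer"].any()


def test_non_noticer_hue_reports_carry_no_information(count_pool):
    """Mutual information between the true hue and non-noticers' hue
    reports is indistinguishable from zero (permutation test)."""
    model = NoticingModel("onset_window", p_detect=0.4)
    cohort = generate_cohort("E3", model, n_per_condition=1500, seed=23,
                             exclusion_probs=CLEAN_COVARIATES,
                             count_pool=count_pool)
    non = cohort[~cohort["reported_noticed"]]
    bins = np.linspace(0, 360, 13)
    tx = np.digitize(non["true_hue_deg"], bins)
    ty = np.digitize(non["hue_report_deg"], bins)

    def mi(a, b):
        joint = np.histogram2d(a, b, bins=12)[0] / len(a)
        px, py = joint.sum(1, keepdims=True), joint.sum(0, keepdims=True)
        nz = joint > 0
        return float((joint[nz] * np.log(joint[nz] / (px @ py)[nz])).sum())

    obs = mi(tx, ty)
    rng = np.random.default_rng(0)
    null = np.array([mi(tx, rng.permutation(ty)) for _ in range(200)])
    assert (null >= obs).mean() > 0.01
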