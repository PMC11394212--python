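"""Threshold calibration: nearest-rank z-threshold rules, axis grid
search against generator ground truth, and frozen-threshold application."""

import numpy as np
import pytest

from binbat import (
    CalibrationConfig,
    CalibrationError,
    Condition,
    InsufficientEventsError,
    SyntheticProfile,
    ThresholdSet,
    TransformSpec,
    WorkflowConfig,
    apply_thresholds,
    apply_transform,
    calibrate,
    calibrate_z_threshold,
    find_axis_thresholds,
    generate_sample,
    nearest_rank_percentile,
)
from binbat.workflow import prepare_sample
from tests.conftest import make_table


class TestNearestRank:
    def test_matches_enumeration_on_small_vectors(self):
        rng = np.random.default_rng(0)
        for n in (1, 2, 7, 50):
            v = rng.normal(size=n)
            s = np.sort(v)
            for q in (1, 25, 50, 75, 99, 100):
                k = max(1, int(np.ceil(q / 100 * n)))
                assert nearest_rank_percentile(v, q) == s[k - 1]


class TestZThreshold:
    def test_one_percent_rule_on_1_to_100(self):
        z = np.arange(1.0, 101.0)
        thr, warnings = calibrate_z_threshold(z, 1.0)
        assert thr == 99.0
        assert np.count_nonzero(z > thr) == 1  # exactly the value 100
        assert not warnings

    def test_seventy_percent_rule_on_1_to_100(self):
        z = np.arange(1.0, 101.0)
        thr, _ = calibrate_z_threshold(z, 70.0)
        assert thr == 30.0
        assert np.count_nonzero(z > thr) == 70

    def test_realized_fraction_never_exceeds_target(self):
        rng = np.random.default_rng(1)
        for n in (10, 57, 213, 1000):
            z = rng.normal(size=n)
            for target in (1.0, 5.0, 70.0):
                thr, _ = calibrate_z_threshold(z, target)
                assert 100.0 * np.count_nonzero(z > thr) / n <= target + 1e-12

    def test_degenerate_distribution_warns_and_yields_zero_positive(self):
        z = np.full(60, 3.3)
        thr, warnings = calibrate_z_threshold(z, 70.0)
        assert np.count_nonzero(z > thr) == 0
        assert any("degenerate" in w for w in warnings)

    def test_below_ten_events_is_error(self):
        with pytest.raises(InsufficientEventsError):
            calibrate_z_threshold(np.arange(9.0), 1.0)

    def test_low_count_warning_between_10_and_50(self):
        _, warnings = calibrate_z_threshold(np.arange(20.0), 10.0)
        assert warnings


class TestAxisSearch:
    def test_recovers_labeled_basophils(self, unstim_transformed):
        table, truth = unstim_transformed
        cfg = CalibrationConfig()
        thr_ssc, thr_fc = find_axis_thresholds(table, cfg)
        ssc = table.marker_values("SSC")
        fc = table.marker_values("FCER1A")
        in_ul = (ssc < thr_ssc) & (fc >= thr_fc)
        is_baso = (truth["population"] == "basophil").to_numpy()
        recovery = (in_ul & is_baso).sum() / is_baso.sum()
        contamination = (in_ul & ~is_baso).sum() / in_ul.sum()
        assert recovery >= 0.90
        assert contamination <= 0.10

    def test_basophil_ablation_fails_calibration(self):
        profile = SyntheticProfile().without_basophils()
        table, _ = generate_sample(profile, Condition.UNSTIM, 50_000, seed=3)
        gated = prepare_sample(table, WorkflowConfig())
        with pytest.raises(CalibrationError):
            find_axis_thresholds(gated, CalibrationConfig())

    def test_tie_breaks_choose_lower_fcer1a_threshold(self):
        # two FcεRIα candidates select the identical quadrant -> tie on
        # purity and count; the lower threshold must win
        n_low, n_high = 80, 20
        fcer1a = np.concatenate([np.full(n_low, 2.11), np.full(n_high, 4.1)])
        ssc = np.full(100, 0.35)
        cd32 = np.concatenate([np.full(n_low, 1.0), np.full(n_high, 5.0)])
        t = make_table({"SSC": ssc, "FCER1A": fcer1a, "CD32": cd32})
        cfg = CalibrationConfig(
            baso_freq_bounds=(0.05, 50.0),
            fcer1a_quantile_grid=(0.5, 0.9),
            ssc_quantile_grid=(0.5,),
        )
        thr_ssc, thr_fc = find_axis_thresholds(t, cfg)
        assert thr_fc == pytest.approx(2.2)  # snapped 50th-percentile candidate


@pytest.fixture(scope="module")
def calibrated(unstim_gated):
    ts, _ = calibrate(unstim_gated, "u", WorkflowConfig().calibration)
    return ts


class TestApplyThresholds:
    def test_self_consistency_on_calibration_sample(self, unstim_gated, calibrated):
        app = apply_thresholds(unstim_gated, calibrated)
        granularity = 100.0 / app.n_basophils
        assert app.cd63_pos_pct <= 1.0 + 1e-9
        assert app.cd63_pos_pct >= 1.0 - granularity - 1e-9
        assert app.cd32_pos_pct <= 70.0 + 1e-9
        assert app.cd32_pos_pct >= 70.0 - granularity - 1e-9

    def test_stimulated_activation_recovered(self, calibrated, default_profile):
        table, truth = generate_sample(default_profile, Condition.POS_CTRL,
                                       100_000, seed=2)
        gated = prepare_sample(table, WorkflowConfig())
        app = apply_thresholds(gated, calibrated)
        assert app.n_basophils >= 400
        assert app.cd63_pos_pct == pytest.approx(40.0, abs=2.0)

    def test_zero_activation_reads_at_false_positive_floor(self, calibrated):
        profile = SyntheticProfile().with_activation(Condition.ALLERGEN, 0.0)
        table, truth = generate_sample(profile, Condition.ALLERGEN, 100_000, seed=4)
        gated = prepare_sample(table, WorkflowConfig())
        app = apply_thresholds(gated, calibrated)
        assert (truth["activated"]).sum() == 0
        assert app.cd63_pos_pct <= 2.0  # about the calibrated 1% floor

    def test_threshold_set_requires_finite_values(self):
        with pytest.raises(ValueError):
            ThresholdSet(thr_ssc=np.inf, thr_fcer1a=1, thr_cd63=1, thr_cd32=1,
                         calibrated_on="u")

    def test_determinism_identical_inputs_identical_thresholds(self, unstim_gated):
        cfg = WorkflowConfig()
        a, _ = calibrate(unstim_gated, "u", cfg.calibration)
        b, _ = calibrate(unstim_gated.subset(np.arange(unstim_gated.n_events)),
                         "u", cfg.calibration)
        assert a == b
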