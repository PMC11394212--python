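"""End-to-end experiment workflow: responder and allergen calls, QC flag
rules, and determinism of the result documents."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from binbat import (
    AllergenCall,
    Condition,
    ConfigError,
    QCCode,
    ResponderStatus,
    SampleMeta,
    Severity,
    SyntheticProfile,
    ThresholdSet,
    WorkflowConfig,
    allergen_call_from,
    analyze_experiment,
    evaluate_qc,
    generate_experiment,
    responder_status_from,
)
from binbat.workflow import SampleResult


def _exp_samples(profile, n_events=50_000, seed=5):
    return [(t, m) for t, m, _ in generate_experiment(profile, n_events=n_events,
                                                      seed=seed, donor_id="D1",
                                                      allergen_name="birch")]


@pytest.fixture(scope="module")
def responder_result():
    profile = SyntheticProfile(allergic=True, responder=True)
    return analyze_experiment(_exp_samples(profile, seed=11), WorkflowConfig())


class TestAnalyzeExperiment:
    def test_responder_with_active_allergen_called_positive(self, responder_result):
        res = responder_result
        assert res.responder_status is ResponderStatus.RESPONDER
        assert res.allergen_calls == {"birch": AllergenCall.POSITIVE}
        assert res.thresholds is not None

    def test_thresholds_frozen_across_samples(self, responder_result):
        ts = {s.thresholds for s in responder_result.samples}
        assert len(ts) == 1

    def test_non_responder_forces_undetermined(self):
        profile = SyntheticProfile(allergic=True, responder=False)
        res = analyze_experiment(_exp_samples(profile, seed=12), WorkflowConfig())
        assert res.responder_status is ResponderStatus.NON_RESPONDER
        assert res.allergen_calls == {"birch": AllergenCall.UNDETERMINED}

    def test_missing_unstim_is_config_error(self, default_profile):
        samples = _exp_samples(default_profile, seed=13)
        no_unstim = [(t, m) for t, m in samples if m.condition is not Condition.UNSTIM]
        with pytest.raises(ConfigError):
            analyze_experiment(no_unstim, WorkflowConfig())

    def test_calibration_failure_blocks_all_calls(self):
        profile = SyntheticProfile(allergic=True).without_basophils()
        res = analyze_experiment(_exp_samples(profile, n_events=20_000, seed=14),
                                 WorkflowConfig())
        assert res.responder_status is ResponderStatus.UNDETERMINED
        assert res.allergen_calls == {"birch": AllergenCall.UNDETERMINED}
        assert all(
            any(f.code is QCCode.CALIBRATION_FAILED for f in s.qc_flags)
            for s in res.samples
        )

    def test_mixed_donors_rejected(self, default_profile):
        samples = _exp_samples(default_profile, seed=15)
        t, m = samples[1]
        samples[1] = (t, SampleMeta("OTHER", m.condition))
        with pytest.raises(ConfigError):
            analyze_experiment(samples, WorkflowConfig())

    def test_result_json_deterministic(self, default_profile):
        a = analyze_experiment(_exp_samples(default_profile, seed=16), WorkflowConfig())
        b = analyze_experiment(_exp_samples(default_profile, seed=16), WorkflowConfig())
        assert a.to_json() == b.to_json()


def _sr(n_gated=20_000, n_baso=200, thresholds=None) -> SampleResult:
    return SampleResult(
        meta=SampleMeta("D1", Condition.UNSTIM), n_gated=n_gated, n_basophils=n_baso,
        cd63_pos_pct=1.0, cd32_pos_pct=69.0, thresholds=thresholds,
    )


class TestEvaluateQC:
    def test_five_basophils_is_blocking(self):
        flags = evaluate_qc(_sr(n_baso=5))
        assert any(f.code is QCCode.LOW_BASOPHILS and f.severity is Severity.BLOCKING
                   for f in flags)

    def test_thirty_basophils_is_warning_only(self):
        flags = evaluate_qc(_sr(n_baso=30))
        assert [f.severity for f in flags] == [Severity.WARNING]

    def test_low_events_warns(self):
        flags = evaluate_qc(_sr(n_gated=3000))
        assert any(f.code is QCCode.LOW_EVENTS for f in flags)

    def test_threshold_above_sample_maximum_flagged(self):
        ts = ThresholdSet(thr_ssc=2.0, thr_fcer1a=3.0, thr_cd63=99.0, thr_cd32=3.0,
                          calibrated_on="u")
        spans = {"SSC": (0.0, 5.0), "FCER1A": (0.0, 6.0), "CD63": (0.0, 6.0),
                 "CD32": (0.0, 6.0)}
        flags = evaluate_qc(_sr(thresholds=ts), channel_spans=spans)
        assert any(f.code is QCCode.THRESHOLD_OUT_OF_RANGE for f in flags)

    def test_clean_synthetic_sample_has_no_flags(self, responder_result):
        for s in responder_result.samples:
            assert s.qc_flags == []


class TestCallLogic:
    @settings(deadline=None, max_examples=200)
    @given(
        pos=st.one_of(st.none(), st.floats(0, 100)),
        allergen=st.one_of(st.none(), st.floats(0, 100)),
        unstim=st.one_of(st.none(), st.floats(0, 100)),
        blocked=st.booleans(),
    )
    def test_calls_are_pure_and_consistent(self, pos, allergen, unstim, blocked):
        cfg = WorkflowConfig()
        status = responder_status_from(pos, blocked, cfg)
        call = allergen_call_from(allergen, unstim, status, blocked, cfg)
        # non-responders and blocked samples never get a definitive call
        if status is not ResponderStatus.RESPONDER or blocked:
            assert call is AllergenCall.UNDETERMINED
        if call is AllergenCall.POSITIVE:
            assert allergen >= cfg.activation_cutoff
            assert allergen >= cfg.activation_fold * unstim
        if status is ResponderStatus.RESPONDER:
            assert pos >= cfg.responder_cutoff and not blocked

    def test_boundary_values(self):
        cfg = WorkflowConfig()
        assert responder_status_from(cfg.responder_cutoff, False, cfg) is ResponderStatus.RESPONDER
        assert responder_status_from(cfg.responder_cutoff - 1e-9, False, cfg) is ResponderStatus.NON_RESPONDER
        assert allergen_call_from(5.0, 2.5, ResponderStatus.RESPONDER, False, cfg) is AllergenCall.POSITIVE
        assert allergen_call_from(5.0, 2.6, ResponderStatus.RESPONDER, False, cfg) is AllergenCall.NEGATIVE
        assert allergen_call_from(4.9, 0.1, ResponderStatus.RESPONDER, False, cfg) is AllergenCall.NEGATIVE
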