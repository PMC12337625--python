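"""Endpoint-definition tests: acceleration, break typing, rhythm classing,
success endpoints, factor categories, patient roll-ups."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from iatpsim.adjudication import (
    AdjudicationRules,
    BreakType,
    LabeledBeat,
    RhythmClass,
    acceleration_test,
    adjudicate_episode,
    classify_break,
    classify_rhythm,
    detection_category,
    patient_summary,
    rate_class,
    sequence_category,
)
from iatpsim.cohort_synth import CohortParams, sample_cohort, simulate_cohort
from iatpsim.device_model import DeviceConfig, Zone, ZoneConfig
from iatpsim.vt_dynamics import IntervalEvent

RULES = AdjudicationRules()


class TestAccelerationRule:
    @pytest.mark.parametrize("pre,post,expected", [
        (340.0, 300.0, True),    # delta 40 >= 30 and >= 34
        (400.0, 365.0, False),   # delta 35 >= 30 but < 40
        (300.0, 270.0, True),    # delta 30 meets both inclusive bounds
        (600.0, 545.0, False),   # delta 55 < 60 (10%)
        (200.0, 170.0, True),    # delta 30 = max(30, 20)
    ])
    def test_examples(self, pre, post, expected):
        assert acceleration_test(pre, post, RULES) is expected

    @given(pre=st.integers(200, 600), post=st.integers(100, 600))
    @settings(max_examples=500, deadline=None)
    def test_matches_direct_rule_evaluation(self, pre, post):
        want = (pre - post >= 30) and (pre - post >= 0.10 * pre)
        assert acceleration_test(float(pre), float(post), RULES) is want

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            acceleration_test(0.0, 300.0, RULES)


def _beats(spec):
    """spec: list of (cl or None, morph, normal)"""
    return [LabeledBeat(cl_ms=c, morph=m, normal=n) for c, m, n in spec]


class TestBreakClassification:
    def test_all_normal_is_type_one(self):
        post = _beats([(800.0, "N", True)] * 5)
        assert classify_break(340.0, "V1", post, RULES) == BreakType.type_I

    def test_single_abnormal_then_normal_is_type_one(self):
        post = _beats([(380.0, "V1", False)] + [(800.0, "N", True)] * 4)
        assert classify_break(340.0, "V1", post, RULES) == BreakType.type_I

    def test_matching_abnormals_are_spontaneous_resumption(self):
        """Beats matching the pre-ATP rhythm in CL and morphology mean the
        train did not cause the termination."""
        post = _beats([(None, "V1", False), (335.0, "V1", False),
                       (338.0, "V1", False), (336.0, "V1", False)]
                      + [(800.0, "N", True)] * 4)
        assert classify_break(340.0, "V1", post, RULES) == BreakType.spontaneous_resumption

    def test_differing_abnormals_are_type_two(self):
        post = _beats([(300.0, "V2", False), (310.0, "V2", False)]
                      + [(800.0, "N", True)] * 4)
        assert classify_break(340.0, "V1", post, RULES) == BreakType.type_II

    def test_cl_difference_alone_makes_type_two(self):
        post = _beats([(290.0, "V1", False), (285.0, "V1", False)]
                      + [(800.0, "N", True)] * 4)
        assert classify_break(340.0, "V1", post, RULES) == BreakType.type_II

    def test_no_normal_run_is_none(self):
        post = _beats([(340.0, "V1", False)] * 10)
        assert classify_break(340.0, "V1", post, RULES) == BreakType.none

    def test_empty_post_events_rejected(self):
        with pytest.raises(ValueError):
            classify_break(340.0, "V1", [], RULES)


def _stream(rows):
    t = 0.0
    out = []
    for interval, marker, morph in rows:
        t += interval
        out.append(IntervalEvent(t, interval, marker, morph))
    return out


class TestRhythmClassification:
    def test_stable_single_morphology_is_mvt(self):
        s = _stream([(800.0, "VS", "N")] * 2 + [(340.0, "TS", "V1")] * 20)
        assert classify_rhythm(s, RULES, 400.0) == RhythmClass.MVT

    def test_morphology_churn_at_short_cl_is_pvt(self, rng):
        rows = [(800.0, "VS", "N")] * 2
        rows += [(float(max(150, rng.normal(210, 50))), "FS", f"P{k:02d}")
                 for k in range(20)]
        assert classify_rhythm(_stream(rows), RULES, 400.0) == RhythmClass.PVT_VF

    def test_sinus_morphology_tachycardia_is_svt(self):
        s = _stream([(800.0, "VS", "N")] * 2 + [(380.0, "TS", "N")] * 20)
        assert classify_rhythm(s, RULES, 400.0) == RhythmClass.SVT

    def test_twave_labels_are_oversensing(self):
        s = _stream([(800.0, "VS", "N")] * 2
                    + [(340.0, "TS", "N"), (380.0, "TS", "T")] * 10)
        assert classify_rhythm(s, RULES, 400.0) == RhythmClass.TWOS

    def test_self_terminating_run_is_nsvt(self):
        s = _stream([(800.0, "VS", "N")] * 2 + [(330.0, "TS", "V1")] * 18
                    + [(810.0, "VS", "N")] * 2)
        assert classify_rhythm(s, RULES, 400.0) == RhythmClass.NSVT

    def test_short_stream_rejected(self):
        with pytest.raises(ValueError, match="insufficient_context"):
            classify_rhythm(_stream([(340.0, "TS", "V1")] * 5), RULES, 400.0)

    def test_agreement_with_generator_truth(self):
        """Rhythm classing recovers the generator's truth on >= 99% of
        episodes in a mixed cohort."""
        cohort = sample_cohort(CohortParams(n_patients=130, seed=31))
        sim = simulate_cohort(cohort)
        assert len(sim.records) >= 1000
        ok = sum(
            classify_rhythm(r.interval_stream, RULES, r.slowest_boundary_ms).value
            == r.true_rhythm
            for r in sim.records)
        assert ok / len(sim.records) >= 0.99


class TestCategories:
    def test_vt_nid_boundary(self):
        zc16 = ZoneConfig(Zone.VT, 400.0, 16, 12, 7)
        zc20 = ZoneConfig(Zone.VT, 400.0, 20, 12, 7)
        assert detection_category(zc16) == "short"
        assert detection_category(zc20) == "extended"

    def test_vf_nominal_thirty_of_forty_is_extended(self):
        zc = ZoneConfig(Zone.VF, 320.0, (30, 40), (12, 16), 3)
        assert detection_category(zc) == "extended"
        zc_short = ZoneConfig(Zone.VF, 320.0, (18, 24), (12, 16), 3)
        assert detection_category(zc_short) == "short"

    @pytest.mark.parametrize("n,zone,expected", [
        (7, Zone.VT, "at_least_nominal"),
        (6, Zone.VT, "below_nominal"),
        (2, Zone.VF, "below_nominal"),
        (3, Zone.VF, "at_least_nominal"),
        (5, Zone.FVT_via_VT, "at_least_nominal"),
        (4, Zone.FVT_via_VF, "below_nominal"),
    ])
    def test_sequence_category(self, n, zone, expected):
        assert sequence_category(n, zone, RULES) == expected

    def test_rate_class_cutoff(self):
        assert rate_class(319.9, RULES) == "rapid"
        assert rate_class(320.0, RULES) == "slower"


class TestEpisodeAdjudication:
    def test_truth_agreement_on_large_seeded_cohort(self):
        """Stream-derived per-sequence effects match the simulator's own
        labels on >= 99% of MVT episodes (5000+ episodes)."""
        n_ep = 0
        n_ok = 0
        mism = []
        for seed in (311, 312):
            cohort = sample_cohort(CohortParams(n_patients=400, seed=seed))
            sim = simulate_cohort(cohort)
            for rec in sim.records:
                if rec.true_rhythm != "MVT":
                    continue
                n_ep += 1
                zc = cohort.device_configs[rec.patient_id].zone_cfg(rec.detected_zone)
                adj = adjudicate_episode(rec, RULES, zone_cfg=zc)
                ok = all(s.effect == e for s, e in
                         zip(rec.sequences, adj.per_sequence_effects))
                n_ok += ok
                if not ok:
                    mism.append(rec.episode_id)
        assert n_ep >= 5000
        assert n_ok / n_ep >= 0.99, f"disagreements: {mism[:20]}"

    def test_success_implication_and_rate_partition(self, sim336, adjudicated336):
        adj = adjudicated336
        mvt = adj[adj["rhythm_class"] == "MVT"]
        # iatp success implies shock-free success
        assert (~mvt["iatp_success"] | mvt["shock_free_success"]).all()
        # rapid + slower partition the MVT episodes
        assert (mvt["rate_class"].isin(["rapid", "slower"])).all()
        n = (mvt["rate_class"] == "rapid").sum() + (mvt["rate_class"] == "slower").sum()
        assert n == len(mvt)

    def test_conventional_burst_rescue_is_shock_free_but_not_iatp_success(self, sim336):
        """Episodes terminated by the follow-on conventional burst count as
        shock-free success but not IATP success."""
        rescued = [r for r in sim336.records
                   if r.true_rhythm == "MVT" and r.conventional_terminated]
        assert rescued, "expected at least one conventional-burst rescue"
        for rec in rescued:
            adj = adjudicate_episode(rec, RULES)
            assert adj.shock_free_success and not adj.iatp_success

    def test_first_effective_before_episode_end_on_reinitiation(self, sim336):
        """When VT re-initiates after a break, the electrophysiologically
        effective sequence precedes the device's episode end."""
        found = 0
        for rec in sim336.records:
            if rec.true_rhythm != "MVT" or rec.episode_end_seq is None:
                continue
            if rec.first_effective_seq is not None and \
               rec.first_effective_seq < rec.episode_end_seq:
                adj = adjudicate_episode(rec, RULES)
                assert adj.first_effective_seq == rec.first_effective_seq
                found += 1
        assert found >= 1


class TestPatientSummary:
    def _adj(self, success, n_seq):
        from iatpsim.adjudication import AdjudicatedEpisode
        return AdjudicatedEpisode(
            patient_id="P0", episode_id="E", rhythm_class=RhythmClass.MVT,
            per_sequence_effects=[], iatp_success=success,
            shock_free_success=success, acceleration_class="none",
            rate_class="slower", detection_category="short",
            sequence_category="at_least_nominal", first_effective_seq=1,
            final_outcome="termination_by_iatp", n_sequences=n_seq)

    def test_all_successful(self):
        s = patient_summary([self._adj(True, 1), self._adj(True, 2), self._adj(True, 5)])
        assert s["all_success"] and s["any_success"] and not s["all_fail"]
        assert s["max_sequences_in_successful_episode"] == 5
        assert s["episode_count"] == 3

    def test_mixed_outcomes(self):
        s = patient_summary([self._adj(True, 2), self._adj(False, 7)])
        assert s["any_success"] and not s["all_success"] and not s["all_fail"]
        assert s["max_sequences_in_successful_episode"] == 2

    def test_all_failures_have_no_max(self):
        s = patient_summary([self._adj(False, 3)])
        assert s["all_fail"] and s["max_sequences_in_successful_episode"] is None

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            patient_summary([])
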