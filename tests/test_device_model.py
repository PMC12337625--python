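"""Detection state machine and IATP therapy-engine tests."""

import numpy as np
import pytest

from iatpsim.device_model import (
    ATPSequence,
    DeviceConfig,
    FinalState,
    SequenceEffect,
    TherapyState,
    Zone,
    ZoneConfig,
    detect_onset,
    device_termination_index,
    interpret_ppi,
    measure_ppi,
    plan_sequence,
    run_episode,
)
from iatpsim.vt_dynamics import Beat, CircuitParams, IntervalEvent, emit_interval_stream


def naive_detect(iv, config):
    """Independent window-scan oracle for detect_onset."""
    counts = {z.zone: 0 for z in config.zones}
    for i, x in enumerate(iv):
        for zc in config.zones:
            if isinstance(zc.nid_initial, tuple):
                xx, yy = zc.nid_initial
                window = iv[max(0, i + 1 - yy): i + 1]
                met = sum(1 for w in window if w < zc.boundary_ms) >= xx
            else:
                counts[zc.zone] = counts[zc.zone] + 1 if x < zc.boundary_ms else 0
                met = counts[zc.zone] >= zc.nid_initial
            if met:
                return zc.zone, i
    return None


class TestDetection:
    def test_vt_consecutive_count(self, nominal_config):
        det = detect_onset([340.0] * 16, nominal_config)
        assert det.zone == Zone.VT and det.index == 15
        assert det.measured_cl_ms == 340.0

    def test_vf_x_of_y_boundary(self):
        cfg = DeviceConfig(zones=(ZoneConfig(Zone.VF, 320.0, (30, 40), (12, 16), 3),
                                  ZoneConfig(Zone.VT, 400.0, 100, 12, 7)))
        # 29 short of the last 40: no detection; one more short: detection
        iv = [500.0] * 11 + [300.0] * 29
        assert detect_onset(iv, cfg) is None
        assert detect_onset(iv + [300.0], cfg).zone == Zone.VF

    def test_alternating_intervals_never_detect(self, nominal_config):
        iv = [300.0, 500.0] * 40
        assert detect_onset(iv, nominal_config) is None
        assert naive_detect(iv, nominal_config) is None

    def test_agrees_with_naive_scan_on_random_streams(self, rng):
        cfg = DeviceConfig(zones=(ZoneConfig(Zone.VF, 320.0, (12, 16), (9, 12), 3),
                                  ZoneConfig(Zone.VT, 400.0, 12, 8, 7)))
        for _ in range(1500):
            iv = rng.choice([250.0, 300.0, 340.0, 380.0, 420.0, 600.0],
                            size=rng.integers(5, 40)).tolist()
            got = detect_onset(iv, cfg)
            want = naive_detect(iv, cfg)
            if want is None:
                assert got is None
            else:
                assert (got.zone, got.index) == want


class TestPlanning:
    def test_first_sequence_defaults(self):
        zc = ZoneConfig(Zone.VT, 400.0, 16, 12, 7, min_s2s3_ms=200.0)
        st = TherapyState(min_s2s3_ms=200.0)
        seq = plan_sequence(st, 340.0, zc)
        assert seq.s1_interval_ms == 299.0       # round(0.88 * 340)
        assert seq.s2_ci_ms == 289.0             # round(0.85 * 340)
        assert seq.s3_ci_ms is None
        assert seq.n_s1 == 8

    def test_s3_not_before_third_sequence_even_when_enabled(self):
        zc = ZoneConfig(Zone.VT, 400.0, 16, 12, 7)
        st = TherapyState(min_s2s3_ms=200.0, seq_index=2, s3_enabled=True)
        assert plan_sequence(st, 340.0, zc).s3_ci_ms is None
        st.seq_index = 3
        assert plan_sequence(st, 340.0, zc).s3_ci_ms is not None

    def test_s2_floor_not_decremented_below_minimum(self):
        st = TherapyState(min_s2s3_ms=200.0, s2_ci_ms=200.0)
        st2 = interpret_ppi(st, 510.0, 340.0, 510.0)  # capture verdict
        assert st2.s2_ci_ms == 200.0

    def test_sequences_exhausted_error(self):
        zc = ZoneConfig(Zone.VT, 400.0, 16, 12, max_sequences=2)
        st = TherapyState(min_s2s3_ms=200.0, seq_index=3)
        with pytest.raises(ValueError, match="sequences_exhausted"):
            plan_sequence(st, 340.0, zc)


class TestPPIInterpretation:
    def test_ppi_within_tolerance_is_capture(self):
        st = TherapyState(min_s2s3_ms=200.0, s2_ci_ms=289.0)
        out = interpret_ppi(st, 510.0, 340.0, 510.0)
        assert out.consecutive_noncapture == 0
        assert out.s2_ci_ms == 269.0             # decrement scheduled

    def test_ppi_beyond_tolerance_is_noncapture(self):
        st = TherapyState(min_s2s3_ms=200.0, s2_ci_ms=289.0)
        out = interpret_ppi(st, 600.0, 340.0, 510.0)
        assert out.consecutive_noncapture == 1
        assert out.s2_ci_ms == 289.0             # no decrement on non-capture

    def test_two_noncaptures_enable_s3_from_sequence_three(self):
        zc = ZoneConfig(Zone.VT, 400.0, 16, 12, 7)
        st = TherapyState(min_s2s3_ms=200.0, s2_ci_ms=289.0, seq_index=2)
        st = interpret_ppi(st, 600.0, 340.0, 510.0)
        assert not st.s3_enabled
        st = interpret_ppi(st, 600.0, 340.0, 510.0)
        assert st.s3_enabled
        assert st.seq_index == 4
        seq = plan_sequence(st, 340.0, zc)
        assert seq.s3_ci_ms == seq.s2_ci_ms - 20.0

    def test_noncapture_at_floor_enables_s3(self):
        st = TherapyState(min_s2s3_ms=200.0, s2_ci_ms=200.0, seq_index=3)
        st = interpret_ppi(st, 600.0, 340.0, 510.0)
        assert st.s3_enabled

    def test_missing_ppi_leaves_state_unchanged(self):
        st = TherapyState(min_s2s3_ms=200.0, s2_ci_ms=289.0)
        out = interpret_ppi(st, None, 340.0, 510.0)
        assert out.s2_ci_ms == 289.0 and out.consecutive_noncapture == 0


class TestMeasurePPI:
    def test_simple_measurement(self):
        stream = [IntervalEvent(1000.0, 299.0, "TP", "paced"),
                  IntervalEvent(1510.0, 510.0, "TS", "V1")]
        assert measure_ppi(stream, 1000.0) == 510.0

    def test_absent_when_no_later_sense(self):
        stream = [IntervalEvent(1000.0, 299.0, "TP", "paced")]
        assert measure_ppi(stream, 1000.0) is None

    def test_round_trip_with_emitted_stream(self):
        beats = [Beat(700.0, "TP", "paced"), Beat(1210.0, "TS", "V1")]
        ev = emit_interval_stream(None, beats)
        assert measure_ppi(ev, 700.0) == 510.0


class TestRunEpisode:
    def test_certain_termination_single_sequence(self, nominal_config):
        c = CircuitParams(term_center_ms=-1e9, p_acc_mvt=0.0, p_acc_pvt=0.0,
                          p_reinit=0.0, p_spont=0.0, p_slow=0.0)
        rec = run_episode(c, nominal_config, np.random.default_rng(0))
        assert rec.final_state == FinalState.terminated_by_atp
        assert len(rec.sequences) == 1
        assert rec.episode_end_seq == 1
        assert rec.shocks_delivered == 0

    def test_never_terminates_exhausts_to_shock(self):
        cfg = DeviceConfig(zones=(
            ZoneConfig(Zone.VF, 320.0, (30, 40), (12, 16), 3),
            ZoneConfig(Zone.VT, 400.0, 16, 12, 7, conventional_burst_after=False),
        ))
        c = CircuitParams(term_center_ms=1e9, p_acc_mvt=0.0, p_acc_pvt=0.0,
                          p_reinit=0.0, p_spont=0.0, p_slow=0.0)
        rec = run_episode(c, cfg, np.random.default_rng(0))
        assert rec.final_state == FinalState.shocked
        assert len(rec.sequences) == 7
        assert rec.shocks_delivered == 1

    def test_internal_consistency_multi_sequence_fraction(self, sim336):
        """P(>= 2 sequences) equals 1 - P(first sequence ends the episode),
        recomputed by an independent scan of the records."""
        mvt = [r for r in sim336.records if r.true_rhythm == "MVT"]
        frac_multi = np.mean([len(r.sequences) >= 2 for r in mvt])
        ended_at_1 = np.mean([len(r.sequences) == 1 for r in mvt])
        assert frac_multi == pytest.approx(1.0 - ended_at_1)

    def test_no_coupling_below_floor_and_s3_rules(self, sim336):
        """Programmed floors and the no-S3-before-sequence-3 rule hold over
        every simulated sequence."""
        assert len(sim336.sequences) > 1000
        seqs = sim336.sequences
        assert (seqs["s2_ci_ms"] >= 150.0).all()
        s3 = seqs.dropna(subset=["s3_ci_ms"])
        assert (s3["s3_ci_ms"] >= 150.0).all()
        assert (s3["seq_index"] >= 3).all()

    def test_min_s2s3_respected_per_zone(self, sim336):
        merged = sim336.sequences.merge(
            sim336.episodes[["episode_id", "min_s2s3_ms"]], on="episode_id")
        assert (merged["s2_ci_ms"] >= merged["min_s2s3_ms"]).all()
        s3 = merged.dropna(subset=["s3_ci_ms"])
        assert (s3["s3_ci_ms"] >= s3["min_s2s3_ms"]).all()

    def test_more_sequences_never_hurt_under_common_random_numbers(self):
        """Paired-seed monotonicity: raising max_sequences cannot turn a
        success into a failure."""
        def success(seed, max_seq):
            cfg = DeviceConfig(zones=(
                ZoneConfig(Zone.VF, 320.0, (30, 40), (12, 16), 3),
                ZoneConfig(Zone.VT, 400.0, 16, 12, max_seq,
                           conventional_burst_after=False),
            ))
            c = CircuitParams(term_center_ms=75.0, p_reinit=0.0)
            rec = run_episode(c, cfg, np.random.default_rng(seed))
            return rec.final_state in (FinalState.terminated_by_atp,
                                       FinalState.spontaneous_termination,
                                       FinalState.rate_below_zone)
        for seed in range(150):
            assert success(seed, 3) <= success(seed, 4)

    def test_episode_termination_matches_naive_scan(self, sim336, nominal_config):
        """The recorded episode end agrees with a naive scan for 8
        consecutive intervals above every boundary."""
        checked = 0
        for rec in sim336.records[:300]:
            iv = [e.interval_ms for e in rec.interval_stream if e.marker != "TP"]
            run = 0
            naive = None
            for i, x in enumerate(iv):
                run = run + 1 if x > rec.slowest_boundary_ms else 0
                if run >= 8:
                    naive = i
                    break
            ended = rec.final_state in (FinalState.terminated_by_atp,
                                        FinalState.spontaneous_termination,
                                        FinalState.rate_below_zone,
                                        FinalState.shocked)
            if ended and rec.final_state != FinalState.rate_below_zone:
                assert naive is not None
                checked += 1
        assert checked > 100

    def test_determinism(self, nominal_config):
        r1 = run_episode(CircuitParams(), nominal_config, np.random.default_rng(5))
        r2 = run_episode(CircuitParams(), nominal_config, np.random.default_rng(5))
        assert r1 == r2


class TestConfigValidation:
    def test_boundaries_must_increase(self):
        with pytest.raises(ValueError):
            DeviceConfig(zones=(ZoneConfig(Zone.VF, 400.0, (30, 40), (12, 16), 3),
                                ZoneConfig(Zone.VT, 320.0, 16, 12, 7)))

    def test_max_sequences_capped_at_ten(self):
        with pytest.raises(ValueError):
            ZoneConfig(Zone.VT, 400.0, 16, 12, max_sequences=11)

    def test_min_s2s3_floor(self):
        with pytest.raises(ValueError):
            ZoneConfig(Zone.VT, 400.0, 16, 12, 7, min_s2s3_ms=120.0)

    def test_json_round_trip(self, nominal_config):
        assert DeviceConfig.from_dict(nominal_config.to_dict()) == nominal_config
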