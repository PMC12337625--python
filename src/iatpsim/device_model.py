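"""ICD detection state machine and closed-loop IATP therapy engine.

Detection follows the two counting styles used by transvenous ICDs:
VT-type zones require a programmable number of *consecutive* intervals
shorter than the zone boundary (the NID), while VF-type zones use a
probabilistic x-of-y counter over the most recent intervals.  An episode
ends when eight consecutive intervals are longer than every programmed
detection boundary.

The therapy engine implements an individualized antitachycardia pacing
(IATP) protocol: every sequence is a burst of S1 stimuli at 88% of the
measured cycle length followed by a single premature extrastimulus (S2),
escalating to double extrastimuli (S2+S3) no earlier than the third
sequence.  Escalation is driven by the post-pacing interval (PPI): a PPI
much longer than the expected reset PPI means the extrastimulus failed to
capture the circuit, and persistent loss of S2 capture makes the
single-extrastimulus approach futile.  Two parameters are programmable per
zone: the maximum number of sequences and the minimum extrastimulus
coupling (min S2/S3).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional, Sequence, Union

import numpy as np

from iatpsim.vt_dynamics import (
    Beat,
    CircuitParams,
    IntervalEvent,
    SVTOutcome,
    SVTParams,
    TrainOutcome,
    emit_interval_stream,
    respond_to_train,
    svt_respond_to_train,
    SINUS_MORPH,
    SINUS_CL_MS,
)

__all__ = [
    "Zone",
    "ZoneConfig",
    "DeviceConfig",
    "TherapyState",
    "ATPSequence",
    "EpisodeRecord",
    "Detection",
    "SequenceEffect",
    "FinalState",
    "NSVTParams",
    "PVTParams",
    "TWOSParams",
    "detect_onset",
    "plan_sequence",
    "interpret_ppi",
    "measure_ppi",
    "run_episode",
    "device_termination_index",
    "PPI_CAPTURE_TOLERANCE_MS",
    "S2_INITIAL_FRACTION",
    "S2_DECREMENT_MS",
]

PPI_CAPTURE_TOLERANCE_MS = 40.0
S1_FRACTION = 0.88
S2_INITIAL_FRACTION = 0.85
S2_DECREMENT_MS = 20.0
N_S1_DEFAULT = 8
POST_THERAPY_BEAT_CAP = 200


class Zone(str, Enum):
    VF = "VF"
    FVT_via_VF = "FVT_via_VF"
    FVT_via_VT = "FVT_via_VT"
    VT = "VT"


#: zones using the x-of-y (probabilistic) counter
VF_TYPE_ZONES = {Zone.VF, Zone.FVT_via_VF}

NOMINAL_SEQUENCES = {"VF": 3, "FVT": 5, "VT": 7}


class SequenceEffect(str, Enum):
    type_I_break = "type_I_break"
    type_II_break = "type_II_break"
    no_effect = "no_effect"
    accelerated_mvt = "accelerated_mvt"
    polymorphic_accel = "polymorphic_accel"
    spontaneous_resumption = "spontaneous_resumption"


class FinalState(str, Enum):
    terminated_by_atp = "terminated_by_atp"
    spontaneous_termination = "spontaneous_termination"
    rate_below_zone = "rate_below_zone"
    shocked = "shocked"
    ongoing = "ongoing"


@dataclass(frozen=True)
class ZoneConfig:
    """Programming of one detection/therapy zone."""

    zone: Zone
    boundary_ms: float
    nid_initial: Union[int, tuple[int, int]]
    nid_redetect: Union[int, tuple[int, int]]
    max_sequences: int
    min_s2s3_ms: float = 200.0
    n_iatp_therapies: int = 1
    conventional_burst_after: bool = False

    def __post_init__(self) -> None:
        if self.boundary_ms <= 0:
            raise ValueError("boundary_ms must be positive")
        if not (0 <= self.max_sequences <= 10):
            raise ValueError("max_sequences must be within 0..10 per therapy slot")
        if self.min_s2s3_ms < 150:
            raise ValueError("min_s2s3_ms must be >= 150 ms")
        is_vf_type = self.zone in VF_TYPE_ZONES
        for nid in (self.nid_initial, self.nid_redetect):
            if is_vf_type and not (isinstance(nid, tuple) and len(nid) == 2):
                raise ValueError("VF-type zones need an (x, y) NID pair")
            if not is_vf_type and not isinstance(nid, int):
                raise ValueError("VT-type zones need an integer NID")

    @property
    def total_sequences(self) -> int:
        return self.max_sequences * self.n_iatp_therapies


@dataclass(frozen=True)
class DeviceConfig:
    """Full device detection/therapy programming (zones fastest first)."""

    zones: tuple[ZoneConfig, ...]
    termination_run: int = 8

    def __post_init__(self) -> None:
        bounds = [z.boundary_ms for z in self.zones]
        if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
            raise ValueError("zone boundaries must strictly increase fastest-to-slowest")

    @property
    def slowest_boundary_ms(self) -> float:
        return self.zones[-1].boundary_ms

    def zone_cfg(self, zone: Zone) -> ZoneConfig:
        for z in self.zones:
            if z.zone == zone:
                return z
        raise KeyError(zone)

    @staticmethod
    def nominal() -> "DeviceConfig":
        """Nominal two-zone programming: VF 320 ms 30/40, VT 400 ms NID 16."""
        return DeviceConfig(
            zones=(
                ZoneConfig(Zone.VF, 320.0, (30, 40), (12, 16), 3),
                ZoneConfig(Zone.VT, 400.0, 16, 12, 7),
            )
        )

    def to_dict(self) -> dict:
        return {
            "termination_run": self.termination_run,
            "zones": [
                {
                    "zone": z.zone.value,
                    "boundary_ms": z.boundary_ms,
                    "nid_initial": list(z.nid_initial) if isinstance(z.nid_initial, tuple) else z.nid_initial,
                    "nid_redetect": list(z.nid_redetect) if isinstance(z.nid_redetect, tuple) else z.nid_redetect,
                    "max_sequences": z.max_sequences,
                    "min_s2s3_ms": z.min_s2s3_ms,
                    "n_iatp_therapies": z.n_iatp_therapies,
                    "conventional_burst_after": z.conventional_burst_after,
                }
                for z in self.zones
            ],
        }

    @staticmethod
    def from_dict(d: dict) -> "DeviceConfig":
        zones = []
        for zd in d["zones"]:
            nid_i = zd["nid_initial"]
            nid_r = zd["nid_redetect"]
            zones.append(
                ZoneConfig(
                    zone=Zone(zd["zone"]),
                    boundary_ms=float(zd["boundary_ms"]),
                    nid_initial=tuple(nid_i) if isinstance(nid_i, list) else int(nid_i),
                    nid_redetect=tuple(nid_r) if isinstance(nid_r, list) else int(nid_r),
                    max_sequences=int(zd["max_sequences"]),
                    min_s2s3_ms=float(zd.get("min_s2s3_ms", 200.0)),
                    n_iatp_therapies=int(zd.get("n_iatp_therapies", 1)),
                    conventional_burst_after=bool(zd.get("conventional_burst_after", False)),
                )
            )
        return DeviceConfig(zones=tuple(zones), termination_run=int(d.get("termination_run", 8)))


@dataclass(frozen=True)
class Detection:
    zone: Zone
    index: int            # index of the interval satisfying the criterion
    measured_cl_ms: float  # median of the last 4 intervals


@dataclass(frozen=True)
class ATPSequence:
    """One delivered IATP sequence and its measured response."""

    seq_index: int
    n_s1: int
    s1_interval_ms: float
    s2_ci_ms: float
    s3_ci_ms: Optional[float] = None
    ppi_ms: Optional[float] = None
    effect: SequenceEffect = SequenceEffect.no_effect


@dataclass
class EpisodeRecord:
    """One detected tachyarrhythmia episode and everything the device saw."""

    patient_id: str
    episode_id: str
    detected_zone: Zone
    initial_cl_ms: float
    true_rhythm: str           # MVT | SVT | PVT_VF | NSVT | TWOS
    sequences: list[ATPSequence] = field(default_factory=list)
    shocks_delivered: int = 0
    final_state: FinalState = FinalState.ongoing
    interval_stream: list[IntervalEvent] = field(default_factory=list)
    episode_end_seq: Optional[int] = None
    first_effective_seq: Optional[int] = None   # generator-side truth
    conventional_attempted: bool = False
    conventional_terminated: bool = False
    morph_id: str = "V1"
    slowest_boundary_ms: float = 400.0


@dataclass
class TherapyState:
    """Mutable planning state of the IATP engine within one episode."""

    min_s2s3_ms: float
    seq_index: int = 1
    n_s1: int = N_S1_DEFAULT
    s2_ci_ms: Optional[float] = None
    s3_enabled: bool = False
    consecutive_noncapture: int = 0


# ---------------------------------------------------------------------------
# detection

def _intervals(stream) -> np.ndarray:
    if len(stream) and isinstance(stream[0], IntervalEvent):
        return np.asarray([e.interval_ms for e in stream], dtype=float)
    return np.asarray(stream, dtype=float)


def detect_onset(stream, config: DeviceConfig) -> Optional[Detection]:
    """Scan an interval series for the first satisfied zone criterion.

    VT-type zones count consecutive sub-boundary intervals; VF-type zones
    require x of the most recent y intervals below the boundary.  When more
    than one zone's criterion is met at the same interval, the fastest zone
    claims the episode.
    """
    iv = _intervals(stream)
    if iv.size == 0:
        raise ValueError("empty stream")
    counts = {z.zone: 0 for z in config.zones}
    for i, x in enumerate(iv):
        for zc in config.zones:  # fastest first
            if zc.zone in VF_TYPE_ZONES:
                xx, yy = zc.nid_initial
                lo = max(0, i + 1 - yy)
                n_short = int(np.sum(iv[lo : i + 1] < zc.boundary_ms))
                met = n_short >= xx
            else:
                if x < zc.boundary_ms:
                    counts[zc.zone] += 1
                else:
                    counts[zc.zone] = 0
                met = counts[zc.zone] >= zc.nid_initial
            if met:
                last4 = iv[max(0, i - 3) : i + 1]
                return Detection(zc.zone, i, float(np.median(last4)))
    return None


def device_termination_index(stream, config: DeviceConfig) -> Optional[int]:
    """Index of the interval completing 8 consecutive intervals longer than
    every detection boundary, or None."""
    iv = _intervals(stream)
    run = 0
    for i, x in enumerate(iv):
        run = run + 1 if x > config.slowest_boundary_ms else 0
        if run >= config.termination_run:
            return i
    return None


# ---------------------------------------------------------------------------
# therapy planning

def plan_sequence(state: TherapyState, measured_cl_ms: float, zone_cfg: ZoneConfig) -> ATPSequence:
    """Plan the next IATP sequence from current engine state.

    The S1 burst is pinned to 88% of the measured cycle length; the S2
    coupling starts at 85% and is decremented 20 ms after each captured but
    unsuccessful sequence, never below the programmed minimum.  An S3 is
    appended only once escalation has been triggered, and never before the
    third sequence.
    """
    if measured_cl_ms <= 0:
        raise ValueError("measured_cl_ms must be positive")
    if state.seq_index > zone_cfg.total_sequences:
        raise ValueError("sequences_exhausted")
    s1 = round(S1_FRACTION * measured_cl_ms)
    if state.s2_ci_ms is None:
        state.s2_ci_ms = float(round(S2_INITIAL_FRACTION * measured_cl_ms))
    s2 = max(state.s2_ci_ms, state.min_s2s3_ms)
    s3 = None
    if state.s3_enabled and state.seq_index >= 3:
        s3 = max(s2 - S2_DECREMENT_MS, state.min_s2s3_ms)
    return ATPSequence(
        seq_index=state.seq_index,
        n_s1=state.n_s1,
        s1_interval_ms=float(s1),
        s2_ci_ms=float(s2),
        s3_ci_ms=None if s3 is None else float(s3),
    )


def interpret_ppi(
    state: TherapyState,
    ppi_ms: Optional[float],
    measured_cl_ms: float,
    expected_reset_ppi_ms: float,
) -> TherapyState:
    """Update engine state from the PPI of a delivered, unsuccessful sequence.

    A PPI exceeding the expected reset PPI by more than 40 ms is judged a
    loss of extrastimulus capture.  Non-capture at the S2 floor, or two
    consecutive non-capture verdicts, makes the single-extrastimulus
    approach futile and enables the S3.  A captured sequence schedules the
    next 20 ms S2 decrement.
    """
    st = replace(state)
    st.seq_index = state.seq_index + 1
    if ppi_ms is None:
        return st
    if ppi_ms > expected_reset_ppi_ms + PPI_CAPTURE_TOLERANCE_MS:
        st.consecutive_noncapture = state.consecutive_noncapture + 1
        at_floor = state.s2_ci_ms is not None and state.s2_ci_ms <= state.min_s2s3_ms
        if at_floor or st.consecutive_noncapture >= 2:
            st.s3_enabled = True
    else:
        st.consecutive_noncapture = 0
        if state.s2_ci_ms is not None:
            st.s2_ci_ms = max(state.s2_ci_ms - S2_DECREMENT_MS, state.min_s2s3_ms)
    return st


def measure_ppi(stream: Sequence[IntervalEvent], last_pace_time: float) -> Optional[float]:
    """Time from the last delivered pace to the next sensed ventricular event."""
    for e in stream:
        if e.time_ms > last_pace_time and e.marker != "TP":
            return e.time_ms - last_pace_time
    return None


# ---------------------------------------------------------------------------
# episode orchestration

@dataclass(frozen=True)
class NSVTParams:
    """Non-sustained VT: a self-terminating run that may reach detection."""

    vtcl_ms: float = 330.0
    run_beats: int = 24
    morph_id: str = "V1"


@dataclass(frozen=True)
class PVTParams:
    """Polymorphic VT/VF: short irregular intervals with morphology churn."""

    mean_cl_ms: float = 220.0
    sd_cl_ms: float = 40.0


@dataclass(frozen=True)
class TWOSParams:
    """T-wave oversensing: sinus rhythm double-counted as short intervals."""

    sinus_cl_ms: float = 720.0


class _StreamBuilder:
    """Accumulates beats and marks them against the device's zones."""

    def __init__(self, config: DeviceConfig):
        self.config = config
        self.beats: list[Beat] = []
        self.t = 0.0

    def add(self, interval_ms: float, morph: str, paced: bool = False) -> float:
        self.t += interval_ms
        if paced:
            marker = "TP"
        else:
            fastest = self.config.zones[0]
            if interval_ms < fastest.boundary_ms and fastest.zone in VF_TYPE_ZONES:
                marker = "FS"
            elif interval_ms < self.config.slowest_boundary_ms:
                marker = "TS"
            else:
                marker = "VS"
        self.beats.append(Beat(self.t, marker, morph))
        return self.t

    def sensed_intervals(self) -> list[float]:
        iv, prev = [], None
        for b in self.beats:
            if b.marker == "TP":
                prev = b.time_ms
                continue
            if prev is not None:
                iv.append(b.time_ms - prev)
            prev = b.time_ms
        return iv


def _jitter(rng: np.random.Generator, cl: float, sd: float = 4.0) -> float:
    return max(120.0, cl + rng.normal(0.0, sd))


def _append_sinus(sb: _StreamBuilder, rng: np.random.Generator, n: int) -> None:
    for _ in range(n):
        sb.add(_jitter(rng, SINUS_CL_MS, 10.0), SINUS_MORPH)


def _run_vt_until_detected(
    sb: _StreamBuilder,
    config: DeviceConfig,
    cl: float,
    morph: str,
    rng: np.random.Generator,
    redetect: bool,
    cap: int = 200,
) -> Optional[Detection]:
    """Append tachycardia beats until a zone criterion fires."""
    cfg = config if not redetect else DeviceConfig(
        zones=tuple(replace(z, nid_initial=z.nid_redetect) for z in config.zones),
        termination_run=config.termination_run,
    )
    start = len(sb.beats)
    for _ in range(cap):
        sb.add(_jitter(rng, cl), morph)
        seg = [b for b in sb.beats[start:]]
        iv = [b2.time_ms - b1.time_ms for b1, b2 in zip(seg, seg[1:])]
        det = detect_onset(iv, cfg) if iv else None
        if det is not None:
            return det
    return None


def run_episode(
    circuit: Union[CircuitParams, SVTParams, NSVTParams, PVTParams, TWOSParams],
    config: DeviceConfig,
    rng: np.random.Generator,
    patient_id: str = "P0",
    episode_id: str = "E0",
    induced_circuit: Optional[CircuitParams] = None,
    p_type_I: float = 0.75,
) -> EpisodeRecord:
    """Simulate one full device episode: detection, therapy, and resolution.

    The loop alternates detection/redetection with therapy delivery until
    the device's 8-interval termination criterion is met, the rhythm slows
    below every zone, therapies exhaust (a shock converts the rhythm), or a
    post-therapy beat cap elapses.  The electrophysiologically effective
    sequence is recorded even when the tachycardia re-initiates before the
    device recognizes termination.
    """
    if isinstance(circuit, CircuitParams):
        rec = _run_mvt_episode(circuit, config, rng, patient_id, episode_id, p_type_I)
    elif isinstance(circuit, SVTParams):
        rec = _run_svt_episode(circuit, config, rng, patient_id, episode_id,
                               induced_circuit or CircuitParams(), p_type_I)
    elif isinstance(circuit, NSVTParams):
        rec = _run_nsvt_episode(circuit, config, rng, patient_id, episode_id)
    elif isinstance(circuit, PVTParams):
        rec = _run_pvt_episode(circuit, config, rng, patient_id, episode_id)
    elif isinstance(circuit, TWOSParams):
        rec = _run_twos_episode(circuit, config, rng, patient_id, episode_id)
    else:
        raise TypeError(f"unsupported rhythm spec: {type(circuit)!r}")
    rec.slowest_boundary_ms = config.slowest_boundary_ms
    return rec


def _build_train(sb: _StreamBuilder, seq: ATPSequence) -> list[float]:
    """Append the paced train to the stream and return stimulus times."""
    times = []
    for k in range(seq.n_s1):
        times.append(sb.add(seq.s1_interval_ms, "paced", paced=True))
    times.append(sb.add(seq.s2_ci_ms, "paced", paced=True))
    if seq.s3_ci_ms is not None:
        times.append(sb.add(seq.s3_ci_ms, "paced", paced=True))
    return times


def _finish_terminated(sb, rng, record, config) -> None:
    _append_sinus(sb, rng, config.termination_run + 2)


def _run_mvt_episode(circuit, config, rng, patient_id, episode_id, p_type_I) -> EpisodeRecord:
    sb = _StreamBuilder(config)
    _append_sinus(sb, rng, 3)
    det = _run_vt_until_detected(sb, config, circuit.vtcl_ms, circuit.morph_id, rng, redetect=False)
    if det is None:  # pragma: no cover - VT always reaches detection
        raise RuntimeError("VT failed to reach detection")
    zone_cfg = config.zone_cfg(det.zone)
    record = EpisodeRecord(
        patient_id=patient_id,
        episode_id=episode_id,
        detected_zone=det.zone,
        initial_cl_ms=det.measured_cl_ms,
        true_rhythm="MVT",
        morph_id=circuit.morph_id,
    )
    state = TherapyState(min_s2s3_ms=zone_cfg.min_s2s3_ms)
    measured_cl = det.measured_cl_ms
    cur = circuit
    expected_reset_ppi: Optional[float] = None
    post_therapy_beats = 0

    while state.seq_index <= zone_cfg.total_sequences:
        seq = plan_sequence(state, measured_cl, zone_cfg)
        last_beat_t = sb.beats[-1].time_ms
        train = _build_train(sb, seq)
        phase = last_beat_t - cur.d_ms  # entry activated d before last sense
        resp = respond_to_train(cur, phase, train, rng)

        if resp.outcome == TrainOutcome.terminated:
            effect = SequenceEffect.type_I_break if rng.random() < p_type_I else SequenceEffect.type_II_break
            if effect == SequenceEffect.type_I_break:
                n_abn = int(rng.random() < 0.5)
                for _ in range(n_abn):
                    sb.add(_jitter(rng, cur.vtcl_ms + 40, 15.0), cur.morph_id)
            else:
                other = "V2" if cur.morph_id != "V2" else "V3"
                for _ in range(2 + int(rng.integers(0, 3))):
                    sb.add(_jitter(rng, cur.vtcl_ms - 60, 5.0), other)
            record.sequences.append(replace(seq, effect=effect))
            if record.first_effective_seq is None:
                record.first_effective_seq = seq.seq_index
            if rng.random() < cur.p_reinit:
                # MVT re-initiates before the 8-interval criterion is met
                # (>= 4 normal beats so the resumption itself is reviewable)
                _append_sinus(sb, rng, 4 + int(rng.integers(0, 4)))
                det2 = _run_vt_until_detected(sb, config, cur.vtcl_ms, cur.morph_id, rng, redetect=True)
                if det2 is None:
                    break
                measured_cl = det2.measured_cl_ms
                state.seq_index += 1
                post_therapy_beats += 12
                continue
            _finish_terminated(sb, rng, record, config)
            record.final_state = FinalState.terminated_by_atp
            record.episode_end_seq = seq.seq_index
            record.interval_stream = emit_interval_stream(cur, sb.beats)
            return record

        if resp.outcome == TrainOutcome.accelerated_mvt:
            record.sequences.append(replace(seq, effect=SequenceEffect.accelerated_mvt))
            cur = cur.accelerated()
            det2 = _run_vt_until_detected(sb, config, cur.vtcl_ms, cur.morph_id, rng, redetect=True)
            if det2 is None:
                break
            measured_cl = det2.measured_cl_ms
            # re-anchor pacing couplings to the new, faster rhythm
            state = TherapyState(min_s2s3_ms=zone_cfg.min_s2s3_ms, seq_index=state.seq_index + 1)
            expected_reset_ppi = None
            post_therapy_beats += 12
            continue

        if resp.outcome == TrainOutcome.degenerated_pvt:
            record.sequences.append(replace(seq, effect=SequenceEffect.polymorphic_accel))
            for _ in range(20):
                sb.add(max(140.0, rng.normal(220.0, 40.0)), f"P{int(rng.integers(0, 99)):02d}")
            record.shocks_delivered = 1
            record.final_state = FinalState.shocked
            _append_sinus(sb, rng, config.termination_run + 2)
            record.interval_stream = emit_interval_stream(cur, sb.beats)
            return record

        # reset or no_capture: rhythm persists; record PPI and adapt
        ppi = resp.ppi_ms
        first_sensed_cl = ppi if ppi is not None else cur.vtcl_ms
        sb.add(float(first_sensed_cl), cur.morph_id)

        u = rng.random()
        if u < cur.p_spont:
            eff = SequenceEffect.spontaneous_resumption
            for _ in range(1 + int(rng.integers(0, 4))):
                sb.add(_jitter(rng, cur.vtcl_ms, 3.0), cur.morph_id)
            record.sequences.append(replace(seq, ppi_ms=ppi, effect=eff))
            if record.first_effective_seq is None:
                record.first_effective_seq = seq.seq_index
            _finish_terminated(sb, rng, record, config)
            record.final_state = FinalState.spontaneous_termination
            record.episode_end_seq = seq.seq_index
            record.interval_stream = emit_interval_stream(cur, sb.beats)
            return record
        if u < cur.p_spont + getattr(cur, "p_slow", 0.0):
            record.sequences.append(replace(seq, ppi_ms=ppi, effect=SequenceEffect.no_effect))
            slow_cl = config.slowest_boundary_ms + 40.0
            for _ in range(config.termination_run + 2):
                sb.add(_jitter(rng, slow_cl, 5.0), cur.morph_id)
            record.final_state = FinalState.rate_below_zone
            record.episode_end_seq = seq.seq_index
            record.interval_stream = emit_interval_stream(cur, sb.beats)
            return record

        record.sequences.append(replace(seq, ppi_ms=ppi, effect=SequenceEffect.no_effect))
        if expected_reset_ppi is None or (ppi is not None and ppi < expected_reset_ppi):
            expected_reset_ppi = ppi
        state = interpret_ppi(state, ppi, measured_cl, expected_reset_ppi if expected_reset_ppi is not None else ppi or 0.0)

        det2 = _run_vt_until_detected(sb, config, cur.vtcl_ms, cur.morph_id, rng, redetect=True)
        if det2 is None:
            break
        measured_cl = det2.measured_cl_ms
        post_therapy_beats += 12
        if post_therapy_beats > POST_THERAPY_BEAT_CAP:
            record.final_state = FinalState.ongoing
            record.interval_stream = emit_interval_stream(cur, sb.beats)
            return record

    # IATP slots exhausted
    if zone_cfg.conventional_burst_after:
        record.conventional_attempted = True
        burst_ci = round(S1_FRACTION * measured_cl)
        last_beat_t = sb.beats[-1].time_ms
        times = [sb.add(burst_ci, "paced", paced=True) for _ in range(8)]
        resp = respond_to_train(cur, last_beat_t - cur.d_ms, times, rng)
        if resp.outcome == TrainOutcome.terminated:
            record.conventional_terminated = True
            _finish_terminated(sb, rng, record, config)
            record.final_state = FinalState.terminated_by_atp
            record.interval_stream = emit_interval_stream(cur, sb.beats)
            return record
        sb.add(resp.ppi_ms if resp.ppi_ms else cur.vtcl_ms, cur.morph_id)
        for _ in range(6):
            sb.add(_jitter(rng, cur.vtcl_ms), cur.morph_id)
    record.shocks_delivered = 1
    record.final_state = FinalState.shocked
    _append_sinus(sb, rng, config.termination_run + 2)
    record.interval_stream = emit_interval_stream(cur, sb.beats)
    return record


def _run_svt_episode(params, config, rng, patient_id, episode_id, induced_circuit, p_type_I) -> EpisodeRecord:
    sb = _StreamBuilder(config)
    _append_sinus(sb, rng, 3)
    det = _run_vt_until_detected(sb, config, params.svt_cl_ms, SINUS_MORPH, rng, redetect=False)
    if det is None:
        # SVT too slow for any zone: no episode; represent as undetected record
        rec = EpisodeRecord(patient_id, episode_id, config.zones[-1].zone,
                            params.svt_cl_ms, "SVT", final_state=FinalState.rate_below_zone)
        rec.interval_stream = emit_interval_stream(params, sb.beats)
        return rec
    zone_cfg = config.zone_cfg(det.zone)
    record = EpisodeRecord(
        patient_id=patient_id,
        episode_id=episode_id,
        detected_zone=det.zone,
        initial_cl_ms=det.measured_cl_ms,
        true_rhythm="SVT",
        morph_id=SINUS_MORPH,
    )
    state = TherapyState(min_s2s3_ms=zone_cfg.min_s2s3_ms)
    while state.seq_index <= zone_cfg.total_sequences:
        seq = plan_sequence(state, det.measured_cl_ms, zone_cfg)
        train = _build_train(sb, seq)
        outcome = svt_respond_to_train(params, train, rng)
        sb.add(params.svt_cl_ms, SINUS_MORPH)
        if outcome == SVTOutcome.pvc:
            for _ in range(1 + int(rng.integers(0, 2))):
                sb.add(_jitter(rng, params.svt_cl_ms - 80, 10.0), "V9")
            record.sequences.append(replace(seq, effect=SequenceEffect.no_effect))
        elif outcome == SVTOutcome.nsvt:
            for _ in range(5):
                sb.add(_jitter(rng, 310.0, 6.0), "V8")
            record.sequences.append(replace(seq, effect=SequenceEffect.no_effect))
        elif outcome == SVTOutcome.induced_mvt:
            record.sequences.append(replace(seq, effect=SequenceEffect.accelerated_mvt))
            sub = _run_mvt_episode(induced_circuit, config, rng,
                                   patient_id, episode_id + "_ind", p_type_I)
            record.sequences.extend(sub.sequences)
            record.shocks_delivered += sub.shocks_delivered
            record.final_state = sub.final_state
            t0 = sb.t
            sb.beats.extend(Beat(e.time_ms + t0, e.marker, e.morph)
                            for e in sub.interval_stream)
            record.interval_stream = emit_interval_stream(params, sb.beats)
            return record
        elif outcome == SVTOutcome.induced_vf:
            record.sequences.append(replace(seq, effect=SequenceEffect.polymorphic_accel))
            for _ in range(20):
                sb.add(max(140.0, rng.normal(210.0, 40.0)), f"P{int(rng.integers(0, 99)):02d}")
            record.shocks_delivered = 1
            record.final_state = FinalState.shocked
            _append_sinus(sb, rng, config.termination_run + 2)
            record.interval_stream = emit_interval_stream(params, sb.beats)
            return record
        else:
            record.sequences.append(replace(seq, effect=SequenceEffect.no_effect))
        if rng.random() < getattr(params, "p_rate_drop", 0.2):
            slow = config.slowest_boundary_ms + 60.0
            for _ in range(config.termination_run + 2):
                sb.add(_jitter(rng, slow, 8.0), SINUS_MORPH)
            record.final_state = FinalState.rate_below_zone
            record.interval_stream = emit_interval_stream(params, sb.beats)
            return record
        det2 = _run_vt_until_detected(sb, config, params.svt_cl_ms, SINUS_MORPH, rng, redetect=True)
        if det2 is None:
            break
        state.seq_index += 1
    record.shocks_delivered = 1
    record.final_state = FinalState.shocked
    _append_sinus(sb, rng, config.termination_run + 2)
    record.interval_stream = emit_interval_stream(params, sb.beats)
    return record


def _run_nsvt_episode(params, config, rng, patient_id, episode_id) -> EpisodeRecord:
    sb = _StreamBuilder(config)
    _append_sinus(sb, rng, 3)
    det = _run_vt_until_detected(sb, config, params.vtcl_ms, params.morph_id, rng,
                                 redetect=False, cap=params.run_beats)
    if det is None:
        rec = EpisodeRecord(patient_id, episode_id, config.zones[-1].zone,
                            params.vtcl_ms, "NSVT", final_state=FinalState.spontaneous_termination)
        _append_sinus(sb, rng, config.termination_run + 2)
        rec.interval_stream = emit_interval_stream(params, sb.beats)
        return rec
    zone_cfg = config.zone_cfg(det.zone)
    record = EpisodeRecord(patient_id, episode_id, det.zone, det.measured_cl_ms, "NSVT",
                           morph_id=params.morph_id)
    # the run self-terminates after detection; committed therapy delivers anyway
    _append_sinus(sb, rng, 1 + int(rng.integers(0, 2)))
    state = TherapyState(min_s2s3_ms=zone_cfg.min_s2s3_ms)
    seq = plan_sequence(state, det.measured_cl_ms, zone_cfg)
    _build_train(sb, seq)
    record.sequences.append(replace(seq, effect=SequenceEffect.spontaneous_resumption))
    record.first_effective_seq = None
    _append_sinus(sb, rng, config.termination_run + 2)
    record.final_state = FinalState.spontaneous_termination
    record.episode_end_seq = 1
    record.interval_stream = emit_interval_stream(params, sb.beats)
    return record


def _run_pvt_episode(params, config, rng, patient_id, episode_id) -> EpisodeRecord:
    sb = _StreamBuilder(config)
    _append_sinus(sb, rng, 3)
    start = len(sb.beats)
    det = None
    for _ in range(120):
        sb.add(max(140.0, rng.normal(params.mean_cl_ms, params.sd_cl_ms)),
               f"P{int(rng.integers(0, 99)):02d}")
        seg = sb.beats[start:]
        iv = [b2.time_ms - b1.time_ms for b1, b2 in zip(seg, seg[1:])]
        det = detect_onset(iv, config) if iv else None
        if det is not None:
            break
    if det is None:  # pragma: no cover
        raise RuntimeError("PVT failed to reach detection")
    zone_cfg = config.zone_cfg(det.zone)
    record = EpisodeRecord(patient_id, episode_id, det.zone, det.measured_cl_ms, "PVT_VF",
                           morph_id="PVT")
    state = TherapyState(min_s2s3_ms=zone_cfg.min_s2s3_ms)
    seq = plan_sequence(state, det.measured_cl_ms, zone_cfg)
    _build_train(sb, seq)
    record.sequences.append(replace(seq, effect=SequenceEffect.no_effect))
    for _ in range(12):
        sb.add(max(140.0, rng.normal(params.mean_cl_ms, params.sd_cl_ms)),
               f"P{int(rng.integers(0, 99)):02d}")
    record.shocks_delivered = 1
    record.final_state = FinalState.shocked
    _append_sinus(sb, rng, config.termination_run + 2)
    record.interval_stream = emit_interval_stream(params, sb.beats)
    return record


def _run_twos_episode(params, config, rng, patient_id, episode_id) -> EpisodeRecord:
    sb = _StreamBuilder(config)
    _append_sinus(sb, rng, 3)
    # every sinus beat double-counted: R-wave then T-wave
    half = params.sinus_cl_ms / 2.0
    start = len(sb.beats)
    det = None
    for _ in range(80):
        sb.add(_jitter(rng, half - 20, 5.0), SINUS_MORPH)
        sb.add(_jitter(rng, half + 20, 5.0), "T")
        seg = sb.beats[start:]
        iv = [b2.time_ms - b1.time_ms for b1, b2 in zip(seg, seg[1:])]
        det = detect_onset(iv, config) if iv else None
        if det is not None:
            break
    if det is None:
        rec = EpisodeRecord(patient_id, episode_id, config.zones[-1].zone,
                            params.sinus_cl_ms, "TWOS", final_state=FinalState.rate_below_zone)
        rec.interval_stream = emit_interval_stream(params, sb.beats)
        return rec
    zone_cfg = config.zone_cfg(det.zone)
    record = EpisodeRecord(patient_id, episode_id, det.zone, det.measured_cl_ms, "TWOS",
                           morph_id=SINUS_MORPH)
    state = TherapyState(min_s2s3_ms=zone_cfg.min_s2s3_ms)
    seq = plan_sequence(state, det.measured_cl_ms, zone_cfg)
    _build_train(sb, seq)
    record.sequences.append(replace(seq, effect=SequenceEffect.no_effect))
    # oversensing abates after therapy
    _append_sinus(sb, rng, config.termination_run + 2)
    record.final_state = FinalState.spontaneous_termination
    record.episode_end_seq = 1
    record.interval_stream = emit_interval_stream(params, sb.beats)
    return record
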