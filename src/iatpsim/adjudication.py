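"""Rule-based episode adjudication: rhythm classing, break typing,
acceleration criteria, success endpoints, and factor categories.

The definitions implemented here are the standard endpoint vocabulary for
device-based ATP studies:

* **Type I break** — termination with at most one abnormal ventricular
  complex after the pacing train.
* **Type II break** — termination preceded by two or more abnormal
  complexes that differ from the pre-ATP rhythm in cycle length or
  morphology.
* **Spontaneous resumption** — two or more post-train complexes matching
  the pre-ATP rhythm in both cycle length and morphology before normal
  rhythm returns (the train did not cause the termination).
* **Accelerated MVT** — post-ATP monomorphic rhythm with cycle length
  shorter than the pre-ATP rhythm by at least 30 ms *and* at least 10%.
* **Polymorphic acceleration** — conversion of MVT to PVT/VF.

*IATP success* is an episode free of shock therapy whose resolution —
termination, spontaneous termination after an attempt, or slowing of the
rhythm below the programmed treatment rate — followed IATP as the final
therapy.  *Shock-free success* is the same but allows any ATP protocol
(e.g. a conventional follow-on burst) as the final therapy.

An "abnormal" ventricular complex is any beat with a cycle length below
the slowest programmed zone boundary or a non-sinus morphology label.
Because the first sensed interval after a train is a post-pacing interval
rather than a cycle length, it is excluded from cycle-length comparisons.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

from iatpsim.device_model import (
    EpisodeRecord,
    FinalState,
    SequenceEffect,
    Zone,
    ZoneConfig,
    VF_TYPE_ZONES,
    DeviceConfig,
)
from iatpsim.vt_dynamics import IntervalEvent, SINUS_MORPH

__all__ = [
    "AdjudicationRules",
    "AdjudicatedEpisode",
    "BreakType",
    "RhythmClass",
    "acceleration_test",
    "classify_break",
    "classify_rhythm",
    "adjudicate_episode",
    "detection_category",
    "sequence_category",
    "rate_class",
    "patient_summary",
]


class RhythmClass(str, Enum):
    MVT = "MVT"
    SVT = "SVT"
    PVT_VF = "PVT_VF"
    NSVT = "NSVT"
    TWOS = "TWOS"


class BreakType(str, Enum):
    type_I = "type_I"
    type_II = "type_II"
    spontaneous_resumption = "spontaneous_resumption"
    none = "none"


@dataclass(frozen=True)
class AdjudicationRules:
    """Thresholds of the endpoint definitions (all in ms unless noted)."""

    accel_abs_ms: float = 30.0
    accel_frac: float = 0.10
    rapid_cutoff_ms: float = 320.0
    type_I_max_abnormal: int = 1
    termination_run: int = 8
    extended_vt_nid_gt: int = 16
    extended_vf_nid_gt: tuple[int, int] = (18, 24)
    nominal_sequences: dict = field(default_factory=lambda: {"VF": 3, "FVT": 5, "VT": 7})
    cl_similarity_ms: float = 40.0
    min_normal_run: int = 4
    mvt_cl_sd_ms: float = 20.0
    pvt_cl_sd_ms: float = 60.0


@dataclass
class AdjudicatedEpisode:
    """All adjudicated fields for one episode."""

    patient_id: str
    episode_id: str
    rhythm_class: RhythmClass
    per_sequence_effects: list[SequenceEffect]
    iatp_success: bool
    shock_free_success: bool
    acceleration_class: str          # none | accelerated_mvt | polymorphic
    rate_class: str                  # rapid | slower
    detection_category: str          # short | extended
    sequence_category: str           # at_least_nominal | below_nominal
    first_effective_seq: Optional[int]
    final_outcome: str               # Figure-4-style vocabulary
    initial_cl_ms: float = 0.0
    n_sequences: int = 0


# ---------------------------------------------------------------------------
# elementary classifiers

def acceleration_test(pre_cl_ms: float, post_cl_ms: float,
                      rules: AdjudicationRules = AdjudicationRules()) -> bool:
    """Monomorphic-acceleration rule: shortened by >= 30 ms and >= 10%."""
    if pre_cl_ms <= 0 or post_cl_ms <= 0:
        raise ValueError("cycle lengths must be positive")
    delta = pre_cl_ms - post_cl_ms
    return delta >= rules.accel_abs_ms and delta >= rules.accel_frac * pre_cl_ms


@dataclass(frozen=True)
class LabeledBeat:
    """A post-train beat labeled for break classification."""

    cl_ms: Optional[float]   # None when the interval is a PPI, not a CL
    morph: str
    normal: bool


def classify_break(
    pre_cl_ms: float,
    pre_morph: str,
    post_events: Sequence[LabeledBeat],
    rules: AdjudicationRules = AdjudicationRules(),
) -> BreakType:
    """Classify the termination mode of one pacing train.

    ``post_events`` are the beats following the train, each labeled
    normal/abnormal.  Classification requires a run of at least
    ``rules.min_normal_run`` consecutive normal beats; without one the
    rhythm did not terminate and the result is ``none``.
    """
    if not post_events:
        raise ValueError("post_events must be nonempty")
    run = 0
    end = None
    for i, b in enumerate(post_events):
        run = run + 1 if b.normal else 0
        if run >= rules.min_normal_run:
            end = i - run + 1
            break
    if end is None:
        return BreakType.none
    abnormal = [b for b in post_events[:end] if not b.normal]
    if len(abnormal) <= rules.type_I_max_abnormal:
        return BreakType.type_I
    def matches_pre(b: LabeledBeat) -> bool:
        if b.morph != pre_morph:
            return False
        if b.cl_ms is None:
            return True
        return abs(b.cl_ms - pre_cl_ms) <= rules.cl_similarity_ms
    if all(matches_pre(b) for b in abnormal):
        return BreakType.spontaneous_resumption
    return BreakType.type_II


def classify_rhythm(
    stream: Sequence[IntervalEvent],
    rules: AdjudicationRules = AdjudicationRules(),
    slowest_boundary_ms: float = 400.0,
) -> RhythmClass:
    """Classify the rhythm present at initial detection.

    Operates on the pre-therapy window (events before the first pace)
    using the synthetic morphology labels: T-wave labels mean oversensing;
    a sinus morphology at tachycardia rate means supraventricular origin;
    morphology churn or highly irregular short cycle lengths mean PVT/VF;
    a stable single-morphology tachycardia is MVT; a run that self-ends
    before therapy is NSVT.
    """
    pre = []
    for e in stream:
        if e.marker == "TP":
            break
        pre.append(e)
    if len(pre) < 8:
        raise ValueError("insufficient_context")
    if any(e.morph == "T" for e in pre):
        return RhythmClass.TWOS
    # walk backwards: slow trailing beats, then the detected tachycardia run
    i = len(pre) - 1
    trailing_slow = 0
    while i >= 1 and pre[i].interval_ms >= slowest_boundary_ms:
        trailing_slow += 1
        i -= 1
    tachy: list[IntervalEvent] = []
    while i >= 1 and pre[i].interval_ms < slowest_boundary_ms:
        tachy.append(pre[i])
        i -= 1
    tachy.reverse()
    if trailing_slow > 0 and len(tachy) >= 4:
        return RhythmClass.NSVT  # tachycardia ended before therapy began
    if len(tachy) < 4:
        raise ValueError("insufficient_context")
    cls = [e.interval_ms for e in tachy]
    morphs = [e.morph for e in tachy]
    if all(m == SINUS_MORPH for m in morphs):
        return RhythmClass.SVT
    sd = statistics.pstdev(cls)
    churn = len(set(morphs)) >= max(3, len(morphs) // 2)
    if churn or (sd > rules.pvt_cl_sd_ms and statistics.median(cls) < rules.rapid_cutoff_ms):
        return RhythmClass.PVT_VF
    if len(set(morphs)) == 1 and sd <= rules.mvt_cl_sd_ms:
        return RhythmClass.MVT
    return RhythmClass.MVT if len(set(morphs)) <= 2 else RhythmClass.PVT_VF


# ---------------------------------------------------------------------------
# factor categories

def detection_category(config_or_zone_cfg, zone: Optional[Zone] = None,
                       rules: AdjudicationRules = AdjudicationRules()) -> str:
    """'extended' when initial VF NID > 18/24 or VT NID > 16, else 'short'."""
    if isinstance(config_or_zone_cfg, DeviceConfig):
        if zone is None:
            raise ValueError("zone required with a DeviceConfig")
        zc = config_or_zone_cfg.zone_cfg(zone)
    else:
        zc = config_or_zone_cfg
    if zc.zone in VF_TYPE_ZONES:
        x, _ = zc.nid_initial
        return "extended" if x > rules.extended_vf_nid_gt[0] else "short"
    return "extended" if zc.nid_initial > rules.extended_vt_nid_gt else "short"


def _zone_family(zone: Zone) -> str:
    if zone == Zone.VF:
        return "VF"
    if zone in (Zone.FVT_via_VF, Zone.FVT_via_VT):
        return "FVT"
    return "VT"


def sequence_category(programmed_n: int, zone: Zone,
                      rules: AdjudicationRules = AdjudicationRules()) -> str:
    nominal = rules.nominal_sequences[_zone_family(zone)]
    return "at_least_nominal" if programmed_n >= nominal else "below_nominal"


def rate_class(initial_cl_ms: float,
               rules: AdjudicationRules = AdjudicationRules()) -> str:
    if initial_cl_ms <= 0:
        raise ValueError("initial_cl_ms must be positive")
    return "rapid" if initial_cl_ms < rules.rapid_cutoff_ms else "slower"


# ---------------------------------------------------------------------------
# episode adjudication

def _segment_trains(stream: Sequence[IntervalEvent]) -> list[tuple[int, int]]:
    """(start, end) index pairs of each consecutive-TP pacing train."""
    trains = []
    i = 0
    n = len(stream)
    while i < n:
        if stream[i].marker == "TP":
            j = i
            while j < n and stream[j].marker == "TP":
                j += 1
            trains.append((i, j))
            i = j
        else:
            i += 1
    return trains


def _pre_rhythm(stream, lo, hi, boundary) -> tuple[float, str]:
    """Median CL and modal morphology of sub-boundary beats in [lo, hi)."""
    beats = [e for e in stream[lo:hi]
             if e.marker != "TP" and 0 < e.interval_ms < boundary]
    beats = beats[-6:]
    if not beats:
        return float("nan"), "?"
    cl = statistics.median(e.interval_ms for e in beats)
    morphs = [e.morph for e in beats]
    return cl, max(set(morphs), key=morphs.count)


def _label_post_window(stream, lo, hi, boundary) -> list[LabeledBeat]:
    out = []
    first = True
    for e in stream[lo:hi]:
        if e.marker == "TP":
            continue
        normal = e.morph == SINUS_MORPH and e.interval_ms >= boundary
        cl = None if first else e.interval_ms
        out.append(LabeledBeat(cl_ms=cl, morph=e.morph, normal=normal))
        first = False
    return out


def adjudicate_episode(ep: EpisodeRecord,
                       rules: AdjudicationRules = AdjudicationRules(),
                       programmed_sequences: Optional[int] = None,
                       zone_cfg: Optional[ZoneConfig] = None) -> AdjudicatedEpisode:
    """Adjudicate one episode from its interval stream and outcome record.

    Per-sequence effects are re-derived from the stream (segmented at the
    pacing trains), independently of the simulator's own effect labels.
    """
    if not ep.sequences and ep.true_rhythm not in ("SVT", "TWOS", "NSVT"):
        raise ValueError("episode has no IATP sequences")
    stream = ep.interval_stream
    boundary = ep.slowest_boundary_ms
    rhythm = classify_rhythm(stream, rules, boundary) if stream else RhythmClass(ep.true_rhythm)

    trains = _segment_trains(stream)
    n_iatp = len(ep.sequences)
    effects: list[SequenceEffect] = []
    first_effective: Optional[int] = None
    pre_cl, pre_morph = _pre_rhythm(stream, 0, trains[0][0], boundary) if trains else (ep.initial_cl_ms, ep.morph_id)

    for k, (lo, hi) in enumerate(trains):
        post_end = trains[k + 1][0] if k + 1 < len(trains) else len(stream)
        post = _label_post_window(stream, hi, post_end, boundary)
        is_last = k == len(trains) - 1
        if not post:
            effects.append(SequenceEffect.no_effect)
            continue
        window = post
        if is_last and ep.shocks_delivered > 0:
            # drop the post-shock sinus tail so a shock conversion is not
            # misread as an ATP break
            k2 = len(window)
            while k2 > 0 and window[k2 - 1].normal:
                k2 -= 1
            window = window[:k2]
        brk = classify_break(pre_cl, pre_morph, window, rules) if window else BreakType.none
        if brk == BreakType.type_I:
            eff = SequenceEffect.type_I_break
        elif brk == BreakType.type_II:
            eff = SequenceEffect.type_II_break
        elif brk == BreakType.spontaneous_resumption:
            eff = SequenceEffect.spontaneous_resumption
        else:
            # rhythm continued: look at the post-train tachycardia
            tachy = [b for b in post if b.cl_ms is not None and b.cl_ms < boundary]
            if tachy:
                morphs = [b.morph for b in tachy]
                churn = len(set(morphs)) >= max(3, len(morphs) // 2) and len(morphs) >= 4
                post_cl = statistics.median(b.cl_ms for b in tachy)
                same_morph_frac = morphs.count(pre_morph) / len(morphs)
                if churn:
                    eff = SequenceEffect.polymorphic_accel
                elif post_cl > 0 and pre_cl > 0 and acceleration_test(pre_cl, post_cl, rules) \
                        and same_morph_frac >= 0.5:
                    eff = SequenceEffect.accelerated_mvt
                else:
                    eff = SequenceEffect.no_effect
                if eff != SequenceEffect.no_effect or abs(post_cl - pre_cl) > rules.cl_similarity_ms:
                    pre_cl, pre_morph = _pre_rhythm(stream, hi, post_end, boundary)
            else:
                eff = SequenceEffect.no_effect
        if k < n_iatp:
            effects.append(eff)
        if eff in (SequenceEffect.type_I_break, SequenceEffect.type_II_break,
                   SequenceEffect.spontaneous_resumption) and first_effective is None:
            first_effective = k + 1
        if brk != BreakType.none and not is_last:
            # rhythm re-initiated after the break: re-measure the pre rhythm
            pre_cl, pre_morph = _pre_rhythm(stream, hi, trains[k + 1][0], boundary)

    while len(effects) < n_iatp:
        effects.append(SequenceEffect.no_effect)

    accel = "none"
    if any(e == SequenceEffect.polymorphic_accel for e in effects):
        accel = "polymorphic"
    elif any(e == SequenceEffect.accelerated_mvt for e in effects):
        accel = "accelerated_mvt"

    no_shock = ep.shocks_delivered == 0
    qualifying = ep.final_state in (
        FinalState.terminated_by_atp,
        FinalState.spontaneous_termination,
        FinalState.rate_below_zone,
    )
    shock_free = no_shock and qualifying
    iatp_final = not (ep.conventional_attempted and ep.conventional_terminated)
    iatp_success = shock_free and iatp_final

    outcome_map = {
        FinalState.terminated_by_atp: "termination_by_conventional_atp"
        if ep.conventional_terminated else "termination_by_iatp",
        FinalState.spontaneous_termination: "spontaneous_termination",
        FinalState.rate_below_zone: "rate_below_zone",
        FinalState.shocked: "shocked",
        FinalState.ongoing: "ongoing",
    }

    det_cat = "short"
    seq_cat = "at_least_nominal"
    if zone_cfg is not None:
        det_cat = detection_category(zone_cfg, rules=rules)
        seq_cat = sequence_category(
            programmed_sequences if programmed_sequences is not None else zone_cfg.total_sequences,
            zone_cfg.zone, rules)
    elif programmed_sequences is not None:
        seq_cat = sequence_category(programmed_sequences, ep.detected_zone, rules)

    return AdjudicatedEpisode(
        patient_id=ep.patient_id,
        episode_id=ep.episode_id,
        rhythm_class=rhythm,
        per_sequence_effects=effects,
        iatp_success=iatp_success,
        shock_free_success=shock_free,
        acceleration_class=accel,
        rate_class=rate_class(ep.initial_cl_ms, rules),
        detection_category=det_cat,
        sequence_category=seq_cat,
        first_effective_seq=first_effective,
        final_outcome=outcome_map[ep.final_state],
        initial_cl_ms=ep.initial_cl_ms,
        n_sequences=len(ep.sequences),
    )


def patient_summary(episodes: Sequence[AdjudicatedEpisode]) -> dict:
    """Per-patient roll-up over that patient's adjudicated MVT episodes."""
    eps = [e for e in episodes if e.rhythm_class == RhythmClass.MVT]
    if not eps:
        raise ValueError("patient has no MVT episodes")
    succ = [e for e in eps if e.iatp_success]
    max_seq = max((e.n_sequences for e in succ), default=None)
    return {
        "any_success": len(succ) > 0,
        "all_success": len(succ) == len(eps),
        "all_fail": len(succ) == 0,
        "max_sequences_in_successful_episode": max_seq,
        "episode_count": len(eps),
    }
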