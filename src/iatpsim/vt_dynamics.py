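"""Phenomenological reentrant-VT circuit and SVT pro-arrhythmia models.

The ventricular tachycardia (VT) model is a single-entry-site excitable-gap
reentry loop: a wavefront circulates with intrinsic cycle length ``vtcl_ms``
and a pacing site communicates with the circuit entry through a one-way
conduction time ``d_ms``.  A stimulus delivered at the pacing site reaches
the entry ``d_ms`` later; if the local tissue there has recovered (the
arrival falls inside the excitable gap) the stimulus captures and resets the
circuit, otherwise it is blocked.  This minimal construction reproduces the
classic entrainment identity for a resetting stimulus,

    PPI = VTCL + 2 * d,

where the post-pacing interval (PPI) is measured at the pacing site from the
last delivered stimulus to the next sensed beat.  Termination of the circuit
by a captured final extrastimulus is stochastic, with probability given by a
logistic curve in the stimulus prematurity at the circuit entry.

The SVT model is rate-only: an atrial-origin rhythm conducted to the
ventricle at ``svt_cl_ms`` that pacing cannot terminate but can, with small
per-sequence probabilities, provoke ectopy or induce a ventricular
arrhythmia.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "COUPLING_FLOOR_MS",
    "CircuitParams",
    "SVTParams",
    "TrainOutcome",
    "TrainResponse",
    "SVTOutcome",
    "IntervalEvent",
    "respond_to_train",
    "svt_respond_to_train",
    "emit_interval_stream",
    "stream_to_csv",
    "stream_from_csv",
]

#: Stimuli with a coupling interval below this floor are ignored
#: (ventricular tissue at the pacing site is refractory).
COUPLING_FLOOR_MS = 150.0

SINUS_MORPH = "N"
SINUS_CL_MS = 800.0


class TrainOutcome(str, Enum):
    reset = "reset"
    terminated = "terminated"
    accelerated_mvt = "accelerated_mvt"
    degenerated_pvt = "degenerated_pvt"
    no_capture = "no_capture"


class SVTOutcome(str, Enum):
    none = "none"
    pvc = "pvc"
    nsvt = "nsvt"
    induced_mvt = "induced_mvt"
    induced_vf = "induced_vf"


@dataclass(frozen=True)
class CircuitParams:
    """Parameters of the reentrant monomorphic-VT circuit.

    Parameters
    ----------
    vtcl_ms
        Intrinsic VT cycle length (ms).
    d_ms
        One-way conduction time from pacing site to circuit entry (ms).
    refractory_ms
        Local refractory period at the circuit entry (ms); the excitable
        gap is ``vtcl_ms - refractory_ms``.
    term_center_ms, term_slope
        Center and slope of the logistic termination-probability curve
        over final-extrastimulus prematurity at the circuit (ms).
    p_acc_mvt, p_acc_pvt
        Per-captured-final-extrastimulus probabilities of acceleration to
        a faster monomorphic VT / degeneration to polymorphic VT-VF.
    accel_factor
        Cycle-length multiplier applied on monomorphic acceleration (<1).
    morph_id
        Categorical ventricular morphology label.
    p_reinit
        Probability that, after a break, the same MVT re-initiates before
        the device recognizes episode termination.
    p_spont
        Per-failed-sequence probability that the VT terminates
        spontaneously afterwards.
    p_slow
        Per-failed-sequence probability that the VT slows below every
        programmed detection zone.
    """

    vtcl_ms: float = 340.0
    d_ms: float = 85.0
    refractory_ms: float = 240.0
    term_center_ms: float = 55.0
    term_slope: float = 12.0
    p_acc_mvt: float = 0.008
    p_acc_pvt: float = 0.003
    accel_factor: float = 0.85
    morph_id: str = "V1"
    p_reinit: float = 0.06
    p_spont: float = 0.01
    p_slow: float = 0.005

    def __post_init__(self) -> None:
        if not (self.vtcl_ms > self.refractory_ms > 0):
            raise ValueError("require vtcl_ms > refractory_ms > 0 (positive excitable gap)")
        if self.d_ms <= 0:
            raise ValueError("d_ms must be positive")
        if not (0.0 <= self.p_acc_mvt + self.p_acc_pvt < 1.0):
            raise ValueError("p_acc_mvt + p_acc_pvt must lie in [0, 1)")
        if not (0.0 < self.accel_factor < 1.0):
            raise ValueError("accel_factor must lie in (0, 1)")

    @property
    def excitable_gap_ms(self) -> float:
        return self.vtcl_ms - self.refractory_ms

    def accelerated(self) -> "CircuitParams":
        """Circuit after monomorphic acceleration (same morphology).

        Refractoriness shortens with rate, so the refractory period scales
        with the cycle length and the relative excitable gap is preserved.
        """
        return replace(self, vtcl_ms=self.accel_factor * self.vtcl_ms,
                       refractory_ms=self.accel_factor * self.refractory_ms)


@dataclass(frozen=True)
class SVTParams:
    """Rate-only supraventricular tachycardia with pro-arrhythmia risk."""

    svt_cl_ms: float = 380.0
    p_pvc: float = 0.0249
    p_nsvt: float = 0.0156
    p_induce_mvt: float = 0.0078
    p_induce_vf: float = 0.0031

    def __post_init__(self) -> None:
        ps = (self.p_pvc, self.p_nsvt, self.p_induce_mvt, self.p_induce_vf)
        if any(p < 0 or p > 1 for p in ps):
            raise ValueError("probabilities must lie in [0, 1]")
        if sum(ps) > 1.0:
            raise ValueError("pro-arrhythmia probabilities must sum to <= 1")
        if self.svt_cl_ms <= 0:
            raise ValueError("svt_cl_ms must be positive")


@dataclass(frozen=True)
class TrainResponse:
    """Outcome of one pacing train delivered into the circuit."""

    outcome: TrainOutcome
    ppi_ms: Optional[float] = None
    new_vtcl_ms: Optional[float] = None
    new_morph_id: Optional[str] = None
    n_captured: int = 0
    final_prematurity_ms: Optional[float] = None


@dataclass(frozen=True)
class IntervalEvent:
    """One sensed or paced ventricular event in a device interval stream."""

    time_ms: float
    interval_ms: float
    marker: str  # VS, TS, FS, TF, TP, BV
    morph: str


def _validate_train(train: Sequence[float]) -> np.ndarray:
    times = np.asarray(train, dtype=float)
    if times.size == 0:
        raise ValueError("empty_train")
    if times.ndim != 1 or np.any(np.diff(times) <= 0):
        raise ValueError("bad_train")
    return times


def respond_to_train(
    params: CircuitParams,
    state: float,
    train: Sequence[float],
    rng: np.random.Generator,
) -> TrainResponse:
    """Deliver a pacing train into the circulating circuit.

    Parameters
    ----------
    params
        Circuit parameters.
    state
        Circuit phase: time (on the train clock) of the most recent
        activation at the circuit entry before the first stimulus arrives.
    train
        Strictly increasing stimulus delivery times at the pacing site (ms).
        Stimuli whose coupling to the previous stimulus falls below
        ``COUPLING_FLOOR_MS`` are ignored.
    rng
        Seeded random generator; consumed only for the terminal
        termination/acceleration draws.

    Returns
    -------
    TrainResponse
        Outcome plus, when the rhythm persists, the PPI measured at the
        pacing site from the last *delivered* stimulus.
    """
    times = _validate_train(train)
    keep = np.ones(times.size, dtype=bool)
    keep[1:] = np.diff(times) >= COUPLING_FLOOR_MS
    delivered = times[keep]

    last_activation = float(state)
    last_capture_time: Optional[float] = None
    n_captured = 0
    final_captured = False
    final_prematurity: Optional[float] = None

    for t in delivered:
        arrival = t + params.d_ms
        # advance the circulating wavefront up to this arrival
        while last_activation + params.vtcl_ms <= arrival:
            last_activation += params.vtcl_ms
        recovered = (arrival - last_activation) >= params.refractory_ms
        if recovered:
            prematurity = (last_activation + params.vtcl_ms) - arrival
            last_activation = arrival
            last_capture_time = t
            n_captured += 1
            final_captured = t == delivered[-1]
            final_prematurity = prematurity if final_captured else None
        else:
            final_captured = False
            final_prematurity = None

    t_last = float(delivered[-1])

    if final_captured and final_prematurity is not None:
        z = (final_prematurity - params.term_center_ms) / params.term_slope
        p_term = 1.0 / (1.0 + math.exp(-z)) if z > -700 else 0.0
        u = rng.random()
        if u < p_term:
            return TrainResponse(
                outcome=TrainOutcome.terminated,
                n_captured=n_captured,
                final_prematurity_ms=final_prematurity,
            )
        v = rng.random()
        if v < params.p_acc_mvt:
            return TrainResponse(
                outcome=TrainOutcome.accelerated_mvt,
                new_vtcl_ms=params.accel_factor * params.vtcl_ms,
                new_morph_id=params.morph_id,
                n_captured=n_captured,
                final_prematurity_ms=final_prematurity,
            )
        if v < params.p_acc_mvt + params.p_acc_pvt:
            return TrainResponse(
                outcome=TrainOutcome.degenerated_pvt,
                new_morph_id="PVT",
                n_captured=n_captured,
                final_prematurity_ms=final_prematurity,
            )
        ppi = params.vtcl_ms + 2.0 * params.d_ms
        return TrainResponse(
            outcome=TrainOutcome.reset,
            ppi_ms=ppi,
            new_vtcl_ms=params.vtcl_ms,
            new_morph_id=params.morph_id,
            n_captured=n_captured,
            final_prematurity_ms=final_prematurity,
        )

    # final stimulus blocked at the circuit (or nothing captured at all)
    if last_capture_time is not None:
        ppi = (t_last - last_capture_time) + params.vtcl_ms + 2.0 * params.d_ms
    else:
        # rhythm never reset: next wavefront reaches the pacing site
        # d_ms after its next entry activation
        nxt = last_activation + params.vtcl_ms
        while nxt + params.d_ms <= t_last:
            nxt += params.vtcl_ms
        ppi = (nxt + params.d_ms) - t_last
    return TrainResponse(
        outcome=TrainOutcome.no_capture,
        ppi_ms=ppi,
        new_vtcl_ms=params.vtcl_ms,
        new_morph_id=params.morph_id,
        n_captured=n_captured,
    )


def svt_respond_to_train(
    params: SVTParams,
    train: Sequence[float],
    rng: np.random.Generator,
) -> SVTOutcome:
    """Draw the pro-arrhythmic effect of one pacing sequence into SVT."""
    _validate_train(train)
    u = rng.random()
    edges = np.cumsum([params.p_pvc, params.p_nsvt, params.p_induce_mvt, params.p_induce_vf])
    if u < edges[0]:
        return SVTOutcome.pvc
    if u < edges[1]:
        return SVTOutcome.nsvt
    if u < edges[2]:
        return SVTOutcome.induced_mvt
    if u < edges[3]:
        return SVTOutcome.induced_vf
    return SVTOutcome.none


@dataclass(frozen=True)
class Beat:
    """One element of an episode history: a beat or pace at an absolute time."""

    time_ms: float
    marker: str
    morph: str


def emit_interval_stream(
    params: object,
    history: Sequence[Beat],
) -> list[IntervalEvent]:
    """Serialize an episode history into a device-style interval stream.

    Each event's ``interval_ms`` is the time elapsed since the previous
    ventricular event (sensed or paced); the first event reports its own
    nominal interval as 0.
    """
    events: list[IntervalEvent] = []
    prev_t: Optional[float] = None
    for b in history:
        interval = 0.0 if prev_t is None else b.time_ms - prev_t
        events.append(IntervalEvent(b.time_ms, interval, b.marker, b.morph))
        prev_t = b.time_ms
    return events


def stream_to_csv(events: Sequence[IntervalEvent]) -> str:
    """Render events as headered CSV (time_ms, interval_ms, marker, morph)."""
    lines = ["time_ms,interval_ms,marker,morph"]
    for e in events:
        lines.append(f"{e.time_ms:g},{e.interval_ms:g},{e.marker},{e.morph}")
    return "\n".join(lines) + "\n"


def stream_from_csv(text: str) -> list[IntervalEvent]:
    lines = [ln for ln in text.strip().splitlines() if ln]
    if not lines or lines[0] != "time_ms,interval_ms,marker,morph":
        raise ValueError("missing or malformed interval-stream header")
    out = []
    for ln in lines[1:]:
        t, iv, marker, morph = ln.split(",")
        out.append(IntervalEvent(float(t), float(iv), marker, morph))
    return out
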