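"""Seeded synthetic cohort: patients, device programming, episode workloads.

The generator emulates the marginal structure of a real-world ICD
remote-monitoring cohort treated with IATP:

* a heavy-tailed per-patient episode count (zero-truncated negative
  binomial; most patients contribute several episodes, a few contribute
  tens),
* a lognormal monomorphic-VT cycle-length law calibrated to a median of
  340 ms with 30.8% of episodes below the 320 ms rapid-VT cutoff,
* physician-discretion programming variation (zone cutoffs, NIDs, maximum
  sequences per Table-2-style weights, min S2/S3 mostly nominal),
* a rhythm admixture of MVT, SVT, PVT/VF, NSVT and T-wave oversensing,
* patient-level outcome correlation through a latent frailty that shifts
  each patient's termination-probability curve.

Every draw flows from a single integer seed, so outputs are byte-identical
across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from iatpsim.device_model import (
    DeviceConfig,
    NSVTParams,
    PVTParams,
    TWOSParams,
    Zone,
    ZoneConfig,
    run_episode,
)
from iatpsim.vt_dynamics import CircuitParams, SVTParams

__all__ = ["CohortParams", "Cohort", "SimulatedCohort", "sample_cohort",
           "simulate_cohort", "sample_clustered_outcomes"]


@dataclass
class CohortParams:
    """Generator laws; defaults are the study conditions being emulated."""

    n_patients: int = 415
    seed: int = 0

    # per-patient episode count: zero-truncated negative binomial
    episode_mean: float = 6.0
    episode_dispersion: float = 0.6
    episode_max: int = 90

    # MVT cycle-length law: lognormal, median 340 ms, 30.8% mass < 320 ms
    vtcl_median_ms: float = 340.0
    vtcl_sigma: float = 0.12186
    vtcl_lo_ms: float = 200.0
    vtcl_hi_ms: float = 600.0

    # conduction time pacing-site -> circuit (PPI - VTCL = 2d)
    d_mean_ms: float = 85.0
    d_sd_ms: float = 45.0
    d_min_ms: float = 10.0

    # rhythm admixture at detection
    p_mvt: float = 0.8685
    p_svt: float = 0.0877
    p_pvt_vf: float = 0.0361
    p_nsvt: float = 0.0073
    p_twos: float = 0.0004

    # patient demographics
    age_mean: float = 68.0
    age_sd: float = 13.3
    p_male: float = 0.817
    p_first_device: float = 0.753
    indication_probs: tuple = (0.424, 0.538, 0.037)   # secondary, primary, other
    device_type_probs: tuple = (0.157, 0.451, 0.392)  # 1ch, 2ch, CRT-D
    missing_demographics_frac: float = 0.092

    # success model: per-patient frailty and factor effects shift the
    # termination-curve center (center_scale ms per log-odds unit)
    frailty_sd: float = 1.0
    term_center_ms: float = 45.0
    term_slope_ms: float = 12.0
    term_center_scale_ms: float = 30.0
    effect_female: float = 0.5
    effect_rapid: float = -0.3
    refractory_frac: tuple = (0.66, 0.76)
    p_acc_mvt: float = 0.018
    p_acc_pvt: float = 0.006

    # fraction of devices with a programmed FVT (via VT) subzone
    p_fvt_zone: float = 0.12

    def __post_init__(self) -> None:
        ps = np.array([self.p_mvt, self.p_svt, self.p_pvt_vf, self.p_nsvt, self.p_twos])
        if np.any(ps < 0):
            raise ValueError("rhythm_probs: probabilities must be nonnegative")
        if abs(ps.sum() - 1.0) > 1e-6:
            raise ValueError("rhythm_probs: probabilities must sum to 1")
        if self.episode_mean <= 1 or self.episode_dispersion <= 0:
            raise ValueError("episode_count_law: need mean > 1 and dispersion > 0")
        if self.vtcl_sigma <= 0:
            raise ValueError("vtcl_law: sigma must be positive")


# Programming weights {n_sequences: percent}, calibrated so the share at or
# above the nominal value (VF 3, FVT 5, VT 7) is 55% / 76% / 76% with the
# nominal value modal
SEQ_WEIGHTS = {
    "VF": {2: 45, 3: 54, 4: 1},
    "FVT": {3: 18, 4: 6, 5: 70, 7: 2, 8: 2, 10: 2},
    "VT": {2: 1, 3: 7, 4: 3, 5: 3, 6: 10, 7: 64, 8: 4, 9: 0.4, 10: 7.6},
}

VT_NID_CHOICES = [12, 18, 20, 24, 30, 40, 50, 100]
VT_NID_WEIGHTS = [0.08, 0.12, 0.40, 0.20, 0.12, 0.04, 0.03, 0.01]
VF_NID_CHOICES = [(12, 16), (18, 24), (24, 32), (45, 60)]
VF_NID_WEIGHTS = [0.05, 0.06, 0.05, 0.03]  # remainder nominal (30, 40)


@dataclass
class Cohort:
    params: CohortParams
    patients: pd.DataFrame
    device_configs: dict            # patient_id -> DeviceConfig
    episode_specs: pd.DataFrame     # one row per planned episode with truth


@dataclass
class SimulatedCohort:
    cohort: Cohort
    records: list                   # EpisodeRecord objects
    episodes: pd.DataFrame
    sequences: pd.DataFrame
    truth: pd.DataFrame
    events: pd.DataFrame


def _sample_ztnb(rng: np.random.Generator, mean: float, dispersion: float,
                 size: int, cap: int) -> np.ndarray:
    """Zero-truncated negative binomial by rejection (exact truncation)."""
    r = dispersion
    p = r / (r + mean)
    out = np.zeros(size, dtype=int)
    todo = np.arange(size)
    while todo.size:
        draw = rng.negative_binomial(r, p, size=todo.size)
        ok = (draw > 0) & (draw <= cap)
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return out


def _sample_vtcl(rng: np.random.Generator, p: CohortParams, size: int) -> np.ndarray:
    mu = np.log(p.vtcl_median_ms)
    out = np.zeros(size)
    todo = np.arange(size)
    while todo.size:
        draw = rng.lognormal(mu, p.vtcl_sigma, size=todo.size)
        ok = (draw >= p.vtcl_lo_ms) & (draw <= p.vtcl_hi_ms)
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return out


def _weighted_choice(rng, mapping: dict) -> int:
    keys = list(mapping)
    w = np.array([mapping[k] for k in keys], dtype=float)
    return int(rng.choice(keys, p=w / w.sum()))


def _sample_device_config(rng: np.random.Generator, p: CohortParams,
                          max_vtcl_ms: float) -> DeviceConfig:
    """Device programming; the VT cutoff is kept above the patient's VT."""
    vf_boundary = float(rng.choice([250, 270, 280, 300, 320, 330],
                                   p=[0.05, 0.10, 0.15, 0.40, 0.25, 0.05]))
    vt_boundary = float(rng.choice([340, 360, 380, 400, 420, 440, 460, 500, 600],
                                   p=[0.08, 0.17, 0.25, 0.20, 0.12, 0.08, 0.05, 0.03, 0.02]))
    vt_boundary = min(600.0, max(vt_boundary, 20.0 * np.ceil((max_vtcl_ms + 45.0) / 20.0)))
    vf_boundary = min(vf_boundary, vt_boundary - 40.0)

    if rng.random() < 0.48:
        vt_nid = 16
    else:
        vt_nid = int(rng.choice(VT_NID_CHOICES, p=np.array(VT_NID_WEIGHTS) / sum(VT_NID_WEIGHTS)))
    if rng.random() < 0.81:
        vf_nid = (30, 40)
    else:
        k = rng.choice(len(VF_NID_CHOICES), p=np.array(VF_NID_WEIGHTS) / sum(VF_NID_WEIGHTS))
        vf_nid = VF_NID_CHOICES[int(k)]

    def min_s2s3() -> float:
        return 200.0 if rng.random() < 0.92 else float(rng.choice([150, 170, 240, 260]))

    zones = [
        ZoneConfig(Zone.VF, vf_boundary, vf_nid, (12, 16),
                   max_sequences=_weighted_choice(rng, SEQ_WEIGHTS["VF"]),
                   min_s2s3_ms=min_s2s3(),
                   conventional_burst_after=bool(rng.random() < 0.5)),
    ]
    if rng.random() < p.p_fvt_zone and vt_boundary - vf_boundary >= 60:
        fvt_boundary = vf_boundary + 20.0
        zones.append(
            ZoneConfig(Zone.FVT_via_VT, fvt_boundary, vt_nid, 12,
                       max_sequences=_weighted_choice(rng, SEQ_WEIGHTS["FVT"]),
                       min_s2s3_ms=min_s2s3(),
                       conventional_burst_after=bool(rng.random() < 0.5)))
    zones.append(
        ZoneConfig(Zone.VT, vt_boundary, vt_nid, 12,
                   max_sequences=_weighted_choice(rng, SEQ_WEIGHTS["VT"]),
                   min_s2s3_ms=min_s2s3(),
                   conventional_burst_after=bool(rng.random() < 0.5)))
    return DeviceConfig(zones=tuple(zones))


def sample_cohort(params: CohortParams) -> Cohort:
    """Draw patients, device programming, and episode specs with truth labels."""
    rng = np.random.default_rng(params.seed)
    n = params.n_patients

    pat_rows = []
    ep_rows = []
    configs: dict[str, DeviceConfig] = {}

    if n == 0:
        patients = pd.DataFrame(columns=[
            "patient_id", "age_years", "sex", "device_type", "indication",
            "first_device", "frailty", "demographics_available"])
        specs = pd.DataFrame(columns=[
            "patient_id", "episode_id", "true_rhythm", "vtcl_ms", "d_ms",
            "refractory_ms", "term_center_ms", "term_slope", "morph_id",
            "svt_cl_ms"])
        return Cohort(params, patients, {}, specs)

    counts = _sample_ztnb(rng, params.episode_mean, params.episode_dispersion,
                          n, params.episode_max)
    for i in range(n):
        pid = f"P{i:04d}"
        age = float(np.clip(rng.normal(params.age_mean, params.age_sd), 18.0, 100.0))
        sex = "M" if rng.random() < params.p_male else "F"
        indication = str(rng.choice(["secondary", "primary", "other"],
                                    p=np.array(params.indication_probs) /
                                    sum(params.indication_probs)))
        device_type = str(rng.choice(["ICD_1ch", "ICD_2ch", "CRT_D"],
                                     p=np.array(params.device_type_probs) /
                                     sum(params.device_type_probs)))
        first_device = bool(rng.random() < params.p_first_device)
        frailty = float(rng.normal(0.0, params.frailty_sd))
        available = bool(rng.random() >= params.missing_demographics_frac)
        pat_rows.append({
            "patient_id": pid, "age_years": round(age, 1), "sex": sex,
            "device_type": device_type, "indication": indication,
            "first_device": first_device, "frailty": round(frailty, 6),
            "demographics_available": available,
        })

        n_ep = int(counts[i])
        rhythms = rng.choice(
            ["MVT", "SVT", "PVT_VF", "NSVT", "TWOS"], size=n_ep,
            p=[params.p_mvt, params.p_svt, params.p_pvt_vf, params.p_nsvt, params.p_twos])
        vtcls = _sample_vtcl(rng, params, n_ep)
        max_vtcl = float(vtcls[rhythms == "MVT"].max()) if np.any(rhythms == "MVT") else 340.0
        config = _sample_device_config(rng, params, max_vtcl)
        configs[pid] = config
        vt_boundary = config.slowest_boundary_ms

        for j in range(n_ep):
            eid = f"{pid}_E{j:03d}"
            rhythm = str(rhythms[j])
            row = {"patient_id": pid, "episode_id": eid, "true_rhythm": rhythm,
                   "vtcl_ms": np.nan, "d_ms": np.nan, "refractory_ms": np.nan,
                   "term_center_ms": np.nan, "term_slope": np.nan,
                   "morph_id": "", "svt_cl_ms": np.nan}
            if rhythm == "MVT":
                vtcl = float(vtcls[j])
                d = 0.0
                while d < params.d_min_ms:
                    d = float(rng.normal(params.d_mean_ms, params.d_sd_ms))
                refractory = float(vtcl * rng.uniform(*params.refractory_frac))
                rapid = vtcl < 320.0
                shift = (frailty
                         + params.effect_female * (sex == "F")
                         + params.effect_rapid * rapid)
                center = params.term_center_ms - params.term_center_scale_ms * shift
                row.update(vtcl_ms=round(vtcl, 1), d_ms=round(d, 1),
                           refractory_ms=round(refractory, 1),
                           term_center_ms=round(center, 2),
                           term_slope=params.term_slope_ms,
                           morph_id=f"V{1 + int(rng.integers(0, 3))}")
            elif rhythm == "SVT":
                lo = max(320.0, vt_boundary - 80.0)
                hi = max(lo + 5.0, vt_boundary - 15.0)
                row.update(svt_cl_ms=round(float(rng.uniform(lo, hi)), 1))
            ep_rows.append(row)

    patients = pd.DataFrame(pat_rows)
    specs = pd.DataFrame(ep_rows)
    return Cohort(params, patients, configs, specs)


def _circuit_from_spec(row: pd.Series, params: CohortParams) -> CircuitParams:
    return CircuitParams(
        vtcl_ms=float(row["vtcl_ms"]),
        d_ms=float(row["d_ms"]),
        refractory_ms=float(row["refractory_ms"]),
        term_center_ms=float(row["term_center_ms"]),
        term_slope=float(row["term_slope"]),
        morph_id=str(row["morph_id"]),
        p_acc_mvt=params.p_acc_mvt,
        p_acc_pvt=params.p_acc_pvt,
    )


def simulate_cohort(cohort: Cohort, rng: Optional[np.random.Generator] = None) -> SimulatedCohort:
    """Run the device model over every planned episode.

    Returns in-memory records plus flat tables (episodes, sequences, truth,
    events) ready to serialize as CSV.
    """
    if rng is None:
        rng = np.random.default_rng(cohort.params.seed + 1)
    records = []
    ep_rows, seq_rows, truth_rows, ev_rows = [], [], [], []
    for _, row in cohort.episode_specs.iterrows():
        pid = row["patient_id"]
        config = cohort.device_configs[pid]
        rhythm = row["true_rhythm"]
        if rhythm == "MVT":
            spec = _circuit_from_spec(row, cohort.params)
        elif rhythm == "SVT":
            spec = SVTParams(svt_cl_ms=float(row["svt_cl_ms"]))
        elif rhythm == "PVT_VF":
            spec = PVTParams()
        elif rhythm == "NSVT":
            spec = NSVTParams()
        else:
            spec = TWOSParams()
        rec = run_episode(spec, config, rng, patient_id=pid,
                          episode_id=row["episode_id"])
        records.append(rec)

        zone_cfg = config.zone_cfg(rec.detected_zone)
        nid = zone_cfg.nid_initial
        nid_x, nid_y = (nid if isinstance(nid, tuple) else (nid, None))
        ep_rows.append({
            "patient_id": rec.patient_id,
            "episode_id": rec.episode_id,
            "detected_zone": rec.detected_zone.value,
            "initial_cl_ms": round(rec.initial_cl_ms, 1),
            "n_sequences": len(rec.sequences),
            "shocks_delivered": rec.shocks_delivered,
            "final_state": rec.final_state.value,
            "episode_end_seq": rec.episode_end_seq,
            "conventional_attempted": rec.conventional_attempted,
            "conventional_terminated": rec.conventional_terminated,
            "morph_id": rec.morph_id,
            "slowest_boundary_ms": rec.slowest_boundary_ms,
            "programmed_sequences": zone_cfg.total_sequences,
            "nid_x": nid_x,
            "nid_y": nid_y,
            "min_s2s3_ms": zone_cfg.min_s2s3_ms,
        })
        for s in rec.sequences:
            seq_rows.append({
                "episode_id": rec.episode_id,
                "seq_index": s.seq_index,
                "n_s1": s.n_s1,
                "s1_interval_ms": s.s1_interval_ms,
                "s2_ci_ms": s.s2_ci_ms,
                "s3_ci_ms": s.s3_ci_ms,
                "ppi_ms": s.ppi_ms,
                "effect": s.effect.value,
            })
        truth_rows.append({
            "episode_id": rec.episode_id,
            "true_rhythm": rec.true_rhythm,
            "vtcl_ms": row["vtcl_ms"],
            "d_ms": row["d_ms"],
            "term_center_ms": row["term_center_ms"],
            "first_effective_seq": rec.first_effective_seq,
            "final_state": rec.final_state.value,
        })
        for e in rec.interval_stream:
            ev_rows.append({
                "episode_id": rec.episode_id,
                "time_ms": round(e.time_ms, 3),
                "interval_ms": round(e.interval_ms, 3),
                "marker": e.marker,
                "morph": e.morph,
            })
    cols_ep = ["patient_id", "episode_id", "detected_zone", "initial_cl_ms",
               "n_sequences", "shocks_delivered", "final_state",
               "episode_end_seq", "conventional_attempted",
               "conventional_terminated", "morph_id", "slowest_boundary_ms",
               "programmed_sequences", "nid_x", "nid_y", "min_s2s3_ms"]
    cols_seq = ["episode_id", "seq_index", "n_s1", "s1_interval_ms",
                "s2_ci_ms", "s3_ci_ms", "ppi_ms", "effect"]
    cols_truth = ["episode_id", "true_rhythm", "vtcl_ms", "d_ms",
                  "term_center_ms", "first_effective_seq", "final_state"]
    cols_ev = ["episode_id", "time_ms", "interval_ms", "marker", "morph"]
    return SimulatedCohort(
        cohort=cohort,
        records=records,
        episodes=pd.DataFrame(ep_rows, columns=cols_ep),
        sequences=pd.DataFrame(seq_rows, columns=cols_seq),
        truth=pd.DataFrame(truth_rows, columns=cols_truth),
        events=pd.DataFrame(ev_rows, columns=cols_ev),
    )


def sample_clustered_outcomes(
    n_patients: int,
    marginal_p: float,
    frailty_sd: float,
    rng: np.random.Generator,
    episode_mean: float = 6.0,
    episode_dispersion: float = 0.6,
    effects: Optional[dict] = None,
) -> pd.DataFrame:
    """Directly sample clustered binary outcomes with a known marginal.

    A reduced-form generator for statistical validation: per-patient
    episode counts from the zero-truncated negative binomial, a latent
    normal frailty per patient, optional binary covariates with log-odds
    ``effects``, and an intercept solved so the *marginal* success
    probability equals ``marginal_p`` at covariate reference levels.
    """
    from iatpsim.stats import marginal_intercept
    from scipy.special import expit

    b0 = marginal_intercept(marginal_p, frailty_sd)
    counts = _sample_ztnb(rng, episode_mean, episode_dispersion, n_patients, 90)
    rows = []
    effects = effects or {}
    for i in range(n_patients):
        u = rng.normal(0.0, frailty_sd)
        covs = {k: int(rng.random() < 0.5) for k in effects}
        eta = b0 + u + sum(effects[k] * covs[k] for k in effects)
        for j in range(int(counts[i])):
            y = int(rng.random() < expit(eta))
            rows.append({"patient_id": f"P{i:04d}", "y": y, **covs})
    return pd.DataFrame(rows)
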