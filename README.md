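# iatpsim

Simulation and clustered-outcome statistics for **individualized
antitachycardia pacing (IATP)** — the closed-loop ICD therapy that
terminates reentrant monomorphic ventricular tachycardia (MVT) with burst
pacing plus one or two adaptive extrastimuli, steering stimulus timing in
real time from the post-pacing interval (PPI).

The package is for methodologists and device-therapy researchers who want
a fully synthetic, seeded, end-to-end replica of how such therapy is
*studied*: a phenomenological reentry circuit that honors the entrainment
identity `PPI = VTCL + 2d`, an ICD detection/therapy state machine
(zones, NIDs, redetection, the 8-interval episode-termination criterion),
deterministic rule-based episode adjudication (Type I/II breaks,
spontaneous resumption, the ≥30 ms-and-≥10% acceleration rule, success
endpoints), a cohort generator with heavy-tailed per-patient episode
counts and patient-level frailty, and generalized estimating equations
(GEE, exchangeable working correlation, sandwich covariance) for the
clustered binary outcomes — so that every adjudication rule and every
statistical estimator can be validated against known ground truth.

## Worked example

One MVT episode — a 340 ms circuit, 85 ms from pacing site to circuit —
detected and treated by a nominally programmed two-zone device:

```python
import numpy as np
from iatpsim import CircuitParams, DeviceConfig, run_episode, adjudicate_episode

rec = run_episode(CircuitParams(vtcl_ms=340, d_ms=85),
                  DeviceConfig.nominal(), np.random.default_rng(1))
adj = adjudicate_episode(rec)
```

which prints (via the snippet in `docs/methods.md`'s conditions):

```
detected zone:        VT
measured CL (ms):     338.90070201683193
sequences delivered:  2
  seq 1: S1=298  S2=288  PPI=510  -> no_effect
  seq 2: S1=302  S2=268  -> type_I_break
final state:          terminated_by_atp
adjudicated success:  True | rate class: slower
```

Reading it: detection in the VT zone measured a cycle length of ~339 ms,
so sequence 1 paced eight S1 at 88% (298 ms) plus an S2 at 85% (288 ms).
The circuit reset but did not terminate; the measured PPI of 510 ms is
exactly `VTCL + 2d = 340 + 170`, so the engine judged the S2 captured and
decremented it 20 ms. Sequence 2's earlier S2 terminated the VT with at
most one abnormal beat after the train — a Type I break — and the episode
ends shock-free, an IATP success in the *slower*-VT stratum (CL ≥ 320 ms).

The same machinery scales to cohorts:

```bash
iatp all --seed 1 --out out/          # synthesize → simulate → adjudicate → analyze
iatp fixture --out out/               # the printed-count fixture + its report
```

`out/report.json` then carries the rhythm mix, the Figure-style outcome
and per-sequence efficacy tables, patient roll-ups, the GEE-adjusted
success/shock-free/acceleration proportions with 95% CIs, and the
univariate/multivariate factor table — every percentage with its
numerator and denominator.

## Layout

| module | contents |
|---|---|
| `iatpsim.vt_dynamics` | reentry circuit, SVT pro-arrhythmia model, interval streams |
| `iatpsim.device_model` | detection state machine, IATP therapy engine, episode loop |
| `iatpsim.adjudication` | endpoint definitions, rhythm classing, factor categories |
| `iatpsim.cohort_synth` | seeded patient/programming/episode generator |
| `iatpsim.stats` | GEE (Liang–Zeger), adjusted proportions, factor tables, t-tests |
| `iatpsim.pipeline` / `iatpsim.cli` | orchestration, printed-count fixture, reports, `iatp` CLI |

`docs/methods.md` documents the model assumptions, parameter defaults
and their rationale, what the synthetic cohorts do and do not emulate,
and the numerical choices.
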