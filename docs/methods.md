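# Methods

`iatpsim` models, at desk scale, the closed-loop individualized
antitachycardia pacing (IATP) therapy pathway of an implantable
cardioverter-defibrillator (ICD), together with the adjudication rules and
clustered-proportion statistics used to report the performance of such
therapy on cohorts of remotely monitored patients. This note records the
model, its assumptions, the parameters that matter, and the choices made
where the design was genuinely open.

## 1. Reentrant VT circuit (`vt_dynamics`)

Monomorphic ventricular tachycardia (MVT) is represented as a
single-entry-site excitable-gap reentry loop. A wavefront circulates with
intrinsic cycle length `vtcl_ms`; the pacing electrode communicates with
the circuit entry through a one-way conduction time `d_ms`. A stimulus
delivered at time *t* reaches the entry at *t + d*; it captures if the
local tissue has recovered (time since the last entry activation ≥
`refractory_ms`) and is otherwise blocked. A captured stimulus resets the
circuit phase.

This minimal geometry was chosen because it reproduces, by construction,
the entrainment identity that PPI-based closed-loop pacing presumes:

    PPI = VTCL + 2·d

for a resetting stimulus, where the post-pacing interval (PPI) is measured
at the pacing site from the last delivered stimulus to the next sensed
beat. When later stimuli fail to capture, the PPI lengthens by the time
since the last resetting stimulus — which is exactly the signal the
therapy engine uses to detect loss of extrastimulus capture.

Termination by a captured final extrastimulus is stochastic with
probability `logistic((p − term_center_ms)/term_slope)` where *p* is the
stimulus prematurity at the circuit entry (ms by which the stimulus
precedes the expected wavefront). Prematurity is physically capped by the
excitable gap `vtcl_ms − refractory_ms`; a circuit whose gap ends well
short of its termination center is therefore hard to terminate no matter
how aggressively couplings are decremented. That cap, not the coupling
floor, is the dominant failure mode in the simulator — an assumption, not
an observation about real circuits.

On non-termination, monomorphic acceleration (probability `p_acc_mvt`)
multiplies the cycle length by `accel_factor` (default 0.85, which always
satisfies the ≥30 ms and ≥10% acceleration rule for cycle lengths ≥300 ms)
and degeneration to polymorphic VT/VF (`p_acc_pvt`) replaces the rhythm
with exponentially jittered short cycles (mean 220 ms, sd 40 ms) and
per-beat morphology churn. Stimuli with coupling below a 150 ms
physiological floor are ignored.

Two small episode-level hazards live on the circuit because they shape
the outcome taxonomy downstream: `p_reinit` (default 0.06), the chance
that a broken MVT re-initiates before the device's 8-interval termination
criterion is met — this is what separates electrophysiologic efficacy
from device-recognized success — and `p_spont`/`p_slow` (0.01/0.005), the
per-failed-sequence chances of spontaneous termination or slowing below
every treatment zone.

The SVT model is rate-only (no atrial channel): ventricular sensing at
`svt_cl_ms` with sinus morphology, plus per-sequence pro-arrhythmia draws
(PVC 0.0249, non-sustained VT 0.0156, induced sustained MVT 0.0078,
induced VF 0.0031). These defaults put the pro-arrhythmic fraction near
33 of 643 sequences, the safety workload the generator emulates. The
model deliberately omits AV association; discriminator behavior is out of
scope, so SVT episodes simply satisfy rate criteria.

Known PPI limitation: the model leaves `d` independent of termination
probability. The package's own separation analysis therefore shows no
PPI−VTCL difference between successful and failed therapy by
construction; this mirrors the null result such analyses report, but the
model cannot adjudicate *why* that null holds in tissue.

## 2. Device model (`device_model`)

Detection follows the two ICD counting styles: VT-type zones need
`nid_initial` *consecutive* intervals below the zone boundary; VF-type
zones need x of the last y. The fastest zone whose criterion is met first
claims the episode; measured cycle length is the median of the last four
intervals. An episode ends on eight consecutive intervals longer than
every programmed boundary. Redetection between sequences uses faster
NIDs (12 for VT-type, 12/16 for VF-type) — the device is already
suspicious — and the VF-type x/y counter restarts after each train.

The IATP engine plans each sequence as an 8-pulse S1 burst at
`round(0.88 × measured CL)` plus one extrastimulus S2, starting at
`round(0.85 × measured CL)` and decremented 20 ms after every captured
but unsuccessful sequence, floored at the programmed minimum S2/S3. A PPI
exceeding the expected reset PPI (the running minimum of observed PPIs)
by more than 40 ms is judged a loss of S2 capture; non-capture at the
floor, or two consecutive non-capture verdicts, marks the
single-extrastimulus approach futile and enables the S3 (coupling
S2 − 20 ms, same floor), which is never delivered before the third
sequence. The exact burst length, starting fraction, decrement, and PPI
tolerance are plausible engineering choices, not published constants;
they are isolated inside `plan_sequence`/`interpret_ppi` so alternative
rules can be swapped without touching the episode loop.

Other closed decisions: therapy keeps the zone programming claimed at
initial detection even if acceleration moves the rate into a faster zone
(real devices re-enter zone menus; the paper trail for that behavior is
thin and the simplification keeps sequence accounting unambiguous); an
optional conventional burst (8 pulses at 88%, no PPI adaptation) may
follow exhausted IATP slots; shocks always convert (no shock failures are
modeled); an episode cap of 200 post-therapy beats returns
`final_state=ongoing` rather than looping.

## 3. Adjudication (`adjudication`)

All endpoint definitions are deterministic re-derivations from the
interval stream, independent of the simulator's own labels (the test
suite exploits that independence as an oracle):

* **Type I break** — at most one abnormal complex after the train, then
  ≥4 consecutive normal beats.
* **Type II break** — ≥2 abnormal complexes differing from the pre-ATP
  rhythm in cycle length (by more than `cl_similarity_ms`, default
  40 ms) or morphology.
* **Spontaneous resumption** — ≥2 abnormal complexes matching the
  pre-ATP rhythm in both respects before normal rhythm returns.
* **Accelerated MVT** — post-train cycle length shorter by ≥30 ms *and*
  ≥10% (inclusive comparisons); **polymorphic acceleration** — conversion
  to morphology churn.
* **IATP success** — shock-free episode resolved by termination,
  spontaneous termination after an attempt, or slowing below the treated
  rates, with IATP as the final therapy; **shock-free success** — the
  same but any ATP protocol may be the final therapy.
* Factor categories: *rapid VT* = initial CL < 320 ms; detection
  *extended* when VT NID > 16 or VF NID x > 18; programmed sequences
  *at least nominal* against the zone map {VF: 3, FVT: 5, VT: 7}.

An "abnormal" complex is any beat with cycle length below the slowest
zone boundary or non-sinus morphology. Because the first sensed interval
after a train is a PPI rather than a cycle length, it is excluded from
cycle-length comparisons (its morphology still counts). When the episode
ended in a shock, the trailing sinus run after the final train is
stripped before break classification so a shock conversion is not
misread as an ATP break. The 4-beat normal-run requirement and the 40 ms
cycle-length similarity tolerance are exposed on `AdjudicationRules`;
40 ms was chosen above sensing jitter, and a threshold below the
acceleration floor is impossible at typical cycle lengths.

Rhythm classing works on the pre-therapy window using the synthetic
labels: T-wave labels ⇒ oversensing; a run that self-ends before therapy
⇒ non-sustained VT; sinus morphology at tachycardia rate ⇒ SVT;
morphology churn or cycle-length sd > 60 ms at short cycle length ⇒
PVT/VF; a stable (sd ≤ 20 ms) single-morphology tachycardia ⇒ MVT. On
simulated cohorts this classifier and the per-sequence effect derivation
agree with generator truth on ≥99% of MVT episodes; disagreements are
surfaced in test output, never dropped.

## 4. Synthetic cohort (`cohort_synth`)

The generator's defaults are the study conditions the package emulates:

| law | default | emulates |
|---|---|---|
| episode count / patient | zero-truncated NB, mean 6, dispersion 0.6, cap 90 | heavy tail 1–88, ≥50% multi-episode patients |
| MVT cycle length | lognormal, median 340 ms, σ=0.12186, truncated [200, 600] | 30.8% of episodes below the 320 ms rapid cutoff |
| conduction time d | Normal(85, 45) ms truncated > 10 | PPI−VTCL ≈ 170 ms with large spread (the truncation makes sd(2d) ≈ 80 ms) |
| rhythm mix | MVT .8685, SVT .0877, PVT/VF .0361, NSVT .0073, TWOS .0004 | the 2259/228/94/19/1 admixture |
| demographics | age N(68, 13.3) in [18, 100]; 81.7% male; 75.3% first device; indication .424/.538/.037; device type .157/.451/.392; 9.2% missing | Table-1-style margins |
| programming | VT cutoff median ≈380 ms, NID 16 in 48%; VF cutoff median 300 ms, 30/40 in 81%; min S2/S3 nominal (200 ms) in 92% | unconstrained physician programming |
| sequences programmed | at-least-nominal share 55% / 76% / 76% (VF/FVT/VT), nominal value modal | therapy-programming practice |

The printed per-level sequence table and the at-least-nominal text rates
in the emulated report are mutually inconsistent (the VT column sums to
an 88% at-least-nominal share against a stated 76%); the generator
follows the text rates and keeps the nominal value modal.

Each patient carries a latent Normal(0, `frailty_sd`) frailty that
shifts the termination-curve center by `term_center_scale_ms` (30 ms)
per unit, along with injected effects for female sex (+0.5) and rapid VT
(−0.3) in the same units. This gives factor analyses on synthetic data a
known ground truth and induces within-patient outcome correlation that
the exchangeable GEE should detect (α̂ > 0). The refractory period is
drawn as `vtcl × U(0.66, 0.76)`; together with `term_center_ms = 45`
this puts overall adjusted IATP success near 0.87–0.90, first-sequence
efficacy in the mid-50s, and a rapid-vs-slower success gap of roughly
8–15 points — the neighborhood of the conditions being emulated, not a
fit to them. Device boundaries are conditioned on the patient's largest
VTCL (cutoff ≥ VTCL + 45 ms) so that every planned episode is
detectable, which is the selection effect implicit in studying *treated*
episodes.

What the generator does **not** emulate: electrogram waveforms,
AV-association and discriminator behavior, programming changes over
time, transmission logistics, follow-up schedules, or any missing-data
structure beyond a missing-demographics fraction. Passing tests
therefore show that the pipeline's logic and statistics behave correctly
under the stated laws — not that the circuit model predicts any real
patient's therapy response.

## 5. Statistics (`stats`)

The binomial-logit marginal model is solved by iteratively reweighted
Liang–Zeger updates. The exchangeable working-correlation parameter is
the moment estimate from Pearson residual cross-products (with the
customary n−p corrections), the scale is estimated from squared Pearson
residuals, and inference uses the robust sandwich covariance.
Convergence requires max |Δβ| < 1e−8 within 100 iterations;
non-convergence is flagged on the fit, never silent. Degenerate or
separated outcomes raise `separation_detected`; in factor tables a
factor with a constant-outcome level is excluded from the multivariate
design and its rows are marked rather than dropped. Exchangeable is the
default working structure (the natural choice for repeated episodes
within patients), with independence available for sensitivity — under
independence the estimates reduce to ordinary logistic GLM, which the
tests verify against an independent reference implementation.

Adjusted proportions are intercept-only fits; 95% intervals are formed
on the log-odds scale (`β̂₀ ± 1.96·robust SE`) and back-transformed,
guaranteeing bounds inside [0, 1]. Wald p-values (not score) are
reported, closed-form from the sandwich. The multivariate factor model
enters all factors additively with no interactions or selection; age is
the only continuous factor and is standardized for conditioning.
Patient-level percentages (any/all-success roll-ups) are raw counts,
matching the arithmetic of printed integer tallies.

t-tests delegate to scipy (`ttest_ind`, `ttest_ind_from_stats`); the
summary-statistic mode exists because printed tables report means and
sds, from which the pooled t (≈0.56 for the PPI−VTCL separation
comparison) is recomputable but the underlying raw-data p-value is not.

`marginal_intercept` solves E_z[expit(b₀ + σz)] = p by 60-node
Gauss–Hermite quadrature and root bracketing; the reduced-form
clustered-outcome sampler built on it is what the recovery, coverage,
and type-I-error tests use, because it makes the true marginal a known
quantity rather than a simulator output.

## 6. Reporting (`pipeline_cli`)

Every percentage in every table carries its numerator and denominator,
and tables cross-foot. `percent` rounds half away from zero through a
one-guard-digit intermediate with a banker's tie-break on the guard
digit — the convention that reproduces tabulated clinical percentages
such as 2259/2601 → 86.8% (86.8512 → 86.85 → 86.8) alongside
228/2601 → 8.8%. The printed-count fixture builds tables whose marginal
counts equal the emulated report's integers exactly (episode mix
2259/228/94/19/1 over 2601; 336 of 415 patients with MVT; 234
all-success and 26 all-fail; 247 treated SVT episodes carrying 643
sequences with 33 pro-arrhythmic outcomes); per-row details are
arbitrary but schema-valid, and the per-patient episode allocation is a
deterministic heavy-tailed split (maximum 88) rather than a draw.

Problem sizes: the default end-to-end run and the acceptance script use
a 336-patient cohort (≈2700 episodes, ≈12 s on one core); property
suites use 10 000 random interval streams for the detection oracle and
≈5 000 MVT episodes for the adjudication-agreement oracle; statistical
calibration uses 200 replicates of 150-patient reduced-form cohorts for
coverage and 500-patient cohorts for recovery. These sizes were chosen
so each check's Monte-Carlo error is small against its tolerance.

## 7. Known limitations

* The circuit is phenomenological: no tissue, restitution, or wavebreak
  dynamics; termination is a logistic draw, not electrophysiology.
* One reentry circuit per episode; no multiple morphologies within an
  episode except through acceleration.
* The device model omits discriminators, charge/battery dynamics, and
  the combined-count subtleties of FVT-via-VF programming (FVT subzones
  share the parent zone's counting style).
* GEE small-sample corrections (Kauermann–Carroll, Mancl–DeRouen) and
  conditional (mixed-effects) models are out of scope.
* The adjudicator sees synthetic morphology labels; nothing here
  replaces human electrogram review.
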