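# Methods

This note documents the models, parameter choices and numerical conventions
behind `remloop`, in the spirit of a methods appendix: what is simulated,
what is assumed, and what the simulation does and does not say about real
recordings.

## Real-time staging pipeline

**Window and update.** The analysis unit is a 5 s window of 1 kHz EEG
(5000 samples) advanced in 100 ms blocks: a 10 Hz decision rate with 98 %
overlap between consecutive windows. The window buffer is a strict
fixed-step contract — pushes must be exactly 100 samples — because the
real acquisition delivers fixed-size packets and any other block size
indicates a configuration error. Until the first 5 s have streamed in,
decisions are emitted as Wake with a `warmup` flag; a deprivation device
must never actuate on a partially filled buffer.

**Spectral estimate.** Each window is Hanning-tapered and zero-padded to
10,000 points before a one-sided FFT periodogram, giving a 0.1 Hz grid from
0 to 500 Hz (5001 bins). The periodogram uses density scaling with the
window-power correction `1/(fs·Σw²)`, so `Σ p(f)·Δf` is a power in mV².
Both classifier features are ratios of band powers, so any consistent
scaling gives identical decisions; density scaling was fixed so that the
intermediate quantities remain physically interpretable. No detrending or
digital filtering is applied beyond the taper: the simulated front end is
analog band-passed at 0.5–500 Hz, and the DC bin is excluded from every
band sum instead.

**Band-edge convention.** Band powers are Riemann sums over half-open
intervals `[f_lo, f_hi)`, which keeps the shared 4 Hz edge from being
counted in both the delta and theta bands, and band power additive over
adjacent bands. The single exception is the terminal Nyquist bin: the
"total" band [0.5, 500] includes the 500 Hz bin so it spans the entire
recorded bandwidth. On a flat spectrum the features therefore evaluate to
exactly `R_θ/δ = 40/35 = 8/7` and `R_HF = 110/499.6`.

**Degenerate spectra.** If the delta band or the total band carries no
power, the feature pair is flagged undefined and the classifier returns
Wake. The fail-safe direction is deliberate: an undefined spectrum must
never fire the actuator's REM branch.

## Classification and calibration

The decision rule is a fixed partition of the feature plane: Wake whenever
`R_HF ≥ τ_HF` (the high-frequency test takes precedence — the only reading
under which the three branches are total and mutually exclusive), otherwise
REM iff `R_θ/δ ≥ τ_θ/δ`, otherwise NREM.

Thresholds are per-animal: `τ_θ/δ = mean − sd` of the REM theta/delta
ratios and `τ_HF = mean + sd` of the NREM high-frequency fractions, both
over labeled 2.5 s baseline epochs, with the sample (n−1) standard
deviation — the conventional estimator at realistic epoch counts. Epochs
flagged as occurring during platform motion are excluded from calibration
(motion artifacts would inflate the NREM HF statistics). A state with fewer
than two usable epochs aborts calibration with an error naming the state.

Majority voting reduces the 10 Hz decision stream to 2.5 s epochs (25
decisions per epoch). Ties are broken REM > NREM > Wake: for a deprivation
device the costly error is a missed REM epoch, and the tie-break is the
only place that asymmetry can be expressed deterministically.

**Validation gate.** Before a closed-loop run, per-state recall on a
held-out labeled session is compared against configurable minima (defaults
REM 0.8, Wake 0.7, NREM 0.8). The defaults are operating criteria of this
package, not physical constants; they were set at levels a working
classifier of this design comfortably exceeds while still catching swapped
or degenerate thresholds. A state absent from the validation session fails
the gate explicitly.

## The virtual mouse

**State dynamics.** Vigilance follows a three-state Markov chain over
(REM, Wake, NREM) stepped at 2.5 s epoch boundaries. The default matrix

```
          REM      Wake     NREM
REM    [ 0.976    0.021    0.003   ]
Wake   [ 0.0      0.98     0.02    ]
NREM   [ 0.0035   0.0156875 0.9808125 ]
```

was constructed to have stationary occupancy exactly (7 %, 45 %, 48 %) —
REM occupancy near 7 % of total time is the baseline figure this kind of
experiment reports — with mean dwell times of ~104 s (REM), ~125 s (Wake)
and ~130 s (NREM), in the range of adult mouse bout durations, and no
direct Wake→REM transitions. Rodent dwell-time distributions are better
described by heavier-tailed laws than the geometric dwell a Markov chain
implies; the chain is a deliberate simplification that fixes occupancy and
transition structure, which is what the downstream statistics consume.

**Signals.** Each state's EEG is a sum of narrowband oscillators —
band-pass filtered white noise (4th-order Butterworth), RMS-calibrated in
mV — plus a 1/f pink background (low-order IIR shaping filter whose power
response follows 1/f across 0.5–500 Hz at this sampling rate). Defaults:

| state | oscillators (centre Hz, bw Hz, RMS mV) | background RMS | EMG RMS |
|-------|----------------------------------------|----------------|---------|
| REM   | theta (6.5, 1.5, 0.25), delta (2.0, 1.5, 0.05) | 0.008 | 0.02 |
| Wake  | theta (6.5, 2.0, 0.10), delta (2.0, 1.5, 0.08), HF (145, 110, 0.08) | 0.02 | 0.40 |
| NREM  | delta (2.0, 1.5, 0.20), theta (6.5, 1.5, 0.05) | 0.015 | 0.08 |

These amplitudes realize the qualitative spectral contract — REM
theta-dominant with atonia, NREM delta-dominant, Wake broadband with high
EMG — with feature-plane separation comparable to what per-animal
calibration achieves on real data (a few percent of epochs near state
transitions are ambiguous, because a 5 s window spans the transition).
Filter states persist across blocks, so spectra are stationary within a
state and signals continuous across the 100 ms control blocks; only the
active state's filters are fed, so a bout onset shows a brief spectral
build-up, as real transitions do. All samples are clipped to the ±5 mV ADC
range and clip events counted.

**Stimulation response.** While the platform moves during REM, the bout
terminates into Wake with probability `arousal_prob = 0.3` per 100 ms cycle
(mean latency ~0.3 s once motion starts). The behavioural response is
probabilistic by design, not deterministic per trigger. An optional linear
decline of `arousal_prob` with session time emulates reduced stimulus
efficacy under accumulated REM pressure during prolonged deprivation;
it is disabled by default. Platform motion also adds broadband 90–200 Hz
artifact (RMS 0.2 mV) to the EEG, so stimulated epochs classify as Wake —
which is also why stimulated epochs are excluded from calibration.

**What the generator does not emulate.** Circadian/ultradian structure,
REM rebound dynamics, electrode drift, multi-channel montages, and
biophysically realistic waveforms (spindles, K-complexes, sawtooth theta).
Passing tests therefore demonstrate that the detection/control/statistics
chain behaves correctly on signals satisfying the stated spectral
contracts — not that the classifier's recall figures would transfer
unchanged to any particular recording rig.

## Closed loop and actuator

The loop is a fixed 100 ms virtual tick (simulated time; a 24 h session
runs in about a minute). Cycle order: plant step → signal block (+ artifact
while the actuator is not idle) → window push → PSD → features →
classification → TTL trigger (high iff the decision is REM, same cycle) →
actuator update. The trigger is level-driven — high exactly while REM is
decided — which is the simplest policy consistent with "trigger within the
same control cycle"; minimum-on-time or refractory behaviour can be layered
on top but defaults to none. Termination is max-duration, optionally a
cumulative-REM-seconds cap.

The actuator ramps linearly at 523.6 rad/s² to 8000 rpm (1.6 s), then holds
(`running`); a low trigger stops it within one cycle. Derived kinematics:
cam speed 8000/103 ≈ 77.7 rpm through the gear reduction, one platform
oscillation per cam revolution ≈ 1.3 Hz. The cam geometry (15 mm / 10 mm
elliptical axes) implies a 5 mm peak-to-peak displacement while the nominal
platform figure is 10 mm; the two disagree in the source hardware
description, so `cam_kinematics` reports both side by side rather than
silently choosing. On the real device the per-cycle computation takes
~20 ms against the 100 ms budget and detection-to-TTL latency is <1 ms;
these are hardware figures, documented but not simulated.

A pre-run self-check verifies the signal source is live, the feature
pipeline returns finite values, and a ~5 s actuation burst toggles the
actuator out of and back to idle; closed-loop entry is refused on any
failure.

Determinism: plant and signal randomness run on independent child streams
of the session seed, and the plant consumes its arousal draw on every REM
cycle whether or not stimulation is enabled — so an `arousal_prob = 0` run
is bit-identical to a stimulation-disabled run, which is the control
comparison the tests rely on.

## Efficacy statistics

Occupancy is the percentage of epochs per state (the three values sum to
100). Fold changes are per-animal baseline/RSD occupancy ratios — the same
orientation for all three states, so selective REM suppression appears as a
large REM ratio with Wake and NREM near 1 — summarized by the geometric
mean. When an occupancy is zero (complete suppression in a finite session),
half of one epoch's occupancy is added to both members of that pair and the
adjustment is reported; this keeps ratios finite without hiding the
adjustment. The 95 % CI is a bias-corrected percentile bootstrap on the log
ratios (10,000 seeded resamples); the percentile family makes no normality
assumption at n = 8 and the bias correction matters because the GM of
ratios is skewed.

The paired Wilcoxon signed-rank test uses the exact conditional null
distribution: differences are ranked by absolute value with midranks for
ties and zeros included in the ranking but excluded from the statistic
(Pratt), and the distribution of the positive-rank sum over all 2^m sign
assignments is computed by dynamic programming over doubled (integer)
ranks. At n = 8 with all differences one-signed the two-sided p is exactly
2/256 ≈ 0.0078, the floor of the design.

## Problem sizes

Tests and the reproduction script run at desk scale, chosen to keep full
runs in minutes while leaving enough epochs for stable statistics: 2 h
calibration baselines (~2900 epochs, enough for ≥ 50 REM epochs in typical
draws), 1 h open-loop validation sessions, 2 h closed-loop deprivation
sessions, 24 h hypnograms (34,560 epochs) wherever only occupancy is
needed, and an 8-animal cohort matching the reference experimental group
size. Two-hour windows make per-animal REM occupancy noisy (SD ≈ 5
percentage points across seeds — occupancy is bout-limited), which the
geometric-mean/CI machinery is designed to absorb; cohort-level conclusions
are stable across seeds.

## Known limitations

- Detection latency is bounded below by the 5 s analysis window: a REM bout
  is detected only once the window is mostly REM, so ~3–5 s of each bout
  survive even with `arousal_prob = 1`. This is a property of the staging
  design, reproduced faithfully, not a simulator artifact.
- The Markov plant has geometric dwell times and no REM-pressure homeostat
  (beyond the optional arousal decline), so rebound phenomena cannot be
  studied with it.
- EDF files are read (via `mne`) but not written; the native signal format
  is float32 binary with a JSON sidecar.
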