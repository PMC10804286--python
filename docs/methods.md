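# Methods

This note documents the models, procedures and numerical choices behind
`somnoresp`, in the spirit of a methods supplement: what each stage
assumes, which parameters matter, and what the synthetic benchmark does
and does not demonstrate about real recordings.

## Signal model and conventions

Recordings are sets of uniformly sampled channels (1000 Hz by default for
respiratory/EEG/EMG/SpO2 channels) sharing one time base; time is seconds
from recording start and every interval is half-open `[t0, t1)`.
Positive flow is inspiration (invertible per call).  The native on-disk
container is a JSON sidecar plus one delimited text file per channel,
versioned (`format_version`), with samples written at 17 significant
digits so round trips are bit-faithful.  No proprietary acquisition
formats are read; EDF support is not included because no EDF library is
part of the dependency set — the text container is the interchange format.

## Tidal-volume calibration

The barometric method attributes chamber-pressure fluctuations to the
warming and humidification of inspired air.  The conversion factor

    F = T_B (P_B − P_H2O_TC) / [ T_B (P_B − P_H2O_TC) − T_C (P_B − P_H2O_TB) ]

uses body and chamber temperature (K), barometric pressure, saturated
vapor pressure at body temperature and humidity-scaled vapor pressure at
chamber temperature (mm Hg).  Saturated vapor pressure is the Antoine
equation for water (A = 8.07131, B = 1730.63, C = 233.426; P in mm Hg, T
in °C), accurate to ~0.5% against steam tables over the validated range
270–320 K; out-of-range temperatures raise.  A non-positive denominator
(body and chamber in thermal/humidity equilibrium) is a degenerate
condition and raises rather than returning a huge factor.  Note the
factor *decreases* with body temperature: warming the body raises
P_H2O_TB, which grows the denominator faster than the numerator.

Volume is linear in pressure (`V = P/P_K · V_K · F`); flow is the
second-order central difference of volume, with an optional zero-phase
20 Hz Butterworth low-pass (off by default — murine breathing is well
below 20 Hz even during sniffing).

Defaults: chamber 29 °C, humidity 0.9 (the chamber is humidified),
barometric 760 mm Hg, calibration injection 0.05 mL.

## Breath segmentation and features

Breaths are delimited by signed zero crossings of flow with a hysteresis
band of 3× a robust noise SD, estimated as `1.4826·MAD(diff(flow))/√2`
— the first difference suppresses the slowly varying respiratory
component, so this tracks the sensor noise floor rather than signal
amplitude.  Zero-crossing segments that stay inside the band, or last
under 20 ms, are merged into their neighbor; noise around zero therefore
never creates breaths, and a flat or noise-only trace yields an empty
breath list rather than an error.

VT is the trapezoidal integral of inspiratory flow; V_Imax1/V_I50/V_Imax2
are the peak flows over `[0, Ti/2)`, at `Ti/2`, and over `[Ti/2, Ti)`.
At 1000 Hz these match analytic waveforms to ≤1 sample in timing and
≤0.1% in amplitude (tested).

Stage-resolved analysis windows: every REM period in full; NREM sampled
as the first ≥20-s NREM run in each 30-min block (one 20-s stretch per
block); wake excluded except for the CO2 challenge.  A "centered" NREM
selection variant is not currently exposed; the first-eligible-run rule
is deterministic and order-independent.

## Sniff and flow-limitation classification

Sniffs are breaths with unusually short inspiration: robust Z score of Ti
(median/MAD) at or below −1.75 within the analysis window.  Two guards
matter in practice: when the MAD is zero (a constant majority of Ti
values) the classical SD is used instead, and when both scales are zero
no sniffs are flagged.  Fewer than 10 breaths cannot support a Z score;
the filter then flags nothing and warns.  The threshold side is the
short-duration side — sniffs are short — with threshold and side
configurable.

A non-sniff breath is inspiratory-flow-limited when (a) flow first comes
within τ of its maximum no later than half of inspiration (early peak),
(b) the relative variation `(max − min)/V_I_max` over the middle 50% of
inspiration is ≤ τ (the mid-inspiratory plateau), and (c) optionally,
effort still rises from plateau onset to plateau end.  τ defaults to
0.10: an unobstructed half-sine varies by `1 − sin(π/4) ≈ 29%` over its
middle half and is always rejected, while clips at severity ≥ 0.7 of the
generator's model pass.  Flow is smoothed with a short boxcar
(min(Ti/8, 25 ms)) before landmarking so additive noise does not inflate
the plateau's apparent variation; the early-peak time uses first
attainment of `(1 − τ)·V_I_max` rather than the exact argmax, because
under noise the argmax of a genuine plateau is uniform over the plateau.

## Sleep staging

5-s epochs are staged from periodogram band powers (2–5, 5–10,
10–20 Hz) and RMS amplitudes; EMG RMS is computed after a 30 Hz
high-pass.  Thresholds self-calibrate per recording: the EMG split
maximizes between-class variance on log EMG RMS (histogram-valley/Otsu),
with a bimodality guard — if the two classes' means differ by less than
2×, there is no distinct wake mode and the EMG criterion is disabled.
The decision rule is: high EMG → Wake; otherwise strict dominance of the
fast band → Wake (quiet wakefulness), of the slow band → NREM, of the
theta band → REM; ties keep the previous epoch's stage.  Staging is
deterministic given the recording.

Automated staging is a convenience, not a dependency: externally scored
hypnograms (two-column `epoch_start_s,stage` CSV) are first-class inputs
to every downstream stage.  Architecture summaries (total sleep time,
per-stage time, bout counts and mean lengths) are plain run-length
encodings of the hypnogram.

## Apnea and desaturation scoring

An apnea is a ≥90% reduction in airflow lasting at least two breath
cycles at the baseline rate or at least 0.7 s; by default either duration
criterion suffices (`min` of the two), with a stricter `max` mode
available.  Candidates are found on a sliding-maximum envelope of |flow|
whose window is one baseline breath period: breathing keeps the envelope
at peak flow, an apnea collapses it, and dilating the sub-threshold
region by half a window undoes the sliding-max erosion, recovering event
boundaries to within ~0.1 s.  Each candidate's depth is then verified
against the median V_I_max of the 10 preceding non-event breaths (breaths
below half the global median peak are treated as in-event and skipped).
Candidates that touch the end of the recording are not scored, since
their completion cannot be observed.  Events carry the stage of their
onset epoch; the apnea index is events per hour of that stage.

Desaturations are scored on a 10 Hz decimated SpO2 trace against a
running baseline (90th percentile of the preceding 120 s): a maximal
interval at or below baseline − 4% lasting at least two median breath
cycles.  The ODI denominator is hours of total sleep (NREM + REM);
wake-onset events are excluded from the index but still reported.

## Hypercapnic ventilatory response

Each CO2 level window must be ≥90 s; breaths from 60 s after the gas
switch to window end, restricted to wake epochs, contribute their
instantaneous VE to the level mean.  The 60-s exclusion is a fixed rule
(a first-order ventilatory transition with τ ≈ 15 s has settled to within
2% by then); an adaptive change-point detector was considered and
rejected as an unnecessary degree of freedom.  The HCVR is the ordinary
least-squares slope of VE (mL/min) on inspired CO2 (%); with two levels
this is the difference quotient exactly.

## Calorimetry

Open-circuit rates use the Haldane transformation
(`H = (1 − FiO2_in − FiCO2_in)/(1 − FiO2_out − FiCO2_out)`):
`VO2 = Q(FiO2_in − FiO2_out·H)`, `VCO2 = Q(FiCO2_out·H − FiCO2_in)`,
with Q the inflow (mL/h; default 30 L/h ≈ 0.5 L/min).  Rates are averaged
on the 11-min collection grid with an optional light/dark partition;
`RER = VCO2/VO2` holds exactly per bin by construction.  Coupling ratios
VE/VO2 and VE/VCO2 convert both sides to mL/min.

## Exact crossover statistics

Wilcoxon signed-rank (within-group deltas, zeros dropped, mid-ranks for
ties) and Mann-Whitney (between groups) compute exact two-sided p-values
as twice the smaller tail, capped at 1.  The null distributions are built
by dynamic programming over doubled (hence integer) mid-ranks —
algebraically identical to enumerating all 2^n sign assignments or
C(N, n_a) labelings, but feasible to n = 25 / N = 20, beyond which a
normal approximation with continuity and tie corrections takes over
(flagged in the result).  Brute-force enumeration is kept in the test
suite as an independent oracle and agrees exactly for all n ≤ 8, as does
scipy's exact mode on tie-free inputs.  Quartiles use linear
interpolation; whiskers are Tukey's (most extreme datum within 1.5·IQR).
Factorial inference (two-way ANOVA / mixed models) is out of scope: the
pipeline emits tidy tables ready for a standard statistics library.

## The synthetic generator

The generator is the benchmark's ground truth and emulates the structure
the analysis assumes:

- **Breaths**: half-sine inspiration with peak `π·VT/(2·Ti)` (inspired
  volume exactly VT), exponential expiration whose area returns volume to
  baseline.  Breath-to-breath jitter: period CV (default 0.08),
  multiplicative amplitude jitter (SD 0.05), additive flow noise
  (SD 0.01 of nominal peak).  The volume channel is the running
  trapezoidal integral of the (noisy) flow, so volume/flow consistency is
  exact by construction.
- **Flow limitation** (REM breaths, default probability 0.4, severity
  0.85): inspiratory flow is clipped at the level the half-sine reaches
  at 20% of Ti, interpolated by severity; at severity 1 the middle 60% of
  inspiration is exactly flat.  Clipped volume is *not* restored —
  obstructed breaths lose volume.  The effort channel of a flow-limited
  breath is a monotone quarter-sine drive scaled by `effort_gain` (1.3),
  so effort rises through the plateau; normal breaths mirror their
  unclipped flow.  The plateau reference at 20% (rather than 25%) of Ti
  puts plateau onset ahead of the flatness window, so severities ≥0.7
  pass the τ = 0.10 test.
- **Sniffs** (probability 0.02): the whole cycle is compressed by
  `ti_scale` (0.4) at unchanged drive amplitude.
- **Apneas**: per-stage Poisson counts (default 0/2/15 per hour in
  W/NREM/REM), durations normal (1.2 ± 0.3 s, min 0.8 s), flow scaled to
  2% (a ≥95% reduction, safely beyond the 90% scoring threshold) while
  effort is multiplied by 1.2 (obstructive pattern).  Placement redraws
  on overlap with a bounded retry budget, then errors.
- **SpO2**: first-order (τ = 1.5 s) response to per-event steps of drawn
  depth (6 ± 1%), lagged 2 s and held 4 s past the event; noise is
  clipped at ±3 SD (pulse-oximeter-like bounded noise), keeping the
  event-free floor within 3 SD of baseline.
- **EEG/EMG**: per same-stage run, band-limited Gaussian noise in the
  stage's band with stage amplitudes 0.7/2.0/0.7 (W/NREM/REM) and EMG
  RMS 1.0/0.3/0.1.  Generation bands are inset ~10% inside the nominal
  analysis bands so filter roll-off keeps the emitted power where the
  stager integrates it.
- **Hypnogram**: semi-Markov bouts, exponential durations (means
  120/180/60 s), configurable transition weights, REM entered only from
  NREM, 5-s epoch grid.
- **CO2 challenge**: minute ventilation is scaled toward
  `1 + gain·CO2%/VE0` with a first-order transition (τ = 15 s), applied
  as per-breath amplitude scaling; the inspired-CO2 trace is emitted as
  its own channel.
- **Calorimetry**: outflow fractions are solved in closed form from the
  inert-gas balance so the Haldane equations recover the configured VO2
  (60 mL/h) and RER (0.85) exactly at the configured chamber flow;
  activity is a Poisson stream (2 breaks/min).

Determinism: one `numpy` generator seeded from `SynthConfig.seed` is
consumed in a fixed order (hypnogram, breath train, apneas, SpO2,
EEG/EMG, metabolic traces); identical configurations are bit-identical.

Default recording length is 600 s — long enough for several sleep-stage
cycles and ~1500 breaths while keeping a full pipeline run under a
second; overnight-scale sessions (hours) are supported by setting
`duration_s`.  The acceptance script uses 1-h recordings for event-rate
recovery, 20 seeds × 10 min for HCVR, and 400-s REM recordings (~1400
breaths) for classifier operating characteristics.

### What the synthetic benchmark does not show

The generator's breaths are smooth templates: real flow traces carry
movement artifacts, swallowing, baseline drift from chamber leaks, and
waveform families the template does not span.  Real EEG is nonstationary
within epochs, real scorers resolve transitional epochs contextually,
and real SpO2 artifacts (probe motion) can mimic desaturations.  Passing
the suite therefore demonstrates correctness of the scoring definitions
and recovery under the stated noise model — not field performance on
arbitrary recordings.  Thresholds (hysteresis multiple, τ, Z cutoff,
staging splits) are exposed precisely so they can be recalibrated against
manually scored data.

## Pipeline and reproducibility

`run_pipeline` executes synthesis-or-load → (optional) pressure
calibration → hypnogram (external file, else EEG/EMG staging) → breath
analysis → classification → event scoring → HCVR → calorimetry, writing
CSV tables plus JSON `summary`/`manifest`.  Every table begins with a
`# config_hash=<sha256 prefix>` comment; the hash covers all
analysis-relevant configuration (not the output path), and a rerun of the
same configuration is byte-identical.  Stage failures preserve partial
outputs and the manifest, and exit nonzero from the CLI.
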