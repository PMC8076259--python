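# Methods

This note documents the models, numerical choices and known limitations of
the `rodentsleep` pipeline: what each stage assumes, which parameters matter
and why their defaults are what they are, and what the synthetic-data
generator does and does not emulate.

## Recording model and preprocessing

A session is two channels (EEG, EMG) sampled at 250 Hz, starting at lights-on
(ZT0) and covering 12 h light + 11 h dark = 23 h (the last hour of the
nominal dark phase is reserved for husbandry and not recorded). The
acquisition chain is emulated by zero-phase 4th-order Butterworth band-passes
(EEG 0.1–100 Hz, EMG 1–100 Hz). Zero-phase (forward–backward) filtering is
used everywhere so that no stage introduces a state-dependent lag into
epoch-aligned features; the price is a doubled effective filter order, which
only deepens stopband rejection.

Downsampling to 125 Hz applies an 8th-order Butterworth low-pass at 0.8× the
target Nyquist (50 Hz) before taking every k-th sample; the decimation factor
must be an integer. Epoching cuts the signal into non-overlapping, contiguous
4 s windows from sample 0; a trailing partial epoch is discarded, and
concatenating the epochs reproduces the retained signal prefix exactly.

## Vigilance-state scoring

The scorer is deliberately minimal and fully inspectable — two features and
two thresholds per recording:

- **EMG RMS** per epoch separates WAKE (high muscle tone) from sleep;
- among low-EMG epochs, the **theta/delta power ratio** (θ 6–9 Hz over
  δ 1–5 Hz, from per-epoch periodograms) separates REMS (ratio > 1) from
  NREMS.

The EMG cut defaults to a two-cluster split of log EMG RMS (1-D k-means,
equivalent to Otsu's criterion for well-separated modes). A fixed percentile
(the conventional alternative, still available as `"p60"`) encodes an
assumed sleep/wake ratio and misclassifies systematically whenever the true
WAKE fraction differs from it — the dark-period WAKE fraction alone spans
roughly 50–85% across the two strains modeled here, so no single percentile
can be right for both. The cluster split is composition-free. If the two
cluster means differ by less than a factor of 2 the EMG distribution is
treated as unimodal and no epoch is called WAKE on EMG evidence alone; this
correctly handles sleep-only segments but means a recording consisting
*entirely* of WAKE cannot be recognized as such without an explicit numeric
threshold (there is no absolute µV scale to anchor to). Both thresholds are
overridable.

**Bout consolidation.** Scored sequences are rescored so that every maximal
run of identical states lasts at least `min_bout_epochs` = 3 epochs (12 s).
The absorption rule scans left to right: a run shorter than the floor takes
the state of the run before it in time (a sub-minimum run at the very start
takes the following run's state), and the scan restarts until a fixpoint.
This is deterministic, order-stable and idempotent, and changes only epochs
that belonged to sub-minimum runs. The floor is exposed because the
published description admits two readings ("longer than 3 epochs" vs "at
least 12 s"); 3 epochs (≥ 12 s) is the default, 4 is one parameter away.

## Sleep architecture

Bouts are the run-length encoding of the hypnogram and tile it exactly.
Phase attribution: a bout belongs to the phase containing its first epoch; a
transition belongs to the phase in which the second bout starts. Transition
percentages are fractions of the phase's transition total; all six ordered
pairs are reported, including W/R, which the generator never produces but
arbitrary hypnograms may contain.

Sleep latency uses the first-5-bout rule: the mean onset time (minutes from
lights-on, 4 s resolution) of the first five NREMS (or REMS) bouts lasting at
least 12 s. A single early transient bout therefore cannot dominate the
statistic, which is the point of the rule for fragmented rodent sleep. Fewer
than five qualifying bouts yields an explicit "insufficient" result rather
than a number. Dark-period REMS latency uses k = 1 (first bout) by default
since the corresponding published comparison describes the time to the first
dark REMS episode; k is a parameter.

State percentages are computed per 2 h bin (boundaries at ZT 0, 2, …, 22,
plus a final 1 h bin ending at ZT23) and per phase; each bin is normalized by
its own epoch count, so the three state percentages always sum to 100. Bins
that start after the hypnogram ends are dropped, which lets the same code
summarize partial recordings.

## Spectral analysis

At 0.25 Hz resolution a 4 s epoch of 500 samples (125 Hz) admits exactly one
Welch segment, so the per-epoch estimate is a single Hamming-windowed
periodogram (the window is the common default of the standard routine and is
configurable). Before the PSD a zero-phase 4th-order 1 Hz Butterworth
high-pass suppresses movement artifacts; it is applied per epoch.

Normalization divides each epoch's PSD by that epoch's total power over the
full one-sided grid (0–62.5 Hz), making spectra dimensionless, summing to 1,
and invariant to any positive rescaling of the signal. All-zero epochs are
flagged and excluded from aggregation. State/phase summaries are the median
and IQR per frequency bin over the epochs of that state and phase, reported
over 1–22.75 Hz. Group curves should aggregate per-animal medians (not
pooled epochs) so each animal contributes equally regardless of how much it
slept.

Band powers sum relative power over grid bins with both edges inclusive
(δ 1.0–5.0, θ 6.0–9.0, α 10.0–15.0, η 16.0–22.75 Hz); the gaps between bands
(5–6, 9–10, 15–16 Hz) are intentionally unassigned, so the four band powers
sum to less than 1.

High-frequency QC: an animal whose median NREMS η relative power falls below
0.5× the cohort median is flagged and excluded from spectral aggregation
only — architecture and spindle outputs keep every animal, mirroring how such
attenuation artifacts affect high frequencies without invalidating scoring
or sigma-band events.

## Spindle detection

The sigma filter is the minimum-order Butterworth band-pass (10–15 Hz
passband) achieving ≥ 24 dB at the 3 and 22 Hz stopband edges (the published
"24 dB/octave" figure corresponds to a 4th-order roll-off; the minimum-order
design meets it at both edges). The envelope is a centered 750 ms moving RMS,
truncated (not padded) at the recording edges, then cubed; cubing spreads the
envelope's dynamic range so that thresholds placed at small multiples of the
mean separate events from background cleanly.

Detection baseline = mean cubed RMS over NREMS samples (configurable to the
whole recording); lower threshold 1.0× and upper 2.5× that baseline. An
event is a maximal excursion above the lower threshold containing at least
one sample above the upper threshold; excursions closer than 0.1 s merge;
events must last 0.5–10 s and start inside a NREMS epoch (full containment is
available as an option). Because both thresholds are multiples of a
recording-derived baseline, detection is exactly invariant to rescaling the
EEG by any positive constant.

A centered 750 ms RMS window fundamentally blurs event boundaries by up to
±375 ms; onset accuracy below that scale depends on how fast a spindle's
envelope rises, which is why the synthetic bursts' taper matters (next
section).

## The synthetic generator

**Hypnograms.** Vigilance states follow a semi-Markov chain at 4 s epoch
resolution: geometric dwell times (mean = the profile's per-state mean bout
duration), an embedded bout-to-bout transition matrix, and separate parameter
sets for light and dark. Geometric dwells are the simplest process with a
controllable mean bout length, and their memorylessness makes the light→dark
switch clean: the per-epoch exit hazard simply changes at the boundary
mid-bout. WAKE→REMS transitions are structurally excluded (five transition
types occur in mouse hypnograms). Given target occupancies π and dwell means
m, the embedded chain's stationary frequencies are q ∝ π/m and the matrix is
solved in closed form; the construction is feasible only when q_N ≥ max(q_W,
q_R) and q_N ≤ ½ — both automatic consequences of NREMS's role as the hub
state — and infeasible parameter sets are rejected with the violated
condition. Long-run state fractions therefore converge to π exactly, which
the tests check against Monte-Carlo standard errors. A profile's
sleep-latency offset forces WAKE for its duration at lights-on before the
chain starts, emulating delayed sleep onset.

**Preset calibration.** The two presets encode the published strain
contrast at the level of per-phase occupancies and mean bout durations taken
from the published per-strain medians (state percentages, bout counts and
durations for each phase), e.g. dark-phase WAKE/NREMS/REMS occupancy
0.53/0.43/0.04 with mean bouts 6.4/3.4/0.6 min for the S1-like profile
versus 0.85/0.14/0.007 and 16.9/2.7/0.4 min for the BL6-like control.
Spindle rates are 5.3 vs 5.6 events per NREMS minute with mean durations
2.0 vs 1.8 s, and sleep-latency offsets 12 vs 0 min. Spectral weights give
NREMS delta dominance (weaker, with more theta, in the S1-like profile), a
REMS ~8 Hz peak (damped in the S1-like profile) and WAKE broadband activity.

**Signals.** Each bout's EEG is spectrally shaped Gaussian noise (FFT-domain
amplitude weighting: a 1/√f backbone times per-band weights, plus a Gaussian
8 Hz component for REMS), normalized to unit RMS; EMG is white noise with
state-ranked amplitude (WAKE > NREMS ≥ REMS). Amplitude units are arbitrary
throughout — the analyses are either ratio-based or normalized, and no µV
scale is modeled.

**Spindle ground truth.** Events form a renewal process inside NREMS bouts
(exponential gaps with a 0.3 s minimum, tuned so the expected count matches
the profile rate per NREMS minute; durations normal around the profile mean,
clipped to [0.5, 10] s and to the containing bout). Bursts are 11 Hz
sinusoids — the peak spindle frequency in mice — with RMS amplitude a
multiple (default 5×) of the recording's own NREMS sigma-band background
RMS, tapered by a Tukey window with 0.375 s ramps. The ramp length is half
the detector's RMS window by design: a crossing-based boundary on a smoothed
envelope sits where the rising taper meets the threshold, and a ramp matching
the smoother's half-width centres that crossing on the nominal onset. (A
full-Hann taper, by contrast, keeps the burst below detectable amplitude for
its first ~0.4 s and biases every detected onset late by about +0.2 s —
more than the 0.25 s at which onset agreement is assessed.)

**What the generator does not emulate.** Electrode drift, movement and
chewing artifacts, the 1 h daily recording gap, inter-animal variability in
absolute spectra beyond the preset weights, spindle frequency variability
(all bursts are 11 Hz), NREMS–REMS ultradian cycling beyond what the Markov
structure produces, and any behavioral correlation structure. Passing tests
on synthetic cohorts therefore demonstrate that the *pipeline* recovers the
structure it assumes, not that the scorer or detector would reach the same
accuracy on real, artifact-laden recordings.

## Statistics

**Mann–Whitney U.** U is reported as min(U_A, U_B) with mid-rank tie
handling. The exact two-tailed p is 2 × P(U′ ≤ U) under the tie-free null,
capped at 1, computed by the restricted-partition recursion
c(u; m, n) = c(u − n; m − 1, n) + c(u; m, n − 1) — the full enumeration of
all C(n_A+n_B, n_A) labelings — used whenever n_A + n_B ≤ 20 and the data are
tie-free. With ties, p comes from the permutation distribution of min-U
(exhaustive when feasible, seeded Monte Carlo otherwise); for larger samples
the normal approximation with tie correction and continuity correction is
used. No continuity correction is applied in the exact path.

**AUC effect size.** AUC = [#(b > a) + ½#(b = a)] / (n_A n_B), oriented as
P(group-B value > group-A value); in strain reports group A = S1-like,
group B = BL6-like, so AUC < 0.5 means the S1-like values tend larger. The
identity AUC ∈ {U, n_A n_B − U}/(n_A n_B) lets the effect size be
reconstructed from any reported U plus the direction of the medians. The 95%
CI is a percentile bootstrap over 10,000 replicates with the two groups
resampled independently; the seed is a required argument so intervals are
reproducible. An AUC whose CI excludes 0.5 is significant at the 5% level;
values above 0.7 or below 0.3 are conventionally a relevant effect.

**Mixed-design ANOVA.** Between-subjects factor strain, within-subjects
factor time (12 time points in the standard report: 2 h bins at hours 2–12
and 14–23). Sums of squares follow the standard mixed decomposition —
subjects-within-groups is the error term for strain; the subject × time
residual is the error term for time and the interaction; group sizes may
differ (time means are then subject-weighted). Degenerate zero-variance
designs return F = 0 (p = 1) when the effect is also zero and F = ∞ (p = 0)
otherwise, rather than 0/0. Post-hoc: per-time-point pooled-variance t tests
with Sidak adjustment p_adj = 1 − (1 − p)^m, m = number of time points.
Sphericity corrections (Greenhouse–Geisser etc.) are intentionally not
applied. QQ data are observed order statistics against standard normal
quantiles at plotting positions (i − ½)/n.

## Problem sizes used in validation

The test-suite and acceptance-script runs use: 1,000 random hypnograms for
the bout-consolidation contract; 10,000 random epochs for the normalization
invariants and white-noise flatness; a 20 min NREMS recording (~100 injected
bursts) for detector recovery; 100 cohort replicates of 8 + 7 synthetic
animals at full 23 h for the strain-contrast directions; an exhaustive U-null
sweep for all n_A + n_B ≤ 12; and 100 random balanced designs for the ANOVA
oracle. These sizes give Monte-Carlo errors comfortably below the margins
being tested while keeping a full validation run around a minute.

## Known limitations

- The scorer is a stand-in for interactive semi-automated scoring plus human
  review; on real data its two-feature rule would need artifact rejection
  and possibly per-animal threshold review.
- EDF files can be read (via mne) but not written; CSV is the round-trip
  format. No EDF writer is bundled.
- Exact tie-handling conventions of commercial statistics packages vary;
  the permutation path documents this package's convention (p = probability
  of a min-U at least as extreme under relabeling).
- The bootstrap resamples groups independently; resampling animals jointly
  is a defensible alternative the API does not currently expose.
- The dark-period REMS latency rule (k = 1 vs k = 5) and the spindle
  containment rule (start-only vs full) are parameters because the
  underlying conventions are ambiguous; defaults are documented above.
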