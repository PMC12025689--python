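# Methods

## Synthetic sessions

The generator produces the statistical structure the two protocols assume,
not physiologically detailed EEG.

**Background.** White noise is spectrally shaped to a 1/f power law (flat
below 1 Hz to keep the variance finite), mixed across channels with a fixed
weight (0.3) toward one shared component, and a common 10 Hz sinusoid at 0.3
relative RMS is added so the Alpha band has structure the fatigue ramp can
act on. Each channel is normalised to a configured RMS (default 10 µV).
Throughout the package `snr` means *peak deterministic amplitude divided by
background RMS*; it is a generator property, not an estimate.

**Passive protocol.** 200 trials at a 6 s pace. The error-trial count is
`round(n_trials × error_rate)` with half-up rounding, enforced exactly: a
fixed label multiset ("Pass" errors, remaining trials split evenly between
"Turn" and "Not") is shuffled under the seed. Per trial one key press is
drawn uniformly in seconds 2.5–4.5 of the trial (the protocol does not pin
response times; this is a convention), with a 100 ms press on the binary
event channel. Error trials add a two-Gaussian ErrP template — ERN at
0.10 s, −5 µV; Pe at 0.30 s, +5 µV; SD 0.04 s — to Fz, Cz and CPz with equal
gain; fronto-central is the standard ErrP locus.

**Active protocol.** Blocks of 4 s flicker + 2 s break; classes 12/15/20 Hz
plus rest, `trials_per_class` each (default 40), shuffled under the seed.
Attended blocks add the class sinusoid plus a half-amplitude second harmonic
(characteristic of SSVEP, and a genuine challenge for the narrowband bank)
to Oz/O1/O2/PO7/Iz with gains 1.0/0.8/0.8/0.6/0.6.

**Fatigue drift.** The Alpha (8–13 Hz) and Theta (4–8 Hz) components are
isolated with a zero-phase order-2 bandpass and re-added with amplitude
factor √g(t) − 1, where the *power* gain g(t) ramps linearly from 1 to the
configured end gain over the session.

**What is not emulated.** Eye blinks, EMG, electrode drift, volume
conduction, inter-subject variability. Passing tests therefore demonstrate
the correctness of the *algorithms* under the protocols' statistical
assumptions, not performance on real recordings: published per-subject
accuracies on real EEG are not reproducible from synthetic data and are not
targets of this package.

## Signal processing

All filters are Butterworth (order 2 unless stated), designed as
second-order sections. Zero-phase forward–backward filtering is the default
for offline analysis (no phase lag; attenuation doubled in dB); a causal
mode exists for real-time parity. Epoch windows are half-open
`[start, end)` with `round((end − start) × fs)` samples, removing
off-by-one ambiguity. Welch spectra use 1 s Hann segments with 50 % overlap
by default (one-sided density convention; both configurable — at 1 Hz
resolution an on-bin tone leaks into adjacent bins, so tests that localise
tones use 2 s segments). Band powers integrate the density over half-open
bands by the trapezoid rule with edges interpolated onto the grid, so flat
density integrates exactly to the band width and contiguous bands are
additive.

## ErrP classification

The 3.5–8.5 Hz ErrP bandwidth is realised in the stated operation order:
lowpass 8.5 Hz at 256 Hz → keep every 8th sample → highpass 3.5 Hz at 32 Hz
(no extra anti-alias filter is needed because the lowpass already
band-limits the signal). Features are the concatenated [−1, 1) s epoch
samples of Fz, Cz and CPz (3 × 64 = 192 features), standardised per feature
with training-fold statistics and a 10⁻¹² variance floor (a constant feature
maps to zero).

BLDA uses the regression formulation: targets +N/N₊ for error and −N/N₋ for
correct trials (class-balanced coding), posterior mean
`w = β(βXᵀX + αI′)⁻¹Xᵀy` with the bias column unpenalised. The fixed-point
evidence updates are

    γ = M − α · tr_pen(A⁻¹),   α ← γ / wᵀw,   β ← (N − γ) / ‖y − Xw‖²

with A = βXᵀX + αI′ and the trace over penalised coordinates only;
iteration stops when both precisions change by < 10⁻⁴ relative, with a
300-step cap (a non-converged fit is returned with a flag — on pure-noise
data α legitimately diverges toward the 10¹⁰ clip as the weights shrink to
zero). The log evidence is recorded per iteration and is non-decreasing in
practice (asserted to 10⁻⁶ tolerance).

Classification is binary (error vs both correct labels); the decision
threshold 0 under balanced target coding is the balanced decision rule, so
chance-level raw accuracy is 0.5 even though the class split is 80/20. Both
raw and balanced accuracy are reported. Cross-validation is stratified
5-fold with a fixed seed; the temporal chain is run once on the continuous
recording (it contains no cross-trial statistics), while standardisation
and fitting happen strictly inside training folds.

## SSVEP classification

Per flicker frequency f the bank holds an order-2 bandpass at f ± 0.25 Hz
(a broadband 5–30 Hz spec is kept for the rest condition). CSP solves
`C_A w = λ(C_A + C_B)w` on trace-normalised average class covariances; the
full eigenvector matrix is kept sorted by λ descending and exactly two
components (first and last) are retained. Features are raw variances of the
two retained components over the full 4 s block (the protocol gives no
shorter decision window); a log transform is deliberately not the default.

Multi-class fusion is one-vs-rest: for each frequency, CSP+LDA is trained
between that class and *all* other trials (other frequencies and rest).
The LDA bias keeps the log class-prior term, so score 0 is the Bayes
boundary under the 1-vs-3 training imbalance — this is what makes
background-only trials fall to the rest class rather than to a coin flip
among frequencies, and it leaves chance-level 4-class accuracy at 25 %.
Prediction is argmax over positive per-frequency scores, rest if none is
positive, ties toward the lowest frequency. Cross-validation is stratified
10-fold over blocks with all models refit per fold.

A degenerate pooled covariance is ridge-regularised by 10⁻⁸ × trace/channels
(logged). Inflating the narrowband margins is permitted (it only degrades
selectivity) and is used by the tests to demonstrate that the ±0.25 Hz bands
matter at low SNR; the selectivity comparison runs at snr = 0.1, the lowest
operating point at which the narrow bank is clearly above chance (below it
both banks sit at the floor and the comparison is uninformative).

## Workload indices

Cleaning is a 0.5–20 Hz zero-phase bandpass followed by average referencing.
ICA-based artifact removal is intentionally absent: the synthetic data
contain no ocular or muscle artifacts, so an ICA step would have nothing
testable to remove; the cleaning function is the hook where one would insert
it for real data. Epochs are [0, 5) s after each event trigger. Band powers
(Theta/Alpha/Beta per Table-style edges 4–8/8–13/13–30 Hz, half-open) are
averaged across Fz, Cz and Oz *before* forming the four indices —
powers-then-ratio, not ratio-then-average. Beta below 10⁻¹² is clamped and
the epoch flagged rather than dropped. "Beginning" and "end" of a session
are the first and last 20 % of epochs by default (the quantification is a
package decision; fractions up to 0.5 keep the segments disjoint).

Useful identities held to numerical precision: MFI × β = α + θ per epoch,
and all four indices are invariant under global amplitude scaling.

## Task-achievement model

Commands are modelled as independent with identical per-event accuracy p,
so a task needing m sequential correct commands succeeds with probability
pᵐ; percentages are rounded half-up to integers. The package reports the
passive single-event prediction as-is rather than guessing any further
adjustment. The Monte-Carlo twin draws m independent Bernoulli(p) variables
per task and reports the success fraction with its binomial standard error.

## Problem sizes and determinism

Default study conditions: 200-trial passive sessions (40 error trials) and
40-blocks-per-class active sessions. Statistical tests use these sizes where
the property demands them (chance bands, drift recovery over 40 seeded
runs) and smaller sessions (10–100 trials) where only mechanics are under
test. Every random quantity — generator, fold shuffling, Monte Carlo —
derives from an explicit integer seed; identical configs and seeds give
bit-identical sessions and reports.

## Known limitations

* Synthetic backgrounds are stationary Gaussian 1/f noise; real EEG is
  non-stationary and artifact-laden, so absolute accuracies here do not
  transfer to real recordings.
* The session container stores samples as float32; in-memory float64
  sessions round-trip to container precision (subsequent round trips are
  bit-identical).
* The one-vs-rest fusion is the minimal multi-class extension of binary
  CSP; pairwise fusion schemes are not implemented.
* Vendor EEG formats (EDF/BDF/BrainVision) are not read; `read_session` is
  the import hook to adapt.
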