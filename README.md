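# bciloop

Passive and active EEG brain–computer-interface pipelines for human-in-the-loop
robot navigation, built on a synthetic session generator so every stage is
testable end-to-end without access to recordings.

The package is aimed at BCI researchers and students who want a compact,
fully reproducible reference implementation of two classic paradigms:

* **Passive BCI (ErrP).** An observer watches a robot navigate; collisions
  elicit an error-related potential — a negative ERN deflection 50–200 ms
  after the event and a positive Pe at 200–500 ms, strongest fronto-centrally.
  A single correctly detected ErrP triggers autonomous obstacle avoidance.
* **Active BCI (SSVEP).** The user attends one of several squares flickering
  at 12/15/20 Hz; the attended frequency (and its harmonic) appears in the
  occipital EEG and is decoded into a navigation command. Avoiding one
  obstacle needs **three** sequential correct commands.

## What is implemented

* `bciloop.synthetic` — oddball sessions (8 channels at 256 Hz: Fz, Cz, CPz,
  Oz, PO7, O1, O2, Iz; 200 trials, 20 % error trials, binary "KeyDown" event
  channel), SSVEP block sessions (4 s flicker + 2 s break), 1/f background
  with a shared 10 Hz rhythm, and a linear Alpha/Theta power ramp emulating
  fatigue.
* `bciloop.dsp` — Butterworth design/application (zero-phase by default),
  integer decimation, event-locked `[start, end)` epoching, Welch spectra,
  trapezoid band powers.
* `bciloop.errp` — the ErrP chain (8.5 Hz lowpass → decimate 256→32 Hz →
  3.5 Hz highpass → [−1, 1) s epochs) and **Bayesian linear discriminant
  analysis**: regression targets +N/N₊, −N/N₋, posterior mean
  `w = β(βXᵀX + αI′)⁻¹Xᵀy` with an unpenalised bias, and α, β chosen by
  fixed-point evidence (log marginal likelihood) maximisation; evaluated by
  stratified 5-fold cross-validation.
* `bciloop.ssvep` — a ±0.25 Hz narrowband Butterworth bank, **common spatial
  patterns** via the generalized eigenproblem `C_A w = λ(C_A + C_B)w`
  (first + last filters retained), variance features, pooled-covariance LDA,
  one-vs-rest fusion with a rest-class fallback, 10-fold cross-validation.
* `bciloop.workload` — 0.5–20 Hz cleaning + average reference, 5 s epochs,
  Welch band powers on Fz/Cz/Oz and the spectral workload indices

  ```
  MFI = (α + θ)/β    θ/α    β/α    α-ratio = α/(α + β + θ)
  ```

  with start-vs-end session deltas.
* `bciloop.tasks` — task-achievement model: a task with m required commands
  at per-event accuracy p succeeds with probability pᵐ (passive m = 1,
  active m = 3), analytically and by Monte Carlo.

## Worked example

```python
from bciloop import SessionConfig, generate_errp_session, crossvalidate_errp
from bciloop import SSVEPConfig, generate_ssvep_session, crossvalidate_ssvep
from bciloop import ACTIVE, PASSIVE, expected_success

session = generate_errp_session(SessionConfig(n_trials=200, error_rate=0.2,
                                              snr=2.0, seed=42))
res = crossvalidate_errp(session, k=5, seed=42)
print(f"ErrP 5-fold accuracy: {res.mean_accuracy:.3f}")

ssvep = generate_ssvep_session(SSVEPConfig(trials_per_class=40, snr=0.3, seed=42))
print(f"SSVEP 10-fold accuracy: {crossvalidate_ssvep(ssvep, k=10, seed=42).mean_accuracy:.3f}")

print(f"passive task achievement at p=0.729: {expected_success(0.729, PASSIVE).percent}%")
print(f"active  task achievement at p=0.757: {expected_success(0.757, ACTIVE).percent}%")
```

prints

```
ErrP 5-fold accuracy: 0.820
SSVEP 10-fold accuracy: 0.963
passive task achievement at p=0.729: 73%
active  task achievement at p=0.757: 43%
```

At an ErrP peak twice the background RMS the passive classifier decodes 82 %
of events; a modest flicker response (0.3× background RMS) already supports
96 % frequency recognition; and the task model shows the structural trade-off:
a subject with *lower* per-event accuracy (72.9 %) achieves a *higher* task
rate passively (single event) than a subject with 75.7 % does actively, where
three sequential correct commands compound to 43 %.

The same stages are available as shell verbs:

```bash
bciloop simulate-errp --n-trials 200 --snr 2 --seed 42 --out sess/
bciloop run-errp --session sess/ --folds 5 --seed 42 --report errp.json
bciloop workload --session sess/ --report workload.json
bciloop task-eval --event-accuracy 75.7 --mode active
```

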