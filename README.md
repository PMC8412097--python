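# respfatigue

Detecting respiratory-muscle fatigue from surface electromyograms (sEMG)
that are contaminated by the heart's electrical activity.

Respiratory sEMG — recorded over the diaphragm or intercostal muscles, for
example while weaning a patient from mechanical ventilation — carries a
spectral signature of neuromuscular fatigue: the power spectrum compresses
toward low frequencies as the muscle tires. The signal is, however, buried
under cardiogenic artifacts (ECG), and naive artifact removal destroys the
very spectral features fatigue detection relies on. This package implements
a complete, testable processing chain for that problem, aimed at biomedical
signal-processing researchers and engineers selecting algorithms for
respiratory sEMG monitoring:

- **Synthetic test benches** with a known ground truth: surrogate sEMG whose
  mean frequency declines on a programmed trajectory, breathing-pattern
  modulation, and a two-lead surrogate ECG whose beat shape varies with a
  simulated lung volume, mixed at a controlled EMG level
  η = RMS(sEMG) / QRS peak-to-peak (small η ⇒ heavy contamination).
- **Artifact removal**: high-pass only (HP15/HP35); template subtraction
  with a beat-averaged heart-cycle template (TS15/TS35), optionally
  wavelet-denoised (TSW15/TSW35); the two-step **TSWD** method — template
  subtraction followed by a heart-phase-synchronous multiplicative damping
  of stationary-wavelet coefficients — and the damping step alone (DSO).
  Each combines with QRS gating (GN = ignore mask, GO = omit gated samples).
- **Fatigue indexes** at 8 Hz: mean frequency (MNF), the spectral moments
  ratio of order five (SMR5 = M(−1)/M(5), with M(k) = Σ fᵏ·P(f) above a
  lower bound b_l), and fuzzy approximate entropy (fApEn); Welch or Burg
  PSD estimation; moving-average smoothing to 1 s information content; and
  normalization against the linear trend G₆₀(t) of the uncontaminated
  60 %-MVC reference so its trend runs from 0 at t = 0 s to 1 at t = 60 s:
  Φ̂(t) = (Φ(t) − G₆₀(0)) / (G₆₀(60) − G₆₀(0)).
- **Evaluation criteria**: γA = RMS deviation from the reference fatigue
  trajectory; γB = two-sample Kolmogorov–Smirnov separability of the 20 %
  vs 60 % MVC fatigue values over the last 15 s; γC = R² of the trajectory's
  line fit. A Friedman/Holm harness compares chain variants across seeds.

## Worked example

`examples/05_evaluate_chain.py` synthesizes a 60 s bench at η = 0.05,
scores several removal methods with SMR5 (Burg PSD, N_e = 256, b_l = 35 Hz)
and prints:

```
method   gating   gammaA   gammaB   gammaC
NONE     GN      0.8247   0.708    0.240
HP15     GN      0.5906   0.758    0.361
TSW15    GN      0.0690   1.000    0.770
TSW15    GO      0.1480   0.900    0.656
TSWD15   GN      0.0354   1.000    0.777
DSO      GN      0.1624   0.975    0.635
```

Without artifact treatment the fatigue trajectory deviates strongly from
the reference (γA ≈ 0.82 in normalized-index units) and is badly disturbed
(γC ≈ 0.24). Template subtraction recovers most of it; the additional
damping step (TSWD15) halves the remaining deviation again while keeping
the 20 %/60 % MVC load cases fully separable (γB = 1.0) — without gating
out the QRS segments. The other examples walk through test-signal
construction, QRS detection, residual-artifact measurement and the raw
fatigue indexes, each printing what the numbers mean.

A thin CLI mirrors the stages (`respfatigue synth | qrs | remove | fatigue
| evaluate | pipeline`); run any subcommand with `--help`.

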