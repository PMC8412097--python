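# Methods

This note documents the models, numerical choices and known limitations of
the `respfatigue` processing chain. Conventions throughout: amplitudes in
μV, time in seconds, sample indices 0-based, intervals half-open
[start, end), causal Butterworth filters in the signal path (a zero-phase
option exists for offline analysis), and every stochastic operation takes
an explicit integer seed — there is no global random state.

## Synthetic test signals

The bench is built so that the *expected fatigue result is known by
construction*; it does not aim at physiological realism beyond the two
properties that matter for the problem: beat-to-beat shape variation of
the cardiac artifact, and sEMG with a known fatigue trajectory.

**Breathing modulation MSM(t).** Period 4 s (1 s inspiration at activity 1,
3 s expiration at activity 0.3, i.e. 15 breaths/min), with raised-cosine
ramps of 0.1 s at the phase changes. The ramp shape is a design choice —
only "smooth" transitions are required — picked for C¹ continuity and a
band-limited spectrum; the ramp duration is configurable.

**Lung-volume weighting WSC(t).** Raised-cosine ascent over the first
0.5 s of inspiration to a plateau of 1, exponential decay with time
constant 1.5 s during expiration, periodic and continuous. Qualitative
target: steep inspiratory ascent, slower decay-like descent. Both
parameters are configurable; the exact analytic form is a stand-in for a
quantity that is only described qualitatively.

**ECG preprocessing and mixing.** Each lead is smoothed with a piecewise
Savitzky–Golay filter: order 5/length 15 inside the QRS vicinity
([−0.05, +0.1) s around each beat, hard switch at the window boundaries),
order 3/length 25 elsewhere. The mixed channel A is the per-sample convex
combination (1 − WSC)·lead I + WSC·lead II, which couples beat morphology
to the breathing phase and thereby raises beat-to-beat irregularity — the
stressor that plain template subtraction cannot absorb.

**Contamination.** ATS = ECG + g·EMG_mod with g = η·QRS_pp / RMS(EMG),
where QRS_pp is the median per-beat peak-to-peak amplitude of lead I inside
the QRS window (median for robustness to outlier beats) and the RMS is
taken over the *unmodulated* sEMG record. Reference signals use the η = 0.2
scale with no ECG added: RSM (modulated; the normalization reference) and
RS (unmodulated).

**Surrogate sources.** The sEMG generator filters white Gaussian noise
frame-wise (0.5 s Hann frames, 50 % overlap-add) with a Gaussian band
(σ = 40 Hz) centered on the instantaneous target mean frequency. Study
conditions, fixed once: the fatiguing 60 %-MVC record declines linearly
130 → 85 Hz over 60 s (a ~35 % MNF drop, typical of a strong sustained
contraction), the non-fatiguing 20 %-MVC record stays at 115 Hz, RMS 50 μV.
The ECG generator sums Gaussian bumps for P, Q, R, S, T (lead I R ≈ 1 mV,
lead II larger R/T), at 72 bpm with RR jitter (fraction 0.05) and per-beat
amplitude/width perturbations shared between leads (fraction 0.10 by
default). What the surrogates do *not* emulate: motion artifacts,
inter-muscular crosstalk, non-sinus rhythms, nonstationary breathing, or
the detailed autocorrelation of real interference-pattern EMG — passing
tests therefore demonstrate correctness of the chain under the stated
model, not clinical performance.

## QRS detection

Structural-intensity style: the signal is low-pass filtered at 28
log-spaced cut-offs between 8 and 45 Hz; at each scale the rectified second
derivative (curvature) is computed, zero-phase so extrema stay aligned
across scales. Extrema are linked across adjacent scales
(nearest-neighbour within 50 ms) into lines; a line's evidence is its
persistence-weighted amplitude. Peaks above half the maximum evidence are
beats, with a 0.25 s refractory rule (strongest first). Rectification makes
detection polarity-invariant; the relative threshold makes it
amplitude-scale-invariant. The original multiscale scheme's exact scale
schedule and scoring function are not recoverable from the available
description, so this detector is *inspired by* that construction, not a
certified reproduction; it sits behind a narrow interface
(`detect_qrs(x, DetectorConfig())` → `QrsAnnotation`) so any detector can
be substituted, and the generators return ground-truth annotations for
experiments where detection quality is not itself under test. Beat times
are then refined by cross-correlating each beat's ±0.1 s segment against
the running average beat within ±25 ms; refinement never reorders beats,
and flat segments or single beats are left untouched. On the surrogate
bench at η ≤ 0.1 the detector holds sensitivity and positive predictivity
above 95 % (typically 100 %) with median timing error ~1 ms.

## Artifact removal

**Template subtraction (TS/TSW).** Work happens at 2048 Hz (linear-
interpolation upsampling; placement precision is the motive) and returns
to 1024 Hz through a polyphase anti-alias decimator. Heart cycles are
segments starting 0.3 s before each beat, one mean RR long. The template
for beat k is the causal running mean of all previous cycles (beat 0 uses
its own segment) — the adaptive-noise-cancellation framing; a global-mean
variant is available. Each template is Savitzky–Golay smoothed (order 6,
length 25), optionally wavelet-denoised (below), trapezoid-tapered (0.1 s
rise, 0.2 s fall) and subtracted in place; overlapping placements sum, and
beats whose segment would cross a record edge are skipped. A third-order
Butterworth high-pass (15 or 35 Hz) follows. On a perfectly regular
surrogate ECG the residual inside complete cycles is < 2 % RMS (the
Savitzky–Golay smoothing error).

**Template denoising (TSW).** Six-level stationary wavelet transform
(Daubechies-5): levels 1–3 zeroed; in levels 4–6 coefficients are zeroed
where the local RMS (25-sample sliding window) is below the level median,
shrunk linearly between the median and twice the median, kept above; a
range zeroed at a coarse level is zeroed at all finer levels. Decisions
are per-sample (the linear shrink zone already provides the smooth
transition, so no run-length hysteresis is added).

**Wavelet damping (TSWD/DSO).** Eight-level stationary wavelet transform
of the (template-subtracted, for TSWD) signal. Per level i, the rectified
coefficients of every complete heart cycle — cycle = [beat−0.3 s,
next beat−0.3 s), linearly resampled to a common grid of round(mean RR·fs)
points — are averaged into the profile wARCA_i(τ_c). With m_τ = median of
the profile and threshold θ_i = (1 + (8 − i)/16)·m_τ, the damping factor is
1 where the profile stays below θ_i and m_τ/wARCA (clipped to (0, 1])
above: coefficients are attenuated toward the baseline level, not hard-
thresholded, and the higher threshold at fine levels protects the
frequency range fatigue indexes live in. The median makes m_τ insensitive
to the artifact itself as long as the artifact occupies a small fraction
of the cycle. Factors are mapped back per cycle by nearest grid point and
multiplied in; samples outside complete cycles and the approximation level
pass through unchanged; a flat profile (no residual artifact) damps
nothing. DSO applies this damping directly to the raw input with no
template subtraction and no post high-pass. The formula for the damping
factor above threshold admits a constant-m_τ reading in the source
material; the ratio reading was chosen because it is continuous at the
threshold and monotone in the artifact strength.

**Gating.** Mask true on [beat − 0.05 s, beat + 0.1 s); always computed,
consumed downstream only under strategy GO.

## Fatigue detection

One value every 0.125 s (8 Hz) from the N_e most recent samples
(N_e ∈ {128, 256, 512, 1024} at 1024 Hz). Under GO the epoch takes the N_e
most recent *ungated* samples, concatenated across gaps; if fewer exist the
value is missing (NaN) and missing values propagate through smoothing
(excluded from each mean) and are dropped, with renormalization, from the
evaluation integrals. Welch PSD uses Hann windows at 50 % overlap with the
subsegment length chosen as the largest that yields exactly k_w segments;
Burg uses an AR fit of order 10 (configurable; sEMG spectra are smooth and
unimodal, so a moderate order suffices) after linear detrending, evaluated
on the epoch-length rFFT grid. Epochs are mean-removed before spectral
estimation. MNF and SMR5 integrate above the lower bound b_l
(default 35 Hz) up to Nyquist; SMR5 = M(−1)/M(5) excludes the f = 0 bin.
fApEn uses embedding m = 2, tolerance r = 0.25·SD, membership
exp(−(d/r)²) on mean-removed Chebyshev template distances, with low-
frequency exclusion delegated to the removal stage's high-pass corner
(15 vs 35 Hz) rather than b_l; a zero-variance epoch returns 0.
Moving-average smoothing uses k = (1 s − L_e)/0.125 s + 1 values (8, 7, 5,
1), causal. Normalization fits an ordinary least-squares line G₆₀ to the
raw 60 %-MVC reference series (gating GN) over 0 < t < 60 s and maps every
series through (Φ − G₆₀(0))/(G₆₀(60) − G₆₀(0)); degeneracy (flat
reference) is judged relative to the index's native scale, since SMR5
lives around 10⁻¹² and MNF around 10².

## Evaluation

γA is the discrete RMS of the difference of normalized series over
(0, 60] s; γB the two-sample KS statistic on values from (45, 60] s
(cross-checked in tests against an exhaustive-threshold oracle); γC the
OLS R² (the standard with-intercept definition, hence within [0, 1]) over
(0, 60) s. The residual QRS fraction — per-beat RMS of the artifact
remaining inside QRS windows relative to the artifact before removal,
averaged over beats, using the generator's ground-truth EMG component —
is this package's own operationalization; the published quantity of the
same name is defined in supplementary material that is not available, so
the metric here is labelled non-certified and is used only for
direction-of-effect statements. The comparison harness runs a Friedman
test (mid-rank ties), selects the best group by rank sum (γA: lower
better; γB, γC: higher better) and compares it 1-to-N with Wilcoxon
signed-rank tests under Holm adjustment at α = 0.05.

## Problem sizes and determinism

The bench default is 60 s records at 1024 Hz (η grid
{0.01, 0.02, 0.05, 0.1, 0.2} available; single-η benches used in most
tests), which is the full duration the evaluation criteria are defined on;
stochastic checks use 5–10 seeds. Seeds are split into per-source child
seeds through `numpy.random.SeedSequence`, and identical configurations
reproduce results bit-for-bit (a hash of the configuration is recorded in
every pipeline row).

## Known limitations

- The detector and the residual-fraction metric are package-own
  constructions where the source description is incomplete (see above).
- Surrogate realism limits are listed under *Synthetic test signals*; in
  particular, conclusions about chain rankings transfer to real recordings
  only to the extent that residual-artifact structure, not sEMG
  autocorrelation detail, drives the ranking.
- Non-sinus rhythms (ectopic/premature beats) are out of scope; the
  template and damping stages assume a roughly periodic artifact.
- The 1024 Hz gate windows (0.05/0.1 s) are not integer sample counts, so
  gated time is exact only at rates where they are (e.g. 1000 Hz); at
  1024 Hz the rounding error is below one sample per beat.
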