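# Methods

This note documents the models, parameter choices, and numerical decisions
behind `oddballv1`, and what the synthetic-data tests do and do not show
about recorded data.

## Stimuli and trial sequences

Stimulus frames are white noise bandpass-filtered in the 2-D Fourier plane
with an isotropic Butterworth magnitude response of order 10, expressed in
cycles/degree via a small-angle pixel↔degree mapping (default: 22-inch
monitor, 47.6 cm wide, 1680 px, 17 cm viewing distance → 0.0955 deg/px).
Six octave-wide bands centered at 0.0075–0.24 cpd tile the range without
overlap (edges at center/√2 and center·√2; band edges are a package
convention — only the centers are canonical).  The filter cutoffs are
inset from the nominal edges by a factor 1.15 so the half-power skirts of
the order-10 response fall inside the band; with cutoffs at the edges
about 10–20% of the output energy would sit just outside.  Filtered
frames are z-scored, mapped so ±3 SD spans [0, 1] (mean luminance 0.5),
and clipped.

Sequence rules: tuning — 6 bands × 20 repeats, uniform shuffle, onsets ≥
stimulus (0.5 s) + 4 s apart with up to 0.5 s jitter, fresh noise seed per
trial; oddball — 200 trials, 12.5% deviants drawn without replacement from
slots 2..n and rejected if adjacent (so every DEV has a preceding STD,
which the pre-DEV trial-matching rule requires), frozen STD texture, fresh
DEV texture, onset gaps 0.5 + 0.5 + U(0.5, 1.2) s; omission — fixed
2.2 s period, every eighth slot withheld.  A full session is ≤ 520 trials.

## Generative model (synthetic sessions)

Each simulated unit has a baseline rate R₀, a DoG tuning profile (or a
flat SF-independent evoked rate for "untuned-by-construction" units), an
adaptation strength a ∈ [0, 1] with an octave-domain spread σₐ, a mismatch
boost b ≥ 0, and an omission motif ∈ {early, mid, late, inhibited, none}.
The evoked rate is piecewise-constant: an early amplitude E on 0.05–0.2 s
and a late amplitude L = late_frac·E (default 0.4) on 0.2–0.5 s.

The rate model is chosen so the analysis-side indices equal planted values
in expectation.  With planted adaptation index
s = a·exp(−Δoct²/2σₐ²) (Δoct = |log₂(pref/0.03)|), oddball responses are
scaled by (1−s)/(1+s), giving iSSA = s exactly at steady state; the factor
relaxes from 1 with a two-trial time constant, so only the first few
trials deviate.  Deviant late windows are scaled by (1+b), giving
iMM = b/(2+b).  Spikes are drawn from the exact inhomogeneous Poisson
process implied by this rate (per-window Poisson counts with uniform
times; Gaussian-bump motif times), which has the same law as fine-grained
binned thinning but is much faster.  Omission motifs are Gaussian rate
bumps at 0.12/0.27/0.42 s (SD 60 ms); the inhibited motif thins baseline
spikes in 0.05–0.45 s.

LFP: per-channel 1/f noise (SD 50 µV) plus a global 6 Hz theta component,
with a biphasic evoked kernel (peak negativity ~30 ms) whose amplitude is
a Gaussian of depth (SD 120 µm) centered on the planted L4 depth (420 µm),
scaled 1.0/0.6/0.8 for CTR-like/STD/DEV trials.  Templates are asymmetric
trough-dominant waveforms with class-specific trough-to-peak (RS 0.7 ms,
FS 0.3 ms) and trough half-depth width (RS ~1.6 ms, FS ~0.8 ms).

Two regimes encode the population structure under study.  Defaults
(illustrative, not fitted — no quantitative generative effect sizes are
available): **wt** — adaptation spread σₐ = 2.0 ± 0.3 octaves; mismatch
boost concentrated superficially (mean b: L2/3 1.2, L4 and L5/6 0.3).
**fx** — σₐ = 0.7 ± 0.15 octaves (adaptation confined near the oddball
SF); uniform mean b = 1.0 across layers (hence stronger L4 mismatch); an
extra 1.6× late-window gain at SF ≥ 0.12 cpd; stronger mid/inhibited and
weaker early omission motifs.  Effect sizes were set so the planted
contrasts are detectable at the 200-units-per-regime scale used by the
end-to-end test; both regimes share everything else (20% FS, 22% SF-flat
units, 5% unresponsive, depths uniform over 20–950 µm).

**Planted-index recovery** uses a dedicated harness
(`synth.recovery_experiment`): all units tuned within about an octave of
the oddball SF, low baselines (0.5–2 Hz), moderate adaptation (0.2–0.7),
larger late fraction, and extended blocks (40 tuning repeats/band, 400
oddball trials).  Under the default study-condition regimes many units
simply do not respond at 0.03 cpd, so their planted index is not
identifiable from an oddball experiment of any length; the recovery claim
(regression slope 1 ± 0.1) is about estimator correctness where the
estimand is defined, not about every unit in a session.

## Analysis choices

- **LFP**: anti-aliased polyphase decimation to 1 kHz; 60 Hz removed with
  a symmetric linear-phase FIR notch (2001 taps, 59–61 Hz stopband)
  applied centered, so there is no group delay.  L4 = channel with the
  most negative trial-averaged deflection 0–100 ms post-onset; ties go to
  the shallower contact.  VEP metrics: peak negativity 0.05–0.5 s and mean
  0.2–0.5 s after subtracting the pre-onset mean.
- **TFR**: 40 complex Morlet wavelets, centers log-spaced 2–80 Hz, cycles
  log-interpolated 3→10, applied to the trial-averaged trace (epochs
  −1.0–1.5 s so the 2 Hz/3-cycle wavelet fits), reflection-padded; power
  dB-normalized to the −0.3–0 s baseline; band means over 0.05–0.5 s in
  theta/alpha/beta/low-gamma/high-gamma.  (Five bands are defined; the
  band list is config.)
- **PSTH**: 10 ms bins, Gaussian kernel of FWHM 100 ms (σ ≈ 42.5 ms;
  "width" is not operationally defined elsewhere, FWHM is this package's
  reading).  z-score uses the pre-stimulus epoch; a zero baseline SD is
  floored at the rate equivalent of one spike per baseline epoch.
- **Responsiveness**: Wilcoxon signed-rank on per-trial counts, −0.25–0.05
  vs 0.05–0.35 s, α = 0.05, ≥ 10 trials.  Oddball indices are computed
  for excited units only.
- **DoG fit**: bounded least squares (widths [0, 1] cpd, other parameters
  [0, 2·max rate]) from the canonical all-0.01 init plus 9 deterministic
  jittered restarts, with an analytic Jacobian.  The curve is normalized
  by its max before fitting and amplitudes rescaled afterwards: the raw
  absolute init/bounds would make the over-parameterized fit
  scale-sensitive, whereas normalization makes preferred SF and Q exactly
  invariant under rate scaling.  fit error = SS_res/SS_tot (∞ for a flat
  curve); preferred SF = argmax of the fitted curve on a dense log grid
  over 0.00375–0.48 cpd; Q = SF_peak/(SF_high − SF_low) with half-maximum
  cutoffs of the baseline-subtracted fitted curve found by bracketing +
  Brent root-finding, undefined (and excluded from Q statistics) when a
  crossing is not bracketed in [0.001, 1] cpd.  **Identifiability caveat**:
  seven parameters interpolate six points, so distinct parameter sets can
  share the sampled values while peaking at different off-sample SFs;
  preferred-SF recovery is therefore guaranteed statistically (median
  error ≤ 0.5 octave over a population) rather than per curve, and the
  "untuned" class (failed fit or error > 0.9) is much rarer here than
  with a fragile single-start optimizer, because the multi-start fit
  almost always finds an interpolant.
- **Indices**: baseline correction uses the −0.25–0.05 s epoch; rows with
  |denominator| < 0.1 Hz are flagged and excluded from index statistics
  (baseline-corrected rates can be negative, making raw ratios
  unbounded).  The iMM late window is 0.2–0.5 s (config).
- **Omission clustering**: input is the z-scored trial-averaged omission
  trace resampled to 45 bins over 0.05–0.5 s, pooled across genotypes
  before any genotype information is used.  k-means is initialized
  deterministically: Ward linkage on the first k PCA scores, initial
  centers = group means — labels depend only on the input, never on a
  seed.  The cluster count maximizes the curvature of the log-inertia
  curve in the kneedle sense (largest vertical deviation from the chord
  joining its endpoints over k = 1..10); a plain second-difference rule
  was rejected because it peaks at the first dominant split rather than
  the slope-change point.  A maximum deviation below 0.1 log units is
  flagged low-confidence and falls back to k = 1.  Cluster ids are
  ordered by peak latency of the cluster means with the negative-mean
  cluster last.  Both inertia (within-cluster SS) and distortion (mean
  nearest-centroid distance) curves are reported; selection uses inertia.
- **Decoding**: shrinkage-regularized LDA (lsqr solver, Ledoit-Wolf
  shrinkage — necessary because pseudo-populations can have more units
  than the 120 tuning trials), stratified 4-fold CV × 5 repeats, the same
  fold seeds across windows so window comparisons are paired; chance for
  six balanced classes is 1 − 1/6.
- **Statistics**: two-sided non-parametric tests via scipy (Mann-Whitney
  with tie correction, exact for small tie-free samples; Wilcoxon with
  zero-differences dropped, p = 1 if all differences are zero; KS
  two-sample).  BH adjustment is applied within an explicit comparison
  family (one family per test type per contrast table), never inferred.

## What the synthetic tests do and do not show

The generator produces Poisson-dispersed spikes with piecewise-constant
evoked rates, stationary baselines, and independent units.  Passing tests
demonstrate that the analysis recovers planted structure under these
conditions — correct windows, trial selection, index algebra, clustering
and decoding machinery.  They do not establish robustness to properties
of real recordings the generator omits: spike-sorting errors, bursting
and refractory structure, rate non-stationarity, correlated noise across
units, eye movements or behavioral state, and non-Poisson count
dispersion.  Layer boundaries (L2/3 < 350 µm ≤ L4 < 500 µm ≤ L5/6) are
config defaults, not measured values.

## Problem sizes

Default scales were chosen to exercise the full design while staying
light: unit tests use short blocks (3–5 tuning repeats, 24–200 oddball/
omission trials, 2–64 channels); the recovery experiment uses 300 units;
the end-to-end experiment uses the full 520-trial layout with 200 units
per regime; clustering validation uses 160 traces (40 per motif).
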