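# Methods

## Signal model and frame geometry

The unit of analysis is one polysomnographic scoring epoch: a 30 s window of
m EEG channels sampled at a common rate Fs, carrying one sleep-stage label
from {S0 (wake), S1, S2, S3, S4, REM}.  At the reference settings (Fs =
512 Hz, m = 4, channels F4-C4, C4-P4, P4-O2, C4-A1) an epoch is an
X ∈ R^{15360×4} matrix.  Recordings are amplitude-normalized by dividing out
the acquisition gain (32.76 for CAP exports) before segmentation; trailing
partial windows are discarded; epochs whose annotation is not one of the six
recognized stages (movement time, unscored) are dropped with a warning.
Annotation epoch k maps to signal window k, both 0-based, with a configurable
offset — the alignment is an assumption of this package, and the offset
exists precisely because annotation conventions vary between exports.
Recordings at a different rate than configured are rejected rather than
resampled, so the rhythm-edge geometry below is never silently distorted.

## Fixed-boundary empirical wavelet filter bank

The empirical wavelet transform (EWT) builds a Littlewood–Paley/Meyer wavelet
filter bank whose band edges sit at boundary points ω_t of the spectrum.
Adaptive variants detect the ω_t from spectral maxima; this package pins them
at the EEG rhythm edges F = (4, 8, 13, 30, 75) Hz via ω_t = 2πF_t/Fs, with
ω_0 = 0 and ω_Ns = π.  Fixing the boundaries makes the bank a pure function
of (F, Fs, N): it is identical for every epoch and every channel, which is
what makes entropies comparable across epochs.

The multivariate construction is defined through the projection of all
channels onto a direction vector before boundary analysis.  Both weight
conventions are implemented — literal 1/m (the default) and unit-norm 1/√m
(the unit-sphere normalization Σv² = 1) — because the two appear in the
multivariate-decomposition literature interchangeably.  With fixed
boundaries the projection has no downstream effect on the bank; it is kept
because it defines the composite signal the construction derives from, and
because an adaptive-boundary extension would act on it.

Filter t is flat (= 1) inside [ω_{t−1} + η_{t−1}, ω_t − η_t] and transitions
over [ω_t − η_t, ω_t + η_t] using the C³ polynomial
g(z) = 35z⁴ − 84z⁵ + 70z⁶ − 20z⁷: the scaling (low-pass) filter falls as
cos(π g/2), each wavelet filter rises as sin(π g/2) at its lower edge and
falls as cos(π g/2) at its upper edge, with matched η at the shared boundary
so cos² + sin² = 1 inside every transition.  The last band has no upper
transition and extends flat to Nyquist (π).  Half-widths are η_t = α·ω_t;
the bank is a tight frame iff neighbouring transitions do not overlap,
α < min_t (ω_{t+1} − ω_t)/(ω_{t+1} + ω_t), and `alpha="auto"` (default)
takes half that bound — α ≈ 0.119 at the reference edges.  An inadmissible
α raises an error naming the offending boundary pair.

Filters are sampled on the two-sided DFT grid of length N through |ω|, so
each response is symmetric about DC.  Mode t of channel c is
Re{IDFT(DFT(x_c)·conj(H_t))}; with real filters and real input the inverse
DFT is already real to machine precision, and the real part only strips
floating-point residue (asserted < 1e−9 of the signal norm in tests).
Synthesis uses the same filters — the tight-frame (partition-of-unity)
property Σ_t H_t(ω)² = 1, verified to < 1e−12 across the full grid, makes
analysis–synthesis exact to ~1e−16 relative error, and mode energies sum to
the signal energy (Parseval).

## Entropy features

**Dispersion entropy (DE).**  The sub-band signal is mapped through the
normal CDF with its own sample mean and standard deviation (population
normalization, ddof = 0); a constant signal maps to 0.5 by convention so
degenerate sub-bands yield DE = 0 rather than NaN.  Levels are assigned by
z = round(a·y + 0.5) with half-away-from-zero rounding (banker's rounding
would make level assignment platform- and value-dependent at exact halves),
clipped to [1, a].  Delay vectors of length L at delay d (N − (L−1)d of
them) define dispersion patterns; DE is the Shannon entropy (natural log) of
the pattern distribution, bounded by [0, L·ln a] and invariant to positive
affine rescaling of the input.  Defaults L = 10, d = 1, a = 2: with a = 2
the pattern space has 2^10 = 1024 cells against ~15k embedding vectors, so
the distribution is well sampled; larger a at L = 10 would undersample
badly.

**Bubble entropy (BE).**  Delay vectors of the raw sub-band are scored by
the number of bubble-sort exchanges needed to sort them ascending — their
inversion count.  A pair of equal values is *not* an inversion (a stable
ascending sort performs no swap); this tie convention is documented and
tested because it determines behaviour on quantized or constant data.  The
swap counts at embedding dimension k are histogrammed over one bin per
achievable count 0..k(k−1)/2 (empty bins carry zero probability and do not
affect the statistic), and the histogram is summarized by the order-2 Rényi
entropy E_k = −ln Σ_b P(b)².  BE = (E_{L+1} − E_L)/ln((L+1)/(L−1)), with
L = 10, d = 1 by default (the delay is a package choice; d = 1 matches the
DE convention).  BE depends only on the ranks of the samples, hence is
invariant to any strictly increasing transform.  Natural logarithms are used
throughout; since BE is a ratio of entropy differences it is base-invariant
anyway.

**Feature vector.**  DE and BE are computed for the five rhythm sub-bands
(δ..γ) of each channel — the residual high band (75 Hz–Nyquist) is excluded
by default, since the rhythms of interest end at γ, but a flag
(`bands=(0,..,5)`) includes it.  Ordering is the DE block then the BE block,
each channel-major then band, giving 2·m·5 = 40 features for 4 channels.

## Hybrid classifier

Training feature vectors are z-scored per feature with training-set
statistics (applied identically to test vectors).  This is a package design
choice: the decision rule sums a reconstruction residual and a Euclidean
distance, and that fusion presumes commensurate scales; without
standardization the largest-variance feature silently dominates both terms.

The standardized training matrix, partitioned by class, forms the dictionary
(atoms = instances, as columns).  One combined sparse code α over the
*concatenated* dictionary is computed by orthogonal matching pursuit:
greedily select the atom of maximal absolute correlation with the current
residual (correlations on norm-1 atoms), refit all selected coefficients by
least squares on the raw atoms, stop at ρ atoms or residual < 1e−12.
A rank-deficient selected set falls back to minimum-norm least squares with
a logged warning.  The per-class residual uses only that class's slice of
α: Res_e = ‖f − F^e α_e‖₂ (raw atoms — the residual definition operates on
the dictionary as stored, normalization is internal to atom selection).
Independently D_e = median of the nn smallest Euclidean distances from f to
class e's instances.  Prediction is argmin_e (Res_e + D_e), ties broken
toward the earliest class (wake-first order) and logged.  ρ defaults to 20
and nn to 10; ρ larger than the dictionary is capped with a warning, and a
class with fewer than nn training instances is rejected at fit time.

**Evaluation.**  Five stage-merging schemes: wake/sleep; wake/NREM/REM;
wake/LS/DS/REM with LS = {S1,S2}, DS = {S3,S4}; five-class with S3∪S4
merged; full six-class.  Protocols: stratified 10-fold CV (90/10 per fold,
no validation block) and a stratified 60/10/30 holdout whose 10% validation
block exists solely for hyper-parameter selection.  Splits are stratified by
instance (subject-wise CV would be the stricter alternative for clinical
claims; it is out of scope here and noted as a limitation).  All splits
derive from an explicit seed; the same seed reproduces identical folds,
predictions and metrics.  Reported metrics: overall accuracy (100·trace/
total), per-class accuracy interpreted as recall C_ii/row_i, sensitivity and
specificity for binary schemes (positive class defaults to "sleep", a flag
flips it), and Cohen's κ = (Pop − Ptp)/(1 − Ptp) with Pop the observed
agreement and Ptp the chance agreement from the row/column marginals.

## Synthetic epoch generator

The generator exists so the full pipeline is testable end to end without any
EEG download.  Each stage template specifies relative power weights over the
five rhythm bands, a broadband white-noise fraction (default 0.3), an
amplitude scale in µV, and per-band spectral peaks.  Band components are
Gaussian noise shaped in the frequency domain by a Gaussian bump (stage-
specific centre and width) truncated exactly at the analysis band edges —
using the same edges as the filter bank makes the band-energy bookkeeping
exact up to transition leakage.  Channels share a common latent source mixed
with channel-specific realizations at correlation 0.7 (default), emulating
the strong inter-channel coherence of referential EEG montages.

A design point worth stating explicitly: the entropy features are invariant
to amplitude, so band *weights* alone — with flat in-band spectra — would
produce stage classes with identical feature distributions.  Stage
differences must live in in-band structure.  They enter twice: through the
stage-specific peak frequency/bandwidth of each rhythm component, and
through the weight-controlled ratio of peaked (structured) to flat (white)
content within each analysis band.  The default templates follow the
classical polysomnographic picture — wake α/β dominant; S1 θ dominant; S2 θ
plus 12–14 Hz spindle bursts (1 s Hann-windowed sinusoids at Poisson
onsets); S3/S4 δ dominant with S4 heavier and narrower; REM mixed θ/β at low
amplitude — with weights, peaks and widths fixed once in
`synth.default_templates()`.

What passing the synthetic benchmark shows: that the filter bank isolates
the rhythm bands, that the entropies resolve in-band structural differences,
and that the classifier recovers the stage partition from them, end to end
and deterministically.  What it does not show: performance on clinical EEG,
whose stage differences are weaker, non-stationary and contaminated — the
generator's separability is by construction, not a claim about real data.
The companion no-signal control (every stage generated from the same
template) verifies the other direction: with no class signal the pipeline
scores at chance, so the benchmark accuracy is not an artifact of the
evaluation machinery.

## Numerical and procedural choices

- DFT convention: unnormalized forward, 1/N inverse (numpy default).
- Filters stored densely on the length-N grid; building the reference
  15360-point bank costs ~1 ms and is done once per configuration.
- Entropy embeddings are vectorized (sliding windows; inversion counts via
  pairwise comparison over the k(k−1)/2 index pairs), ~0.15 s per 4-channel
  30 s epoch for the full 40-feature vector.
- Problem sizes in tests: unit tests run on 2–4 s frames (the constructions
  are length-independent); the end-to-end benchmark uses 60 epochs per stage
  (360 epochs), chosen to give ≥ 54 training instances per class in every
  fold — comfortably above nn = 10 — while keeping a full run at a few
  minutes.
- The hyper-parameter comparison (ρ=20, nn=10 vs ρ=2, nn=1) averages
  accuracy over five repeated 10-fold runs with shared folds: on a
  near-separable benchmark both settings sit at the accuracy ceiling and a
  single run differs by individual tie-broken instances, so the repeated
  average is the meaningful estimator of the trend.
- Degenerate inputs: constant sub-bands give DE = BE = 0; zero-norm
  dictionary atoms are rejected; κ is undefined (error) when all mass sits
  in one row/column pair.

## Known limitations

- Stage annotations are aligned to signal windows positionally; misaligned
  exports require the epoch offset to be set by the caller.
- Instance-level stratified CV shares a recording's epochs between train and
  test folds; subject-wise evaluation would be required for generalization
  claims across patients.
- The generator omits artifacts, K-complex morphology and 1/f background;
  synthetic accuracy is an upper bound of sorts, not an estimate of clinical
  performance.
- OMP equals exhaustive best-subset selection only near orthogonality; on
  coherent dictionaries (correlated training instances) it is the standard
  greedy approximation.
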