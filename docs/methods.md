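# Methods

This note documents the models and procedures implemented in `doamon`, the
assumptions behind them, the parameters that matter, and what the synthetic
studies do and do not demonstrate.

## The monitoring problem

During general anesthesia the clinician needs a single, continuously
updated number describing how deeply unconscious the patient is.
Commercial EEG monitors (e.g., the bispectral index, BIS) provide such a
0–100 index but are proprietary. The open method implemented here derives
the index from single-channel forehead EEG (125 Hz) in three steps:

1. **Multiscale entropy (MSE) features.** In each 30 s sliding window
   (3750 samples, advanced every 5 s) sample entropy is computed on
   coarse-grained copies of the window at scales τ = 1..20.
2. **Optional artifact filtering.** Noise-assisted multivariate empirical
   mode decomposition (MEMD) splits the record into intrinsic mode
   functions (IMFs); summing IMF2 + IMF3 removes both the fastest noise
   band and the slow, high-amplitude electro-oculographic (EOG) blink
   band.
3. **ANN fusion.** A feed-forward network (20 inputs → 20 tanh hidden
   units → 1 linear output) regresses the per-window entropies onto a
   gold-standard consciousness series (BIS export or the mean of
   expert-drawn 0–100 curves, both at 0.2 Hz), yielding the fused index,
   clipped to [0, 100].

## Sample entropy and MSE

For a series of N points, embedding dimension m and tolerance r,

    SampEn(m, r, N) = −ln(A / B)

with B the number of distinct template pairs (i < j, templates of m
consecutive points) whose Chebyshev distance is ≤ r, and A the number of
those pairs still within r when both templates are extended by one point.
Conventions: self-matches excluded; r = 0.2 × SD of the series
(population SD); entropies in nats. When A or B is zero, or the series
has zero SD, the value is undefined and reported as NaN — windows are
never silently dropped; downstream consumers decide how to handle gaps.

Coarse-graining at scale τ averages non-overlapping blocks of τ samples
(trailing remainder discarded). Two conventions matter and are
configurable but fixed by default:

* the tolerance is derived from the **scale-1** SD and held fixed across
  scales, so the profile measures loss of fast structure rather than the
  1/√τ shrinkage of the variance;
* the tolerance is computed **per window**, not from the whole record.

For i.i.d. Gaussian noise these conventions give the closed form
MSE(τ) = −ln erf(0.1 √τ), which the test suite uses as an analytic
oracle (30 series of 30 000 points; agreement within 3 standard errors at
every scale). The inner pair count is an O(N²) loop compiled with numba;
an independent brute-force enumeration in the test suite must agree with
it exactly, count for count.

At scale 20 a 3750-sample window leaves only 187 coarse-grained points.
Entropy estimates at the largest scales are therefore noisier — the
motivation for combining scales instead of trusting any single one.

## MEMD and the IMF2+IMF3 filter

EMD decomposes a signal into IMFs ordered high → low frequency plus a
residue; the decomposition is exact by construction (the residue is the
remainder after subtracting every IMF). The multivariate extension sifts
all channels jointly: the signal is projected onto `n_directions = 64`
quasi-uniform unit vectors (a Hammersley point set pushed through the
Gaussian quantile and normalised), the multivariate signal is
cubic-spline-interpolated through each projection's maxima (mirror
extension of boundary extrema), and the envelopes are averaged to
estimate the local mean. Joint sifting guarantees every channel yields
the same number of IMFs.

Sifting stops when the envelope-mean to signal amplitude ratio falls
below 0.075 (at most 100 iterations). Implementation experience: the
joint mean envelope alone leaves "riding waves" in individual channels —
the per-channel IMF acceptance criterion |#extrema − #zero-crossings| ≤ 1
was violated by ~2% of extrema even after 100 joint sifts. Each extracted
component is therefore polished with a few classic univariate sifts
(envelopes through the channel's own extrema) until the criterion holds;
a terminal component with too few extrema to envelope is left in the
residue rather than emitted as an IMF. With this refinement every emitted
IMF satisfies the acceptance criterion while completeness stays exact.

Single-channel EEG uses the noise-assisted mode: 2 channels of
independent white noise at 0.1 × signal SD are stacked next to the
signal, the joint decomposition runs, and only the signal channel's IMFs
are returned — no noise enters the output (unlike ensemble EMD). The
noise-channel count, amplitude and seed are configurable and recorded.

The default denoising reconstruction sums IMF2 + IMF3 of that
decomposition. At 125 Hz this keeps the mid-frequency EEG band while
dropping IMF1 (fastest noise) and the slow IMFs that carry blink
transients and ocular drift. Filtering is applied to the whole record
once, before windowing. Band reconstructions exclude the residue by
default; pass `include_residue=True` where the trend matters.

## ANN index model

Inputs and the 0–100 target are standardised with training-split
statistics (the output scaling is stored in the model and undone at
prediction). Samples are split 70/15/15 into training/validation/test at
random per sample; training uses backpropagation (adam, learning rate
0.01, squared error) with early stopping on validation loss (patience 20
epochs, max 1000). The trained weights serialise to JSON; prediction is
the package's own forward pass, which must reproduce the training
backend's outputs exactly in tests. Predictions are clipped to [0, 100].
Rows with undefined entropies are dropped for training and yield NaN at
prediction.

Feature/target alignment: MSE windows end every 5 s and the gold standard
ticks every 5 s, possibly offset; each gold sample is paired with the
window whose end time is nearest, within 2.5 s.

The pre/post-filter combination takes, per scale, whichever analysis
(unfiltered or filtered) correlates better with the gold standard —
filtering helps scale 1 and nearby scales and hurts large scales, so the
combined feature set outperforms either alone.

## Evaluation statistics

Agreement is summarised by the Pearson correlation and its square (the
coefficient of determination as regression tooling reports it). Across
several recordings the coefficient of variation, CV = 100 × SD/mean with
sample SD (n−1), of the per-case correlations summarises robustness.
Zero-variance inputs yield an undefined (NaN) report. In the paired
t-test, a zero-variance difference vector yields p = 1 when the common
difference is zero and p = 0 otherwise, by convention.

## Synthetic study conditions

The generators define the conditions under which the package's claims are
tested; each default was chosen once for realism:

* **Awake EEG** ("preoperation"): band-limited 1/f (pink) Gaussian noise,
  0.5–45 Hz, plus an alpha-band (8–12 Hz) accent at 0.4 relative SD.
  The 1/f shape matters: with a flat broadband spectrum, coarse-graining
  removes nearly all signal power at large scales and an added artifact
  dominates them, which real EEG's low-frequency-heavy spectrum prevents.
* **Anesthesia EEG** ("maintenance"): slow-wave-dominated noise (4th-order
  low-pass at 5 Hz) plus a weak 8–30 Hz component at 0.25 relative SD;
  ≥ 70% of power lies below 8 Hz. Records are zero-mean with a nominal
  10 µV SD (entropy analysis is amplitude-invariant).
* **EOG**: Poisson-timed blinks (default 0.25 /s) of 200–400 ms and
  5–10 × EEG SD, as Gaussian bumps, riding on continuous slow ocular
  drift (< 1.5 Hz) at 0.3 × the blink-train SD. The drift term reflects
  that an awake eye is never still; without it, strong contamination
  collapses the entropy uniformly at all scales and the characteristic
  scale-dependence of artifact sensitivity cannot appear. A zero blink
  rate yields silence.
* **SNR mixing**: the artifact is scaled so that
  10·log₁₀(P_clean/P_artifact) equals the requested dB value, with power
  the mean squared amplitude over the whole record. The study grid is
  10 → −20 dB in −1 dB steps (31 levels) plus the unmixed original.
* **Gold curve**: awake ≈ 95, smooth sigmoid descent to a 46–54 plateau,
  recovery near the end, small slow drift, sampled at 0.2 Hz, clipped to
  [0, 100].
* **Depth-modulated EEG**: pointwise mixture of awake and anesthesia
  noise weighted by the gold curve, plus broadband sensor noise at 0.3
  relative SD emulating instrument/EMG noise. The noise term gives the
  multiscale index its advantage a mechanism: it blurs scale-1 entropy
  (which sees every fast fluctuation) much more than the coarse-grained
  larger scales. The end-to-end study uses a 1800 s recording
  (≈ 355 windows, ≈ 360 gold samples).

What these studies show: that the implementation reproduces the
qualitative behaviour the method is built on — artifact sensitivity
concentrated at scale 1, awake/anesthesia separation, fused-index
recovery of a known consciousness curve (held-out r > 0.9, above the
scale-1-only model). What they do not show: clinical performance. The
generators contain no burst suppression, no spindles or k-complexes, no
drug-specific spectral signatures, no nonstationary artifact regimes; the
published per-patient correlations on real recordings cannot be
reproduced from synthetic data.

## Numerical choices and limitations

* Problem sizes in the test-suite studies (30 s – 60 s records, 5–10
  cases, 6–20 decompositions) are desk-scale versions of the full
  studies; the white-noise calibration runs at the full 30 × 30 000
  points.
* MEMD caps at 12 IMFs per decomposition; sifting raises a diagnostic
  error naming the IMF index if it cannot converge.
* All generators and the pipeline are bit-reproducible given seeds; the
  pipeline writes every artifact with fixed float formatting so reruns
  are byte-identical.
* EDF files can be read (via `mne`, optional extra); the package writes
  CSV. The supported gold-standard ingestion path is two-column CSV.
* Undefined entropies propagate as NaN end to end; no interpolation is
  performed on behalf of the caller.
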