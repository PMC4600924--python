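# doamon — EEG depth-of-anesthesia monitoring via multiscale entropy

`doamon` implements an open, single-channel-EEG method for tracking a
patient's depth of anesthesia (DOA) during surgery. Commercial monitors
such as the bispectral index (BIS) distil frontal EEG into a 0–100
consciousness index with undisclosed algorithms; this package builds such
an index from published, inspectable components:

1. **Multiscale entropy (MSE) features.** In every 30 s sliding window
   (3750 samples at 125 Hz, advanced 5 s) the sample entropy

       SampEn(m, r, N) = −ln(A / B)

   is computed on coarse-grained copies of the window at scales
   τ = 1..20 (m = 2, r = 0.2 × SD, Chebyshev distance, self-matches
   excluded). Scale 1 is plain SampEn; larger scales average
   τ consecutive samples first and expose slower structure.
2. **MEMD artifact filtering (optional).** Noise-assisted multivariate
   empirical mode decomposition splits the record into intrinsic mode
   functions (IMFs); reconstructing from IMF2 + IMF3 removes the slow,
   high-amplitude electro-oculographic (EOG) blink band along with the
   fastest noise.
3. **ANN fusion.** A feed-forward network (20 entropy inputs → 20 tanh
   hidden units → 1 linear output; 70/15/15 train/validation/test split,
   early stopping) regresses the per-window entropies onto a 0.2 Hz
   gold standard (a BIS export or the mean of expert-drawn 0–100
   curves), yielding the fused index clipped to [0, 100].

The package also implements the two studies that justify the design: the
per-scale EOG-sensitivity study (coefficient of variation of each
scale's entropy across an SNR grid from 10 dB to −20 dB) and the
awake-vs-anesthesia discrimination study (paired two-tailed t-tests per
scale, p < 0.05), plus synthetic generators for every input so the whole
pipeline runs without clinical data.

Audience: researchers in anesthesia monitoring and nonlinear
physiological signal analysis who want a transparent, testable reference
implementation.

## Worked example

`examples/04_doa_index.py` builds a synthetic 30-minute case — a known
consciousness curve drives an EEG generator whose spectrum interpolates
between awake and anesthetised — then trains and evaluates the index:

```text
inputs: 1800 s EEG at 125 Hz, 360 gold samples at 0.2 Hz
features: 355 windows x 20 scales
held-out Pearson r = 0.915  (R^2 = 0.838, 53 test samples)
index range: [44.8, 100.0]
```

The held-out correlation of 0.915 means the fused index reconstructs the
consciousness curve on windows it never saw in training; the index series
itself is the 0–100 number a clinician would watch. The other examples
demonstrate the generators (`01`), the white-noise entropy calibration
against the analytic −ln erf(0.1 √τ) curve (`02`), the MEMD filter
(`03`: sub-4 Hz power fraction 0.818 → 0.445 at −5 dB contamination),
and the sensitivity/discrimination studies (`05`: CV 52% at scale 1
falling to 26% at scale 20; awake scale-1 entropy 1.68 vs 0.88 under
anesthesia, p ≈ 1e−9).

A thin CLI wraps the same functions:

```sh
doamon simulate --kind eeg --duration 60 --seed 1 --out eeg.csv
doamon filter --in eeg.csv --imfs 2,3 --seed 2 --out filtered.csv
doamon mse --in filtered.csv --scales 1:20 --out mse.csv
doamon train --features mse.csv --gold gold.csv --out model.json
doamon predict --model model.json --features mse.csv --out index.csv
doamon run --seed 17 --out-dir run/
```

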