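# Methods

This note records the models, parameter choices and numerical decisions
behind `ecochg`, and what the synthetic validation does and does not show.

## Signal model

A recording holds 100 stimulus-locked epochs per acoustic polarity.
The cochlear microphonic is modelled as a gated pure tone at the stimulus
frequency `f`:

    s(t) = a · env(t) · sin(2π f (t − d)),

where `d` is the onset delay (default 1 ms, the recording delay of the
stimulation table) and `env` gates the tone to the stimulus duration with
1 ms raised-cosine ramps (shortened to half the duration for very short
bursts). Condensation epochs carry `+s(t) + n(t)`, rarefaction epochs
`−s(t) + n(t)`, with `n` white Gaussian noise (default SD 1 µV; the
absolute µV scale is nominal — clinical amplitudes vary by an order of
magnitude and only "microvolt range" is known). Optional defects:

- **Baseline wander** — a <20 Hz sinusoid with per-epoch random phase
  (off by default).
- **Stitching artifacts** — a step of fixed amplitude at a fixed sample
  index in every epoch, the signature of concatenated recording buffers.
- **Outlier epochs** — a contiguous block of epochs replaced by noise
  (generator) or sign-flipped (injector). Blocks, not scattered singles,
  because real interference (movement, transient pickup) arrives in
  bursts — and because the exclusion rule correlates *Gaussian-weighted*
  epochs with the ensemble mean, so an isolated flipped epoch is diluted
  by its four neighbours to a near-zero correlation and is undetectable
  by that rule in principle. Uncorrelated (pure-noise) outliers likewise
  sit near r = 0 and are never caught by the r < −0.2 rule; only
  anti-correlated defects are.

### SNR convention and calibration

All stated SNRs are ± (plus-minus) averaging estimates on the **raw DIF
epoch ensemble**: the plain average of the DIF epochs holds `s` plus
residual noise of power `σ²/(2n)` (two polarities averaged, n pairs); the
alternating-sign average cancels `s` and estimates that residual. The
generator calibrates the tone amplitude to a target SNR by bisection on

    SNR(a) = 10 log10( a² · mean(env·sin)² · 2n / σ² ),

which is deterministic and exact up to estimator noise (≈0.4 dB SD per
recording). The objective band-pass (100 Hz–5 kHz at fs = 20 kHz) removes
roughly half the white-noise power, so pipeline SNR estimates read about
3 dB above the raw-domain target; comparisons in this package are always
within one domain. The shipped dataset recipes reuse the clinical mean
SNRs per frequency and level category (≈2.3–5.6 dB).

Sampling rate defaults to 20 kHz so the 5 kHz band edge sits well inside
Nyquist; it is stored per file, never assumed.

## Preprocessing chain

Order: stitching removal → Gaussian weighting → epoch exclusion →
band-pass → DIF/SUM derivation and SNR.

- **Stitching removal.** Candidate step indices are detected on the
  ensemble-mean epoch where the absolute first difference exceeds 8× its
  median (constants exposed in the API); the step amplitude is estimated
  per epoch as the jump minus the epoch's local median first difference
  and subtracted from the discontinuity onward. Detection on the mean
  buys a √n sensitivity gain and is valid because buffer stitching sits
  at the same sample in every epoch. Per-epoch independent steps are out
  of scope.
- **Gaussian weighting.** Each epoch is replaced by a kernel-weighted
  mean of itself and its ±2 neighbours, kernel
  `w(l) = exp(−½ (l/(σ(K−1)/2))²)`, σ = 0.4, K = 5 (weights 1, 0.458,
  0.0439). The printed weighted sum is normalized by the sum of the
  weights in use so amplitudes are preserved; at the ends the kernel is
  truncated to available neighbours and renormalized, keeping the epoch
  count unchanged (the exclusion percentages assume that). For white
  noise the weighted-epoch variance is `σ²Σw²/(Σw)² ≈ 0.354 σ²`.
- **Exclusion.** Weighted epochs are Pearson-correlated with the mean of
  all epochs; r < −0.2 excludes, at most `floor(0.1·N)` epochs (the worst
  first). Zero-variance epochs get r = 0 and are logged. Exclusion runs
  per polarity (it precedes DIF pairing in the chain); DIF pairing prunes
  to the common index range afterwards.
- **Band-pass.** 2nd-order Butterworth applied forward-backward
  (zero-phase) per epoch; 100 Hz–5 kHz for the objective path, 10 Hz–5 kHz
  for visual display.

### Which epochs feed which consumer

The pipeline keeps two epoch versions after exclusion and filtering: the
Gaussian-**weighted** epochs form the displayed/averaged DIF response and
the scalograms, while the cleaned **unweighted** epochs feed the
statistical detectors and the reported ± SNR. The reason is statistical,
not cosmetic: a 5-epoch moving average across epochs makes neighbouring
rows serially dependent. For the Hotelling test this shrinks the row-wise
sample covariance by ≈0.354 while leaving the variance of the ensemble
mean unchanged, inflating T² roughly threefold on pure noise and driving
the type-I error toward 1; for the buffer split, weighted epochs leak
across the random buffers and give a spurious mean correlation of ≈0.4 on
noise. Similarly, the reported ± SNR uses unweighted epochs because the
alternating-sign average of smoothed epochs cancels the smoothing kernel
almost entirely (factor ≈0.086 in amplitude) and would overstate SNR by
>20 dB. With this split the preprocessing SNR gain on defective
ensembles comes from exclusion, which is exactly what the exclusion step
exists to do.

## Hotelling's T² on time-voltage means

The measurement window is partitioned into Q contiguous windows with
boundaries `round(j·T/Q)` (every sample in exactly one window); each
epoch's window means form one row of the N×Q matrix V. Rows are the CON
epochs stacked with the **sign-flipped** RAR epochs: the CM inverts with
polarity, so flipping RAR aligns it across rows, the no-CM null keeps a
zero mean, and N ≈ 200 supports the full Q sweep to 195 where 100 rows
would make the covariance singular beyond Q = 99. (How the original
matrix was assembled is not derivable from its published description
given the Q ≤ N − 1 constraint; this stacking is this package's
documented reconstruction.)

`T² = N x̄ᵀS⁻¹x̄` with the unbiased covariance S (Cholesky solve;
singularity raises with advice to lower Q), `F = T²(N−Q)/(Q(N−1))`
referred to F(Q, N−Q), upper-tail p, detection at p < α = 0.01. Q tuning
maximizes training accuracy per frequency over 5…195 step 5, skipping
grid values above N−1 or the sample count, ties to the smallest Q (fewer
parameters, more error dof). The shipped per-frequency defaults
(250→90, 500→80, 750→100, 1000→85, 1500→105, 2000→100) are the values
tuned on the clinical data; on white-noise synthetics the optimum is
usually much smaller — the tuner exists to find it for whatever data it
is given.

## Buffer-split correlation

Per repetition, each polarity's epochs are randomly split into two equal
buffers (odd counts drop one random epoch so the buffer means stay
identically distributed); CORR is the mean of the two within-polarity
Pearson correlations of buffer means, and the final coefficient averages
100 repetitions (deterministic per seed). Zero-variance buffer means
contribute r = 0, logged. A maximum-likelihood logistic regression maps
the coefficient to P(response), decision at 0.5; under perfect separation
(common on clean synthetic data, where the ML slope diverges) the model
falls back to a steep logistic centred midway between the classes and
flags it.

## Scalogram CNN

The averaged DIF trace is transformed with a complex Morlet wavelet
(centre frequency ω₀ ≈ 6, exposed), 64 log-spaced scales covering
100–5,000 Hz pseudo-frequencies; the magnitude is min-max normalized per
image (an all-zero trace yields an all-zero image, flagged), bilinearly
resampled to 224×224 and replicated across 3 channels — replication
rather than a colormap, which would inject an arbitrary nonlinearity.

Two backbones. The **compact** default is a from-scratch numpy CNN:
channel-mean + 8×8 average pooling to 28×28, conv3×3(8)–ReLU–maxpool2–
conv3×3(16)–ReLU–maxpool2–dense(1), binary cross-entropy, SGD with
momentum 0.9, batch 8, ≤25 epochs, inputs standardized with training
statistics, He initialization, deterministic per seed. Its default
learning rate is 0.05: the 1e-4 of the transfer protocol is meant for
fine-tuning pretrained features and cannot move a randomly initialized
network within 25 epochs. The **large-pretrained** backbone (ImageNet
AlexNet with the last two classifier layers replaced for binary output,
lr 1e-4) is implemented behind a lazy torch import and raises a clear
error when torch is unavailable. Stratified k-fold cross-validation
(default 10) reports per-fold accuracy/AUC and a pooled AUC, then
retrains the final model on the full training set.

## Evaluation stack

Accuracy/sensitivity/specificity with a normal-approximation 95% CI
half-width on accuracy (the CI method attached to published accuracy
tables is not stated; this is the assumption). ROC/AUC via rank-based
scoring (ties rank-averaged, so AUC equals Mann-Whitney U/(n₁n₀));
Hotelling scores enter as 1 − p. DeLong's test uses midrank placement
values; the one-sided p for AUC_a > AUC_b is Φ̄(z), exactly 0.5 for
identical scores, and degenerate zero-variance cases resolve by AUC
ordering. Fleiss' kappa is computed from category counts (undefined —
returned NaN — when every item lands unanimously in one overall
category); per-rater false-positive rates are taken against the
consensus label. The consensus rule is unanimity with one re-presentation
of 2-of-3 positive splits; a persistent non-unanimous second round counts
as noise (the published rule text never shows a round-2 split outcome;
"valid responses by all three" decides it here).

The benchmark runner splits 70/30 stratified by frequency × label (the
original split's stratification is unstated; stratifying stabilizes
per-frequency metrics), tunes everything on the training split only,
guards against split leakage, and reports metrics, ROC curves and
pairwise DeLong comparisons on the test split as JSON.

## What the synthetic validation shows — and does not

White Gaussian noise makes detection easier than clinical reality: at the
clinical mean SNRs (2.3–5.6 dB on a 100-epoch average) all three
detectors separate classes almost perfectly, so benchmark AUCs near 1.0
confirm correctness of the implementations, not clinical performance.
The detectors' discrimination thresholds sit near −7 dB raw-DIF SNR under
these conditions. Correlated noise, electrode artifacts, morphology and
latency variation of real CM responses are not modelled; published
clinical accuracies are therefore not reproducible here, and the
validation targets are calibration (type-I error at the binomial CI),
oracle equivalence of every statistic, directional preprocessing gains,
and monotone power with correct method ordering.

Problem sizes used by the validation suite, chosen for a single-CPU
workflow: 5,000 replicates for the type-I calibration; a 600-recording
benchmark (100 per level category plus 300 noise controls at 500 Hz);
power curves over 0–20 dB in 5 dB steps at 40 recordings per point;
200 ensembles for the preprocessing-gain check, at 10 dB SNR with a 15%
sign-flipped burst (a clear-response condition — the exclusion rule can
only act where outliers are identifiable); permutation and bootstrap
oracles at 4,000 draws with agreement bands scaled to the Monte-Carlo
standard error.

## Known limitations

- No biophysical cochlear model; no CAP/SP/ANN waveform synthesis, and
  detection of those components is out of scope.
- The exclusion rule cannot remove uncorrelated (r ≈ 0) outlier epochs;
  that is a property of the published rule, faithfully kept.
- No 50/60 Hz notch filtering or adaptive artifact regression.
- The compact CNN is deliberately small; it is not an architecture-search
  result, and no trained weights are distributed.
- Proprietary recording-system exports are not read; the HDF5/CSV
  container is the interchange format.
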