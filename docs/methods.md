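# Methods

## Pipeline model and assumptions

The analysis treats each 1-s multichannel epoch as an independent,
labeled observation and each channel's gamma-band (30–55 Hz) normalized
spectral entropy (SE) as a scalar complexity summary. The working
assumptions are: epochs are artifact-free; channels are informative
individually (ranking is univariate); SE values per channel are close
enough to normal for a t-test on group means (checked descriptively
with the Kolmogorov–Smirnov diagnostic, never enforced); and group
membership is the only systematic difference between the two sets of
epochs.

## Gamma-band filtering

- Elliptic band-pass, 30–55 Hz, with 0.5 dB passband ripple and 40 dB
  stopband attenuation (single-pass values; both configurable). The
  source description fixes only "sixth-order elliptic, 30–55 Hz";
  0.5 dB/40 dB are conventional elliptic design values.
- "Sixth-order" is read as the order of the band-pass transfer function
  (low-pass prototype order 3). The alternative reading — prototype
  order 6, i.e. a band-pass of order 12 — was implemented and rejected:
  its poles lie at radius 0.992, so edge ringing decays over more than
  256 samples and measurably contaminates the central half of a 1-s
  epoch (a 5 Hz tone is attenuated only ~77 dB there after the double
  pass, versus ~88 dB for the order-6 band-pass). The cost of the
  order-6 reading is wide transition bands (the low side reaches 40 dB
  only near 10 Hz); this is acceptable because the entropy step
  restricts the spectrum to the 30–55 Hz bins anyway, so transition-band
  leakage outside those bins never enters the feature.
- Zero phase is obtained by forward/backward filtering (second-order
  sections for stability), with odd-reflection padding of 3× the filter
  order. Even-reflection padding leaves larger edge kinks and was
  measurably worse in the stopband (~77 dB instead of ~88 dB for the
  5 Hz case above). Because edge transients outlive the epoch, a single
  padded pass is not exactly symmetric under time reversal; the operator
  is symmetrized — averaged with its time-reversed application — which
  makes commutation with time reversal exact at machine precision and
  leaves the frequency response unchanged.
- The double pass squares the magnitude response: passband ripple
  doubles in dB and stopband attenuation doubles. All response checks on
  filtered signals use these double-pass bounds.

## Spectral entropy

- Spectral estimate: single-window magnitude-squared FFT periodogram of
  the full epoch, no taper, no segment averaging. At 256 samples/256 Hz
  this gives exactly 1-Hz bins; the closed band [30, 55] then contains
  N = 26 bins with both edges bin-aligned. Normalization is
  Parseval-consistent (one-sided powers sum to Σx²).
- SE = −(1/log N) Σ Pₙ log Pₙ over the in-band bins, with
  Pₙ = P/Σ_band P, 0·log 0 := 0 by continuity, and natural logarithms
  (the base cancels in the normalization; fixed for reproducibility).
  Values are clipped to [0, 1] against last-bit round-off.
- The entropy is computed on the *filtered* signal's band bins,
  matching the stated pipeline order; `gamma_se_features(...,
  filtered=False)` exposes the unfiltered variant for sensitivity
  analysis, since band restriction alone already discards out-of-band
  bins.

## Synthetic generator

Each channel trace is
`√w · noise + √(1−w) · tone + background`, where *noise* is unit-power
Gaussian noise band-limited to 30–55 Hz, *tone* is a unit-power 40 Hz
sinusoid with random phase, and *background* is unit-power 1/f noise
below 30 Hz (fixed constants; it exists so the band-pass has real
out-of-band energy to remove). The mixing weight w ∈ [0, 1] is the
complexity dial: it is the fraction of in-band power carried by the
noise, so mean SE rises strictly from ≈0 (pure tone) to ≈0.87 (pure
band noise; sampling fluctuations of the periodogram keep it below 1).
Power-linear mixing is deliberate — with amplitude-linear mixing the
power ratio goes as w², flattening the dial near w = 1 until grid steps
drown in sampling noise.

Complexity, not amplitude, is manipulated because normalized SE is
scale-invariant; an amplitude effect would be invisible to the feature.
Controls use `base_complexity` (default w = 0.3) everywhere; alcoholic
epochs use a larger w in the planted channels only. The `effect` knob is
expressed directly in feature units (target mean SE difference): a pilot
simulation (100 single-channel epochs per point on a 21-point w grid,
run through the exact filter + entropy pathway, fixed internal seed)
maps mean SE as a function of w, and the planted weight is read off by
inverse interpolation. The pilot's fixed seed makes the effect→weight
map a pure function of the sampling geometry, so it is cached without
breaking the seeded determinism of epoch generation. Requested effects
beyond the w = 1 ceiling raise a calibration error. Realized gaps land
within a few hundredths of the target (e.g. +0.189 realized for 0.2
requested at 600 epochs/group).

What the generator does **not** emulate: eye-blink/muscle artifacts
(the target data are artifact-cleaned before analysis), ERP morphology
(no stimulus-locked peaks), inter-channel spatial correlation (channels
are independent), and absolute SE levels of real recordings (only the
qualitative structure — values in (0,1), group gaps confined to chosen
channels — is matched). Tests passing on synthetic data therefore
validate the *pipeline's statistics and algorithms*, not claims about
real EEG.

## Ranking

- Welch t with unbiased variances and Welch–Satterthwaite df; two-sided
  p from Student's t. Group 1 is alcoholic, so t > 0 means higher
  alcoholic SE (more disorder).
- Ordering: channels with p < α (default 0.05) first, then descending
  |t| within each block, ties to the lower channel index. |t| is used
  rather than the raw mean difference because it is the quantity the
  test defines; `order_by="mean_gap"` exposes the mean-difference
  alternative, and with comparable per-channel variances the two nearly
  coincide.
- No multiple-testing correction is applied (the gate is a ranking
  device, not an inference claim).
- In cross-validated evaluation the ranking is computed on the training
  partition by default (leakage hygiene); `rank_scope="pooled"`
  reproduces a whole-dataset ranking. Same for the PCA fit
  (`pca_scope`). Internal channel indices are 0-based; reported tables
  are 1-based.
- KS normality uses parameters estimated from the sample, so its
  p-value is anti-conservative (Lilliefors caveat); it is a diagnostic
  only.

## PCA

Explicit covariance route: center, V = XᵀX/(N−1), `eigh`, descending
eigenvalues. Round-off negatives are clamped to zero (tolerance 1e−10).
Eigenvector sign is fixed by making each component's largest-magnitude
entry positive; for degenerate (tied) eigenvalues any orthonormal basis
of the eigenspace is acceptable and tests compare subspaces by principal
angles, not entrywise. d is always explicit — no automatic selection by
explained variance. Covariance, not correlation: SE features already
share the [0, 1] scale.

## Evaluation

- k-NN with k = 3 by default (odd, minimizing vote ties; the source
  description never states k, so every reported run states its k) and
  Euclidean distance on component scores. Distance ties break toward the
  lower training index; vote ties toward the class of the single nearest
  neighbor — both fixed so results are exactly reproducible.
- 50% stratified holdout with an explicit seed, replicated over seeds
  (a single split is not a testable contract). Alcoholic is the
  positive class for sensitivity/specificity.
- ROC sweeps the distinct k-NN vote fractions as thresholds; trapezoidal
  AUC, which equals the Mann–Whitney concordance probability with ties
  counted half.
- At N = all channels, ranked and non-ranked selection differ only by a
  channel permutation, and PCA + k-NN are permutation-invariant, so the
  two reports are *exactly* identical — the package asserts equality
  rather than mere statistical indistinguishability.

## Problem sizes and degenerate inputs

The shipped study uses 600 epochs/group × 61 channels × 256 samples,
with 10 planted channels (41–50, 1-based) at effect 0.2 — the planted
set sits outside the first 15 native channels so the ranked/non-ranked
contrast at N ∈ {25, 15} is informative. Replicated checks use 100–500
regenerations at reduced channel counts (8–16) chosen to keep full-suite
runtime in minutes while leaving thousands of channel-level tests for
rate estimates. At effect 0.2 the ranked pipeline saturates (planted
per-channel t ≈ 60 at 600/group ⇒ 100% holdout efficiency); the
efficiency-vs-d trend is then flat at the ceiling, and graded curves
appear at weaker effects or smaller samples.

Degenerate inputs fail loudly with typed errors: all-zero in-band power
(entropy undefined), both group variances zero (t undefined), constant
samples (KS undefined), single-class truth (ROC undefined), bands with
fewer than two bins, d > N, k > training size.

## Known limitations

- The trial-file reader targets the whitespace-delimited public-archive
  dialect only (no EDF/BDF, no montage handling, no download client).
- Only the gamma band and only spectral entropy are implemented; no
  other bands, entropy variants, or time-frequency features.
- The generator's independence across channels means channel-selection
  results here do not probe correlated-channel regimes (where, e.g.,
  ranking redundant neighbors is wasteful).
- Efficiency ceilings: with strong planted effects the k-NN stage is not
  the bottleneck and comparisons between (N, d) cells lose resolution.
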