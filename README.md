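# gammase

Gamma-band spectral-entropy analysis of two-group visual event-related
potentials (ERPs): channel ranking by Welch's t-test, PCA reduction, and
k-NN classification with holdout validation.

## The problem

Visual ERPs of alcoholic subjects show reduced evoked gamma (30–55 Hz)
oscillations during object-recognition tasks, but only in some scalp
regions. Given 1-s, multichannel EEG epochs from an alcoholic and a
control group, the analysis asks: *which channels separate the groups,
and does selecting channels by that separability improve classification
over taking channels in recording order?*

The pipeline:

1. **Gamma extraction** — each trace is band-passed to 30–55 Hz with a
   sixth-order elliptic filter applied forward/backward (zero phase).
2. **Feature extraction** — each (epoch, channel) trace is summarized by
   its normalized spectral entropy over the band,

   SE[f₁, f₂] = −(1 / log N) Σᵢ Pₙ(fᵢ) log Pₙ(fᵢ),

   where Pₙ(fᵢ) is the in-band power spectrum normalized to sum to one
   and N is the number of in-band bins (26 at 1-Hz resolution). SE ∈
   [0, 1]: ≈0 for a narrowband (ordered) spectrum, ≈1 for a flat
   (disordered) one.
3. **Channel ranking** — per channel, Welch's two-sample t
   (t = (x̄₁ − x̄₂)/√(s₁²/n₁ + s₂²/n₂)) on the SE values of the two
   groups; channels with p < 0.05 rank first, ordered by |t|.
4. **Reduction** — PCA via the explicit covariance route
   (V = XᵀX/(N−1) after centering), keeping the top d components.
5. **Classification** — k-NN (k = 3, Euclidean) on the component
   scores, 50% stratified holdout, replicated over seeds; reported as
   efficiency (accuracy), sensitivity/specificity (alcoholic positive),
   and ROC/AUC.

Because the EEG recordings themselves are external, the package ships a
seeded synthetic generator that emulates the study's structure: two
groups of 1-s, 61-channel epochs in which designated channels carry a
calibrated group difference in gamma-band spectral complexity. A
permissive reader for the public alcoholism-database trial-file format
is included for use with real data.

## Worked example

The numbered scripts under `analysis/` run the whole study:

```sh
python analysis/01_simulate.py --seed 1      # define the synthetic study
python analysis/02_extract_features.py       # filter + spectral entropy
python analysis/03_rank_channels.py          # Welch-t channel ranking
python analysis/04_classification_grid.py --seed 1
```

With the default study (600 epochs/group, 61 channels, channels 41–50
planted at a target mean SE gap of 0.2), step 02 prints

```
SE range [0.222, 0.832]
mean SE gap (alcoholic - control): planted +0.189 (target +0.200), non-planted +0.0003
```

— the generator's calibration realizes the requested effect in feature
units, and only where planted. Step 03 finds exactly the planted
channels on top (15/61 channels pass the p < 0.05 gate: the 10 planted
ones plus ~5% false positives among the 51 null channels):

```
 rank  channel         t   p  mean_alcoholic  mean_control  significant
    1       50 62.957343 0.0        0.611399      0.415620         True
    2       42 61.765895 0.0        0.604100      0.415530         True
    ...
```

Step 04 shows the headline contrast. The planted channels lie outside
the first 15 native channels, so native-order selection at N = 25 or 15
never sees them and stays at chance, while ranked selection recovers
them (efficiency in %, mean over 5 holdout seeds):

```
 n_channels  n_pcs  efficiency_pct_nonranked  efficiency_pct_ranked
         61      5                   100.000                  100.0
         25      5                    48.833                  100.0
         25     25                    49.767                  100.0
         15     15                    49.200                  100.0
ranking gain at N=25: +50.92 percentage points (mean over d and seeds)
```

At N = 61 both modes select every channel, so ranking is a pure
permutation and the reports are identical by construction. At the
default effect size the ranked pipeline saturates at 100%; weaker
effects give graded efficiency curves (see `docs/methods.md`).

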