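# Methods

`colliclust` re-implements, as a tested library, the analysis chain used to
characterize superior-colliculus (SC) population responses to natural
movies recorded with two-photon calcium imaging: trace preprocessing,
PCA-based feature extraction, Gaussian-mixture clustering with BIC model
selection, subsampling stability analysis, battery-derived tuning indices,
2-D Gaussian receptive-field (RF) fitting, and density-recovery-profile
(DRP) anatomy. Because raw recordings of this kind are rarely
redistributable, the package ships a synthetic-session generator that
plants known ground truth with the statistical structure the analysis
assumes, so every stage can be verified end to end.

## The synthetic session

A session emulates a 600 × 600 μm imaging field scanned at 4.8 Hz with
~3,200 ROIs organized into 16 planted response clusters of ~200 neurons
(all counts configurable). Stimuli are four natural-movie surrogates and a
six-protocol artificial battery (moving bar in 12 directions, looming,
11 × 11 sparse noise, chirp, blue/green color, and size tuning), each shown
for 10 repetitions.

**Movies.** Each movie is a sequence of windows into a large random
texture whose spatial power spectrum falls as 1/f², the hallmark statistic
of natural scenes. The four movies differ in their dynamics: slow drift
with luminance modulation, fast translation, a jittery random walk, and a
gentle zoom cycle (an expanding-flow surrogate). Movie durations are not a
constrained quantity; the default is 20 s per movie at the 4.8 Hz analysis
rate. Per-frame brightness, RMS contrast (spatial SD / spatial mean) and
motion energy are reported; motion energy is implemented as the mean
squared inter-frame luminance difference — the simplest definition that
reproduces the qualitative time course of the alternatives based on
spatiotemporal filter banks, which are out of scope.

**Movie responses.** Cluster structure is planted at the cluster level.
Each cluster owns a template trace: an RF-weighted movie drive (the
cluster's mean RF integrated against the frames), rectified, mixed with its
rectified temporal derivative according to a per-cluster transientness, and
convolved with a single-exponential calcium kernel (default τ = 0.5 s);
per-cluster gains over the four movies set movie preference, with four
clusters strongly movie-selective. Member neurons are template + smooth
Gaussian jitter. Two generator details matter and were chosen deliberately:

* *Template-shaped jitter.* The jitter amplitude follows the template
  (silent where the template is silent, vanishing near its global peak).
  The analysis normalizes each neuron's concatenated response to [0, 1];
  if jitter is left free-running, the per-neuron min/max anchors of that
  normalization fluctuate in a skewed extreme-value fashion that a
  full-covariance GMM happily carves into spurious components. Shaping the
  jitter keeps the planted within-cluster distribution Gaussian *after*
  normalization, which is the premise of the mixture model being tested.
* *Template diversification.* The separation parameter controls the
  *mean* between-template distance in units of the within-cluster SD
  (default 5, comfortably above the ≥ 4 regime in which model selection is
  expected to recover the planted count). With only four movies, two
  clusters can nonetheless draw near-duplicate gain vectors; the generator
  therefore redraws the movie gains and temporal character of any cluster
  whose template comes closer than 0.7 × the mean pairwise distance to
  another's, keeping the planted clusters pairwise distinct.

**Battery responses.** Per-neuron tuning curves generate the battery
drives: a cosine-family direction tuning whose vector-sum DSI/OSI equal the
planted values exactly on the 12-direction grid (requiring
dsi + osi ≤ 1/2; a fully selective neuron degenerates to a single-direction
response), log-Gaussian size tuning centered on the planted preferred
size, geometric habituation across the 10 looming repetitions, and
segment-wise chirp/color envelopes controlled by planted CSI/PFSI/FSI and
rebound amplitudes. Bar sweeps are separated by 1.5-s gray gaps so calcium
tails decay between directions. The sparse-noise block stores
per-presentation peak amplitudes (121 black + 121 white squares) rather
than a frame-resolved 484-s series; this keeps sessions small without
changing anything the RF stage consumes.

**Raw signal model.** Raw fluorescence is
F_raw = F₀ + F₀·drive + r·F_neuropil + drift + noise with F₀ = 1,
r = 0.7, iid Gaussian noise per repetition (default SD 0.1, a calibration
level at which gated neurons sit far above the SNR threshold and planted
DSI is recovered with rank correlation ≥ 0.9), and a slow sinusoidal
drift (amplitude 0.05). The neuropil trace is the field-mean drive plus
its own baseline and noise, so the standard correction
F_true = F_raw − 0.7·F_neuropil is exactly invertible in the noiseless
limit.

**Anatomy.** The first half of the clusters are "compact": RF centers
within an 8° disc and somata in Gaussian anatomical patches whose
same-cluster density halves at `patch_radius_um` (default 100 μm,
i.e. σ ≈ 60 μm); they also sit preferentially in the upper 100 μm.
Remaining clusters span the field. Each neuron carries a genotype label
(six mouse lines) and a functional-type label (24 types, with two dominant
types per cluster) for the breakdown and composition analyses.

### What the generator does *not* emulate

Real optics and photon shot noise, spiking and nonlinear calcium-indicator
dynamics, eye movements and locomotion, real movie content, overlapping
ROIs, and slow non-stationarities beyond a sinusoidal drift. Passing tests
therefore demonstrate that the analysis recovers structure *of the kind it
assumes*; they do not certify behavior under real-data pathologies such as
segmentation errors or strongly non-Gaussian cluster shapes.

## Preprocessing

F_true = F_raw − r·F_neuropil (r default 0.7); slow baseline removed by
subtracting the 8th-percentile value of a 15-s window centered on each
frame, with windows truncated (never padded) at trace edges — truncation
avoids fabricating data; ΔF/F = (F − F₀)/F₀ with F₀ the mean corrected
fluorescence during the pre-stimulus gray period of each block. Response
reliability per stimulus is SNR = Var_t[⟨C⟩_r] / ⟨Var_r[C]⟩_t for the
time × repetition matrix C. Degenerate conventions: identical nonconstant
repetitions give +∞ (zero noise), a constant matrix gives 0, so gating is
monotone in both limits. ROIs are kept when the diameter is 10–20 μm and
SNR > 0.35 for at least one stimulus (the "reliable for any stimulus"
reading; a per-stimulus pooling is configurable).

## Features and clustering

Trial-averaged responses to the four movies are concatenated in fixed
order and min–max normalized to [0, 1] per neuron. PCA supplies the
feature basis; the feature count is the smallest number of components
reaching 70% explained variance (a fixed count is available), and feature
weights are standardized columnwise. A Gaussian mixture with full
covariances (diagonal and others configurable) is fit for K = 2..30 with
50 restarts per K; BIC = −2 ln L + k ln n selects K, with k counted from
the covariance structure. Restarts are seeded with k-means++ draws:
with well-separated modes, purely random starts essentially never place
one component per mode at exactly the right K, which biases the BIC argmin
upward purely through under-fitting — an optimization artifact, not model
evidence. Plain random restarts remain available
(`init_params="random_from_data"`). Vanishing covariances are regularized
(1e-6 on the diagonal); hard labels are posterior argmax with ties to the
lowest component index. The cluster dendrogram uses Ward linkage on
Euclidean distances between cluster means in feature space.

## Stability

90% of neurons are resampled 100 times (1,000 available by config) and the
mixture refit at the selected K with 3 restarts per subset (the restart
count for subset refits is a free choice; 3 k-means++ restarts on
well-separated data recover the full-data optimum reliably and keep the
stage inside a minute). Per original cluster, the Jaccard similarity
(intersection/union against the best-matching subset cluster, computed on
the subset's neurons) is averaged over subsets; clusters below 0.5 count
as unstable. The displayed form of the similarity quotient in the source
material inverts the ratio (union over intersection, ≥ 1); the
intersection-over-union reading is implemented since it is the one bounded
in [0, 1] and the one on which the 0.5 rule is meaningful. The
co-association matrix is the fraction of subsets containing both neurons
of a pair in which they co-cluster (pairs never co-sampled are flagged and
excluded from averages); the between-cluster rate averages it over
cluster pairs. Cluster matching elsewhere is greedy maximum-intersection
with ties to the lower index.

## Tuning indices

Peak response = maximum of the trial-averaged ΔF/F inside the stimulus
window given by the block schedule (window edges are a package choice; the
schedule is explicit metadata). Negative peaks are rectified to zero
before index computation — the vector-sum and paired-ratio formulas
presume nonnegative weights — except RtM, which by definition keeps its
sign for motion-suppressed neurons. DSI/OSI are the normalized magnitudes
of the response-weighted circular vector sums (angle doubled for OSI).
The paired indices (HI, LSI, MSI, CSI, PFSI, FSI, SSI, BGI) all take the
form (a − b)/(a + b) with a + b = 0 flagged NaN. Chirp quantities use the
literal windows: R_low is the peak in the first 3 s of the frequency
modulation, R_high in the last 2 s, and RaFM/RaAM are the amplitudes 1.6 s
after each modulation ends minus the mean of the gray segment preceding
that modulation; no onset-latency compensation is applied. BSS is the
argmax diameter with ties to the smallest. The relative selectivity index
subtracts fixed references (RtM 0, DSI 0.15, OSI 0.15, HI 0, LSI 0, MSI 0,
CSI 0, PFSI 0.5, FSI 0, RaFM 0, RaAM 0, BSS 8, SSI 0, BGI 0,
RFS 90 deg²). The cluster SI table reports per-cluster mean RSI,
normalized by the columnwise maximum absolute value, masked where a
one-sample t-test against zero gives p ≥ .05 or is degenerate
(zero-variance or < 2 neurons). Composition analysis row-normalizes the
cluster × functional-type cross-tabulation and calibrates a chi-square
distance from the global type distribution against a permutation null
(type labels shuffled; default 1,000 permutations) — the deviation
statistic is a package choice, as no specific test is canonical here.

## Receptive fields

The 11 × 11 sparse-noise map (ON and OFF sub-maps combined by per-square
maximum; whether to fit them separately is unresolved in the source
material) is fit with a rotated elliptical Gaussian by bounded least
squares, multi-start from the map's top-3 peaks plus random perturbations
(10 starts, early exit once a start explains 99.5% of variance; centers
bounded within 10° of the grid). Width bounds keep the half-maximum area
π·2ln2·B·C at or above one grid square (25 deg²), which also guards the
degenerate single-hot-square map. A fit is *clear* when r² ≥ 0.5 — the
source text states the gate in the opposite direction in one place, but
only r² ≥ 0.5 is consistent with "clear RFs" and with the figures built on
them. RF coverage per cluster is the area of the union of half-maximum
ellipses of clear fits, rasterized at 0.5°; clusters split into compact
(< 900 deg²) and full-field groups. Coverage had no formal definition in
the source; the half-maximum union is the natural extension of the size
convention.

## Anatomy

The DRP ρ(r) = N(r)/A(r) uses same-cluster neighbor counts per annulus
(default bin width 20 μm, radius up to 300 μm) averaged over reference
cells, and annulus areas clipped to the convex hull of *all* recorded
neurons, estimated by seeded Monte-Carlo sampling (10⁴ points per
annulus). Fields with ≤ 5 neurons are excluded. The half-peak radius is
the smallest radius at or beyond the profile's peak where density falls
below half the peak — for a compact patch this is the radius at which the
patch density has decayed to half, the quantity that patch size statements
refer to. (A first-exceedance-from-zero rule would return the first bin
center for any monotonically decaying profile and carries no information
about patch size.) Depth breakdowns default to 0–100 μm vs deeper.

## Problem sizes and numerical choices

Defaults were chosen so a full default-session analysis (3,200 neurons,
K = 2..30 × 50 restarts, 100 subsamples) completes in a few minutes on one
CPU: movie surrogates at 48 × 64 px, 20 s each; EM with `max_iter` 200 and
tolerance 1e-3; subset refits with 3 restarts; DRP Monte-Carlo at 10⁴
points per annulus; coverage rasterized at 0.5°. The test suite uses
3-cluster sessions of ~100 neurons for unit-level checks and the full
default session for the end-to-end criteria. All randomness flows from
explicit seeds (`numpy.random.default_rng`); identical configs produce
byte-identical outputs.

## Known limitations

* The generator plants Gaussian within-cluster structure by construction;
  BIC's clean recovery of the planted K says nothing about K selection
  under real, non-Gaussian cluster shapes.
* Battery index recovery is exact only in the noiseless limit and up to
  calcium-kernel tail leakage between adjacent stimulus windows.
* The chirp stimulus is modeled at the response-envelope level; the 4.8 Hz
  sampling cannot represent the actual 0.5–8 Hz luminance modulation, only
  its envelope, so FSI-type indices are meaningful as orderings rather
  than absolute values.
* Composition analysis takes any externally supplied type labeling; the
  generator's 24-type labeling is a convenience, not a model of the real
  functional-type taxonomy.
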