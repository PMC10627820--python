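# Methods

## The retrieval problem

Canopy-top height (RH98: the height at which 98% of a LiDAR waveform's
energy has returned) can be measured directly only at sparse footprints
by spaceborne waveform LiDAR, while multispectral imagery is dense but
only indirectly related to vertical structure. `canopyfuse` implements a
probabilistic regression that fuses the two: a fully convolutional
network maps a multi-band image (plus cyclically encoded coordinates) to
a per-pixel Gaussian over canopy height, trained only at labelled
footprint pixels, with deep-ensemble epistemic uncertainty and
inverse-variance fusion over repeated acquisitions.

## Model

**Network.** A stem 3×3 convolution (ReLU) feeds `B` residual blocks of
depthwise-separable 3×3 convolutions; block layout is
`t = relu(sep1(x)); t = sep2(t); y = relu(x + t)`. There is no
downsampling, so output resolution equals input resolution and patches
of any size can be processed. Two independent 1×1 convolution heads read
the shared trunk: one for the mean, one for the log-variance. Predicting
log-variance keeps the optimization unconstrained while guaranteeing a
strictly positive variance after exponentiation; the log-variance is
clipped to ±8 (normalized units) with gradient masking, which is inactive
in ordinary training and only guards early divergence. The receptive-field
half-width is `1 + 2B` pixels (one per 3×3 convolution).

The deployment-scale profile is 8 blocks × 256 filters; the desk-scale
profile used throughout the tests is 2 blocks × 32 filters. The profile
changes capacity and speed only, not the algorithm.

**Coordinate encoding.** `(sin(πφ/180), sin(πλ/180), cos(πλ/180))` for
latitude φ and longitude λ. Latitude is bounded on [−90, 90] and needs a
single monotone channel; longitude is periodic and needs the sine/cosine
pair to stay continuous across the antimeridian.

**Loss.** The Gaussian negative log-likelihood
`mean_i [ (μ̂_i − y_i)² / (2σ̂²_i) + ½ log σ̂²_i ]`
is averaged over *valid label pixels only*; unlabeled pixels contribute
nothing (sparse supervision). Zero valid pixels raise an error rather
than returning a silent 0. Channels and target are standardized with
training-split statistics; the variance transforms consistently by the
squared target sd, so optimizing in normalized space is equivalent up to
an additive constant and predictions are reported in metres.

**Ensemble and fusion.** K networks (default 5 at deployment scale, 3 in
the desk-scale experiments) are trained from independent random
initializations. Each acquisition date is processed by one uniformly
drawn member (deterministic given a seed). The T per-date Gaussians at a
pixel are merged by inverse-variance weighting `p_t ∝ 1/σ̂²_t`
(renormalized over the valid, cloud-free dates at that pixel), and the
fused variance follows the weighted law of total variance:
`Var(ŷ) = Σ p_t μ̂_t² − (Σ p_t μ̂_t)² + Σ p_t σ̂²_t`. Variances are
floored at 1e−6 m² before inversion (logged) to avoid overflow; the
between-date term is clipped at round-off zero. Pixels with no valid date
are nodata.

**Imbalance correction.** Labels are binned into 1-m height intervals;
per-sample weights `q_k = sqrt(1/N_k) / Σ_j sqrt(1/N_j)` (softened
inverse frequency, normalized over nonempty bins — empty bins are
excluded rather than imputed). Fine-tuning with the weighted loss updates
*only* the mean head: the trunk and variance head are bit-identical
afterwards, which preserves the uncertainty calibration. The weight
enters as a per-sample multiplicative factor inside the loss mean, the
most literal reading of softened inverse-frequency reweighting.

## Training schedule

Adam, batch 64, base learning rate 1e−4 at deployment scale with a ×0.1
step decay at 40% and 70% of the iteration budget (the milestones are
budget fractions so the schedule shape is preserved at any scale). The
desk-scale experiments use base lr 3e−3 and 500 iterations per member
(150 for fine-tuning), sized so a full 3-member study runs on a single
CPU in minutes; at these budgets the larger learning rate is needed for
convergence, and held-out recovery (r ≈ 0.98 on synthetic scenes) shows
it is adequate. Batches sample uniformly from patches that contain at
least one valid label pixel. A non-finite loss aborts with diagnostics.

## Synthetic scenes

The simulator generates what the method assumes about real data:

* **Height field** — marginal distribution is a zero-inflated mixture
  (default: 35% bare at 0 m; otherwise 5% tall N(35, 6²) and 95% low
  N(8, 5²), clipped to [0, 60] m), which reproduces a long-tailed,
  low-vegetation-dominated height distribution. Spatial texture comes
  from a rank copula: iid mixture draws are assigned to pixels by the
  rank of Gaussian-filtered white noise (correlation length 4 px), so
  stands/clearings appear without disturbing the marginal.
* **Reflectance** — each of the 12 bands applies a monotone saturating
  link `offset + gain·(1 − exp(−h/scale))` with band-specific parameters
  (visible-like bands darken with canopy, NIR-like brighten) plus
  Gaussian sensor noise (sd 0.02 reflectance units); saturation makes
  tall canopies spectrally ambiguous, the regime the method targets.
  Acquisitions differ by noise and by spatially correlated cloud masks
  covering a configurable fraction (default 30%) of pixels per date.
* **Footprints** — the label is the maximum height over pixels whose
  centre lies within 12.5 m (25-m footprint) of the *true* centre, plus
  Gaussian label noise (default 2 m; the true label error magnitude is
  not established, so this is a free parameter), clipped at 0. The
  *reported* centre is jittered by an isotropic Gaussian (default 8 m
  per axis, RMS displacement ≈ 11 m, on the order of the 15–20 m
  geolocation uncertainty of early-release spaceborne LiDAR).
  Rasterization writes each label into the 10-m pixel containing the
  reported centre; off-grid footprints are dropped and counted, and
  pixel collisions keep the last-written label with a logged collision
  count (deterministic and auditable).
* **Scene-class zeroing** — labels whose pixel is classed bare or water
  are forced to 0 m, mirroring the scene-classification correction for
  geolocation noise.

What the simulator does **not** emulate: radiative-transfer physics,
phenology/seasonality, topographic slope effects, atmospheric residuals,
inter-band correlated noise, or geographically varying height–spectrum
relationships. Passing tests therefore demonstrate the *mechanics* of
the method (sparse-supervision optimization, uncertainty propagation,
calibration, imbalance correction) — not that the trained network
transfers to real imagery.

## Footprint harmonization of fine CHMs

1-m canopy height models are made comparable to footprint heights by a
circular max-pool (pixels whose centre distance ≤ 12 m, inclusive;
neighbourhoods clipped at the grid edge so no padding value enters the
max) with stride 1, then block aggregation to the 10-m grid. The
aggregation operator after max-pooling is not canonically fixed; block
mean is the default, with `nearest` and `max` available. The 12-m
comparison radius is deliberately distinct from the 12.5-m label-synthesis
radius — they serve different roles. Block means accumulate in row-major
order so results are bit-reproducible against a literal double-loop
computation.

## Evaluation protocols

* Point metrics RMSE/MAE/ME/NME; balanced variants computed per 5-m
  reference interval and averaged unweighted over nonempty intervals.
* Calibration: samples sorted by predicted variance (stable sort, ties
  by sample index) into K equal-count bins, remainder to the last bin;
  per-bin RMSE vs RMV; UCE weights bins by occupancy, AUCE uniformly.
* Uncertainty filtering: `fixed-fraction` drops the top fraction by
  predicted variance; `adaptive-relative` drops by relative standard
  deviation `√u / max(ŷ, 0.1 m)` — the 0.1-m floor avoids division by
  near-zero predictions over bare ground — preserving the tall end of
  the height range.

## Numerical choices and degenerate inputs

* All randomness flows from explicit seeds (NumPy `default_rng`); every
  operation is bit-reproducible on one machine.
* Channel sds are floored at 1e−6 before standardization (geo channels
  of a single scene are nearly constant).
* Windowed tile inference uses an overlap margin equal to the
  receptive-field half-width and centre-cropped stitching; interior
  equality with whole-tile inference is a tested contract (tolerance
  1e−5 m for float32 accumulation-order differences).
* Map export: height as uint8 whole metres (round-half-even, clipped to
  [0, 254], warning on clip) with 255 as the nodata sentinel in both
  bands; a lossless float32 export is available.
* Degenerate inputs: zero footprints give an empty set; an all-cloudy
  stack gives an all-nodata map with a warning; an empty catalog window
  raises; fusion with any non-positive valid variance raises.

## Problem sizes in tests and the acceptance script

The end-to-end study uses 40 scenes of 48×48 px at 10 m, 220 footprints
per scene (~4.5k usable 15×15 patches), a 3-member ensemble of the small
profile trained 500 iterations each plus 150 fine-tuning iterations, and
4 held-out scenes — chosen as the smallest study at which the imbalance
and calibration effects are clearly measurable on a single CPU. Monte
Carlo checks use 1e5–1e6 draws.

## Known limitations

* The NumPy network trains by explicit backpropagation on CPU; it is
  meant for desk-scale experiments, not for training on millions of real
  patches.
* Fusion assumes per-date predictions are conditionally independent
  given the scene; correlated member errors inflate confidence.
* Calibration of the fused product is diagnosed (UCE/AUCE) but not
  automatically re-fitted; post-hoc recalibration is left to the user.
* The equirectangular scene geo-model is adequate for 100-km scenes but
  not for continental mosaics.
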