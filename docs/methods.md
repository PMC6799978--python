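# Methods

This note documents the models, algorithms and defaults behind
`hypoquant`, the design choices made where the procedure was genuinely
open, and what the synthetic-data tests do and do not demonstrate about
real data.

## Synthetic dynamics model

The generator for calcium traces and movies (`hypoquant.synth`) is the
simplest model that simultaneously exposes the three features the
analysis code must cope with — anti-correlated slow dynamics, discrete
transients, and baseline drift:

1. **Latent states.** Per-region latents are correlated Gaussian
   processes: white noise is mixed through a factor of the target
   correlation matrix (eigendecomposition with small negative eigenvalues
   clipped at zero; matrices with eigenvalues below −1e−9 are rejected,
   naming the offending eigenvalue) and smoothed with a Gaussian kernel of
   width `latent_tau` (default 5 s), then rescaled by the kernel's L2 norm
   so the latents have unit variance. Sample correlations converge to the
   target as the recording grows; at 600 s with a 5 s timescale the
   effective sample count is a few tens, so single-run estimates scatter
   by roughly ±0.06 around the target.
2. **Events.** A Bernoulli-thinned Poisson train: per frame, an event
   occurs with probability `rate_hz/fps · max(0, 1 + gain·latent)`,
   clipped to [0, 1]. The linear link preserves most of the latent
   correlation at the event-rate level; strongly nonlinear links
   (e.g. log-linear) were rejected because they attenuate the very
   anti-correlation the tests must recover.
3. **Calcium kernel.** Single-exponential decay `exp(−t/τ)` with
   τ = `kernel_tau` = 4 s, a GCaMP6s-like phenomenology — sufficient for
   testing detection, not a biophysical model.
4. **Trace.** `baseline + c0 + c1·t + c2·t² + spike_amp·(events ⊛ kernel)
   + N(0, noise_sd²)`. Noise is additive Gaussian (not mixed
   Poisson–Gaussian) because the detection thresholds downstream are
   variance-based.

Defaults: `rate_hz` 0.05 Hz (3 events/min — the scale of per-epoch
single-ROI transient rates in this preparation), `baseline` 1.0,
`spike_amp` 0.3, `noise_sd` 0.02, no drift. Movie generation gives every
pixel of a region that region's calcium trace plus independent pixel
noise; voxel-level tests use a higher rate (0.8 Hz) because cell-sized
voxels aggregate many cells and neuropil and fluctuate continuously.

All randomness derives from one user seed through named substreams
(`substream(seed, name)`), so every product is bit-reproducible and each
generator's streams are independent of the others.

**What the generator does not emulate:** optics (the PSF is an isotropic
Gaussian; blobs are point sources), bleaching, movement artifacts,
Poisson shot noise, neuropil contamination, kinematic realism of bouts,
or the slow state-dependent baseline shifts that confound long recordings.
Passing the recovery tests therefore shows the *algorithms* are correct
and calibrated at realistic SNR, not that the pipeline is robust to every
artifact of real microscopy.

## Stained-stack quantification

**ROI means.** Arithmetic mean over mask voxels, restricted to a declared
z-slab where one exists (the cH readout uses only its most ventral
planes). Background subtraction uses the mean over a background mask and
may produce negative values, which are reported as-is. For stacks without
a registration channel the masks are drawn per-fish; voxels are averaged
directly rather than per-plane-then-across-planes (the two differ when
plane areas differ; direct averaging is the single documented convention).

**Normalisation.** Per-fish values are divided by the mean of the
continuously fed control group, making the control mean exactly 1 and the
output scale-free.

**Active-cell counting.** Four stages, mirroring a standard
stained-section workflow, all parameters in µm and converted through the
voxel size:

1. background reduction — subtract a wide Gaussian estimate of slowly
   varying background (`background_radius`, default 20 µm);
2. contrast normalisation — divide by the robust noise scale
   (1.4826·MAD) of the flattened image, optionally saturating a
   `contrast` fraction of extreme voxels (default off). An earlier
   percentile-stretch design was rejected: on signal-free images it
   amplifies pure noise into the detection range, and on sparse-signal
   images it clips the blobs it should keep;
3. adaptive threshold — keep voxels exceeding the local mean over a
   `threshold_block` window (default 25 µm) by `threshold_offset` noise
   SDs (default 6);
4. connected components (face adjacency in 3-D, 8-neighbourhood for a
   single plane) filtered to `size_range` (µm³, or µm² in 2-D).

The count is monotone non-increasing in the threshold offset in the
detection regime (offsets above the noise floor, ≳5 SDs); at offsets
inside the noise band, threshold structure can merge neighbouring
components and break monotonicity. Counting is only meaningful where
labelled cells are well separated — the procedure undercounts dense,
overlapping populations by design, which is why synthetic validation
stacks place cells at ≥10 voxels separation.

**θ ratios.** θ_A and θ_P are differences of group means (artemia −
control, paramecia − control). A difference — not a fold change — is the
only definition that works identically for intensity and count metrics
and is invariant to adding a constant to all groups. The ratio θ_A/θ_P is
reported as NaN when |θ_P| falls below a floor (default 1e−9).

**Voxelization and ICA.** Stacks are block-averaged into cubes of edge
4.7 µm by default (the "4.7 µm voxel" is read as an edge length; the
alternative volume reading is available by passing a different edge).
Fish with any unobserved voxel are excluded. Each remaining fish is
divided by its own 10th-percentile intensity (overall-brightness
normalisation), the across-fish mean is subtracted per voxel, and the
fish-by-voxel array is decomposed — each fish a signal, each voxel a
sample — by PCA to `n_pcs` (default 30) and symmetric FastICA with the
cubic ('pow3') nonlinearity to `n_ics` (default 30), via scikit-learn.
Component maps are reported as voxel z-scores, each signed so its
maximum-|z| voxel is positive (a deterministic display convention; ICA is
otherwise sign- and permutation-free). Fish loadings are the
least-squares expression of each fish's vector in the component maps.
Degenerate inputs (all fish identical after normalisation) are rejected
with a rank-deficiency error.

## Calcium-trace analysis

**Δf/f.** Two baseline definitions are offered, because the appropriate
F₀ depends on the experiment: the mean over a declared pre-stimulus epoch,
or a running 10th percentile over a 60 s window (robust to drift). The
resolved definition is recorded in the output metadata; neither is claimed
to be canonical.

**Detrending.** Least-squares quadratic fit subtracted from the trace
(time centred for conditioning). Idempotent to 1e−10; sparse transients
pass through with <5 % amplitude distortion.

**Spike detection.** The detector is a documented, parameterised choice
validated against synthetic ground truth:

- noise scale σ̂ from the 25th percentile of |first differences|, scaled
  by the half-normal quantile (σ = q₀.₂₅/(√2·Φ⁻¹(0.625))). Differencing
  removes slow structure; the low quantile keeps the estimate clean even
  when calcium tails occupy most samples (robust to ~75 % contamination),
  which the usual MAD-of-trace estimator is not;
- local maxima with height ≥ `k_mad`·σ̂ (default 4) and at least
  `min_separation_s` (default 5 s) apart. A local-prominence condition at
  half the height threshold (evaluated over a ±2·separation window)
  rejects noise ripples riding a decaying tail. Height is the primary
  criterion: a pure prominence rule either passes the full peak-to-trough
  range of noise (global prominence) or fails transients riding an
  earlier transient's tail (saddle-limited prominence);
- each detection is localised at its onset — the frame of steepest rise
  in the preceding separation window — because with a slow kernel the
  apparent maximum wanders several frames along the tail;
- amplitude = local prominence (Δf/f above the transient's own local
  baseline).

At 6× noise SD and 1 fps this recovers ≥97 % of isolated transients with
≥97 % precision, and produces no false positives on pure noise at
`k_mad` = 5 over hundreds of trace-minutes. Transients closer than the
separation window merge into single detections.

**Epoch metrics.** Σ Δf/f over epoch samples, spikes/min, and the mean
per-spike amplitude (NaN for spike-free epochs). Whether published
amplitudes are per-spike means or epoch maxima is ambiguous; per-spike
mean is implemented.

**Spike-triggered average.** Target segments aligned at trigger times,
each baseline-subtracted by its own pre-window mean; mean and SEM across
segments. Clipped triggers are dropped and counted. Pooling across fish
weights by trigger count.

**Cross-correlogram.** Zero-lag Pearson correlation between cell-sized
voxel traces (default 6 px tiles; block means, tiles under 50 % inside
the region masks dropped, majority-region labels), voxels ordered in
region blocks. Lagged correlation is out of scope.

**Rank statistic.** For each source voxel, other voxels are sorted
ascending by r (ties broken by voxel index — deterministic); for rank *n*
the fraction of source-region voxels whose *n*-th partner lies in each
target region is divided by that target's chance fraction, computed
excluding the source voxel itself (a voxel cannot be its own partner).
Un-normalised probabilities sum to 1 over targets. The permutation null
for this statistic must be computed on exchangeable voxels (e.g.
independent traces with randomly assigned labels): shuffling labels on
strongly block-structured data leaves every source voxel pointing at the
same few globally most-anti-correlated partners, so the null ratio does
not concentrate.

## Optogenetic windows

Pre window = [onset − 90 s, onset); post window = [offset,
offset + 90 s). The post window starts at pulse *offset*, not onset, so
stimulation-artifact frames are never analysed; whether published windows
abut onset or offset is a convention choice, not a data fact. Mean, sum
and max Δf/f are reported per window, pulse and ROI; clipped pulses are
excluded and counted. Each pulse is one statistical unit, with per-fish
aggregation available for sensitivity analysis.

The paired test is the Wilcoxon signed-rank: exact null for n ≤ 25
without tied |differences|; with ties, exact sign-flip enumeration up to
n = 15 (all 2ⁿ assignments); normal approximation otherwise. Zero
differences are dropped before ranking by default (Pratt's method
available); an all-zero difference vector returns p = 1 with a warning.
One-tailed tests are used only under a prior directional prediction. The
empirical type-I rate at α = 0.05 over 10⁴ null simulations (n = 20
pairs) sits within [0.04, 0.06] — the residual deviation from 0.05 is the
discreteness of the exact null.

## Behavior statistics

**Featurization.** Each bout is 22 posture measurements × 10 frames
(~167 ms at 60 Hz), concatenated frame-major into a 220-vector. The 20
tail tangent angles are successive inter-segment direction changes along
an arc-length-resampled skeleton (21 points → 20 segments); resampling
makes the angle count independent of tracker point density. The first
angle is referenced to a per-frame body axis when one is supplied,
otherwise to the first segment's own direction. Angles are signed and
wrapped to (−π, π], so the representation is invariant to rigid motions
of the frame and negates under mirror reflection. The two eye gaze
angles are appended per frame as given (signed per-eye; a
convergence-referenced variant would be a caller-side transform).

**Embedding.** Any object with a `fit_transform` contract; default t-SNE
with PCA initialisation, sample-capped perplexity and a fixed seed.

**Hunting probability.** Bouts in 3-min bins over 45 min;
p̂ = n_hunting/n with exact two-sided Clopper–Pearson intervals at 90 %.
"Hunting-related" defaults to {j-turn, pursuit, abort, strike} and is
configurable, since which types count (aborts in particular) is a
judgement call. Empty bins report NaN. Per-bin group comparisons use the
two-sided Fisher exact test. Clopper–Pearson is conservative by
construction (coverage ≥ nominal, approaching it from above as n grows);
coverage lands between 89 and 91 % for the large-n regimes the
acceptance run simulates.

**Gut fluorescence.** The per-sample background level (mean over a
background mask) is subtracted from every gut pixel; integrated and mean
above-background intensity are both reported, clipped at zero. The
integral over thousands of pixels accumulates any spatially correlated
background texture, so on noisy wide-field images the readout carries an
O(background_sd · √(effective patches) · patch area) error — exact
recovery holds only for flat backgrounds, which is what the noiseless
oracle tests use.

## Pipeline and I/O

CSV is the interchange spine (traces with a `time_s` column and a JSON
metadata sidecar; spikes, bouts, metrics as flat tables), TIFF holds
images and movies, HDF5 is an alternative movie container, JSON holds
configs, ground truth and statistics. A pipeline run writes its resolved
configuration and a structured log next to its outputs; identical
config + seed reproduces outputs bit-for-bit, and no stage mutates its
inputs.

## Problem sizes

The test suite and acceptance script run everything at desk scale:
600–1800 s traces at 1–5 fps, 60×90 px movies (600 cell-sized voxels),
10×96×96 stacks (50 per counting sweep), 40 fish × 400 voxels for ICA,
10⁴ simulations for the type-I and coverage calibrations. These sizes
give the Monte-Carlo margins the assertions need while keeping the whole
suite under a minute of compute for the statistics-heavy parts.

## Known limitations

- The spike detector is calibrated for sparse transients at ≥5× noise SD
  on detrended traces; dense event trains merge and rates saturate.
- Cell counting assumes well-separated cells; it is not a segmentation
  method for dense nuclei.
- The rank statistic's null requires exchangeability, as discussed above.
- The gut-fluorescence integral degrades with correlated background
  texture.
- ICA recovery was validated for sparse spatial sources; sources
  occupying large fractions of the field are sub-Gaussian indicators for
  which the cubic nonlinearity can return rotated mixtures.
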