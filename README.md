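# hypoquant

Quantification pipeline for antagonistic hypothalamic feeding-state
activity in larval zebrafish.

The caudal hypothalamus (cH) and the lateral hypothalamus (mLH, lLH) show
opposing activity across hunger states: cH activity is high in
food-deprived fish and collapses when feeding resumes, while LH activity
does the reverse, and the two structures anti-correlate on short
timescales during calcium imaging. `hypoquant` implements the
quantification procedures behind that kind of study, for anyone analysing
fixed-tissue activity stains, calcium imaging, optogenetic perturbations
or high-speed feeding behavior in this system:

- **stained stacks** (anti-pERK / anti-tERK): ROI mean fluorescence with
  per-sample background subtraction, normalisation to a continuously fed
  control group, adaptive-threshold active-cell counting, per-cell pERK at
  annotated points, prey-type activity-change ratios θ_A/θ_P, and the
  voxelize → normalise → FastICA map decomposition;
- **calcium traces and movies**: Δf/f = (F − F₀)/F₀, quadratic baseline
  detrending, calcium-spike detection with per-epoch metrics (Σ Δf/f,
  spikes/min, mean amplitude), spike-triggered averages, downsampling into
  cell-sized voxels, zero-lag cross-correlograms, and an anti-correlation
  rank statistic: the probability that a voxel's *n*-th most
  anti-correlated partner lies in each region, normalised by that region's
  chance (occupancy) fraction;
- **optogenetic sessions**: mean / summed / maximum Δf/f in fixed windows
  before pulse onset and after pulse offset, with one-/two-tailed Wilcoxon
  signed-rank tests treating each stimulation event as one unit;
- **feeding behavior**: 220-dimensional bout posture vectors (20 tail
  tangent angles + 2 eye gaze angles × 10 frames), a pluggable 2-D
  embedding (t-SNE by default), hunting-bout probability in 3-min bins
  with exact Clopper–Pearson 90 % CIs and per-bin Fisher exact tests, and
  background-corrected gut-fluorescence food intake;
- **synthetic data** (`hypoquant.synth`): generators for every input above
  with ground truth attached — two neural populations with anti-correlated
  latent dynamics, spike-convolved calcium kernels, drift and noise;
  stained stacks with blob-like cells on textured background; Bernoulli
  bout streams; optogenetic sessions with post-stimulus rate modulation;
  gut images with a known integrated signal.

Real imaging data is assumed registered; inter-fish registration,
atlas-based significance mapping and movie motion correction are out of
scope.

## Worked example

Simulate 30 min of anti-correlated cH/lLH activity (latent correlation
−0.8), compute Δf/f, detect lLH calcium spikes, and measure the cH
response triggered on them:

```python
import numpy as np
from hypoquant.synth import LatentModel, generate_traces
from hypoquant.traces import (compute_dff, detrend_quadratic, detect_spikes,
                              epoch_metrics, spike_triggered_average)

model = LatentModel(n_regions=2,
                    latent_corr=np.array([[1.0, -0.8], [-0.8, 1.0]]),
                    seed=7)
raw, truth = generate_traces(model, duration_s=1800, fps=1.0,
                             roi_labels=("cH", "lLH"))
dff = compute_dff(raw)

llh = detrend_quadratic(dff.trace("lLH"), dff.fps)
ch = detrend_quadratic(dff.trace("cH"), dff.fps)
spikes = detect_spikes(llh, dff.fps, roi="lLH")
print(f"lLH spikes detected: {len(spikes)} "
      f"(true events: {len(truth.event_times[1])})")

dff.epochs["baseline"] = (0.0, 300.0)
m = epoch_metrics(dff, spikes, "baseline", roi="lLH")
print(f"baseline epoch: {m.freq_per_min:.2f} spikes/min, "
      f"mean amplitude {100 * m.amplitude:.1f}% dF/F")

sta = spike_triggered_average(spikes, ch, dff.fps, window_s=(30, 60))
post = sta.lags_s > 0
print(f"cH deflection at lLH spikes: {100 * sta.mean[post].min():.1f}% dF/F "
      f"({sta.n_used} triggers)")
```

```
lLH spikes detected: 69 (true events: 91)
baseline epoch: 1.60 spikes/min, mean amplitude 29.4% dF/F
cH deflection at lLH spikes: -3.5% dF/F (67 triggers)
```

The detector reports separable transients, so clusters of events closer
than the 5 s separation window merge into single detections (69 of 91
generated events here). The negative cH deflection around lLH spikes is
the anti-correlation signature: when the lLH fires, cH activity drops
below its pre-spike baseline.

Every analysis is also a CLI invocation (`hypoquant synth`, `dff`,
`spikes`, `sta`, `xcorr`, `rankstat`, `perk-intensity`, `perk-count`,
`theta`, `ica`, `opto`, `bouts`, `gut`, `run`); `hypoquant run --config
cfg.json` executes a multi-stage pipeline reproducibly, writing the
resolved configuration and a structured log next to its outputs.

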