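"""Synthetic data generators with attached ground truth.

Every generator here emulates one of the raw data products the pipeline
consumes — calcium traces/movies from two antagonistic hypothalamic
populations, stained z-stacks with blob-like active cells, Bernoulli bout
streams with a time-varying hunting probability, optogenetic sessions with
post-stimulus rate modulation, and gut-fluorescence images with a known
ingested signal — and returns a :class:`~hypoquant.datatypes.GroundTruth`
alongside the product so that every downstream operation can be scored
without re-simulation.

The dynamics model is deliberately simple: per-region latent states are
correlated, temporally smoothed Gaussian processes; calcium events are a
Bernoulli-thinned (per frame) Poisson train whose rate is linearly
modulated by the latent; events are convolved with a single-exponential
calcium kernel; baseline drift is quadratic and noise additive Gaussian.
This is the simplest model that simultaneously exposes anti-correlation,
discrete transients and slow drift to the analysis code.

All randomness derives from a single user seed through named substreams,
so identical calls reproduce identical outputs bit-for-bit.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

from .datatypes import (
    BOUT_LABELS,
    BoutTable,
    GroundTruth,
    StainedStack,
    StimSession,
    TraceSet,
)

__all__ = [
    "LatentModel",
    "RegionSpec",
    "StackSpec",
    "generate_traces",
    "generate_movie",
    "generate_stack",
    "generate_bout_stream",
    "generate_opto_session",
    "generate_gut_image",
]


def substream(seed: int, *names: str) -> np.random.Generator:
    """A named, reproducible random substream of a single user seed."""
    keys = [int(seed)] + [zlib.crc32(n.encode()) for n in names]
    return np.random.default_rng(keys)


# --------------------------------------------------------------------------
# latent dynamics / calcium traces
# --------------------------------------------------------------------------


@dataclass
class LatentModel:
    """Generative model of correlated multi-region calcium activity.

    Parameters
    ----------
    n_regions
        Number of regions (trace channels).
    latent_corr
        Target pairwise correlation matrix of the latent states; symmetric,
        unit diagonal, positive semi-definite (eigenvalues >= -1e-9).
    rate_hz
        Baseline event rate per region (events/s); scalar or per-region.
        Default 0.05 Hz (3 events/min), the scale of single-ROI transient
        rates reported per epoch in this preparation.
    kernel_tau
        Calcium-kernel decay constant (s). Default 4 s, a GCaMP6s-like
        decay.
    latent_tau
        Temporal smoothing scale of the latent state (s); sets how long
        high-/low-activity excursions last. Default 5 s.
    rate_gain
        Linear modulation strength of the latent on the event rate:
        rate(t) = rate_hz * max(0, 1 + rate_gain * latent(t)).
    drift_coeffs
        Quadratic baseline drift ``(c0, c1, c2)``: c0 + c1*t + c2*t^2
        (intensity units, units/s, units/s^2).
    noise_sd
        Additive Gaussian noise SD (intensity units).
    baseline
        Resting fluorescence level (intensity units).
    spike_amp
        Peak fluorescence added per event (intensity units).
    seed
        User seed; all substreams derive from it.
    """

    n_regions: int = 2
    latent_corr: np.ndarray | None = None
    rate_hz: float | Sequence[float] = 0.05
    kernel_tau: float = 4.0
    latent_tau: float = 5.0
    rate_gain: float = 1.0
    drift_coeffs: tuple[float, float, float] = (0.0, 0.0, 0.0)
    noise_sd: float = 0.02
    baseline: float = 1.0
    spike_amp: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 1:
            raise ValueError("n_regions must be >= 1")
        if self.latent_corr is None:
            self.latent_corr = np.eye(self.n_regions)
        self.latent_corr = np.asarray(self.latent_corr, dtype=float)
        n = self.n_regions
        if self.latent_corr.shape != (n, n):
            raise ValueError(
                f"latent_corr must be {n}x{n}, got {self.latent_corr.shape}"
            )
        if not np.allclose(self.latent_corr, self.latent_corr.T, atol=1e-12):
            raise ValueError("latent_corr must be symmetric")
        if not np.allclose(np.diag(self.latent_corr), 1.0, atol=1e-12):
            raise ValueError("latent_corr must have unit diagonal")
        w = np.linalg.eigvalsh(self.latent_corr)
        if w.min() < -1e-9:
            raise ValueError(
                f"latent_corr is not positive semi-definite: eigenvalue {w.min():.3e}"
            )
        self.rate_hz = np.broadcast_to(
            np.asarray(self.rate_hz, dtype=float), (n,)
        ).copy()
        if np.any(self.rate_hz < 0):
            raise ValueError("rate_hz must be >= 0")
        if self.kernel_tau <= 0:
            raise ValueError("kernel_tau must be > 0")
        if self.latent_tau <= 0:
            raise ValueError("latent_tau must be > 0")

    def corr_factor(self) -> np.ndarray:
        """A factor A with A @ A.T == latent_corr (PSD-safe)."""
        w, v = np.linalg.eigh(self.latent_corr)
        return v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def _latent_traces(model: LatentModel, n_frames: int, fps: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Unit-variance correlated latents, smoothed on latent_tau."""
    white = rng.standard_normal((n_frames, model.n_regions))
    white = white @ model.corr_factor().T
    sigma = model.latent_tau * fps
    lat = ndimage.gaussian_filter1d(white, sigma, axis=0, mode="reflect")
    # restore unit variance: the L2 norm of the smoothing kernel
    impulse = np.zeros(max(n_frames, int(16 * sigma) + 1))
    impulse[impulse.size // 2] = 1.0
    norm = np.sqrt(np.sum(ndimage.gaussian_filter1d(impulse, sigma) ** 2))
    return lat / norm


def _event_matrix(model: LatentModel, latent: np.ndarray, fps: float,
                  rng: np.random.Generator,
                  rate_scale: np.ndarray | None = None) -> np.ndarray:
    """Bernoulli event indicator per (frame, region).

    ``rate_scale`` optionally multiplies the instantaneous rate per
    (frame, region) — used for optogenetic post-window modulation.
    """
    lam = model.rate_hz[None, :] * np.clip(1.0 + model.rate_gain * latent, 0.0, None)
    if rate_scale is not None:
        lam = lam * rate_scale
    p = np.clip(lam / fps, 0.0, 1.0)
    return (rng.random(latent.shape) < p).astype(float)


def _calcium(events: np.ndarray, model: LatentModel, fps: float) -> np.ndarray:
    """Exponential-kernel convolution of the event train (per region)."""
    n = events.shape[0]
    k = np.exp(-np.arange(int(np.ceil(10 * model.kernel_tau * fps)) + 1)
               / (model.kernel_tau * fps))
    out = np.empty_like(events)
    for j in range(events.shape[1]):
        out[:, j] = np.convolve(events[:, j], k)[:n]
    return model.spike_amp * out


def generate_traces(model: LatentModel, duration_s: float, fps: float,
                    roi_labels: Sequence[str] | None = None,
                    ) -> tuple[TraceSet, GroundTruth]:
    """Simulate raw fluorescence traces for ``model.n_regions`` ROIs.

    The trace is ``baseline + drift(t) + spike_amp * (events ⊛ exp kernel)
    + noise``. Returns a raw-fluorescence :class:`TraceSet`
    (``kind="raw"``) and the ground truth (latent traces, event times).
    """
    n_frames = int(round(duration_s * fps))
    if n_frames < 10:
        raise ValueError("duration_s * fps must give at least 10 samples")
    latent = _latent_traces(model, n_frames, fps, substream(model.seed, "latent"))
    events = _event_matrix(model, latent, fps, substream(model.seed, "events"))
    cal = _calcium(events, model, fps)
    t = np.arange(n_frames) / fps
    c0, c1, c2 = model.drift_coeffs
    drift = c0 + c1 * t + c2 * t ** 2
    noise = model.noise_sd * substream(model.seed, "noise").standard_normal(cal.shape)
    raw = model.baseline + drift[:, None] + cal + noise
    if roi_labels is None:
        roi_labels = tuple(f"region{i}" for i in range(model.n_regions))
    ts = TraceSet(raw, fps=fps, roi_labels=roi_labels, kind="raw",
                  meta={"model_seed": model.seed})
    gt = GroundTruth(
        event_times=[t[events[:, j] > 0] for j in range(model.n_regions)],
        latent_traces=latent,
    )
    return ts, gt


def generate_movie(model: LatentModel, duration_s: float, fps: float,
                   region_masks: dict[str, np.ndarray],
                   pixel_noise_sd: float = 0.1,
                   ) -> tuple[np.ndarray, GroundTruth]:
    """Simulate a time × y × x movie of spatially contiguous populations.

    Each pixel of region *i* carries that region's calcium trace plus
    independent pixel noise; pixels outside every mask contain noise only.
    Returns the movie and ground truth holding the per-region calcium
    traces, latents and event times.
    """
    if len(region_masks) != model.n_regions:
        raise ValueError(
            f"model has {model.n_regions} regions but {len(region_masks)} masks given"
        )
    names = list(region_masks)
    masks = [np.asarray(region_masks[n], dtype=bool) for n in names]
    shape = masks[0].shape
    if any(m.shape != shape for m in masks):
        raise ValueError("region masks must agree in shape")
    n_frames = int(round(duration_s * fps))
    latent = _latent_traces(model, n_frames, fps, substream(model.seed, "latent"))
    events = _event_matrix(model, latent, fps, substream(model.seed, "events"))
    cal = _calcium(events, model, fps)
    movie = np.zeros((n_frames,) + shape)
    for j, m in enumerate(masks):
        movie[:, m] = cal[:, j][:, None]
    movie += pixel_noise_sd * substream(model.seed, "pixels").standard_normal(movie.shape)
    t = np.arange(n_frames) / fps
    gt = GroundTruth(
        event_times=[t[events[:, j] > 0] for j in range(model.n_regions)],
        latent_traces=latent,
        extras={"region_traces": cal, "region_names": names},
    )
    return movie, gt


# --------------------------------------------------------------------------
# stained stacks
# --------------------------------------------------------------------------


@dataclass
class RegionSpec:
    """Cell population of one region in a synthetic stained stack."""

    name: str
    mask: np.ndarray
    density: float  # active cells per 1000 mask voxels
    intensity_mean: float = 3000.0
    intensity_sd: float = 300.0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.density < 0:
            raise ValueError(f"region {self.name!r}: density must be >= 0")


@dataclass
class StackSpec:
    """Recipe for a synthetic stained stack (or 2-D image).

    ``shape`` may be 3-D ``(z, y, x)`` or 2-D ``(y, x)``. Region masks must
    be pairwise disjoint. Ground-truth cell centres and intensities are
    always emitted with the image. Shapes are capped at 2**24 voxels to
    keep single stacks comfortably in memory.
    """

    shape: tuple[int, ...]
    regions: list[RegionSpec] = field(default_factory=list)
    psf_sigma: tuple[float, ...] | float = 1.5
    background_mean: float = 100.0
    background_sd: float = 5.0
    texture_sigma: float = 2.0
    min_separation: float = 10.0  # between cell centres, in voxel units
    voxel_size: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        if len(self.shape) not in (2, 3):
            raise ValueError("shape must be (z, y, x) or (y, x)")
        if int(np.prod(self.shape)) > 2 ** 24:
            raise ValueError("stack larger than the documented 2**24-voxel cap")
        if np.isscalar(self.psf_sigma):
            self.psf_sigma = (float(self.psf_sigma),) * len(self.shape)
        else:
            self.psf_sigma = tuple(float(s) for s in self.psf_sigma)
        if self.voxel_size is None:
            self.voxel_size = (1.0,) * len(self.shape)
        for r in self.regions:
            if r.mask.shape != self.shape:
                raise ValueError(f"region {r.name!r} mask shape mismatch")
        for i, a in enumerate(self.regions):
            for b in self.regions[i + 1:]:
                if np.any(a.mask & b.mask):
                    raise ValueError(f"regions {a.name!r} and {b.name!r} overlap")


def _place_centers(mask: np.ndarray, n: int, min_sep: float, margin: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Dart-throw ``n`` centres inside ``mask``, >= margin from its edge.

    Falls back (with a warning) to unconstrained placement for centres that
    cannot be placed at the requested separation.
    """
    interior = ndimage.distance_transform_edt(mask) > margin
    if not interior.any():
        interior = mask
    candidates = np.argwhere(interior)
    placed: list[np.ndarray] = []
    tries = 0
    while len(placed) < n and tries < 100 * max(n, 1):
        c = candidates[rng.integers(len(candidates))]
        if all(np.linalg.norm(c - p) >= min_sep for p in placed):
            placed.append(c)
        tries += 1
    if len(placed) < n:
        warnings.warn(
            f"could only place {len(placed)}/{n} cells at separation "
            f">= {min_sep}; remaining centres placed without the constraint",
            stacklevel=2,
        )
        while len(placed) < n:
            placed.append(candidates[rng.integers(len(candidates))])
    return np.array(placed).reshape(len(placed), mask.ndim)


def _blob_image(spec: StackSpec, centers: dict[str, np.ndarray],
                intensities: dict[str, np.ndarray],
                rng: np.random.Generator) -> np.ndarray:
    """Background texture plus PSF-blurred unit-mass blobs.

    Each cell contributes a Gaussian blob whose *integrated* intensity
    equals its ground-truth intensity (the blur kernel is normalised), so
    integral-recovery oracles are exact.
    """
    img = np.zeros(spec.shape)
    for name in centers:
        for c, a in zip(centers[name], intensities[name]):
            img[tuple(int(v) for v in c)] += a
    img = ndimage.gaussian_filter(img, sigma=spec.psf_sigma, mode="reflect")
    texture = ndimage.gaussian_filter(
        rng.standard_normal(spec.shape), spec.texture_sigma, mode="reflect"
    )
    tex_sd = texture.std()
    if tex_sd > 0 and spec.background_sd > 0:
        img += spec.background_sd * texture / tex_sd
    img += spec.background_mean
    return np.clip(img, 0.0, None)


def generate_stack(spec: StackSpec) -> tuple[StainedStack, GroundTruth]:
    """Simulate a stained stack with region-dependent active-cell densities.

    The pERK channel holds the blobs plus textured background; a tERK
    channel holds an independent background texture (so ratio-style
    normalisations have something to divide by). Cell counts per region are
    ``round(density * mask_voxels / 1000)``.
    """
    rng = substream(spec.seed, "stack")
    margin = int(np.ceil(4 * max(np.atleast_1d(spec.psf_sigma)))) + 1
    centers: dict[str, np.ndarray] = {}
    intensities: dict[str, np.ndarray] = {}
    for r in spec.regions:
        n = int(round(r.density * r.mask.sum() / 1000.0))
        centers[r.name] = _place_centers(r.mask, n, spec.min_separation, margin, rng)
        intensities[r.name] = np.clip(
            rng.normal(r.intensity_mean, r.intensity_sd, size=n), 0.0, None
        )
    perk = _blob_image(spec, centers, intensities, rng)
    terk = _blob_image(spec, {}, {}, substream(spec.seed, "terk"))
    if len(spec.shape) == 2:
        perk, terk = perk[None], terk[None]
    stack = StainedStack(
        np.stack([perk, terk]),
        channel_roles=("pERK", "tERK"),
        voxel_size=(spec.voxel_size if len(spec.voxel_size) == 3
                    else (1.0,) + tuple(spec.voxel_size)),
    )
    gt = GroundTruth(cell_centers=centers, cell_intensities=intensities)
    return stack, gt


def generate_gut_image(total_signal: float, spec: StackSpec,
                       n_deposits: int = 6) -> tuple[np.ndarray, GroundTruth]:
    """Simulate a gut-fluorescence image with a known ingested signal.

    Deposits are Gaussian blobs placed well inside the region named
    ``"gut"``; their integrated intensities sum to ``total_signal`` exactly
    (before background noise). Returns a 2-D (or 3-D, per ``spec.shape``)
    image and the ground truth.
    """
    if total_signal < 0:
        raise ValueError("total_signal must be >= 0")
    gut = next((r for r in spec.regions if r.name == "gut"), None)
    if gut is None:
        raise ValueError('spec must contain a region named "gut"')
    rng = substream(spec.seed, "gut")
    margin = int(np.ceil(4 * max(np.atleast_1d(spec.psf_sigma)))) + 1
    if total_signal == 0:
        centers = np.zeros((0, len(spec.shape)), dtype=int)
        weights = np.zeros(0)
    else:
        centers = _place_centers(gut.mask, n_deposits, spec.min_separation,
                                 margin, rng)
        weights = rng.dirichlet(np.full(len(centers), 4.0)) * total_signal
    img = _blob_image(spec, {"gut": centers}, {"gut": weights}, rng)
    gt = GroundTruth(total_signal=float(total_signal),
                     cell_centers={"gut": centers},
                     cell_intensities={"gut": weights})
    return img, gt


# --------------------------------------------------------------------------
# behavioral bout streams
# --------------------------------------------------------------------------

#: relative frequency of hunting sub-types among hunting-labelled bouts
_HUNT_MIX = {"j-turn": 0.30, "pursuit": 0.40, "abort": 0.15, "strike": 0.15}


def _bout_feature_mean(label: str, n_features: int) -> np.ndarray:
    """Deterministic label-conditioned mean posture vector.

    Hunting bouts carry elevated eye-convergence entries (the last two of
    every 22-feature frame block) and a mild tail-curvature signature;
    exploratory bouts sit near zero.
    """
    mu = np.zeros(n_features)
    if label == "exploratory":
        return mu
    per_frame = 22
    sig = substream(zlib.crc32(label.encode()), "bout-mean").normal(
        0.0, 0.3, size=n_features
    )
    mu += sig
    for f in range(n_features // per_frame):
        mu[f * per_frame + 20 : f * per_frame + 22] += 0.6  # eye convergence
    return mu


def generate_bout_stream(p_hunt: Callable[[np.ndarray], np.ndarray] | float,
                         bout_rate_hz: float, duration_s: float, seed: int = 0,
                         n_features: int = 220, fish_id: str = "fish0",
                         group: str = "") -> tuple[BoutTable, GroundTruth]:
    """Simulate a labelled bout stream with time-varying hunting probability.

    Bout times follow a homogeneous Poisson process at ``bout_rate_hz``;
    each bout is hunting-labelled with probability ``p_hunt(t)`` (callable
    or constant in [0, 1]) and otherwise ``exploratory``. Hunting bouts are
    assigned a sub-type (j-turn/pursuit/abort/strike) from a fixed mixture.
    Posture features are drawn from label-conditioned Gaussians.
    """
    if bout_rate_hz < 0:
        raise ValueError("bout_rate_hz must be >= 0")
    rng = substream(seed, "bouts")
    if bout_rate_hz == 0:
        empty = BoutTable(np.zeros(0), np.zeros((0, n_features)),
                          np.array([], dtype=object), fish_id, group)
        return empty, GroundTruth(bout_labels=np.array([], dtype=object),
                                  true_p_hunt=np.zeros(0))
    n_max = int(bout_rate_hz * duration_s + 10 * np.sqrt(bout_rate_hz * duration_s) + 10)
    gaps = rng.exponential(1.0 / bout_rate_hz, size=n_max)
    times = np.cumsum(gaps)
    times = times[times < duration_s]
    p_fun = p_hunt if callable(p_hunt) else (lambda t, p=float(p_hunt): np.full_like(t, p))
    p = np.asarray(p_fun(times), dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p_hunt must be bounded in [0, 1]")
    is_hunt = rng.random(times.size) < p
    subtypes = rng.choice(list(_HUNT_MIX), size=times.size,
                          p=list(_HUNT_MIX.values()))
    labels = np.where(is_hunt, subtypes, "exploratory").astype(object)
    feats = rng.normal(0.0, 1.0, size=(times.size, n_features))
    for lab in set(labels):
        sel = labels == lab
        feats[sel] += _bout_feature_mean(str(lab), n_features)
    table = BoutTable(times, feats, labels, fish_id, group)
    gt = GroundTruth(bout_labels=labels.copy(), true_p_hunt=p)
    return table, gt


# --------------------------------------------------------------------------
# optogenetic sessions
# --------------------------------------------------------------------------


def generate_opto_session(model: LatentModel,
                          pulses: Sequence[tuple[float, float]],
                          effect: float | Sequence[float],
                          window_s: float = 90.0,
                          fps: float = 1.0,
                          duration_s: float | None = None,
                          roi_labels: Sequence[str] | None = None,
                          ) -> tuple[StimSession, GroundTruth]:
    """Simulate a stimulation session with post-pulse rate modulation.

    Inside the ``window_s`` seconds following each pulse offset, each
    region's event rate is multiplied by its ``effect`` factor (suppression
    < 1, excitation > 1); elsewhere the base model applies. Traces are
    returned as Δf/f-like values (calcium + noise, zero baseline).

    Pre/post windows of consecutive pulses must not overlap, and every
    window must fit inside the trace.
    """
    pulses = [(float(a), float(d)) for a, d in pulses]
    if duration_s is None:
        duration_s = (pulses[-1][0] + pulses[-1][1] + window_s) if pulses else 10 * window_s
    for (a, d) in pulses:
        if a - window_s < 0 or a + d + window_s > duration_s + 1e-9:
            raise ValueError(
                f"pulse at {a} s: pre/post {window_s} s windows exceed the trace"
            )
    for (a0, d0), (a1, _) in zip(pulses, pulses[1:]):
        if a0 + d0 + window_s > a1 - window_s:
            raise ValueError(
                f"post window of pulse at {a0} s overlaps pre window of pulse at {a1} s"
            )
    effect = np.broadcast_to(np.asarray(effect, dtype=float),
                             (model.n_regions,)).copy()
    n_frames = int(round(duration_s * fps))
    t = np.arange(n_frames) / fps
    scale = np.ones((n_frames, model.n_regions))
    for (a, d) in pulses:
        in_post = (t >= a + d) & (t < a + d + window_s)
        scale[in_post] = effect[None, :]
    latent = _latent_traces(model, n_frames, fps, substream(model.seed, "latent"))
    events = _event_matrix(model, latent, fps, substream(model.seed, "events"),
                           rate_scale=scale)
    cal = _calcium(events, model, fps)
    noise = model.noise_sd * substream(model.seed, "noise").standard_normal(cal.shape)
    if roi_labels is None:
        roi_labels = tuple(f"region{i}" for i in range(model.n_regions))
    ts = TraceSet(cal + noise, fps=fps, roi_labels=roi_labels, kind="dff",
                  meta={"model_seed": model.seed})
    session = StimSession(ts, pulses, window_s=window_s)
    gt = GroundTruth(
        event_times=[t[events[:, j] > 0] for j in range(model.n_regions)],
        latent_traces=latent,
        opto_effect=effect,
    )
    return session, gt
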