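"""Quantification of stained brain stacks.

Covers the fixed-tissue activity readouts: ROI mean fluorescence with
per-sample background subtraction, normalisation of per-fish values to the
continuously fed control group, adaptive-threshold active-cell counting,
per-cell intensity extraction at annotated points, prey-type activity-change
ratios (θ_A/θ_P), and the voxelize → normalise → ICA map procedure.

Coordinates are 0-based ``(z, y, x)``; physical parameters are in µm and
converted through the stack's ``voxel_size``.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
from scipy import ndimage
from sklearn.decomposition import PCA, FastICA

from .datatypes import (
    CellCountParams,
    IcaResult,
    RoiSet,
    StainedStack,
    ThetaResult,
)

__all__ = [
    "roi_mean_intensity",
    "normalize_to_control",
    "count_active_cells",
    "perk_at_points",
    "theta_ratio",
    "voxelize",
    "run_ica",
]


def roi_mean_intensity(stack: StainedStack, rois: RoiSet, roi: str,
                       channel: str = "pERK",
                       subtract_background: bool = False,
                       background_roi: str = "background") -> float:
    """Mean channel intensity over an ROI, optionally background-corrected.

    The mean is taken over all mask voxels (restricted to the ROI's z-slab
    when one is declared — the cH readout uses only its most ventral
    planes). With ``subtract_background``, the mean over the background
    mask is subtracted; the result may be negative and is reported as-is.
    """
    vol = stack.channel(channel)
    mask = rois.effective_mask(roi)
    if mask.shape != vol.shape:
        raise ValueError(f"ROI {roi!r} mask shape {mask.shape} != stack {vol.shape}")
    value = float(vol[mask].mean())
    if subtract_background:
        bg_mask = rois.effective_mask(background_roi)
        value -= float(vol[bg_mask].mean())
    return value


def normalize_to_control(values: Sequence[float],
                         control_values: Sequence[float]) -> np.ndarray:
    """Divide per-fish values by the control-group mean.

    By construction the normalised control group has mean exactly 1. The
    control mean must be bounded away from zero.
    """
    values = np.asarray(values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if control.size == 0:
        raise ValueError("control group is empty")
    mean = control.mean()
    if abs(mean) < 1e-12:
        raise ValueError(f"control mean {mean:.3e} too close to zero to normalise by")
    return values / mean


def _to_voxels(length_um: float, voxel_size: tuple[float, ...]) -> np.ndarray:
    """Convert an isotropic physical length to per-axis voxel counts."""
    return np.asarray([length_um / v for v in voxel_size])


def cell_segmentation_mask(stack: StainedStack, params: CellCountParams,
                           channel: str = "pERK") -> np.ndarray:
    """Binary mask of strongly stained cells (the thresholding stages).

    1. background reduction: subtract a wide Gaussian estimate of slowly
       varying background (scale ``background_radius`` µm);
    2. contrast normalisation: divide by the robust (MAD-based) noise
       scale, optionally saturating a ``contrast`` fraction of extreme
       voxels;
    3. adaptive threshold: voxel kept where its value exceeds the local
       mean over a ``threshold_block`` µm window by ``threshold_offset``
       noise SDs.
    """
    vol = stack.channel(channel)
    squeeze = vol.shape[0] == 1  # single plane: work in 2-D
    img = vol[0] if squeeze else vol
    vsize = stack.voxel_size[1:] if squeeze else stack.voxel_size

    bg_sigma = _to_voxels(params.background_radius, vsize)
    if np.any(bg_sigma < 1):
        raise ValueError(
            f"background_radius {params.background_radius} µm is below one "
            f"voxel ({stack.voxel_size} µm) on some axis"
        )
    flat = img - ndimage.gaussian_filter(img, sigma=bg_sigma)

    scale = 1.4826 * np.median(np.abs(flat - np.median(flat)))
    if scale <= 0:
        return np.zeros(vol.shape, dtype=bool)
    z = flat / scale
    if params.contrast > 0:
        lo, hi = np.quantile(z, [params.contrast, 1.0 - params.contrast])
        z = np.clip(z, lo, hi)

    block = np.maximum(_to_voxels(params.threshold_block, vsize), 1.0)
    local_mean = ndimage.uniform_filter(z, size=tuple(
        int(round(b)) | 1 for b in block))  # odd window
    binary = z > local_mean + params.threshold_offset
    return binary[None] if squeeze else binary


def count_active_cells(stack: StainedStack, rois: RoiSet, roi: str,
                       params: CellCountParams | None = None,
                       channel: str = "pERK",
                       ) -> tuple[int, list[dict]]:
    """Count strongly stained cells inside an ROI.

    Connected components of the adaptive-threshold mask, restricted to the
    ROI, are filtered to ``params.size_range`` (physical area µm² for
    single-plane stacks, volume µm³ otherwise). Returns the count and a
    list of objects with 0-based ``(z, y, x)`` centroids and physical
    sizes. Reliable only where labelled cells are well separated.
    """
    if params is None:
        params = CellCountParams()
    binary = cell_segmentation_mask(stack, params, channel)
    mask = rois.effective_mask(roi)
    binary = binary & mask
    squeeze = binary.shape[0] == 1
    work = binary[0] if squeeze else binary
    if squeeze:
        # single-plane default: 8-neighbourhood
        structure = ndimage.generate_binary_structure(2, 2)
        voxel_measure = stack.voxel_size[1] * stack.voxel_size[2]
    else:
        structure = ndimage.generate_binary_structure(3, params.connectivity)
        voxel_measure = float(np.prod(stack.voxel_size))
    labels, n = ndimage.label(work, structure=structure)
    objects: list[dict] = []
    if n:
        sizes = ndimage.sum_labels(np.ones_like(work, dtype=float), labels,
                                   index=np.arange(1, n + 1)) * voxel_measure
        centroids = ndimage.center_of_mass(work, labels, np.arange(1, n + 1))
        lo, hi = params.size_range
        for size, c in zip(sizes, centroids):
            if lo <= size <= hi:
                zyx = (0.0,) + tuple(c) if squeeze else tuple(c)
                objects.append({"centroid_zyx": zyx, "size": float(size)})
    return len(objects), objects


def perk_at_points(stack: StainedStack, points: Sequence[Sequence[float]],
                   radius_um: float, channel: str = "pERK") -> np.ndarray:
    """Mean channel intensity in a sphere around each annotated point.

    The sphere respects anisotropic voxel size; ``radius_um -> 0`` returns
    the voxel value at each point. Points are 0-based ``(z, y, x)``.
    """
    vol = stack.channel(channel)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[1] != 3:
        raise ValueError("points must be (z, y, x) triples")
    oob = [i for i, p in enumerate(pts)
           if np.any(p < 0) or np.any(p > np.asarray(vol.shape) - 1)]
    if oob:
        raise ValueError(f"points out of bounds at indices {oob}")
    vs = np.asarray(stack.voxel_size)
    half = np.floor(radius_um / vs).astype(int)
    offs = np.mgrid[tuple(slice(-h, h + 1) for h in half)].reshape(3, -1).T
    offs = offs[np.sum((offs * vs) ** 2, axis=1) <= radius_um ** 2 + 1e-12]
    if offs.size == 0:
        offs = np.zeros((1, 3), dtype=int)
    out = np.empty(len(pts))
    for i, p in enumerate(pts):
        idx = np.round(p).astype(int) + offs
        keep = np.all((idx >= 0) & (idx < np.asarray(vol.shape)), axis=1)
        sel = idx[keep]
        out[i] = vol[sel[:, 0], sel[:, 1], sel[:, 2]].mean()
    return out


def theta_ratio(metric_artemia: Sequence[float],
                metric_control: Sequence[float],
                metric_paramecia: Sequence[float],
                floor: float = 1e-9) -> ThetaResult:
    """Prey-type activity changes relative to the unfed control.

    θ_A and θ_P are differences of group means (artemia − control and
    paramecia − control); the ratio θ_A/θ_P separates prey-detection from
    prey-ingestion responses and is NaN when |θ_P| < ``floor``. Works for
    either normalised-intensity or active-cell-count metrics, and is
    invariant to adding a constant to all three groups.
    """
    groups = [np.asarray(g, dtype=float) for g in
              (metric_artemia, metric_control, metric_paramecia)]
    if any(g.size == 0 for g in groups):
        raise ValueError("all three groups must be nonempty")
    theta_a = float(groups[0].mean() - groups[1].mean())
    theta_p = float(groups[2].mean() - groups[1].mean())
    if abs(theta_p) < floor:
        ratio = float("nan")
    else:
        ratio = theta_a / theta_p
    return ThetaResult(theta_a=theta_a, theta_p=theta_p, ratio=ratio, floor=floor)


def voxelize(stack: StainedStack, rois: RoiSet | None, voxel_edge_um: float,
             channel: str = "pERK",
             ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Downsample a stack into cubes of edge ``voxel_edge_um`` (block means).

    Returns ``(vector, coverage, coords)`` where ``vector`` holds the mean
    intensity of each downsampled cell, flattened in C order over the
    downsampled ``(z, y, x)`` grid, ``coverage`` is True where the block is
    fully inside the union of the supplied ROI masks (all True when
    ``rois`` is None), and ``coords`` gives each block's origin in native
    voxels. Trailing partial blocks are dropped.
    """
    vol = stack.channel(channel)
    factors = tuple(max(1, int(round(voxel_edge_um / v)))
                    for v in stack.voxel_size)
    if any(voxel_edge_um < v - 1e-9 for v in stack.voxel_size):
        raise ValueError(
            f"voxel_edge {voxel_edge_um} µm below native voxel size {stack.voxel_size}"
        )
    trimmed = tuple(s - s % f for s, f in zip(vol.shape, factors))
    v = vol[: trimmed[0], : trimmed[1], : trimmed[2]]
    blocks = tuple(t // f for t, f in zip(trimmed, factors))
    v = v.reshape(blocks[0], factors[0], blocks[1], factors[1],
                  blocks[2], factors[2])
    vector = v.mean(axis=(1, 3, 5)).ravel()
    if rois is None:
        coverage = np.ones(vector.size, dtype=bool)
    else:
        union = np.zeros(vol.shape, dtype=bool)
        for name in rois.masks:
            union |= rois.effective_mask(name)
        u = union[: trimmed[0], : trimmed[1], : trimmed[2]].reshape(v.shape)
        coverage = u.all(axis=(1, 3, 5)).ravel()
    zz, yy, xx = np.meshgrid(*[np.arange(b) * f for b, f in zip(blocks, factors)],
                             indexing="ij")
    coords = np.stack([zz.ravel(), yy.ravel(), xx.ravel()], axis=1)
    return vector, coverage, coords


def run_ica(vectors: np.ndarray, coverage: np.ndarray | None = None,
            n_pcs: int = 30, n_ics: int = 30, seed: int = 0,
            max_iter: int = 1000) -> IcaResult:
    """Spatially independent components of per-fish voxel vectors.

    Fish with any unobserved voxel (``coverage`` False anywhere) are
    excluded. Each kept fish is normalised for overall brightness by its
    own 10th-percentile intensity, then the across-fish mean is subtracted
    per voxel. The fish-by-voxel array is decomposed — each fish a signal,
    each voxel a sample — by PCA to ``n_pcs`` followed by symmetric FastICA
    with the cubic nonlinearity, yielding ``n_ics`` component maps reported
    as voxel z-scores (signed so each map's maximum-|z| voxel is positive).
    """
    X = np.asarray(vectors, dtype=float)
    if X.ndim != 2:
        raise ValueError("vectors must be a fish × voxel matrix")
    n_fish, n_vox = X.shape
    if coverage is None:
        coverage = np.ones_like(X, dtype=bool)
    coverage = np.asarray(coverage, dtype=bool)
    if coverage.shape != X.shape:
        raise ValueError("coverage must match vectors in shape")
    kept = np.flatnonzero(coverage.all(axis=1))
    if kept.size <= n_pcs:
        raise ValueError(
            f"only {kept.size} fully covered fish for n_pcs={n_pcs}; "
            f"ICA needs more fish than principal components"
        )
    Xk = X[kept]
    p10 = np.percentile(Xk, 10.0, axis=1, keepdims=True)
    if np.any(p10 <= 0):
        raise ValueError("10th-percentile brightness <= 0 for some fish")
    Xk = Xk / p10
    Xk = Xk - Xk.mean(axis=0, keepdims=True)
    if float(np.abs(Xk).max(initial=0.0)) < 1e-12:
        raise ValueError(
            "voxel matrix is rank-deficient after normalisation "
            "(all fish identical); no components to extract"
        )
    n_pcs_eff = min(n_pcs, kept.size - 1, n_vox)
    n_ics_eff = min(n_ics, n_pcs_eff)
    # samples = voxels, signals = fish
    data = Xk.T  # (n_voxels, n_fish)
    if n_pcs_eff < min(data.shape):
        data = PCA(n_components=n_pcs_eff, random_state=seed).fit_transform(data)
    ica = FastICA(n_components=n_ics_eff, algorithm="parallel", fun="cube",
                  whiten="unit-variance", max_iter=max_iter,
                  random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence warnings on tiny fixtures
        sources = ica.fit_transform(data)  # (n_voxels, n_ics)
    maps = sources.T
    sd = maps.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    maps = (maps - maps.mean(axis=1, keepdims=True)) / sd
    flip = np.sign(maps[np.arange(maps.shape[0]),
                        np.argmax(np.abs(maps), axis=1)])
    flip[flip == 0] = 1.0
    maps = maps * flip[:, None]
    # fish loadings: least-squares expression of each fish in the IC maps
    loadings, *_ = np.linalg.lstsq(sources * flip[None, :], Xk.T, rcond=None)
    loadings = loadings.T  # (fish, n_ics)
    return IcaResult(components=maps, fish_loadings=loadings,
                     kept_fish=kept, n_pcs=n_pcs_eff, n_ics=n_ics_eff)
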