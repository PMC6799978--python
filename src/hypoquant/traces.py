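"""Calcium-trace analysis.

Δf/f computation, quadratic baseline detrending, calcium-spike detection
and per-epoch metrics, left/right lobe averaging, spike-triggered averages,
movie downsampling into cell-sized voxels, zero-lag cross-correlograms, and
the anti-correlation rank-enrichment statistic.

Δf/f is stored as a dimensionless fraction throughout; multiply by 100 for
the percentage scale used in figures.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .datatypes import CorrMap, DffParams, SpikeTrain, TraceSet

__all__ = [
    "compute_dff",
    "detrend_quadratic",
    "detect_spikes",
    "epoch_metrics",
    "average_sides",
    "spike_triggered_average",
    "downsample_movie",
    "crosscorrelogram",
    "anticorr_rank_stat",
    "EpochMetrics",
    "StaResult",
]


def compute_dff(raw: TraceSet | np.ndarray, params: DffParams | None = None,
                fps: float | None = None,
                roi_labels: tuple[str, ...] | None = None,
                events: dict | None = None,
                epochs: dict | None = None) -> TraceSet:
    """Δf/f = (F − F0)/F0 with a declared baseline definition.

    ``raw`` may be a raw-fluorescence :class:`TraceSet` or a plain
    time × ROI array (then ``fps`` is required). The baseline is either the
    mean over a named epoch (``epoch_mean``) or a per-frame running
    percentile (``running_percentile``); the resolved definition is
    recorded in the output metadata. F0 must be positive for every ROI.
    """
    if params is None:
        params = DffParams()
    if isinstance(raw, TraceSet):
        values, fps = raw.values, raw.fps
        roi_labels = roi_labels or raw.roi_labels
        events = events if events is not None else dict(raw.events)
        epochs = epochs if epochs is not None else dict(raw.epochs)
    else:
        values = np.atleast_2d(np.asarray(raw, dtype=float))
        if fps is None:
            raise ValueError("fps is required when raw is a plain array")
        roi_labels = roi_labels or tuple(f"roi{i}" for i in range(values.shape[1]))
        events = events or {}
        epochs = epochs or {}
    if not np.all(np.isfinite(values)):
        raise ValueError("raw traces must be finite")

    if params.f0_mode == "epoch_mean":
        if params.f0_epoch not in epochs:
            raise ValueError(
                f"f0 epoch {params.f0_epoch!r} not declared (has {sorted(epochs)})"
            )
        a, b = epochs[params.f0_epoch]
        sel = slice(int(np.floor(a * fps)), int(np.ceil(b * fps)))
        f0 = values[sel].mean(axis=0, keepdims=True)
    else:
        win = int(round(params.f0_window_s * fps))
        if win < 10:
            raise ValueError(
                f"f0 window of {params.f0_window_s} s at {fps} fps is below 10 samples"
            )
        f0 = ndimage.percentile_filter(
            values, params.f0_percentile, size=(win, 1), mode="nearest"
        )
    bad = np.flatnonzero(np.min(np.atleast_2d(f0), axis=0) <= 0)
    if bad.size:
        names = [roi_labels[i] for i in bad]
        raise ValueError(f"non-positive f0 for ROI(s) {names}")
    dff = (values - f0) / f0
    return TraceSet(dff, fps=fps, roi_labels=roi_labels, events=events,
                    epochs=epochs, kind="dff",
                    meta={"f0_mode": params.f0_mode,
                          "f0_percentile": params.f0_percentile,
                          "f0_window_s": params.f0_window_s,
                          "f0_epoch": params.f0_epoch})


def detrend_quadratic(trace: np.ndarray, fps: float = 1.0) -> np.ndarray:
    """Subtract a least-squares quadratic baseline from a trace.

    Removes slow drift while preserving sparse transients; refitting a
    quadratic to the output gives coefficients ≈ 0 (idempotence).
    """
    y = np.asarray(trace, dtype=float)
    if y.ndim != 1:
        raise ValueError("detrend_quadratic expects a single 1-D trace")
    if y.size < 3:
        raise ValueError("need at least 3 samples to fit a quadratic")
    t = np.arange(y.size) / fps
    t = t - t.mean()  # centre for conditioning
    coeffs = np.polynomial.polynomial.polyfit(t, y, 2)
    return y - np.polynomial.polynomial.polyval(t, coeffs)


def noise_scale_mad(trace: np.ndarray) -> float:
    """Robust noise SD estimate: scaled median absolute deviation."""
    y = np.asarray(trace, dtype=float)
    return float(1.4826 * np.median(np.abs(y - np.median(y))))


def noise_scale_diff(trace: np.ndarray, quantile: float = 0.25) -> float:
    """Noise SD from a low quantile of absolute first differences.

    Differencing removes slow structure (drift); taking a low quantile of
    |Δy| instead of the median keeps the estimate clean even when calcium
    tails occupy a large fraction of the samples (robust to ~75 %
    contamination at the default). For white noise, |Δy| is half-normal
    with scale σ√2, so σ = q_p(|Δy|) / (√2 Φ⁻¹((1+p)/2)).
    """
    y = np.asarray(trace, dtype=float)
    if y.size < 2:
        return 0.0
    from scipy.stats import norm

    q = float(np.quantile(np.abs(np.diff(y)), quantile))
    return q / (np.sqrt(2.0) * norm.ppf((1.0 + quantile) / 2.0))


def detect_spikes(trace: np.ndarray, fps: float, k_mad: float = 4.0,
                  min_separation_s: float = 5.0, smooth_s: float = 0.0,
                  roi: str = "", detrended: bool = True) -> SpikeTrain:
    """Detect calcium transients as prominent local maxima.

    The trace (assumed baseline-detrended; pass ``detrended=False`` to have
    :func:`detrend_quadratic` applied first) is lightly boxcar-smoothed
    over ``smooth_s`` seconds; the noise scale is estimated robustly from
    the MAD of the unsmoothed trace's first differences (insensitive to
    the transients themselves) and rescaled to the smoothed domain. Local
    maxima are kept when both their height and their prominence exceed
    ``k_mad`` times that scale, with at least ``min_separation_s`` between
    peaks; the height condition keeps peak-to-trough noise excursions from
    qualifying on prominence alone. The reported amplitude is the peak
    prominence (Δf/f above the local baseline).
    """
    y = np.asarray(trace, dtype=float)
    if y.ndim != 1:
        raise ValueError("detect_spikes expects a single 1-D trace")
    min_sep = max(1, int(round(min_separation_s * fps)))
    if y.size <= min_sep:
        raise ValueError(
            f"trace of {y.size} samples shorter than the separation window "
            f"({min_sep} samples)"
        )
    if not detrended:
        y = detrend_quadratic(y, fps)
    sigma_raw = noise_scale_diff(y)
    win = max(1, int(round(smooth_s * fps)))
    if win > 1:
        y = ndimage.uniform_filter1d(y, size=win, mode="nearest")
    sigma = sigma_raw / np.sqrt(win)
    if sigma == 0:
        sigma = float(np.std(y))
    if sigma == 0:
        return SpikeTrain(np.zeros(0), np.zeros(0), roi)
    # the height threshold is primary; prominence (evaluated over a local
    # wlen window, against the transient's own local baseline rather than
    # an inter-spike saddle) only rejects ripples riding a decaying tail
    peaks, props = signal.find_peaks(y, height=k_mad * sigma,
                                     prominence=0.5 * k_mad * sigma,
                                     distance=min_sep,
                                     wlen=4 * min_sep + 1)
    # localise each transient at its onset: with a slow decay kernel the
    # apparent maximum wanders a few frames along the tail, while the
    # steepest rise pins the event frame
    dy = np.diff(y, prepend=y[0])
    times = np.empty(peaks.size, dtype=float)
    prev = 0
    for i, p in enumerate(peaks):
        w0 = max(prev + 1, p - min_sep + 1, 1)
        onset = w0 + int(np.argmax(dy[w0: p + 1])) if w0 <= p else p
        times[i] = onset / fps
        prev = p
    return SpikeTrain(times, props["prominences"], roi)


@dataclass
class EpochMetrics:
    """Per-epoch activity metrics for one ROI."""

    sum_dff: float  # Σ Δf/f over epoch samples (fraction · samples)
    freq_per_min: float  # spikes/min
    amplitude: float  # mean in-epoch spike amplitude (fraction); NaN if none
    n_spikes: int


def epoch_metrics(ts: TraceSet, spikes: SpikeTrain, epoch: str,
                  roi: str | None = None) -> EpochMetrics:
    """Integrated Δf/f, spike frequency and mean spike amplitude per epoch.

    ``freq`` is the in-epoch spike count divided by the epoch length in
    minutes; ``amplitude`` is reported as NaN when the epoch holds no
    spikes.
    """
    if epoch not in ts.epochs:
        raise ValueError(f"epoch {epoch!r} not declared (has {sorted(ts.epochs)})")
    a, b = ts.epochs[epoch]
    if b <= a:
        raise ValueError(f"epoch {epoch!r} has non-positive length")
    roi = roi or spikes.roi or ts.roi_labels[0]
    trace = ts.trace(roi)
    t = ts.times
    in_epoch = (t >= a) & (t < b)
    sum_dff = float(trace[in_epoch].sum())
    sel = (spikes.times >= a) & (spikes.times < b)
    n = int(sel.sum())
    freq = n / ((b - a) / 60.0)
    amp = float(spikes.amplitudes[sel].mean()) if n else float("nan")
    return EpochMetrics(sum_dff=sum_dff, freq_per_min=freq, amplitude=amp,
                        n_spikes=n)


_SIDE_RE = re.compile(r"(?:^|[_\-\s])(left|right|l|r)(?:[_\-\s]|$)", re.IGNORECASE)


def _split_side(label: str) -> tuple[str, str | None]:
    """Split an ROI label into (region, side); side None when absent."""
    m = _SIDE_RE.search(label)
    if not m:
        return label, None
    side = "left" if m.group(1).lower().startswith("l") else "right"
    region = (label[: m.start()] + label[m.end():]).strip("_- ")
    return region, side


def average_sides(ts: TraceSet) -> TraceSet:
    """Average paired left/right lobe traces per region.

    Labels carry the side as a ``left``/``right`` (or ``L``/``R``) token,
    e.g. ``"cH_left"``. Unpaired labels pass through unchanged with a
    warning.
    """
    groups: dict[str, dict[str, int]] = {}
    for i, lab in enumerate(ts.roi_labels):
        region, side = _split_side(lab)
        groups.setdefault(region, {})[side or lab] = i
    cols, labels = [], []
    for region, members in groups.items():
        if set(members) == {"left", "right"}:
            cols.append((ts.values[:, members["left"]]
                         + ts.values[:, members["right"]]) / 2.0)
            labels.append(region)
        else:
            for key, i in members.items():
                warnings.warn(f"ROI {ts.roi_labels[i]!r} has no left/right "
                              "partner; passed through unaveraged", stacklevel=2)
                cols.append(ts.values[:, i])
                labels.append(ts.roi_labels[i])
    return TraceSet(np.column_stack(cols), fps=ts.fps, roi_labels=tuple(labels),
                    events=dict(ts.events), epochs=dict(ts.epochs),
                    kind=ts.kind, meta=dict(ts.meta))


@dataclass
class StaResult:
    """Spike-triggered average of a target trace."""

    lags_s: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n_used: int
    n_dropped: int


def spike_triggered_average(trigger: SpikeTrain, target: np.ndarray,
                            fps: float, window_s: tuple[float, float] = (30.0, 60.0),
                            ) -> StaResult:
    """Average of target segments aligned at trigger spike times.

    Each segment spans ``window_s = (pre, post)`` seconds around its
    trigger and is baseline-subtracted by its own pre-window mean, so the
    result reads as the mean deflection relative to the pre-spike level.
    Triggers whose window would clip the trace are dropped and counted.
    """
    y = np.asarray(target, dtype=float)
    pre, post = window_s
    n_pre, n_post = int(round(pre * fps)), int(round(post * fps))
    if n_pre < 1 or n_post < 1:
        raise ValueError("window_s must give at least one sample on each side")
    idx = np.round(trigger.times * fps).astype(int)
    ok = (idx - n_pre >= 0) & (idx + n_post < y.size)
    n_dropped = int((~ok).sum())
    idx = idx[ok]
    if idx.size == 0:
        raise ValueError("no trigger has its full window inside the trace")
    segs = np.stack([y[i - n_pre : i + n_post + 1] for i in idx])
    segs = segs - segs[:, :n_pre].mean(axis=1, keepdims=True)
    mean = segs.mean(axis=0)
    sem = (segs.std(axis=0, ddof=1) / np.sqrt(segs.shape[0])
           if segs.shape[0] > 1 else np.full(mean.shape, np.nan))
    lags = (np.arange(-n_pre, n_post + 1)) / fps
    return StaResult(lags_s=lags, mean=mean, sem=sem, n_used=int(idx.size),
                     n_dropped=n_dropped)


def downsample_movie(movie: np.ndarray, cell_size_px: int,
                     region_masks: dict[str, np.ndarray] | None = None,
                     min_fill: float = 0.5,
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Block-average a time × y × x movie into cell-sized voxels.

    Tiles of ``cell_size_px`` × ``cell_size_px`` pixels are averaged per
    frame; trailing partial tiles are dropped. When ``region_masks`` are
    supplied, tiles with less than ``min_fill`` of their pixels inside the
    union of masks are discarded and each kept tile is labelled with the
    region contributing most pixels. Returns ``(voxel_traces, labels,
    coords)`` with ``voxel_traces`` time × voxel and ``coords`` the (y, x)
    tile origins.
    """
    m = np.asarray(movie, dtype=float)
    if m.ndim != 3:
        raise ValueError("movie must be time × y × x")
    if cell_size_px < 1:
        raise ValueError("cell_size_px must be >= 1")
    c = int(cell_size_px)
    T, Y, X = m.shape
    ny, nx = Y // c, X // c
    m = m[:, : ny * c, : nx * c].reshape(T, ny, c, nx, c)
    traces = m.mean(axis=(2, 4)).reshape(T, ny * nx)
    yy, xx = np.meshgrid(np.arange(ny) * c, np.arange(nx) * c, indexing="ij")
    coords = np.stack([yy.ravel(), xx.ravel()], axis=1)
    if region_masks is None:
        labels = np.array([""] * (ny * nx), dtype=object)
        return traces, labels, coords
    fills = {}
    for name, mask in region_masks.items():
        mm = np.asarray(mask, dtype=bool)[: ny * c, : nx * c]
        fills[name] = mm.reshape(ny, c, nx, c).mean(axis=(1, 3)).ravel()
    names = list(fills)
    fill_mat = np.stack([fills[n] for n in names])  # region × tile
    total = fill_mat.sum(axis=0)
    keep = total >= min_fill
    labels = np.array([names[i] for i in np.argmax(fill_mat, axis=0)],
                      dtype=object)
    return traces[:, keep], labels[keep], coords[keep]


def crosscorrelogram(voxel_traces: np.ndarray, labels: np.ndarray,
                     coords: np.ndarray | None = None) -> CorrMap:
    """Zero-lag Pearson correlation matrix between voxel Δf/f traces.

    Voxels are reordered into contiguous region blocks (stable within a
    region). Zero-variance voxels are dropped with a warning.
    """
    X = np.asarray(voxel_traces, dtype=float)
    labels = np.asarray(labels)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a time × voxel matrix with >= 2 voxels")
    if X.shape[0] < 10:
        raise ValueError("need at least 10 timepoints")
    if labels.shape != (X.shape[1],):
        raise ValueError("one label per voxel required")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        warnings.warn(f"dropping {int((sd == 0).sum())} zero-variance voxel(s)",
                      stacklevel=2)
        keep = sd > 0
        X, labels = X[:, keep], labels[keep]
        if coords is not None:
            coords = np.asarray(coords)[keep]
    order = np.argsort(labels, kind="stable")
    X, labels = X[:, order], labels[order]
    if coords is not None:
        coords = np.asarray(coords)[order]
    r = np.corrcoef(X.T)
    np.fill_diagonal(r, 1.0)
    return CorrMap(r=r, voxel_labels=labels, voxel_coords=coords)


def anticorr_rank_stat(cmap: CorrMap, max_rank: int = 5) -> pd.DataFrame:
    """Region enrichment of each voxel's most anti-correlated partners.

    For each source voxel, the other voxels are sorted ascending by
    correlation (ties broken by voxel index). For rank *n*, the fraction of
    source-region voxels whose *n*-th most anti-correlated partner lies in
    each target region is divided by that region's chance fraction — its
    share of all voxels excluding the source voxel itself. A ratio of 1
    means no enrichment over region occupancy.

    Returns a tidy frame with columns ``source``, ``target``, ``rank``,
    ``prob``, ``chance``, ``ratio``.
    """
    r = cmap.r
    labels = cmap.voxel_labels
    n_vox = r.shape[0]
    regions = sorted(set(labels.tolist()))
    if len(regions) < 2:
        raise ValueError("rank statistic needs at least 2 regions")
    if not 1 <= max_rank < n_vox:
        raise ValueError(f"max_rank must be in [1, {n_vox - 1})")
    counts = {reg: int(np.sum(labels == reg)) for reg in regions}
    # partner ranking per source voxel: ascending r, self excluded,
    # ties broken deterministically by voxel index (lexsort's second key)
    rows = []
    partner_region = np.empty((n_vox, max_rank), dtype=object)
    for i in range(n_vox):
        order = np.lexsort((np.arange(n_vox), r[i]))
        order = order[order != i][:max_rank]
        partner_region[i] = labels[order]
    for src in regions:
        src_idx = np.flatnonzero(labels == src)
        for rank in range(1, max_rank + 1):
            partners = partner_region[src_idx, rank - 1]
            for tgt in regions:
                chance = (counts[tgt] - (tgt == src)) / (n_vox - 1)
                prob = float(np.mean(partners == tgt))
                rows.append({"source": src, "target": tgt, "rank": rank,
                             "prob": prob, "chance": chance,
                             "ratio": prob / chance if chance > 0 else np.nan})
    return pd.DataFrame(rows)
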