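"""Core data containers shared across the pipeline.

Conventions used throughout the package:

* image axes are ``(z, y, x)`` (or ``(channel, z, y, x)`` for multi-channel
  stacks) and coordinates are 0-based voxel indices in ``(z, y, x)`` order;
* physical lengths are micrometres, converted through ``voxel_size``;
* Δf/f is stored as a dimensionless fraction (multiply by 100 for %);
* times are seconds from the start of the recording.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StainedStack",
    "RoiSet",
    "TraceSet",
    "SpikeTrain",
    "DffParams",
    "CellCountParams",
    "ThetaResult",
    "IcaResult",
    "CorrMap",
    "StimSession",
    "BoutTable",
    "BinStats",
    "GroundTruth",
]


@dataclass
class StainedStack:
    """A registered multi-channel intensity volume.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, nz, ny, nx)`` with finite,
        non-negative intensities.
    channel_roles
        One unique role name per channel, e.g. ``("pERK", "tERK")``.
    voxel_size
        Physical voxel size ``(z, y, x)`` in µm.
    """

    data: np.ndarray
    channel_roles: tuple[str, ...]
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(
                f"stack data must be (channel, z, y, x); got shape {self.data.shape}"
            )
        self.channel_roles = tuple(self.channel_roles)
        if len(self.channel_roles) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_roles)} channel roles for "
                f"{self.data.shape[0]} channels"
            )
        if len(set(self.channel_roles)) != len(self.channel_roles):
            raise ValueError(f"channel roles not unique: {self.channel_roles}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("stack intensities must be finite")
        if np.any(self.data < 0):
            raise ValueError("stack intensities must be >= 0")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be 3 positive lengths, got {self.voxel_size}")

    @property
    def shape(self) -> tuple[int, int, int]:
        """Spatial shape ``(nz, ny, nx)``."""
        return self.data.shape[1:]

    def channel(self, role: str) -> np.ndarray:
        """Return the ``(z, y, x)`` volume for a channel role."""
        try:
            idx = self.channel_roles.index(role)
        except ValueError:
            raise KeyError(
                f"channel role {role!r} not in stack (has {self.channel_roles})"
            ) from None
        return self.data[idx]


@dataclass
class RoiSet:
    """Named boolean voxel masks over a stack, with optional z-slabs.

    ``z_range`` entries are inclusive ``(z_lo, z_hi)`` bounds restricting a
    mask to a slab (the caudal-hypothalamus ROI, for instance, is analysed
    only over its most ventral planes).
    """

    masks: dict[str, np.ndarray]
    z_range: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.masks = {name: np.asarray(m, dtype=bool) for name, m in self.masks.items()}
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise ValueError(f"ROI masks disagree in shape: {sorted(shapes)}")
        for name, m in self.masks.items():
            if m.ndim != 3:
                raise ValueError(f"mask {name!r} must be 3-D (z, y, x)")
            if not m.any():
                raise ValueError(f"mask {name!r} is empty")

    def effective_mask(self, name: str) -> np.ndarray:
        """Mask restricted to its z-slab (when one is declared)."""
        if name not in self.masks:
            raise KeyError(f"no ROI named {name!r} (has {sorted(self.masks)})")
        m = self.masks[name]
        if name in self.z_range:
            lo, hi = self.z_range[name]
            out = np.zeros_like(m)
            out[lo : hi + 1] = m[lo : hi + 1]
            if not out.any():
                raise ValueError(
                    f"ROI {name!r} is empty after restricting to z-planes [{lo}, {hi}]"
                )
            return out
        return m


@dataclass
class TraceSet:
    """Time × ROI fluorescence traces with event/epoch annotations.

    ``values`` holds Δf/f fractions when ``kind == "dff"`` and raw
    fluorescence (arbitrary units) when ``kind == "raw"``.
    """

    values: np.ndarray
    fps: float
    roi_labels: tuple[str, ...]
    events: dict[str, float] = field(default_factory=dict)
    epochs: dict[str, tuple[float, float]] = field(default_factory=dict)
    kind: str = "dff"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.fps = float(self.fps)
        if self.fps <= 0:
            raise ValueError(f"fps must be > 0, got {self.fps}")
        self.roi_labels = tuple(self.roi_labels)
        if len(self.roi_labels) != self.values.shape[1]:
            raise ValueError(
                f"{len(self.roi_labels)} labels for {self.values.shape[1]} trace columns"
            )
        if len(set(self.roi_labels)) != len(self.roi_labels):
            raise ValueError(f"roi labels not unique: {self.roi_labels}")
        dur = self.duration_s
        for name, (a, b) in self.epochs.items():
            if not (0.0 <= a < b <= dur + 1e-9):
                raise ValueError(
                    f"epoch {name!r} = ({a}, {b}) s outside trace [0, {dur:.3f}] s"
                )

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    @property
    def times(self) -> np.ndarray:
        """Frame times (s), frame i sampled at i / fps."""
        return np.arange(self.n_frames) / self.fps

    # Backwards-friendly alias used where the semantics are unambiguous.
    @property
    def dff(self) -> np.ndarray:
        if self.kind != "dff":
            raise ValueError(f"TraceSet holds {self.kind!r} values, not dff")
        return self.values

    def trace(self, label: str) -> np.ndarray:
        try:
            idx = self.roi_labels.index(label)
        except ValueError:
            raise KeyError(f"no ROI {label!r} (has {self.roi_labels})") from None
        return self.values[:, idx]


@dataclass
class SpikeTrain:
    """Detected calcium transients for one ROI."""

    times: np.ndarray
    amplitudes: np.ndarray
    roi: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.times.shape != self.amplitudes.shape:
            raise ValueError("times and amplitudes must align")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("spike times must be strictly increasing")
        if np.any(self.amplitudes <= 0):
            raise ValueError("spike amplitudes must be > 0")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class DffParams:
    """Baseline (f0) definition for Δf/f.

    ``f0_mode`` is ``"epoch_mean"`` (mean raw fluorescence over a declared
    baseline epoch, named by ``f0_epoch``) or ``"running_percentile"``
    (per-frame percentile over a centred running window).
    """

    f0_mode: str = "running_percentile"
    f0_epoch: str = "baseline"
    f0_percentile: float = 10.0
    f0_window_s: float = 60.0

    def __post_init__(self) -> None:
        if self.f0_mode not in ("epoch_mean", "running_percentile"):
            raise ValueError(f"unknown f0_mode {self.f0_mode!r}")
        if not 0.0 < self.f0_percentile < 100.0:
            raise ValueError("f0_percentile must be in (0, 100)")
        if self.f0_window_s <= 0:
            raise ValueError("f0_window_s must be > 0")


@dataclass
class CellCountParams:
    """Parameters of the active-cell counting procedure (all lengths in µm).

    The stages mirror a standard stained-section workflow: background
    reduction (rolling-Gaussian subtraction of structure larger than
    ``background_radius``), contrast normalisation to robust noise units
    (dividing by the MAD-based noise scale, optionally saturating a
    ``contrast`` fraction of extreme voxels), a local-mean adaptive
    threshold over a ``threshold_block`` window raised by
    ``threshold_offset`` noise SDs, and connected-component size
    filtering. ``size_range`` is in µm² for single-plane stacks and µm³
    otherwise.
    """

    background_radius: float = 20.0
    contrast: float = 0.0
    threshold_block: float = 25.0
    threshold_offset: float = 6.0
    size_range: tuple[float, float] = (4.0, 400.0)
    connectivity: int = 1

    def __post_init__(self) -> None:
        lo, hi = self.size_range
        if not (0 <= lo < hi):
            raise ValueError(f"size_range must satisfy 0 <= min < max, got {self.size_range}")
        for name in ("background_radius", "threshold_block"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.contrast < 0.5:
            raise ValueError("contrast saturation fraction must be in [0, 0.5)")
        if self.threshold_offset < 0:
            raise ValueError("threshold_offset must be >= 0")


@dataclass
class ThetaResult:
    """Prey-type activity changes relative to an unfed control group.

    ``theta_a`` is the artemia-induced change, ``theta_p`` the
    paramecia-induced change (difference of group means, in the units of the
    input metric); ``ratio`` = θ_A/θ_P, NaN when |θ_P| is below ``floor``.
    """

    theta_a: float
    theta_p: float
    ratio: float
    floor: float

    @property
    def ratio_defined(self) -> bool:
        return np.isfinite(self.ratio)


@dataclass
class IcaResult:
    """Spatially independent components of per-fish voxel activity vectors."""

    components: np.ndarray  # (n_ics, n_voxels) z-scored maps
    fish_loadings: np.ndarray  # (n_kept_fish, n_ics)
    kept_fish: np.ndarray  # indices into the input fish axis
    n_pcs: int
    n_ics: int


@dataclass
class CorrMap:
    """Zero-lag Pearson correlation matrix between voxel traces."""

    r: np.ndarray
    voxel_labels: np.ndarray
    voxel_coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.voxel_labels = np.asarray(self.voxel_labels)
        n = self.r.shape[0]
        if self.r.shape != (n, n):
            raise ValueError("correlation matrix must be square")
        if self.voxel_labels.shape != (n,):
            raise ValueError("one region label per voxel required")
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-8):
            raise ValueError("correlation matrix must have unit diagonal")

    @property
    def n_voxels(self) -> int:
        return self.r.shape[0]

    def region_fraction(self, region: str) -> float:
        return float(np.mean(self.voxel_labels == region))


@dataclass
class StimSession:
    """A calcium recording with an optogenetic pulse schedule.

    ``pulses`` is a sorted list of ``(onset_s, duration_s)``; the analysis
    window of length ``window_s`` is taken immediately before pulse onset and
    immediately after pulse offset, never including stimulation frames.
    Pulses whose windows would clip the trace are dropped (and counted) by
    the window-metric computation, not here.
    """

    ts: TraceSet
    pulses: list[tuple[float, float]]
    window_s: float = 90.0
    target_rois: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.pulses = [(float(a), float(b)) for a, b in self.pulses]
        if any(d <= 0 for _, d in self.pulses):
            raise ValueError("pulse durations must be > 0")
        onsets = [a for a, _ in self.pulses]
        if sorted(onsets) != onsets:
            raise ValueError("pulses must be sorted by onset")
        for (a0, d0), (a1, _) in zip(self.pulses, self.pulses[1:]):
            if a0 + d0 > a1:
                raise ValueError(
                    f"pulses overlap: ({a0}, dur {d0}) runs past onset {a1}"
                )
        if self.window_s <= 0:
            raise ValueError("window_s must be > 0")
        if self.target_rois is None:
            self.target_rois = self.ts.roi_labels
        else:
            self.target_rois = tuple(self.target_rois)
            missing = set(self.target_rois) - set(self.ts.roi_labels)
            if missing:
                raise ValueError(f"target ROIs not in trace set: {sorted(missing)}")


#: The closed set of bout categories.
BOUT_LABELS = ("j-turn", "pursuit", "abort", "strike", "exploratory")

#: Default set counted as hunting-related.
HUNTING_LABELS = ("j-turn", "pursuit", "abort", "strike")


@dataclass
class BoutTable:
    """Per-bout start times, posture features and category labels."""

    start_s: np.ndarray
    features: np.ndarray
    labels: np.ndarray
    fish_id: str = "fish0"
    group: str = ""

    def __post_init__(self) -> None:
        self.start_s = np.asarray(self.start_s, dtype=float)
        self.features = np.atleast_2d(np.asarray(self.features, dtype=float))
        self.labels = np.asarray(self.labels, dtype=object)
        n = self.start_s.size
        if n == 0:
            self.features = self.features.reshape(0, self.features.shape[-1] if self.features.size else 220)
        if self.features.shape[0] != n or self.labels.shape != (n,):
            raise ValueError("start_s, features and labels must align")
        bad = set(self.labels) - set(BOUT_LABELS) - {"unlabeled"}
        if bad:
            raise ValueError(f"unknown bout labels: {sorted(bad)}")

    def __len__(self) -> int:
        return self.start_s.size

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"start_s": self.start_s, "label": self.labels})
        df["fish_id"] = self.fish_id
        df["group"] = self.group
        return df


@dataclass
class BinStats:
    """Hunting-bout probability in one time bin, with a binomial CI."""

    bin_start_min: float
    n_bouts: int
    n_hunting: int
    p_hat: float
    ci_lo: float
    ci_hi: float
    conf: float = 0.90

    def __post_init__(self) -> None:
        if np.isfinite(self.p_hat):
            if not (0.0 <= self.p_hat <= 1.0):
                raise ValueError("p_hat must lie in [0, 1]")
            if not (self.ci_lo - 1e-12 <= self.p_hat <= self.ci_hi + 1e-12):
                raise ValueError("confidence interval must contain p_hat")


@dataclass
class GroundTruth:
    """Generator-side truth attached to every synthetic product.

    Only the fields meaningful for a given product are populated; the rest
    stay ``None``. This is what downstream recovery tests score against.
    """

    event_times: list[np.ndarray] | None = None
    latent_traces: np.ndarray | None = None
    cell_centers: dict[str, np.ndarray] | None = None
    cell_intensities: dict[str, np.ndarray] | None = None
    bout_labels: np.ndarray | None = None
    true_p_hunt: np.ndarray | None = None
    opto_effect: np.ndarray | None = None
    total_signal: float | None = None
    extras: dict = field(default_factory=dict)

    def to_jsonable(self) -> dict:
        """A JSON-serialisable view (arrays become lists)."""

        def conv(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, dict):
                return {k: conv(x) for k, x in v.items()}
            if isinstance(v, (list, tuple)):
                return [conv(x) for x in v]
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            return v

        return {
            k: conv(v)
            for k, v in self.__dict__.items()
            if v is not None and (not isinstance(v, dict) or v)
        }
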