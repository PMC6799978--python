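"""Bout featurization, embedding hook, binned hunting-probability
statistics and gut-fluorescence food-intake quantification.

A swim bout is represented as a point in 220-dimensional posture space:
22 posture measurements (20 tail tangent angles encoding tail shape plus
the two eye gaze angles) accumulated over the first 10 tracked frames
(~167 ms at 60 Hz) of the bout, concatenated frame-major.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import BinStats, BoutTable, HUNTING_LABELS

__all__ = [
    "featurize_bout",
    "embed_bouts",
    "hunting_probability",
    "per_bin_fisher",
    "gut_fluorescence",
]


def _resample_arclength(points: np.ndarray, n_out: int) -> np.ndarray:
    """Resample an ordered 2-D polyline to ``n_out`` equidistant points.

    Equidistance is in cumulative chord length, which converges to true
    arc length as the input sampling densifies.
    """
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] <= 0:
        raise ValueError("degenerate skeleton: zero total length")
    target = np.linspace(0.0, s[-1], n_out)
    return np.column_stack([np.interp(target, s, points[:, k]) for k in (0, 1)])


def _wrap(angle: np.ndarray) -> np.ndarray:
    """Wrap angles to (−π, π]."""
    return np.angle(np.exp(1j * angle))


def tail_tangent_angles(points: np.ndarray, n_segments: int = 20,
                        body_axis: float | None = None) -> np.ndarray:
    """Successive inter-segment direction changes along a tail skeleton.

    The skeleton is resampled to ``n_segments + 1`` equidistant points;
    angle *k* is the signed direction change from segment *k−1* to segment
    *k*, with the first segment referenced to ``body_axis`` (radians; when
    None, the first segment's own direction is used, making the first
    angle zero). A straight tail gives the zero vector; mirror reflection
    negates every angle.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("skeleton points must be (n, 2)")
    if pts.shape[0] < n_segments + 1:
        raise ValueError(
            f"need >= {n_segments + 1} skeleton points, got {pts.shape[0]}"
        )
    res = _resample_arclength(pts, n_segments + 1)
    d = np.diff(res, axis=0)
    headings = np.arctan2(d[:, 1], d[:, 0])
    ref = headings[0] if body_axis is None else float(body_axis)
    return _wrap(np.diff(headings, prepend=ref))


def featurize_bout(tail_points: Sequence[np.ndarray] | np.ndarray,
                   eye_angles: np.ndarray, n_frames: int = 10,
                   n_segments: int = 20,
                   body_axis: Sequence[float] | None = None,
                   bout_id: str = "") -> np.ndarray:
    """Posture feature vector of one bout: 22 measurements × 10 frames.

    Per frame the feature block is the ``n_segments`` tail tangent angles
    followed by the two eye gaze angles; blocks are concatenated
    frame-major into a vector of length ``(n_segments + 2) * n_frames``
    (220 with defaults). ``body_axis`` optionally provides the per-frame
    heading reference for the tangent angles.
    """
    eye = np.asarray(eye_angles, dtype=float)
    if len(tail_points) < n_frames:
        raise ValueError(
            f"bout {bout_id!r}: {len(tail_points)} frames < n_frames={n_frames}"
        )
    if eye.shape[0] < n_frames or eye.shape[1] != 2:
        raise ValueError(
            f"bout {bout_id!r}: eye_angles must be (>= {n_frames}, 2)"
        )
    blocks = []
    for f in range(n_frames):
        ref = None if body_axis is None else float(body_axis[f])
        try:
            ang = tail_tangent_angles(np.asarray(tail_points[f]), n_segments, ref)
        except ValueError as e:
            raise ValueError(f"bout {bout_id!r}, frame {f}: {e}") from None
        blocks.append(np.concatenate([ang, eye[f]]))
    return np.concatenate(blocks)


def embed_bouts(features: np.ndarray, method=None, seed: int = 0) -> np.ndarray:
    """Map bout feature vectors to 2-D with a pluggable embedding.

    ``method`` is any object with a ``fit_transform(X) -> (n, 2)`` contract
    (a t-SNE instance, for example); by default a t-SNE with
    PCA initialisation and a sample-size-capped perplexity is used.
    Deterministic for a given seed.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 10:
        raise ValueError("need a bout × feature matrix with >= 10 bouts")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    if method is None:
        from sklearn.manifold import TSNE

        method = TSNE(n_components=2, random_state=seed, init="pca",
                      perplexity=min(30.0, (X.shape[0] - 1) / 3.0))
    out = np.asarray(method.fit_transform(X), dtype=float)
    if out.shape != (X.shape[0], 2):
        raise ValueError("embedding method must return (n_bouts, 2)")
    return out


def clopper_pearson(k: int, n: int, conf: float = 0.90) -> tuple[float, float]:
    """Exact (Clopper–Pearson) two-sided binomial confidence interval."""
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    alpha = 1.0 - conf
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def hunting_probability(bouts: BoutTable, bin_min: float = 3.0,
                        horizon_min: float = 45.0, conf: float = 0.90,
                        hunting_labels: Sequence[str] = HUNTING_LABELS,
                        ) -> list[BinStats]:
    """Per-bin probability of a hunting-related bout, with exact 90% CIs.

    Bouts inside the ``horizon_min`` horizon are grouped into ``bin_min``
    bins; per bin, ``p_hat = n_hunting / n_bouts`` with a two-sided
    Clopper–Pearson interval at ``conf``. Hunting-related defaults to
    {j-turn, pursuit, abort, strike}; empty bins report NaN.
    """
    hunting = set(hunting_labels)
    n_bins = int(np.ceil(horizon_min / bin_min))
    t_min = bouts.start_s / 60.0
    is_hunt = np.array([lab in hunting for lab in bouts.labels])
    out: list[BinStats] = []
    for b in range(n_bins):
        lo, hi = b * bin_min, min((b + 1) * bin_min, horizon_min)
        sel = (t_min >= lo) & (t_min < hi)
        n, k = int(sel.sum()), int(is_hunt[sel].sum())
        if n == 0:
            out.append(BinStats(lo, 0, 0, float("nan"), float("nan"),
                                float("nan"), conf))
            continue
        ci_lo, ci_hi = clopper_pearson(k, n, conf)
        out.append(BinStats(lo, n, k, k / n, ci_lo, ci_hi, conf))
    return out


def per_bin_fisher(group_a: Sequence[tuple[int, int]],
                   group_b: Sequence[tuple[int, int]]) -> np.ndarray:
    """Two-sided Fisher exact p-value per time bin.

    Each group supplies ``(n_hunting, n_other)`` per bin; bin *i* is tested
    on the 2×2 table ``[[a_hunt, a_other], [b_hunt, b_other]]``.
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=int))
    b = np.atleast_2d(np.asarray(group_b, dtype=int))
    if a.shape != b.shape or a.shape[1] != 2:
        raise ValueError("groups must align as (n_bins, 2) count pairs")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("counts must be nonnegative")
    ps = np.empty(a.shape[0])
    for i in range(a.shape[0]):
        _, ps[i] = stats.fisher_exact([a[i], b[i]], alternative="two-sided")
    return ps


def gut_fluorescence(image: np.ndarray, gut_mask: np.ndarray,
                     background_mask: np.ndarray) -> dict[str, float]:
    """Background-corrected gut fluorescence (food-intake readout).

    The per-sample background level — the mean over ``background_mask`` —
    is subtracted from every gut pixel; both the integrated and the mean
    above-background intensity over ``gut_mask`` are reported, clipped at
    zero. Raising the whole image by a constant leaves the result
    unchanged, and disjoint deposits measure additively (noiseless case).
    """
    img = np.asarray(image, dtype=float)
    gut = np.asarray(gut_mask, dtype=bool)
    bg = np.asarray(background_mask, dtype=bool)
    if gut.shape != img.shape or bg.shape != img.shape:
        raise ValueError("masks must match the image shape")
    if not gut.any() or not bg.any():
        raise ValueError("gut and background masks must be nonempty")
    if np.any(gut & bg):
        raise ValueError("gut and background masks must be disjoint")
    level = float(img[bg].mean())
    excess = img[gut] - level
    return {
        "integrated": max(0.0, float(excess.sum())),
        "mean": max(0.0, float(excess.mean())),
        "background_level": level,
        "n_pixels": int(gut.sum()),
    }
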