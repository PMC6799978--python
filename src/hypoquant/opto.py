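"""Pre/post stimulation window metrics and their paired statistics.

Activity around each optogenetic pulse is summarised over fixed-length
windows: the ``window_s`` seconds ending at pulse onset (pre) and the
``window_s`` seconds starting at pulse offset (post). Stimulation frames —
which carry the stimulus artifact — are never included in either window.
Each pulse is one statistical unit; a per-fish aggregation helper is
offered for sensitivity analysis.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import StimSession

__all__ = ["window_metrics", "paired_test", "aggregate_per_fish"]


def window_metrics(session: StimSession) -> tuple[pd.DataFrame, int]:
    """Mean, summed and maximum Δf/f per pre/post window, pulse and ROI.

    Pre window = ``[onset − window_s, onset)``; post window =
    ``[offset, offset + window_s)``. Pulses whose windows would clip the
    trace are excluded; their number is returned alongside the metric
    table (columns ``pulse``, ``roi``, ``pre_mean``, ``post_mean``,
    ``pre_sum``, ``post_sum``, ``pre_max``, ``post_max``).
    """
    ts = session.ts
    t = ts.times
    w = session.window_s
    rows = []
    n_excluded = 0
    for p, (onset, dur) in enumerate(session.pulses):
        pre = (t >= onset - w) & (t < onset)
        post = (t >= onset + dur) & (t < onset + dur + w)
        if onset - w < -1e-9 or onset + dur + w > ts.duration_s + 1e-9 \
                or not pre.any() or not post.any():
            n_excluded += 1
            continue
        for roi in session.target_rois:
            y = ts.trace(roi)
            rows.append({
                "pulse": p, "roi": roi,
                "pre_mean": float(y[pre].mean()),
                "post_mean": float(y[post].mean()),
                "pre_sum": float(y[pre].sum()),
                "post_sum": float(y[post].sum()),
                "pre_max": float(y[pre].max()),
                "post_max": float(y[post].max()),
            })
    cols = ["pulse", "roi", "pre_mean", "post_mean", "pre_sum", "post_sum",
            "pre_max", "post_max"]
    return pd.DataFrame(rows, columns=cols), n_excluded


def paired_test(pre: np.ndarray, post: np.ndarray, tail: str = "two",
                zero_method: str = "drop") -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired pre/post values.

    ``tail`` is ``"two"``, ``"one-greater"`` (post > pre predicted) or
    ``"one-less"`` (post < pre predicted) — a one-tailed test is used only
    where there is a prior prediction of direction. Zero differences are
    dropped before ranking by default (``zero_method="pratt"`` keeps
    them). The exact null distribution is used for n ≤ 25 without tied
    |differences|; with ties the exact sign-flip enumeration is used up to
    n = 15 and the normal approximation beyond. When every difference is
    zero, the test is uninformative: returns p = 1 with a warning.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("pre and post must be equal-length 1-D arrays")
    if pre.size < 5:
        raise ValueError("need at least 5 pairs")
    alt = {"two": "two-sided", "one-greater": "greater", "one-less": "less"}
    if tail not in alt:
        raise ValueError(f"tail must be one of {sorted(alt)}, got {tail!r}")
    d = post - pre
    if np.all(d == 0):
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return 0.0, 1.0
    nz = d[d != 0]
    ties = np.unique(np.abs(nz)).size < nz.size
    if zero_method == "drop" and nz.size <= 25 and not ties:
        method = "exact"
    elif zero_method == "drop" and nz.size <= 15:
        # tied |differences|: enumerate all 2^n sign assignments exactly
        method = stats.PermutationMethod(n_resamples=2 ** 16)
    else:
        method = "approx"
    res = stats.wilcoxon(
        post, pre, alternative=alt[tail],
        zero_method="wilcox" if zero_method == "drop" else "pratt",
        method=method,
    )
    return float(res.statistic), float(res.pvalue)


def aggregate_per_fish(metrics: pd.DataFrame, fish_ids: np.ndarray,
                       ) -> pd.DataFrame:
    """Collapse per-pulse metrics to per-fish means (sensitivity analysis).

    ``fish_ids`` assigns a fish to each row of the per-pulse metric table;
    the paired test can then be run on the per-fish rows instead of
    treating every pulse as a unit.
    """
    df = metrics.copy()
    df["fish_id"] = np.asarray(fish_ids)
    value_cols = [c for c in df.columns if c.startswith(("pre_", "post_"))]
    return df.groupby(["fish_id", "roi"], as_index=False)[value_cols].mean()
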