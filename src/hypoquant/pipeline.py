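"""Reproducible multi-stage runs.

A :class:`RunConfig` names the stages to execute, their parameters and the
input paths; :func:`run_pipeline` resolves stage dependencies, executes
them in order, and writes every product plus the resolved configuration and
a structured log into the run directory, so a run can be reproduced exactly
from its own outputs. No stage mutates its inputs on disk.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, io, opto, synth, traces as trace_ops
from .datatypes import DffParams, StimSession

__all__ = ["RunConfig", "run_pipeline"]

#: execution order; dependencies are implicit in this sequence
_STAGE_ORDER = ["synth_traces", "synth_movie", "synth_bouts", "dff",
                "spikes", "xcorr", "rankstat", "opto", "bouts"]


@dataclass
class RunConfig:
    """Fully serialisable description of one pipeline run."""

    out_dir: str
    stages: list[str] = field(default_factory=list)
    seed: int = 0
    paths: dict[str, str] = field(default_factory=dict)
    params: dict[str, dict] = field(default_factory=dict)
    log_level: str = "info"

    def stage_params(self, stage: str) -> dict:
        return dict(self.params.get(stage, {}))


def _voxel_labels_from_columns(cols: list[str]) -> np.ndarray:
    """Voxel CSV columns are ``region:index``; the label is the region."""
    return np.array([c.split(":", 1)[0] for c in cols], dtype=object)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages in dependency order.

    Returns the run directory. Identical config + seed reproduces
    bit-identical outputs; any stage failure aborts with the stage name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []
    state: dict[str, object] = {}

    unknown = set(config.stages) - set(_STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    for key, p in config.paths.items():
        if not Path(p).exists():
            raise FileNotFoundError(f"configured input {key!r} missing: {p}")

    def record(stage: str, **info) -> None:
        log.append({"stage": stage, **info})

    for stage in [s for s in _STAGE_ORDER if s in config.stages]:
        p = config.stage_params(stage)
        try:
            if stage == "synth_traces":
                model = synth.LatentModel(seed=config.seed, **p.pop("model", {}))
                ts, gt = synth.generate_traces(
                    model, p.get("duration_s", 600.0), p.get("fps", 1.0))
                io.write_traces(ts, out / "traces_raw.csv")
                io.write_json(gt.to_jsonable(), out / "traces_truth.json")
                state["raw_traces"] = ts
                record(stage, n_frames=ts.n_frames, n_rois=len(ts.roi_labels))
            elif stage == "synth_bouts":
                table, gt = synth.generate_bout_stream(
                    p.get("p_hunt", 0.2), p.get("bout_rate_hz", 0.5),
                    p.get("duration_s", 2700.0), seed=config.seed)
                io.write_bouts(table, out / "bouts.csv")
                io.write_json(gt.to_jsonable(), out / "bouts_truth.json")
                state["bouts"] = table
                record(stage, n_bouts=len(table))
            elif stage == "synth_movie":
                model = synth.LatentModel(seed=config.seed, **p.pop("model", {}))
                shape = tuple(p.get("shape", (36, 60)))
                masks = _default_movie_masks(shape, model.n_regions)
                movie, gt = synth.generate_movie(
                    model, p.get("duration_s", 600.0), p.get("fps", 5.0),
                    masks, p.get("pixel_noise_sd", 0.1))
                io.write_movie(movie, out / "movie.tif")
                state["movie"], state["movie_masks"] = movie, masks
                record(stage, n_frames=movie.shape[0], shape=list(shape))
            elif stage == "dff":
                raw = state.get("raw_traces")
                if raw is None:
                    raw = io.read_traces(config.paths["traces"])
                dff = trace_ops.compute_dff(raw, DffParams(**p))
                io.write_traces(dff, out / "dff.csv")
                state["dff"] = dff
                record(stage, f0_mode=dff.meta["f0_mode"])
            elif stage == "spikes":
                ts = state.get("dff")
                if ts is None:
                    ts = io.read_traces(config.paths["dff"])
                rows = []
                for roi in ts.roi_labels:
                    detr = trace_ops.detrend_quadratic(ts.trace(roi), ts.fps)
                    st = trace_ops.detect_spikes(detr, ts.fps, roi=roi, **p)
                    rows.append(pd.DataFrame(
                        {"roi": roi, "time_s": st.times,
                         "amplitude": st.amplitudes}))
                df = (pd.concat(rows, ignore_index=True) if rows
                      else pd.DataFrame(columns=["roi", "time_s", "amplitude"]))
                io.write_table(df, out / "spikes.csv")
                record(stage, n_spikes=len(df))
            elif stage == "xcorr":
                if "movie" in state:
                    vox, labels, coords = trace_ops.downsample_movie(
                        state["movie"], p.get("cell_size_px", 6),
                        state.get("movie_masks"))
                else:
                    df = pd.read_csv(config.paths["voxel_traces"])
                    cols = [c for c in df.columns if c != "time_s"]
                    vox = df[cols].to_numpy()
                    labels = _voxel_labels_from_columns(cols)
                    coords = None
                cmap = trace_ops.crosscorrelogram(vox, labels, coords)
                mat = pd.DataFrame(cmap.r, columns=[str(l) for l in cmap.voxel_labels])
                io.write_table(mat, out / "corr_matrix.csv")
                (out / "corr_labels.txt").write_text(
                    "\n".join(str(l) for l in cmap.voxel_labels) + "\n")
                state["cmap"] = cmap
                record(stage, n_voxels=cmap.n_voxels)
            elif stage == "rankstat":
                cmap = state.get("cmap")
                if cmap is None:
                    mat = pd.read_csv(config.paths["corr_matrix"])
                    from .datatypes import CorrMap
                    cmap = CorrMap(mat.to_numpy(),
                                   np.array(mat.columns, dtype=object))
                df = trace_ops.anticorr_rank_stat(cmap, p.get("max_rank", 5))
                io.write_table(df, out / "rank_enrichment.csv")
                record(stage, max_rank=p.get("max_rank", 5))
            elif stage == "opto":
                ts = state.get("dff")
                if ts is None:
                    ts = io.read_traces(config.paths["dff"])
                pulses_df = pd.read_csv(config.paths["pulses"])
                if not {"onset_s", "duration_s"} <= set(pulses_df.columns):
                    raise ValueError("pulse schedule needs onset_s, duration_s")
                session = StimSession(ts, list(zip(pulses_df["onset_s"],
                                                   pulses_df["duration_s"])),
                                      window_s=p.get("window_s", 90.0))
                metrics, n_excl = opto.window_metrics(session)
                io.write_table(metrics, out / "opto_metrics.csv")
                stats = {}
                for roi, g in metrics.groupby("roi"):
                    if len(g) >= 5:
                        s, pv = opto.paired_test(
                            g["pre_sum"].to_numpy(), g["post_sum"].to_numpy(),
                            tail=p.get("tail", "two"))
                        stats[roi] = {"statistic": s, "p": pv, "n_pulses": len(g)}
                io.write_json({"excluded_pulses": n_excl, "per_roi": stats},
                              out / "opto_stats.json")
                record(stage, n_pulses=len(metrics), excluded=n_excl)
            elif stage == "bouts":
                table = state.get("bouts")
                if table is None:
                    table = io.read_bouts(config.paths["bouts"])
                bins = behavior.hunting_probability(
                    table, p.get("bin_min", 3.0), p.get("horizon_min", 45.0),
                    p.get("conf", 0.90))
                io.write_table(pd.DataFrame([vars(b) for b in bins]),
                               out / "hunting_bins.csv")
                record(stage, n_bins=len(bins))
        except Exception as e:
            record(stage, error=str(e))
            io.write_json(log, out / "run_log.json")
            raise RuntimeError(f"stage {stage!r} failed: {e}") from e

    io.write_json(asdict(config), out / "resolved_config.json")
    io.write_json(log, out / "run_log.json")
    return out


def _default_movie_masks(shape: tuple[int, int],
                         n_regions: int) -> dict[str, np.ndarray]:
    """Side-by-side rectangular region masks spanning the frame."""
    names = ["cH", "lLH", "mLH", "PVO"][:n_regions] or ["cH"]
    masks = {}
    width = shape[1] // n_regions
    for i, name in enumerate(names[:n_regions]):
        m = np.zeros(shape, dtype=bool)
        m[:, i * width : (i + 1) * width] = True
        masks[name] = m
    return masks
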