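"""Readers and writers for every delimited-text dialect in the pipeline.

All tables are UTF-8 CSV with a header row and '.' decimal separator.
Floats are written with 17 significant digits ("%.17g"), which always
round-trips IEEE doubles, so every writer/reader pair recovers values
losslessly and identical in-memory data produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import DensityProfile, FrustumStack, GroundTruth, PointMap, TrialTraceSet
from .errors import DataError

__all__ = [
    "write_trace_set",
    "read_trace_set",
    "write_point_map",
    "read_point_map",
    "write_zones",
    "read_zones",
    "write_density_profiles",
    "read_density_profiles",
    "read_frustums",
    "write_frustums",
    "write_ground_truth",
    "read_ground_truth",
    "write_table",
    "read_table",
]


def _require(path: Path) -> Path:
    if not path.exists():
        raise DataError(f"missing input file: {path}")
    return path


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.17g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(_require(Path(path)), float_precision="round_trip")


def write_trace_set(ts: TrialTraceSet, out_dir) -> None:
    """Write traces.csv (trial_id, roi_id, frame, F) and trials.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n_t, n_r, n_f = ts.traces.shape
    trial_ids = np.repeat(ts.trial_table["trial_id"].to_numpy(), n_r * n_f)
    roi_ids = np.tile(np.repeat(ts.roi_ids, n_f), n_t)
    frames = np.tile(np.arange(n_f), n_t * n_r)
    long = pd.DataFrame(
        {"trial_id": trial_ids, "roi_id": roi_ids, "frame": frames,
         "F": ts.traces.ravel()}
    )
    long.to_csv(out / "traces.csv", index=False, float_format="%.17g")
    trials = ts.trial_table.copy()
    trials["sampling_rate_hz"] = ts.sampling_rate_hz
    trials.to_csv(out / "trials.csv", index=False, float_format="%.17g")


def read_trace_set(in_dir) -> TrialTraceSet:
    """Read the traces.csv/trials.csv pair back into a dense trial set."""
    in_dir = Path(in_dir)
    trials = pd.read_csv(_require(in_dir / "trials.csv"), float_precision="round_trip")
    long = pd.read_csv(_require(in_dir / "traces.csv"), float_precision="round_trip")
    trial_order = trials["trial_id"].to_numpy()
    roi_order = pd.unique(long["roi_id"])
    n_f = int(long["frame"].max()) + 1
    t_idx = pd.Categorical(long["trial_id"], categories=trial_order).codes
    r_idx = pd.Categorical(long["roi_id"], categories=roi_order).codes
    traces = np.empty((len(trial_order), len(roi_order), n_f))
    traces[t_idx, r_idx, long["frame"].to_numpy()] = long["F"].to_numpy()
    rate = float(trials["sampling_rate_hz"].iloc[0])
    return TrialTraceSet(
        traces=traces,
        sampling_rate_hz=rate,
        trial_table=trials.drop(columns=["sampling_rate_hz"]),
        roi_ids=np.asarray(roi_order),
    )


def write_point_map(pm: PointMap, path) -> None:
    """points.csv: label, x, y (+ grid extent columns repeated per row)."""
    df = pm.points.copy()
    df["grid_w"] = pm.grid_extent[0]
    df["grid_h"] = pm.grid_extent[1]
    write_table(df, path)


def read_point_map(path) -> PointMap:
    df = read_table(path)
    extent = (float(df["grid_w"].iloc[0]), float(df["grid_h"].iloc[0]))
    return PointMap(
        points=df[["label", "x", "y"]].copy(), grid_extent=extent
    )


def write_zones(zones: list[np.ndarray], tags, path) -> None:
    """zones.csv: zone_id, tag, vertex_idx, x, y (one row per vertex)."""
    rows = []
    for zid, (verts, tag) in enumerate(zip(zones, tags)):
        for vid, (x, y) in enumerate(np.asarray(verts, float)):
            rows.append({"zone_id": zid, "tag": tag, "vertex_idx": vid,
                         "x": x, "y": y})
    write_table(pd.DataFrame(rows), path)


def read_zones(path) -> tuple[list[np.ndarray], list[str]]:
    df = read_table(path)
    zones, tags = [], []
    for zid, grp in df.groupby("zone_id", sort=True):
        grp = grp.sort_values("vertex_idx")
        zones.append(grp[["x", "y"]].to_numpy(float))
        tags.append(grp["tag"].iloc[0])
    return zones, tags


def write_density_profiles(profiles: list[DensityProfile], path) -> None:
    """density_profiles.csv: section_id, zone_idx, tag, count[, area_um2]."""
    rows = []
    for p in profiles:
        for i, (c, tag) in enumerate(zip(p.zone_counts, p.zone_tags)):
            row = {"section_id": p.section_id, "zone_idx": i, "tag": tag,
                   "count": c}
            if p.zone_areas_um2 is not None:
                row["area_um2"] = p.zone_areas_um2[i]
            rows.append(row)
    write_table(pd.DataFrame(rows), path)


def read_density_profiles(path) -> list[DensityProfile]:
    df = read_table(path)
    profiles = []
    for sid, grp in df.groupby("section_id", sort=True):
        grp = grp.sort_values("zone_idx")
        areas = grp["area_um2"].to_numpy(float) if "area_um2" in grp.columns else None
        profiles.append(
            DensityProfile(
                section_id=str(sid),
                zone_counts=grp["count"].to_numpy(float),
                zone_tags=tuple(grp["tag"]),
                zone_areas_um2=areas,
            )
        )
    return profiles


def write_frustums(stacks: dict[str, list[tuple[float, float, float]]], path) -> None:
    """frustums.csv: glom_id, segment_idx, d_top_um, d_bottom_um, h_um."""
    rows = []
    for glom_id, segments in stacks.items():
        for i, (d_top, d_bot, h) in enumerate(segments):
            rows.append({"glom_id": glom_id, "segment_idx": i,
                         "d_top_um": d_top, "d_bottom_um": d_bot, "h_um": h})
    write_table(pd.DataFrame(rows), path)


def read_frustums(path) -> dict[str, FrustumStack]:
    """Read diameter-based segment tables into radius-based stacks."""
    df = read_table(path)
    stacks = {}
    for glom_id, grp in df.groupby("glom_id", sort=True):
        grp = grp.sort_values("segment_idx")
        stacks[str(glom_id)] = FrustumStack.from_diameters(
            list(zip(grp["d_top_um"], grp["d_bottom_um"], grp["h_um"]))
        )
    return stacks


def _truth_key(key) -> str:
    if isinstance(key, tuple):
        return "|".join(str(k) for k in key)
    return str(key)


def write_ground_truth(truth: GroundTruth, path) -> None:
    payload = {}
    for name in ("true_amplitudes", "true_latencies", "true_responsive",
                 "true_modulated", "true_coloc_fraction"):
        val = getattr(truth, name)
        if val is not None:
            payload[name] = {_truth_key(k): v for k, v in val.items()}
    if truth.true_zone_bias is not None:
        payload["true_zone_bias"] = truth.true_zone_bias
    if truth.extras:
        payload["extras"] = truth.extras
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_ground_truth(path) -> GroundTruth:
    payload = json.loads(_require(Path(path)).read_text())
    kwargs = {}
    for name in ("true_amplitudes", "true_latencies", "true_responsive",
                 "true_modulated", "true_coloc_fraction"):
        if name in payload:
            kwargs[name] = {
                tuple(k.split("|")) if "|" in k else k: v
                for k, v in payload[name].items()
            }
    if "true_zone_bias" in payload:
        kwargs["true_zone_bias"] = payload["true_zone_bias"]
    if "extras" in payload:
        kwargs["extras"] = payload["extras"]
    return GroundTruth(**kwargs)
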