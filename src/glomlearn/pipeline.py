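"""End-to-end orchestration: simulate -> respond -> metrics -> modulate ->
spatial -> density/coloc -> behavior, with a machine-readable run manifest.

Each stage reads and writes the delimited-text dialects in
:mod:`glomlearn.io`; a failure aborts with an error naming the stage. All
randomness is expanded from the single configured seed into per-stage child
seeds (recorded in the manifest), so a rerun with the same config reproduces
every output table byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behavior import session_summary
from .config import PipelineConfig
from .datatypes import CSMINUS, CSPLUS
from .errors import GlomlearnError, ParameterError
from .expression import colocalization_score, expression_bias, frustum_volume
from .io import (
    read_density_profiles,
    read_frustums,
    read_point_map,
    read_table,
    read_trace_set,
    write_density_profiles,
    write_frustums,
    write_ground_truth,
    write_point_map,
    write_table,
    write_trace_set,
)
from .metrics import latency_table, selectivity_table
from .modulation import PermutationConfig, modulation_table
from .spatial import bulb_geometry, fraction_responsive_map, polar_activation_map
from .synthetic import (
    SyntheticSessionSpec,
    generate_behavior_session,
    generate_density_sections,
    generate_point_maps,
    generate_roi_layout,
    generate_trial_traces,
)
from .traces import compute_dff, smooth_moving_average, summarize_responses, trial_peaks

__all__ = ["child_seeds", "simulate_inputs", "run_pipeline"]

_STAGE_NAMES = ("simulate", "respond", "metrics", "modulate", "spatial",
                "coloc", "density", "volume", "behavior")


def child_seeds(seed: int, n: int) -> list[int]:
    """Expand one seed into n independent child seeds (each < 2**31)."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s & 0x7FFFFFFF) for s in state]


def simulate_inputs(cfg: PipelineConfig, in_dir: Path) -> dict[str, int]:
    """Generate every pipeline input under ``in_dir``; returns row counts."""
    sim = dict(cfg.simulate)
    n_rois = int(sim.pop("n_rois", 50))
    seeds = child_seeds(cfg.rng_seed, 5)
    rng = np.random.default_rng(seeds[0])
    # planted session: a third of ROIs respond to CS+, a third to CS-,
    # amplitudes ~0.2-0.6 dF/F, onsets in the first half of the odor window
    amp = np.zeros((n_rois, 2))
    lat = np.zeros((n_rois, 2), dtype=int)
    spec_probe = SyntheticSessionSpec(n_rois=1, **{k: v for k, v in sim.items()
                                                  if k in ("sampling_rate_hz", "baseline_s", "stim_s", "post_s")})
    max_lat = max(1, spec_probe.n_stim_frames // 2)
    for r in range(n_rois):
        kind = r % 3
        if kind < 2:
            amp[r, kind] = rng.uniform(0.2, 0.6)
            lat[r, kind] = rng.integers(0, max_lat)
    spec = SyntheticSessionSpec(
        n_rois=n_rois, amplitude_map=amp, latency_map=lat,
        rng_seed=seeds[0], **sim,
    )
    traces, truth = generate_trial_traces(spec)
    write_trace_set(traces, in_dir)
    coords, boundary = generate_roi_layout(n_rois, rng_seed=seeds[1])
    write_table(coords, in_dir / "roi_coords.csv")
    write_table(pd.DataFrame(boundary, columns=["x", "y"]),
                in_dir / "boundary.csv")
    radius = cfg.coloc_radius_px if cfg.coloc_radius_px is not None else 3.0
    pm, coloc_truth = generate_point_maps(
        n_pixels_per_gene=400, grid=(512.0, 512.0), planted_coloc=0.5,
        rng_seed=seeds[2], radius=radius,
    )
    write_point_map(pm, in_dir / "points.csv")
    profiles, bias_truth = generate_density_sections(
        n_sections=8, zone_tags=("CS+", "neutral", "neutral", "CS-"),
        mean_counts=(60.0, 40.0, 40.0, 30.0), rng_seed=seeds[3],
    )
    write_density_profiles(profiles, in_dir / "density_profiles.csv")
    write_frustums(
        {"glom0": [(50.0, 70.0, 20.0), (70.0, 40.0, 25.0)],
         "glom1": [(60.0, 60.0, 30.0)]},
        in_dir / "frustums.csv",
    )
    outcomes = generate_behavior_session(
        n_trials=76, p_lick_csplus=0.9, p_lick_csminus=0.3, rng_seed=seeds[4]
    )
    write_table(outcomes, in_dir / "behavior_trials.csv")
    # lick events consistent with the outcomes: one mid-window lick when licked
    lick_rows = outcomes[outcomes["licked_in_window"]]
    licks = pd.DataFrame(
        {"trial_id": lick_rows["trial_id"],
         "lick_time_s": 2.0 + 0.3 + 1.0}  # odor_off 2 s + delay + 1 s
    )
    write_table(licks, in_dir / "licks.csv")
    truth.true_coloc_fraction = coloc_truth.true_coloc_fraction
    truth.true_zone_bias = bias_truth.true_zone_bias
    truth.extras = {"coloc_radius": radius, "child_seeds": seeds}
    write_ground_truth(truth, in_dir / "ground_truth.json")
    return {"trials": traces.n_trials, "rois": n_rois,
            "behavior_trials": len(outcomes)}


def run_pipeline(cfg: PipelineConfig, out_dir, in_dir=None,
                 stages=None) -> dict:
    """Run the configured stages and return the manifest dict.

    With ``in_dir=None`` the synthetic generators produce all inputs under
    ``out_dir/inputs`` first. ``stages`` restricts execution (default: all).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stages_explicit = stages is not None
    stages = tuple(stages) if stages else _STAGE_NAMES
    unknown = set(stages) - set(_STAGE_NAMES)
    if unknown:
        raise ParameterError(f"unknown stages: {sorted(unknown)}")
    counts: dict[str, dict] = {}
    current = "setup"
    try:
        if in_dir is None:
            in_dir = out_dir / "inputs"
            current = "simulate"
            if "simulate" in stages:
                counts["simulate"] = simulate_inputs(cfg, in_dir)
        in_dir = Path(in_dir)

        summary = None
        if "respond" in stages:
            current = "respond"
            traces = read_trace_set(in_dir)
            summary = summarize_responses(
                traces, smooth_ms=cfg.smooth_ms, pre_window_s=cfg.baseline_s,
                k=cfg.k_threshold, run_length=cfg.run_length,
            )
            write_table(summary, out_dir / "response_summary.csv")
            counts["respond"] = {"rows": len(summary)}

        if "metrics" in stages:
            current = "metrics"
            traces = read_trace_set(in_dir)
            dff = compute_dff(traces)
            sel = selectivity_table(dff=dff, smooth_ms=cfg.smooth_ms)
            lat = latency_table(dff, k=cfg.k_threshold,
                                run_length=cfg.run_length,
                                pre_window_s=cfg.baseline_s)
            write_table(sel, out_dir / "selectivity.csv")
            write_table(lat, out_dir / "latency.csv")
            counts["metrics"] = {"selectivity_rows": len(sel),
                                 "latency_rows": len(lat)}

        if "modulate" in stages:
            current = "modulate"
            traces = read_trace_set(in_dir)
            dff = smooth_moving_average(compute_dff(traces), cfg.smooth_ms)
            peaks = trial_peaks(dff)
            rows_a = dff.trials_of(CSPLUS)
            rows_b = dff.trials_of(CSMINUS)
            mod = modulation_table(
                peaks[rows_a], peaks[rows_b], dff.roi_ids,
                PermutationConfig(n_perm=cfg.n_perm, alpha=cfg.alpha,
                                  rng_seed=cfg.rng_seed),
            )
            write_table(mod, out_dir / "modulation.csv")
            counts["modulate"] = {"rows": len(mod)}

        if "spatial" in stages:
            current = "spatial"
            coords = read_table(in_dir / "roi_coords.csv")
            boundary = read_table(in_dir / "boundary.csv")[["x", "y"]].to_numpy()
            geom = bulb_geometry(boundary)
            polar = polar_activation_map(coords, geom)
            write_table(polar, out_dir / "polar_map.csv")
            if summary is None and (out_dir / "response_summary.csv").exists():
                summary = read_table(out_dir / "response_summary.csv")
            if summary is not None:
                fmap = fraction_responsive_map(summary, coords)
                write_table(fmap, out_dir / "fraction_map.csv")
                counts["spatial"] = {"polar_rows": len(polar),
                                     "fraction_bins": len(fmap)}
            else:
                counts["spatial"] = {"polar_rows": len(polar)}

        if "coloc" in stages and cfg.coloc_radius_px is None and not stages_explicit:
            # the radius has no principled default; a default full run skips
            # the stage rather than inventing one
            logging.getLogger("glomlearn").warning(
                "coloc stage skipped: coloc_radius_px not configured"
            )
        elif "coloc" in stages:
            current = "coloc"
            if cfg.coloc_radius_px is None:
                raise ParameterError("coloc stage requires coloc_radius_px")
            pm = read_point_map(in_dir / "points.csv")
            labels = pm.labels()
            rows = []
            for i, g1 in enumerate(labels):
                for g2 in labels[i + 1:]:
                    res = colocalization_score(pm, g1, g2, cfg.coloc_radius_px)
                    rows.append({"gene1": g1, "gene2": g2,
                                 "radius_px": res.radius,
                                 "raw_count": res.raw_count,
                                 "normalized": res.normalized})
            write_table(pd.DataFrame(rows), out_dir / "coloc.csv")
            counts["coloc"] = {"pairs": len(rows)}

        if "density" in stages:
            current = "density"
            profiles = read_density_profiles(in_dir / "density_profiles.csv")
            bias = expression_bias(profiles)
            write_table(pd.DataFrame([{"bias": bias,
                                       "n_sections": len(profiles)}]),
                        out_dir / "bias.csv")
            counts["density"] = {"sections": len(profiles)}

        if "volume" in stages:
            current = "volume"
            stacks = read_frustums(in_dir / "frustums.csv")
            vol_rows = [{"glom_id": gid, "volume_um3": frustum_volume(st)}
                        for gid, st in stacks.items()]
            write_table(pd.DataFrame(vol_rows), out_dir / "volumes.csv")
            counts["volume"] = {"glomeruli": len(vol_rows)}

        if "behavior" in stages:
            current = "behavior"
            outcomes = read_table(in_dir / "behavior_trials.csv")
            write_table(outcomes, out_dir / "outcomes.csv")
            write_table(session_summary(outcomes),
                        out_dir / "session_summary.csv")
            counts["behavior"] = {"trials": len(outcomes)}
    except GlomlearnError as err:
        raise GlomlearnError(f"stage '{current}' failed: {err}") from err

    cfg_json = json.dumps(cfg.to_dict(), sort_keys=True)
    manifest = {
        "config": cfg.to_dict(),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": cfg.rng_seed,
        "child_seeds": child_seeds(cfg.rng_seed, 5),
        "version": __version__,
        "stage_counts": counts,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                      sort_keys=True))
    return manifest
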