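"""Seeded benchmark experiments on synthetic sessions with planted truth.

Each function builds its inputs from the synthetic generators, runs the
relevant pipeline stage, and measures recovery of the planted quantities.
They are the package's own validation experiments: the same functions back
the acceptance tests and the reproduction script, so the numbers those
report are always recomputed from scratch.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .datatypes import CSMINUS, CSPLUS, PointMap
from .expression import colocalization_score, expression_bias
from .modulation import PermutationConfig, modulation_table
from .pipeline import child_seeds
from .synthetic import (
    SyntheticSessionSpec,
    generate_density_sections,
    generate_point_maps,
    generate_trial_traces,
    zone_expectations_for_bias,
)
from .traces import compute_dff, smooth_moving_average, summarize_responses, trial_peaks

__all__ = [
    "noiseless_recovery",
    "responsiveness_calibration",
    "modulation_type1_error",
    "modulation_power",
    "coloc_oracle_check",
    "bias_recovery",
]


def _planted_session_spec(
    n_rois: int, n_trials_per_odor: int, noise_sd: float,
    amplitude: float, responsive_fraction: float, seed: int,
    random_amplitudes: bool = False,
) -> SyntheticSessionSpec:
    """Session where the first ``responsive_fraction`` of ROIs respond to CS+."""
    rng = np.random.default_rng(seed)
    amp = np.zeros((n_rois, 2))
    lat = np.zeros((n_rois, 2), dtype=int)
    n_planted = int(round(responsive_fraction * n_rois))
    probe = SyntheticSessionSpec(n_rois=1)
    # keep the plateau at least 4 frames long so the four-frame onset rule
    # (and a 3-frame smoothing window) can sit entirely on it
    max_lat = probe.n_stim_frames - 4
    for r in range(n_planted):
        amp[r, 0] = rng.uniform(0.1, 1.0) if random_amplitudes else amplitude
        lat[r, 0] = rng.integers(0, max_lat + 1)
    return SyntheticSessionSpec(
        n_rois=n_rois, n_trials_per_odor=n_trials_per_odor,
        noise_sd=noise_sd, amplitude_map=amp, latency_map=lat, rng_seed=seed,
    )


def noiseless_recovery(seed: int, n_rois: int = 50,
                       n_trials_per_odor: int = 20) -> dict:
    """Exactness of the full chain on a noiseless session.

    Every ROI gets a random planted amplitude and onset for CS+; the chain
    (dF/F -> smoothing -> peaks; onset detection) must return them exactly.
    """
    spec = _planted_session_spec(
        n_rois, n_trials_per_odor, noise_sd=0.0, amplitude=0.0,
        responsive_fraction=1.0, seed=seed, random_amplitudes=True,
    )
    traces, truth = generate_trial_traces(spec)
    summary = summarize_responses(traces)
    amp_errors, lat_errors = [], []
    for _, row in summary.iterrows():
        key = (row["roi_id"], row["odor"])
        amp_errors.append(abs(row["peak_dff"] - truth.true_amplitudes[key]))
        if truth.true_amplitudes[key] > 0:
            lat_errors.append(
                abs(row["onset_latency_frame"] - truth.true_latencies[key])
            )
    return {
        "max_amplitude_error": float(np.max(amp_errors)),
        "max_latency_error_frames": float(np.max(lat_errors)),
        "n_rois": n_rois,
        "n_trials_per_odor": n_trials_per_odor,
    }


def responsiveness_calibration(
    seed: int, n_seeds: int = 20, n_rois: int = 50,
    n_trials_per_odor: int = 20, noise_sd: float = 0.05,
    amplitude_in_sd: float = 5.0,
) -> dict:
    """Hit/false-call rates of the 3xSD responsiveness rule under noise.

    Half the ROIs respond to CS+ with amplitude ``amplitude_in_sd * noise_sd``;
    the rest are null. Rates are pooled over ``n_seeds`` seeded replicates.
    """
    hits = falses = n_planted_total = n_null_total = 0
    for s in child_seeds(seed, n_seeds):
        spec = _planted_session_spec(
            n_rois, n_trials_per_odor, noise_sd,
            amplitude=amplitude_in_sd * noise_sd,
            responsive_fraction=0.5, seed=s,
        )
        traces, truth = generate_trial_traces(spec)
        summary = summarize_responses(traces)
        for _, row in summary.iterrows():
            truly = truth.true_responsive[(row["roi_id"], row["odor"])]
            if truly:
                n_planted_total += 1
                hits += bool(row["responsive"])
            else:
                n_null_total += 1
                falses += bool(row["responsive"])
    return {
        "planted_flagged_fraction": hits / n_planted_total,
        "null_flagged_fraction": falses / n_null_total,
        "n_seeds": n_seeds,
        "n_planted": n_planted_total,
        "n_null": n_null_total,
    }


def _session_peaks_by_odor(spec: SyntheticSessionSpec):
    traces, _ = generate_trial_traces(spec)
    dff = smooth_moving_average(compute_dff(traces), 300.0)
    peaks = trial_peaks(dff)
    return peaks[dff.trials_of(CSPLUS)], peaks[dff.trials_of(CSMINUS)], dff.roi_ids


def modulation_type1_error(
    seed: int, n_replicates: int = 50, n_rois: int = 200,
    n_trials_per_odor: int = 20, n_perm: int = 1000, alpha: float = 0.05,
) -> dict:
    """False modulation-call rate on fully null sessions, after BH.

    Each replicate is a noise-only session; per-trial CS+ peaks are tested
    against CS- peaks per ROI. Reports the mean fraction of non-unchanged
    calls over replicates and the standard error of that mean.
    """
    fractions = []
    for s in child_seeds(seed, n_replicates):
        spec = SyntheticSessionSpec(
            n_rois=n_rois, n_trials_per_odor=n_trials_per_odor,
            noise_sd=0.05, rng_seed=s,
        )
        peaks_a, peaks_b, roi_ids = _session_peaks_by_odor(spec)
        table = modulation_table(
            peaks_a, peaks_b, roi_ids,
            PermutationConfig(n_perm=n_perm, alpha=alpha, rng_seed=s),
        )
        fractions.append(float((table["direction"] != "unchanged").mean()))
    fractions = np.asarray(fractions)
    se = fractions.std(ddof=1) / np.sqrt(n_replicates) if n_replicates > 1 else 0.0
    return {
        "mean_fraction_called": float(fractions.mean()),
        "se": float(se),
        "alpha": alpha,
        "n_replicates": n_replicates,
    }


def modulation_power(
    seed: int, n_rois: int = 200, planted_fraction: float = 0.1,
    shift_in_sd: float = 2.0, n_trials: int = 20, n_perm: int = 1000,
    alpha: float = 0.05,
) -> dict:
    """Detection rate for a planted mean shift in per-trial peak responses.

    ``planted_fraction`` of ROIs get a ``shift_in_sd``-SD upward shift in
    condition B; the test must call them ``increased``.
    """
    rng = np.random.default_rng(seed)
    sigma = 0.1
    n_planted = int(round(planted_fraction * n_rois))
    a = rng.normal(0.3, sigma, (n_trials, n_rois))
    b = rng.normal(0.3, sigma, (n_trials, n_rois))
    b[:, :n_planted] += shift_in_sd * sigma
    table = modulation_table(
        a, b, [f"roi{r:03d}" for r in range(n_rois)],
        PermutationConfig(n_perm=n_perm, alpha=alpha, rng_seed=seed),
    )
    planted = table.iloc[:n_planted]
    nulls = table.iloc[n_planted:]
    return {
        "planted_called_correct_fraction": float(
            (planted["direction"] == "increased").mean()
        ),
        "null_called_fraction": float((nulls["direction"] != "unchanged").mean()),
        "n_planted": n_planted,
        "n_rois": n_rois,
    }


def coloc_oracle_check(seed: int, n_maps: int = 100, max_points: int = 200) -> dict:
    """Exact agreement of the KD-tree score with an O(n^2) pair count."""
    max_raw_diff = 0
    max_norm_diff = 0.0
    for s in child_seeds(seed, n_maps):
        rng = np.random.default_rng(s)
        n1, n2 = rng.integers(1, max_points, 2)
        pm, _ = generate_point_maps(
            int(max(n1, n2)), grid=(50.0, 50.0),
            planted_coloc=float(rng.random()), rng_seed=s,
        )
        g1 = pm.coords("Gene1")[:n1]
        g2 = pm.coords("Gene2")[:n2]
        radius = float(rng.uniform(0, 5))
        sub = PointMap(
            points=pd.DataFrame({
                "label": ["Gene1"] * len(g1) + ["Gene2"] * len(g2),
                "x": np.concatenate([g1[:, 0], g2[:, 0]]),
                "y": np.concatenate([g1[:, 1], g2[:, 1]]),
            }),
            grid_extent=(50.0, 50.0),
        )
        res = colocalization_score(sub, "Gene1", "Gene2", radius)
        brute = int((cdist(g1, g2) <= radius).sum())
        max_raw_diff = max(max_raw_diff, abs(res.raw_count - brute))
        max_norm_diff = max(
            max_norm_diff,
            abs(res.normalized - brute / np.sqrt(len(g1) * len(g2))),
        )
    # identical-set, radius-0 normalization
    rng = np.random.default_rng(seed)
    pts = rng.uniform(0, 50, (20, 2))
    both = PointMap(
        points=pd.DataFrame({
            "label": ["Gene1"] * 20 + ["Gene2"] * 20,
            "x": np.tile(pts[:, 0], 2), "y": np.tile(pts[:, 1], 2),
        }),
        grid_extent=(50.0, 50.0),
    )
    identity = colocalization_score(both, "Gene1", "Gene2", 0.0).normalized
    return {
        "max_raw_count_difference": int(max_raw_diff),
        "max_normalized_difference": float(max_norm_diff),
        "identical_set_radius0_normalized": float(identity),
        "n_maps": n_maps,
    }


def bias_recovery(
    seed: int, targets=(-1.0, 0.0, 1.5), n_replicates: int = 100,
    n_sections: int = 10,
) -> dict:
    """Recovery of planted expression bias from Poisson section counts.

    For each target bias a four-zone expectation vector with exactly that
    planted bias is built, ``n_replicates`` seeded section stacks are drawn,
    and the mean estimate and its standard error are reported.
    """
    out = {}
    for i, b in enumerate(targets):
        means, tags = zone_expectations_for_bias(b)
        estimates = [
            expression_bias(
                generate_density_sections(n_sections, tags, means, rng_seed=s)[0]
            )
            for s in child_seeds(seed + i, n_replicates)
        ]
        estimates = np.asarray(estimates)
        out[b] = {
            "planted": float(b),
            "mean_estimate": float(estimates.mean()),
            "se": float(estimates.std(ddof=1) / np.sqrt(n_replicates)),
            "n_replicates": n_replicates,
        }
    return out
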