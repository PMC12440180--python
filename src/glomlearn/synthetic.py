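"""Synthetic session generators with planted ground truth.

Every input the pipeline consumes can be generated here, with the planted
truth returned alongside so downstream estimates can be benchmarked:

* trial-structured fluorescence traces (pseudorandom CS+/CS- order, 2-s
  pre-stimulus baseline, 2-s odor window, additive Gaussian noise, planted
  response amplitudes and onset latencies),
* labeled transcript point maps with a planted colocalized fraction,
* per-section zone count profiles with planted CS+/CS- density bias,
* go/no-go behavioral sessions with per-odor lick probabilities.

All randomness flows from explicit ``rng_seed`` fields — never global state
— so identical spec + seed reproduce outputs bit for bit.

The response kernel rises to the planted amplitude in a single frame at the
planted latency, holds a plateau through the end of the stimulus, then
decays exponentially. In the noiseless case the smoothed-trace peak equals
the planted amplitude exactly (provided the plateau is at least as long as
the smoothing window) and the onset frame equals the planted latency, which
is what makes the generator usable as an exact oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import outcome_for
from .datatypes import CSMINUS, CSPLUS, DensityProfile, GroundTruth, PointMap, TrialTraceSet
from .errors import GeometryError, ParameterError

__all__ = [
    "SyntheticSessionSpec",
    "generate_trial_traces",
    "generate_roi_layout",
    "generate_point_maps",
    "generate_density_sections",
    "generate_behavior_session",
    "pseudorandom_odor_sequence",
    "planted_zone_bias",
]

ODORS = (CSPLUS, CSMINUS)
ALLOWED_RATES = (10.0, 13.3, 15.0)


@dataclass
class SyntheticSessionSpec:
    """Parameters of one synthetic imaging session.

    ``amplitude_map`` and ``latency_map`` are ``(n_rois, 2)`` arrays over the
    odor order (CS+, CS-): true peak dF/F amplitudes (>= 0) and onset frame
    offsets from stimulus onset (must fall inside the stimulus window).
    ``noise_sd`` is in dF/F units; ``f0`` sets the raw fluorescence scale.
    """

    n_rois: int = 50
    n_trials_per_odor: int = 20
    sampling_rate_hz: float = 10.0
    baseline_s: float = 2.0
    stim_s: float = 2.0
    post_s: float = 2.0
    noise_sd: float = 0.05
    f0: float = 100.0
    decay_tau_s: float = 0.5
    amplitude_map: np.ndarray | None = None
    latency_map: np.ndarray | None = None
    rng_seed: int = 0
    session: str = "session1"
    max_same_odor_run: int = 3

    def __post_init__(self) -> None:
        if self.n_rois < 1:
            raise ParameterError("n_rois must be >= 1")
        if self.n_trials_per_odor < 1:
            raise ParameterError("n_trials_per_odor must be >= 1")
        if not any(np.isclose(self.sampling_rate_hz, r) for r in ALLOWED_RATES):
            raise ParameterError(
                f"sampling_rate_hz must be one of {ALLOWED_RATES}"
            )
        for name in ("baseline_s", "stim_s", "post_s", "f0", "decay_tau_s"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.amplitude_map is None:
            self.amplitude_map = np.zeros((self.n_rois, 2))
        self.amplitude_map = np.asarray(self.amplitude_map, dtype=float)
        if self.amplitude_map.shape != (self.n_rois, 2):
            raise ParameterError("amplitude_map must have shape (n_rois, 2)")
        if np.any(self.amplitude_map < 0):
            raise ParameterError("amplitude_map entries must be >= 0")
        if self.latency_map is None:
            self.latency_map = np.zeros((self.n_rois, 2), dtype=int)
        self.latency_map = np.asarray(self.latency_map, dtype=int)
        if self.latency_map.shape != (self.n_rois, 2):
            raise ParameterError("latency_map must have shape (n_rois, 2)")
        if np.any(self.latency_map < 0) or np.any(self.latency_map >= self.n_stim_frames):
            raise ParameterError("latency_map entries must fall inside the stimulus window")

    @property
    def n_pre_frames(self) -> int:
        return int(round(self.baseline_s * self.sampling_rate_hz))

    @property
    def n_stim_frames(self) -> int:
        return int(round(self.stim_s * self.sampling_rate_hz))

    @property
    def n_post_frames(self) -> int:
        return int(round(self.post_s * self.sampling_rate_hz))

    @property
    def n_frames(self) -> int:
        return self.n_pre_frames + self.n_stim_frames + self.n_post_frames


def pseudorandom_odor_sequence(
    n_per_odor: int, rng: np.random.Generator, max_run: int = 3
) -> list[str]:
    """Shuffled CS+/CS- sequence with at most ``max_run`` consecutive repeats.

    Built by sequential sampling weighted by the remaining trial counts,
    excluding the odor that would extend a run past ``max_run``; rare dead
    ends (the tail forcing an over-long run) trigger a fresh attempt.
    """
    if max_run < 1:
        raise ParameterError("max_run must be >= 1")
    for _ in range(1000):
        remaining = {CSPLUS: n_per_odor, CSMINUS: n_per_odor}
        seq: list[str] = []
        run_odor, run_len = None, 0
        while sum(remaining.values()):
            choices = [
                o for o in ODORS
                if remaining[o] > 0 and not (o == run_odor and run_len >= max_run)
            ]
            if not choices:
                break  # dead end; retry from scratch
            weights = np.array([remaining[o] for o in choices], dtype=float)
            odor = choices[rng.choice(len(choices), p=weights / weights.sum())]
            seq.append(odor)
            remaining[odor] -= 1
            run_len = run_len + 1 if odor == run_odor else 1
            run_odor = odor
        if len(seq) == 2 * n_per_odor:
            return seq
    raise ParameterError("could not satisfy the same-odor run constraint")


def _response_kernel(spec: SyntheticSessionSpec, latency_offset: int) -> np.ndarray:
    """Unit kernel: 0 until onset, 1 through last stimulus frame, then decay."""
    n = spec.n_frames
    on = spec.n_pre_frames + int(latency_offset)
    off = spec.n_pre_frames + spec.n_stim_frames - 1  # last stimulus frame
    k = np.zeros(n)
    k[on : off + 1] = 1.0
    tau = spec.decay_tau_s * spec.sampling_rate_hz
    t_post = np.arange(off + 1, n)
    k[off + 1 :] = np.exp(-(t_post - off) / tau)
    return k


def generate_trial_traces(
    spec: SyntheticSessionSpec,
) -> tuple[TrialTraceSet, GroundTruth]:
    """Simulate one session of raw fluorescence traces.

    Each (trial, ROI) trace is ``f0 * (1 + amplitude * kernel + noise)`` with
    i.i.d. Gaussian noise of SD ``noise_sd`` in dF/F units; the trial order
    is a seeded pseudorandom CS+/CS- sequence.
    """
    rng = np.random.default_rng(spec.rng_seed)
    odors = pseudorandom_odor_sequence(
        spec.n_trials_per_odor, rng, spec.max_same_odor_run
    )
    n_trials = len(odors)
    odor_col = {CSPLUS: 0, CSMINUS: 1}
    signal = np.zeros((n_trials, spec.n_rois, spec.n_frames))
    for r in range(spec.n_rois):
        for o, odor in enumerate(ODORS):
            amp = spec.amplitude_map[r, o]
            if amp == 0:
                continue
            kernel = amp * _response_kernel(spec, spec.latency_map[r, o])
            rows = [t for t, od in enumerate(odors) if od == odor]
            signal[rows, r, :] += kernel
    noise = rng.normal(0.0, spec.noise_sd, size=signal.shape) if spec.noise_sd > 0 else 0.0
    traces = spec.f0 * (1.0 + signal + noise)
    stim_on = spec.n_pre_frames
    stim_off = stim_on + spec.n_stim_frames - 1
    trial_table = pd.DataFrame(
        {
            "trial_id": [f"t{i:03d}" for i in range(n_trials)],
            "odor": odors,
            "session": spec.session,
            "stim_on_frame": stim_on,
            "stim_off_frame": stim_off,
        }
    )
    roi_ids = np.array([f"roi{r:03d}" for r in range(spec.n_rois)])
    trace_set = TrialTraceSet(
        traces=traces,
        sampling_rate_hz=spec.sampling_rate_hz,
        trial_table=trial_table,
        roi_ids=roi_ids,
    )
    truth = GroundTruth(
        true_amplitudes={
            (roi_ids[r], odor): float(spec.amplitude_map[r, odor_col[odor]])
            for r in range(spec.n_rois)
            for odor in ODORS
        },
        true_latencies={
            (roi_ids[r], odor): int(stim_on + spec.latency_map[r, odor_col[odor]])
            for r in range(spec.n_rois)
            for odor in ODORS
        },
        true_responsive={
            (roi_ids[r], odor): bool(spec.amplitude_map[r, odor_col[odor]] > 0)
            for r in range(spec.n_rois)
            for odor in ODORS
        },
    )
    return trace_set, truth


def generate_roi_layout(
    n_rois: int,
    rng_seed: int = 0,
    semi_axes: tuple[float, float] = (220.0, 160.0),
    center: tuple[float, float] = (256.0, 256.0),
    n_boundary_vertices: int = 48,
) -> tuple[pd.DataFrame, np.ndarray]:
    """ROI centroids uniform inside an oval bulb outline.

    Returns ``(coords, boundary)``: a ``roi_id, x, y`` table and the oval's
    vertex array, matching the dialects the spatial stage reads.
    """
    if n_rois < 1:
        raise ParameterError("n_rois must be >= 1")
    a, b = semi_axes
    if a <= 0 or b <= 0:
        raise GeometryError("semi_axes must be positive")
    rng = np.random.default_rng(rng_seed)
    # uniform in the ellipse via the polar transform of a uniform disk
    u = np.sqrt(rng.random(n_rois))
    phi = rng.uniform(0, 2 * np.pi, n_rois)
    x = center[0] + a * u * np.cos(phi)
    y = center[1] + b * u * np.sin(phi)
    coords = pd.DataFrame(
        {"roi_id": [f"roi{r:03d}" for r in range(n_rois)], "x": x, "y": y}
    )
    ang = np.linspace(0, 2 * np.pi, n_boundary_vertices, endpoint=False)
    boundary = np.column_stack(
        [center[0] + a * np.cos(ang), center[1] + b * np.sin(ang)]
    )
    return coords, boundary


def generate_point_maps(
    n_pixels_per_gene: int,
    grid: tuple[float, float],
    planted_coloc: float,
    rng_seed: int = 0,
    radius: float = 3.0,
    genes: tuple[str, str] = ("Gene1", "Gene2"),
) -> tuple[PointMap, GroundTruth]:
    """Two-gene transcript pixel map with a planted colocalized fraction.

    A fraction ``planted_coloc`` of the second gene's pixels is placed
    uniformly within ``radius`` of randomly chosen first-gene pixels (offset
    resampled until inside the grid); the remainder — and all first-gene
    pixels — are uniform on the grid. ``planted_coloc=1`` with ``radius=0``
    makes the two pixel sets identical.
    """
    if not 0 <= planted_coloc <= 1:
        raise ParameterError("planted_coloc must lie in [0, 1]")
    if n_pixels_per_gene < 1:
        raise ParameterError("n_pixels_per_gene must be >= 1")
    w, h = grid
    if w <= 0 or h <= 0:
        raise GeometryError("grid extent must be positive in both dimensions")
    rng = np.random.default_rng(rng_seed)
    g1 = np.column_stack(
        [rng.uniform(0, w, n_pixels_per_gene), rng.uniform(0, h, n_pixels_per_gene)]
    )
    n_coloc = int(round(planted_coloc * n_pixels_per_gene))
    g2 = np.empty((n_pixels_per_gene, 2))
    anchors = g1[rng.integers(0, n_pixels_per_gene, n_coloc)]
    for i in range(n_coloc):
        while True:
            if radius == 0:
                offset = np.zeros(2)
            else:
                r = radius * np.sqrt(rng.random())
                phi = rng.uniform(0, 2 * np.pi)
                offset = np.array([r * np.cos(phi), r * np.sin(phi)])
            cand = anchors[i] + offset
            if 0 <= cand[0] <= w and 0 <= cand[1] <= h:
                g2[i] = cand
                break
    n_free = n_pixels_per_gene - n_coloc
    g2[n_coloc:] = np.column_stack(
        [rng.uniform(0, w, n_free), rng.uniform(0, h, n_free)]
    )
    points = pd.DataFrame(
        {
            "label": [genes[0]] * n_pixels_per_gene + [genes[1]] * n_pixels_per_gene,
            "x": np.concatenate([g1[:, 0], g2[:, 0]]),
            "y": np.concatenate([g1[:, 1], g2[:, 1]]),
        }
    )
    truth = GroundTruth(
        true_coloc_fraction={tuple(genes): float(n_coloc / n_pixels_per_gene)},
        extras={"radius": radius},
    )
    return PointMap(points=points, grid_extent=(w, h)), truth


def planted_zone_bias(mean_counts, zone_tags) -> float:
    """Bias of an expectation vector: (mean CS+ - mean CS-) / SD(all zones)."""
    mean_counts = np.asarray(mean_counts, dtype=float)
    tags = np.asarray(zone_tags)
    diff = mean_counts[tags == "CS+"].mean() - mean_counts[tags == "CS-"].mean()
    sd = mean_counts.std(ddof=1)
    if sd == 0:
        return 0.0 if diff == 0 else float("nan")
    return float(diff / sd)


def zone_expectations_for_bias(
    target_bias: float,
    base: float = 400.0,
    spread: float = 100.0,
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Four-zone expectation vector whose planted bias equals ``target_bias``.

    Solves, within the one-parameter family ``(base + x, base, base,
    base - spread)`` tagged ``(CS+, neutral, neutral, CS-)``, for the x that
    makes :func:`planted_zone_bias` hit the target. The family's bias is
    continuous and strictly increasing in x with range (-2, 2), so any
    target of magnitude < 2 has a unique solution; expectations are checked
    to stay non-negative.
    """
    from scipy.optimize import brentq

    if abs(target_bias) >= 2:
        raise ParameterError("target_bias magnitude must be < 2 for this family")
    if base <= 0 or spread <= 0:
        raise ParameterError("base and spread must be > 0")
    tags = ("CS+", "neutral", "neutral", "CS-")

    def f(x: float) -> float:
        return planted_zone_bias(
            np.array([base + x, base, base, base - spread]), tags
        ) - target_bias

    lo, hi = -(base - 1e-9), 100.0 * (base + spread)
    x = brentq(f, lo, hi, xtol=1e-12, rtol=1e-14)
    v = np.array([base + x, base, base, base - spread])
    if np.any(v < 0):
        raise ParameterError("no non-negative expectation vector for this target")
    return v, tags


def generate_density_sections(
    n_sections: int,
    zone_tags,
    mean_counts,
    rng_seed: int = 0,
) -> tuple[list[DensityProfile], GroundTruth]:
    """Per-section Poisson zone counts with a planted CS+/CS- bias.

    ``zone_tags`` orders the dorsal zones (labels CS+/CS-/neutral, at least
    one CS+ and one CS-); ``mean_counts`` gives the Poisson expectation per
    zone, shared by all sections.
    """
    if n_sections < 1:
        raise ParameterError("n_sections must be >= 1")
    tags = tuple(zone_tags)
    if len(tags) < 2:
        raise ParameterError("need at least 2 zones")
    if "CS+" not in tags or "CS-" not in tags:
        raise ParameterError("need at least one CS+ and one CS- zone tag")
    mean_counts = np.asarray(mean_counts, dtype=float)
    if mean_counts.shape != (len(tags),):
        raise ParameterError("mean_counts must align with zone_tags")
    if np.any(mean_counts < 0):
        raise ParameterError("mean_counts must be >= 0")
    rng = np.random.default_rng(rng_seed)
    profiles = [
        DensityProfile(
            section_id=f"s{i:03d}",
            zone_counts=rng.poisson(mean_counts).astype(float),
            zone_tags=tags,
        )
        for i in range(n_sections)
    ]
    truth = GroundTruth(true_zone_bias=planted_zone_bias(mean_counts, tags))
    return profiles, truth


def generate_behavior_session(
    n_trials: int,
    p_lick_csplus: float,
    p_lick_csminus: float,
    rng_seed: int = 0,
    max_same_odor_run: int = 3,
) -> pd.DataFrame:
    """Pseudorandom go/no-go session with Bernoulli lick outcomes.

    Returns a trial outcome table (``trial_id, odor, licked_in_window,
    outcome``) with ``n_trials`` rows, odors balanced to within one trial.
    """
    if n_trials < 1:
        raise ParameterError("n_trials must be >= 1")
    for name, p in (("p_lick_csplus", p_lick_csplus), ("p_lick_csminus", p_lick_csminus)):
        if not 0 <= p <= 1:
            raise ParameterError(f"{name} must lie in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    odors = pseudorandom_odor_sequence(
        (n_trials + 1) // 2, rng, max_same_odor_run
    )[:n_trials]
    p = np.where(np.array(odors) == CSPLUS, p_lick_csplus, p_lick_csminus)
    licked = rng.random(n_trials) < p
    return pd.DataFrame(
        {
            "trial_id": [f"t{i:03d}" for i in range(n_trials)],
            "odor": odors,
            "licked_in_window": licked,
            "outcome": [outcome_for(o, l) for o, l in zip(odors, licked)],
        }
    )
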