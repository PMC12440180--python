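"""Core in-memory containers shared across the pipeline.

The substrate of all response metrics is :class:`TrialTraceSet`: a dense
``(n_trials, n_rois, n_frames)`` fluorescence array plus a trial table with
odor labels and stimulus frames. Spatial inputs travel as :class:`PointMap`
(labeled 2-D points), immunofluorescence zone counts as
:class:`DensityProfile`, and glomerulus geometry as :class:`FrustumStack`.

Tabular results (response summaries, selectivity, modulation calls) are plain
pandas DataFrames with documented column schemas; see the writer functions in
:mod:`glomlearn.io` for the on-disk dialects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, GeometryError

#: Columns required in every trial table.
TRIAL_COLUMNS = ("trial_id", "odor", "session", "stim_on_frame", "stim_off_frame")

#: Canonical odor labels for the go/no-go task.
CSPLUS = "CS+"
CSMINUS = "CS-"


@dataclass
class TrialTraceSet:
    """Per-trial, per-ROI fluorescence time series with acquisition metadata.

    Parameters
    ----------
    traces
        Array of shape ``(n_trials, n_rois, n_frames)``. Raw fluorescence or
        dF/F depending on pipeline stage.
    sampling_rate_hz
        Acquisition rate in frames per second.
    trial_table
        One row per trial with columns ``trial_id, odor, session,
        stim_on_frame, stim_off_frame``. ``stim_off_frame`` is the last
        stimulus frame (inclusive).
    roi_ids
        Identifier per ROI, length ``n_rois``.
    is_dff
        Whether ``traces`` already hold dF/F values.
    """

    traces: np.ndarray
    sampling_rate_hz: float
    trial_table: pd.DataFrame
    roi_ids: np.ndarray
    is_dff: bool = False

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces, dtype=float)
        if self.traces.ndim != 3:
            raise DataError("traces must be a (n_trials, n_rois, n_frames) array")
        if not np.all(np.isfinite(self.traces)):
            raise DataError("fluorescence values must be finite")
        if self.sampling_rate_hz <= 0:
            raise DataError("sampling_rate_hz must be > 0")
        self.roi_ids = np.asarray(self.roi_ids)
        if self.roi_ids.shape[0] != self.n_rois:
            raise DataError("roi_ids length does not match traces")
        missing = [c for c in TRIAL_COLUMNS if c not in self.trial_table.columns]
        if missing:
            raise DataError(f"trial_table missing columns: {missing}")
        if len(self.trial_table) != self.n_trials:
            raise DataError("trial_table row count does not match traces")
        on = self.trial_table["stim_on_frame"].to_numpy()
        off = self.trial_table["stim_off_frame"].to_numpy()
        if not np.all((on < off) & (off < self.n_frames)):
            raise DataError("require stim_on_frame < stim_off_frame < n_frames")

    @property
    def n_trials(self) -> int:
        return self.traces.shape[0]

    @property
    def n_rois(self) -> int:
        return self.traces.shape[1]

    @property
    def n_frames(self) -> int:
        return self.traces.shape[2]

    @property
    def stim_on_frame(self) -> int:
        """Common stimulus-onset frame (all trials share it in a set)."""
        on = self.trial_table["stim_on_frame"].unique()
        if len(on) != 1:
            raise DataError("trials do not share a stimulus onset frame")
        return int(on[0])

    @property
    def stim_off_frame(self) -> int:
        off = self.trial_table["stim_off_frame"].unique()
        if len(off) != 1:
            raise DataError("trials do not share a stimulus offset frame")
        return int(off[0])

    def roi_index(self, roi_id) -> int:
        idx = np.flatnonzero(self.roi_ids == roi_id)
        if idx.size == 0:
            raise DataError(f"unknown roi_id: {roi_id!r}")
        return int(idx[0])

    def trials_of(self, odor: str) -> np.ndarray:
        """Row indices of trials with the given odor label."""
        mask = (self.trial_table["odor"] == odor).to_numpy()
        if not mask.any():
            raise DataError(f"no trials with odor {odor!r}")
        return np.flatnonzero(mask)

    def odors(self) -> list[str]:
        return list(pd.unique(self.trial_table["odor"]))


@dataclass
class PointMap:
    """Labeled 2-D point sets (transcript pixels or cell centroids).

    ``points`` has columns ``label, x, y``; coordinates are in pixels on a
    grid of ``grid_extent = (width, height)``.
    """

    points: pd.DataFrame
    grid_extent: tuple[float, float]
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        w, h = self.grid_extent
        if w <= 0 or h <= 0:
            raise GeometryError("grid_extent must be positive in both dimensions")
        for col in ("label", "x", "y"):
            if col not in self.points.columns:
                raise DataError(f"points table missing column {col!r}")
        x = self.points["x"].to_numpy(float)
        y = self.points["y"].to_numpy(float)
        if len(x) and (x.min() < 0 or y.min() < 0 or x.max() > w or y.max() > h):
            raise DataError("point coordinates fall outside grid_extent")

    def coords(self, label: str) -> np.ndarray:
        """``(n, 2)`` coordinates of all points carrying ``label``."""
        sub = self.points[self.points["label"] == label]
        if sub.empty:
            raise DataError(f"no points labeled {label!r}")
        return sub[["x", "y"]].to_numpy(float)

    def labels(self) -> list[str]:
        return list(pd.unique(self.points["label"]))


#: Zone tags for density profiles.
ZONE_TAGS = ("CS+", "CS-", "neutral")


@dataclass
class DensityProfile:
    """Per-section vector of cell counts over ordered dorsal zones."""

    section_id: str
    zone_counts: np.ndarray
    zone_tags: tuple[str, ...]
    zone_areas_um2: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.zone_counts = np.asarray(self.zone_counts, dtype=float)
        if np.any(self.zone_counts < 0):
            raise DataError("zone counts must be non-negative")
        if len(self.zone_tags) != self.zone_counts.shape[0]:
            raise DataError("zone_tags length must match zone_counts")
        bad = set(self.zone_tags) - set(ZONE_TAGS)
        if bad:
            raise DataError(f"unknown zone tags: {sorted(bad)}")
        if self.zone_areas_um2 is not None:
            self.zone_areas_um2 = np.asarray(self.zone_areas_um2, dtype=float)
            if np.any(self.zone_areas_um2 <= 0):
                raise GeometryError("zone areas must be positive")

    @property
    def values(self) -> np.ndarray:
        """Density (count/area) when areas are supplied, else raw counts."""
        if self.zone_areas_um2 is not None:
            return self.zone_counts / self.zone_areas_um2
        return self.zone_counts


@dataclass
class FrustumStack:
    """A glomerulus modeled as vertically conjoined frusta.

    ``segments`` is a list of ``(r_top_um, r_bottom_um, h_um)``; adjacent
    segments must share the interface radius.
    """

    segments: list[tuple[float, float, float]]

    def __post_init__(self) -> None:
        if not self.segments:
            raise GeometryError("frustum stack must have at least one segment")
        for r_top, r_bot, h in self.segments:
            if r_top < 0 or r_bot < 0:
                raise GeometryError("frustum radii must be >= 0")
            if h <= 0:
                raise GeometryError("frustum heights must be > 0")
        for (_, r_bot, _), (r_top_next, _, _) in zip(self.segments, self.segments[1:]):
            if not np.isclose(r_bot, r_top_next, rtol=0.0, atol=1e-9):
                raise GeometryError(
                    "adjacent frustum segments must share the interface radius"
                )

    @classmethod
    def from_diameters(cls, diam_segments) -> "FrustumStack":
        """Build from ``(d_top_um, d_bottom_um, h_um)`` tuples (halve to radii)."""
        return cls([(dt / 2.0, db / 2.0, h) for dt, db, h in diam_segments])


@dataclass
class BulbGeometry:
    """Manually traced olfactory-bulb boundary with its area centroid."""

    boundary: np.ndarray  # (n, 2) vertices in image pixels
    centroid: tuple[float, float]
    max_radius: float

    def __post_init__(self) -> None:
        self.boundary = np.asarray(self.boundary, dtype=float)
        if self.boundary.ndim != 2 or self.boundary.shape[1] != 2:
            raise GeometryError("boundary must be an (n, 2) vertex array")
        if self.max_radius <= 0:
            raise GeometryError("max_radius must be > 0")


@dataclass
class GroundTruth:
    """Planted ground truth emitted by the synthetic generators.

    Only the fields relevant to the generator that produced it are filled;
    the rest stay ``None``. Keys of the per-ROI/odor maps are
    ``(roi_id, odor)`` tuples.
    """

    true_amplitudes: dict | None = None
    true_latencies: dict | None = None  # absolute onset frame per (roi, odor)
    true_responsive: dict | None = None
    true_modulated: dict | None = None  # roi_id -> increased/decreased/unchanged
    true_coloc_fraction: dict | None = None  # (gene1, gene2) -> proportion
    true_zone_bias: float | None = None
    extras: dict = field(default_factory=dict)
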