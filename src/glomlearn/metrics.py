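"""Selectivity indexing and response onset-latency detection.

The selectivity index contrasts an ROI's mean peak response to the rewarded
odor (CS+) against the punished odor (CS-), scaled by the spread of all its
per-trial peaks:

    SI = (mean CS+ peaks - mean CS- peaks) / SD(pooled per-trial peaks)

|SI| > 1 labels an ROI highly selective (for CS+ if positive, CS- if
negative); the closed interval [-1, 1] is labeled low so every finite SI
gets a label.

Onset latency is detected on the unsmoothed trial-averaged dF/F: the first
frame at or after stimulus onset that begins a run of ``run_length``
(default 4) consecutive frames all exceeding ``k`` times the baseline SD.
Smoothing is deliberately not applied here, since it would shift onsets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import TrialTraceSet
from .errors import DataError, ParameterError
from .traces import baseline_sd_all, compute_dff

__all__ = [
    "selectivity_index",
    "classify_selectivity",
    "selectivity_table",
    "onset_latency",
    "onset_latency_frame",
    "latency_table",
    "latency_shift",
    "LatencyRecord",
]

HIGH_CSPLUS = "high_csplus"
HIGH_CSMINUS = "high_csminus"
LOW = "low"


def selectivity_index(peaks_csplus, peaks_csminus) -> float:
    """SI = (mean CS+ - mean CS-) / sample SD of the pooled per-trial peaks.

    Positive values mean CS+-preferring. Returns NaN (the undefined-SI
    marker) when the pooled peaks have zero SD; never returns +/-inf.
    """
    a = np.asarray(peaks_csplus, dtype=float)
    b = np.asarray(peaks_csminus, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DataError("both odors need at least one per-trial peak")
    pooled = np.concatenate([a, b])
    if pooled.size < 2:
        raise DataError("need at least 2 pooled peaks for the SD")
    sd = pooled.std(ddof=1)
    if sd == 0:
        return float("nan")
    return float((a.mean() - b.mean()) / sd)


def classify_selectivity(si: float) -> str | None:
    """Map an SI to high_csplus (>1), high_csminus (<-1) or low ([-1, 1]).

    NaN (undefined SI) maps to None and the ROI is dropped from summaries.
    """
    if np.isnan(si):
        return None
    if np.isinf(si):
        raise ParameterError("selectivity index must be finite")
    if si > 1:
        return HIGH_CSPLUS
    if si < -1:
        return HIGH_CSMINUS
    return LOW


@dataclass
class LatencyRecord:
    roi_id: object
    odor: str
    session: object
    onset_frame: int | None
    onset_s: float | None


def onset_latency_frame(
    dff: TrialTraceSet, roi_id, odor: str, k: float = 3.0,
    run_length: int = 4, pre_window_s: float = 2.0,
) -> int | None:
    """First frame starting a suprathreshold run in the trial-averaged dF/F.

    Returns the absolute frame index, or None when no run of ``run_length``
    consecutive frames above ``k * baseline_sd`` exists at/after onset.
    """
    if run_length < 1:
        raise ParameterError("run_length must be >= 1")
    if not dff.is_dff:
        dff = compute_dff(dff)
    r = dff.roi_index(roi_id)
    rows = dff.trials_of(odor)
    mean_trace = dff.traces[rows, r, :].mean(axis=0)
    threshold = float(baseline_sd_all(dff, pre_window_s)[r]) * k
    stim_on = dff.stim_on_frame
    above = mean_trace > threshold
    for t in range(stim_on, dff.n_frames - run_length + 1):
        if above[t : t + run_length].all():
            return t
    return None


def onset_latency(
    dff: TrialTraceSet, roi_id, odor: str, k: float = 3.0,
    run_length: int = 4, pre_window_s: float = 2.0,
) -> LatencyRecord:
    """Full latency record; ``onset_s`` is seconds from stimulus onset."""
    frame = onset_latency_frame(dff, roi_id, odor, k, run_length, pre_window_s)
    session = dff.trial_table["session"].iloc[0]
    if frame is None:
        return LatencyRecord(roi_id, odor, session, None, None)
    onset_s = (frame - dff.stim_on_frame) / dff.sampling_rate_hz
    return LatencyRecord(roi_id, odor, session, frame, onset_s)


def selectivity_table(dff_smoothed_peaks: pd.DataFrame | None = None,
                      dff: TrialTraceSet | None = None,
                      smooth_ms: float = 300.0) -> pd.DataFrame:
    """Per-ROI SI and label table (columns: roi_id, si, label).

    Either pass a per-trial peak table with columns ``roi_id, odor, peak``
    or a dF/F :class:`TrialTraceSet` (smoothed internally).
    """
    from .traces import smooth_moving_average, trial_peaks

    if dff_smoothed_peaks is None:
        if dff is None:
            raise ParameterError("provide a peak table or a trace set")
        sm = smooth_moving_average(dff, smooth_ms)
        peaks = trial_peaks(sm)
        records = []
        for r, roi in enumerate(dff.roi_ids):
            records.extend(
                {"roi_id": roi, "odor": o, "peak": peaks[t, r]}
                for o in dff.odors()
                for t in dff.trials_of(o)
            )
        dff_smoothed_peaks = pd.DataFrame(records)
    rows = []
    for roi, grp in dff_smoothed_peaks.groupby("roi_id", sort=False):
        a = grp.loc[grp["odor"] == "CS+", "peak"].to_numpy()
        b = grp.loc[grp["odor"] == "CS-", "peak"].to_numpy()
        si = selectivity_index(a, b)
        rows.append({"roi_id": roi, "si": si, "label": classify_selectivity(si)})
    return pd.DataFrame(rows)


def latency_table(dff: TrialTraceSet, k: float = 3.0, run_length: int = 4,
                  pre_window_s: float = 2.0) -> pd.DataFrame:
    """Latency records for every (ROI, odor); columns match latency.csv."""
    rows = []
    for odor in dff.odors():
        for roi in dff.roi_ids:
            rec = onset_latency(dff, roi, odor, k, run_length, pre_window_s)
            rows.append(
                {
                    "roi_id": rec.roi_id,
                    "odor": rec.odor,
                    "session": rec.session,
                    "onset_frame": np.nan if rec.onset_frame is None else rec.onset_frame,
                    "onset_s": np.nan if rec.onset_s is None else rec.onset_s,
                }
            )
    return pd.DataFrame(rows)


def latency_shift(pre: pd.DataFrame, post: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Per-(ROI, odor) onset shift in seconds between two sessions.

    Both inputs are latency tables (as from :func:`latency_table`). Returns
    ``(shift_table, n_excluded)`` where the table has columns
    ``roi_id, odor, shift_s`` with ``shift_s = post - pre``, and ROIs with an
    onset in only one session are excluded and counted.
    """
    merged = pre.merge(post, on=["roi_id", "odor"], suffixes=("_pre", "_post"))
    if merged.empty:
        raise DataError("no matched (roi_id, odor) pairs between sessions")
    ok = merged["onset_s_pre"].notna() & merged["onset_s_post"].notna()
    n_excluded = int((~ok).sum())
    out = merged.loc[ok, ["roi_id", "odor"]].copy()
    out["shift_s"] = (
        merged.loc[ok, "onset_s_post"] - merged.loc[ok, "onset_s_pre"]
    ).to_numpy()
    return out.reset_index(drop=True), n_excluded
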