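"""dF/F conversion, smoothing, peak extraction and responsiveness calls.

The processing chain mirrors standard widefield calcium-imaging practice:
raw fluorescence is normalized to a pre-stimulus baseline
(``dF/F = (F - F0)/F0``), smoothed with a short centered moving average
(300 ms by default), and the per-trial peak within the odor window is taken
as the response. An ROI counts as responsive to an odor when its
trial-averaged peak exceeds ``k`` times the SD of its baseline noise
(``k = 3`` by default), the SD being measured on unsmoothed dF/F over a
2-s pre-stimulus window pooled across trials.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .datatypes import TrialTraceSet
from .errors import DataError, ParameterError

__all__ = [
    "compute_dff",
    "smooth_moving_average",
    "trial_peaks",
    "peak_response",
    "baseline_sd",
    "classify_responsive",
    "summarize_responses",
]


def compute_dff(
    traces: TrialTraceSet, baseline_window: tuple[int, int] | None = None
) -> TrialTraceSet:
    """Convert raw fluorescence to dF/F against a pre-stimulus baseline.

    Parameters
    ----------
    traces
        Raw fluorescence trial set.
    baseline_window
        Half-open frame interval ``[start, stop)`` used for the per-trial,
        per-ROI baseline mean F0. Defaults to the full pre-stimulus interval
        ``[0, stim_on_frame)``. Must lie entirely before stimulus onset.

    Returns
    -------
    TrialTraceSet
        New set with ``traces`` holding ``(F - F0)/F0`` and ``is_dff=True``.

    Raises
    ------
    ParameterError
        If the window is empty or extends into the stimulus period.
    DataError
        If any (trial, ROI) baseline mean F0 is <= 0.
    """
    stim_on = traces.stim_on_frame
    if baseline_window is None:
        baseline_window = (0, stim_on)
    start, stop = baseline_window
    if stop <= start:
        raise ParameterError("baseline_window is empty")
    if start < 0 or stop > stim_on:
        raise ParameterError("baseline_window must lie before stimulus onset")
    f0 = traces.traces[:, :, start:stop].mean(axis=2)
    bad = np.argwhere(f0 <= 0)
    if bad.size:
        t, r = bad[0]
        raise DataError(
            f"non-positive baseline F0 for trial "
            f"{traces.trial_table['trial_id'].iloc[t]!r}, roi {traces.roi_ids[r]!r}"
        )
    dff = (traces.traces - f0[:, :, None]) / f0[:, :, None]
    return replace(traces, traces=dff, is_dff=True)


def smoothing_window_frames(window_ms: float, rate_hz: float) -> int:
    """Moving-average width in frames: round(ms * rate / 1000), forced odd upward."""
    w = int(np.floor(window_ms * rate_hz / 1000.0 + 0.5))
    if w < 1:
        raise ParameterError(
            f"smoothing window {window_ms} ms is under one frame at {rate_hz} Hz"
        )
    if w % 2 == 0:
        w += 1
    return w


def smooth_moving_average(dff: TrialTraceSet, window_ms: float = 300.0) -> TrialTraceSet:
    """Centered moving average along frames with shrinking edge windows.

    Edge frames average over whatever part of the window falls inside the
    trace, so no frames are discarded and a constant trace is unchanged.
    """
    w = smoothing_window_frames(window_ms, dff.sampling_rate_hz)
    half = w // 2
    x = dff.traces
    n = x.shape[2]
    # cumulative-sum formulation: mean over [t-half, t+half] clipped to [0, n)
    csum = np.concatenate(
        [np.zeros(x.shape[:2] + (1,)), np.cumsum(x, axis=2)], axis=2
    )
    t = np.arange(n)
    lo = np.clip(t - half, 0, n)
    hi = np.clip(t + half + 1, 0, n)
    smoothed = (csum[:, :, hi] - csum[:, :, lo]) / (hi - lo)
    return replace(dff, traces=smoothed)


def trial_peaks(dff_smoothed: TrialTraceSet, roi_id=None, odor: str | None = None):
    """Per-trial maxima of the smoothed trace over the stimulus window.

    With ``roi_id``/``odor`` given, returns a 1-D array of per-trial peaks for
    that ROI over trials of that odor. With both omitted, returns the full
    ``(n_trials, n_rois)`` peak matrix (used by the vectorized summaries).
    """
    on, off = dff_smoothed.stim_on_frame, dff_smoothed.stim_off_frame
    window = dff_smoothed.traces[:, :, on : off + 1]
    peaks = window.max(axis=2)
    if roi_id is None and odor is None:
        return peaks
    if roi_id is None or odor is None:
        raise ParameterError("give both roi_id and odor, or neither")
    rows = dff_smoothed.trials_of(odor)
    return peaks[rows, dff_smoothed.roi_index(roi_id)]


def peak_response(dff_smoothed: TrialTraceSet, roi_id, odor: str) -> float:
    """Mean over trials of the per-trial stimulus-window peak dF/F."""
    return float(trial_peaks(dff_smoothed, roi_id, odor).mean())


def baseline_sd(dff: TrialTraceSet, roi_id, pre_window_s: float = 2.0) -> float:
    """Sample SD (ddof=1) of dF/F over the pre-stimulus window, pooled across trials.

    The window is the last ``pre_window_s`` seconds before stimulus onset.
    """
    sds = baseline_sd_all(dff, pre_window_s)
    return float(sds[dff.roi_index(roi_id)])


def baseline_sd_all(dff: TrialTraceSet, pre_window_s: float = 2.0) -> np.ndarray:
    """Per-ROI pooled pre-stimulus SD; vectorized form of :func:`baseline_sd`."""
    stim_on = dff.stim_on_frame
    n_pre = int(round(pre_window_s * dff.sampling_rate_hz))
    start = stim_on - n_pre
    if start < 0:
        raise DataError(
            f"pre-stimulus window of {pre_window_s} s does not fit before onset"
        )
    block = dff.traces[:, :, start:stim_on]  # (trials, rois, frames)
    if block.shape[0] * block.shape[2] < 2:
        raise DataError("need at least 2 pooled baseline frames per ROI")
    pooled = np.moveaxis(block, 1, 0).reshape(dff.n_rois, -1)
    return pooled.std(axis=1, ddof=1)


def classify_responsive(peak_dff: float, baseline_sd: float, k: float = 3.0) -> bool:
    """Responsive iff ``peak_dff > k * baseline_sd`` (strict).

    With zero baseline SD this reduces to ``peak_dff > 0``.
    """
    if k < 0:
        raise ParameterError("threshold multiplier k must be >= 0")
    if baseline_sd < 0:
        raise ParameterError("baseline_sd must be >= 0")
    return bool(peak_dff > k * baseline_sd)


def summarize_responses(
    raw: TrialTraceSet,
    baseline_window: tuple[int, int] | None = None,
    smooth_ms: float = 300.0,
    pre_window_s: float = 2.0,
    k: float = 3.0,
    run_length: int = 4,
    per_trial_threshold: bool = False,
) -> pd.DataFrame:
    """Run the full response chain and tabulate one row per (ROI, odor).

    Columns: ``roi_id, odor, peak_dff, baseline_sd, responsive,
    onset_latency_frame`` (latency is NaN when no onset is detected).

    ``per_trial_threshold=True`` applies the ``k*SD`` test to each trial's
    peak and calls the ROI responsive when the median trial is; the default
    tests the trial-averaged peak.
    """
    from .metrics import onset_latency_frame  # local import avoids a cycle

    dff = raw if raw.is_dff else compute_dff(raw, baseline_window)
    smoothed = smooth_moving_average(dff, smooth_ms)
    peaks = trial_peaks(smoothed)  # (n_trials, n_rois)
    sds = baseline_sd_all(dff, pre_window_s)
    rows = []
    for odor in dff.odors():
        tr = dff.trials_of(odor)
        mean_peaks = peaks[tr].mean(axis=0)
        for r, roi in enumerate(dff.roi_ids):
            if per_trial_threshold:
                responsive = bool(np.median(peaks[tr, r] > k * sds[r]) > 0.5)
            else:
                responsive = classify_responsive(mean_peaks[r], sds[r], k)
            onset = onset_latency_frame(dff, roi, odor, k=k, run_length=run_length)
            rows.append(
                {
                    "roi_id": roi,
                    "odor": odor,
                    "peak_dff": float(mean_peaks[r]),
                    "baseline_sd": float(sds[r]),
                    "responsive": responsive,
                    "onset_latency_frame": np.nan if onset is None else onset,
                }
            )
    return pd.DataFrame(rows)
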