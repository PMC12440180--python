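"""Go/no-go trial scoring and session discrimination accuracy.

A trial is scored from whether the animal licked inside the response window
— a 3-s window opening 0.3 s after odor delivery (anchored at odor offset by
default; onset anchoring is available since "after odor delivery" admits
both readings). Licking on CS+ is a hit, withholding a miss; licking on CS-
is a false alarm, withholding a correct rejection. Session accuracy is the
balanced mean of the hit rate and the correct-rejection rate, so unequal
trial counts per odor cannot skew it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import CSMINUS, CSPLUS
from .errors import DataError, ParameterError

__all__ = ["score_trials", "outcome_for", "session_accuracy", "session_summary"]

HIT = "hit"
MISS = "miss"
FALSE_ALARM = "false_alarm"
CORRECT_REJECTION = "correct_rejection"


def outcome_for(odor: str, licked: bool) -> str:
    if odor == CSPLUS:
        return HIT if licked else MISS
    if odor == CSMINUS:
        return FALSE_ALARM if licked else CORRECT_REJECTION
    raise DataError(f"unknown odor label: {odor!r}")


def score_trials(
    trials: pd.DataFrame,
    licks: pd.DataFrame,
    window_delay_s: float = 0.3,
    window_dur_s: float = 3.0,
    anchor: str = "offset",
) -> pd.DataFrame:
    """Score each trial into hit/miss/false_alarm/correct_rejection.

    Parameters
    ----------
    trials
        One row per trial with ``trial_id, odor`` and ``odor_on_s,
        odor_off_s`` (trial-relative seconds).
    licks
        ``trial_id, lick_time_s`` rows, zero or more per trial.
    window_delay_s, window_dur_s
        The response window is ``[anchor_time + delay, anchor_time + delay +
        duration)`` — closed at the start, open at the end, so a lick exactly
        at the window start counts.
    anchor
        ``"offset"`` (default) anchors at odor offset, ``"onset"`` at onset.

    Returns
    -------
    Copy of ``trials`` with ``licked_in_window`` and ``outcome`` columns.
    """
    if window_dur_s <= 0 or window_delay_s < 0:
        raise ParameterError("window must have positive duration, delay >= 0")
    if anchor not in ("onset", "offset"):
        raise ParameterError("anchor must be 'onset' or 'offset'")
    anchor_col = "odor_on_s" if anchor == "onset" else "odor_off_s"
    out = trials.copy()
    lick_groups = dict(tuple(licks.groupby("trial_id")["lick_time_s"])) if len(licks) else {}
    licked = []
    for _, row in out.iterrows():
        t0 = row[anchor_col] + window_delay_s
        t1 = t0 + window_dur_s
        times = lick_groups.get(row["trial_id"])
        hit_window = False
        if times is not None:
            ts = times.to_numpy(float)
            hit_window = bool(np.any((ts >= t0) & (ts < t1)))
        licked.append(hit_window)
    out["licked_in_window"] = licked
    out["outcome"] = [
        outcome_for(o, l) for o, l in zip(out["odor"], out["licked_in_window"])
    ]
    return out


def session_accuracy(table: pd.DataFrame, pooled: bool = False) -> float:
    """Discrimination accuracy of a scored trial table.

    Balanced by default: ``((hits / n_CS+) + (CRs / n_CS-)) / 2``. With
    ``pooled=True`` returns the raw fraction of correct trials instead.
    """
    cs_plus = table[table["odor"] == CSPLUS]
    cs_minus = table[table["odor"] == CSMINUS]
    if cs_plus.empty or cs_minus.empty:
        raise DataError("need at least one trial of each odor")
    hit_rate = float((cs_plus["outcome"] == HIT).mean())
    cr_rate = float((cs_minus["outcome"] == CORRECT_REJECTION).mean())
    if pooled:
        n_correct = (cs_plus["outcome"] == HIT).sum() + (
            cs_minus["outcome"] == CORRECT_REJECTION
        ).sum()
        return float(n_correct / len(table))
    return (hit_rate + cr_rate) / 2.0


def session_summary(table: pd.DataFrame) -> pd.DataFrame:
    """One-row summary: accuracy, CR rate, and lick frequency per odor."""
    cs_plus = table[table["odor"] == CSPLUS]
    cs_minus = table[table["odor"] == CSMINUS]
    return pd.DataFrame(
        [
            {
                "accuracy": session_accuracy(table),
                "cr_rate": float(
                    (cs_minus["outcome"] == CORRECT_REJECTION).mean()
                ),
                "hit_rate": float((cs_plus["outcome"] == HIT).mean()),
                "lick_freq_csplus": float(cs_plus["licked_in_window"].mean()),
                "lick_freq_csminus": float(cs_minus["licked_in_window"].mean()),
                "n_trials": len(table),
            }
        ]
    )
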