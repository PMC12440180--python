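"""Permutation-based modulation testing with Benjamini-Hochberg FDR control.

Each ROI's per-trial peak responses under two conditions (e.g. sessions
before and after odor-reward learning) are compared with a Welch two-sample
t statistic. The null distribution is built by pooling all trials and
reassigning condition labels uniformly at random ``n_perm`` times (1,000 by
default), so the test makes no normality assumption — the t statistic is
only the ranking device. Two-sided p-values use the add-one correction

    p = (1 + #{|t_perm| >= |t_obs|}) / (n_perm + 1)

which keeps p strictly inside (0, 1]. Across ROIs the p-values are adjusted
with the step-up Benjamini-Hochberg procedure and each ROI is called
``increased`` (q < alpha, t > 0), ``decreased`` (q < alpha, t < 0) or
``unchanged``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, ParameterError

__all__ = [
    "PermutationConfig",
    "permutation_test",
    "welch_t",
    "benjamini_hochberg",
    "classify_modulation",
    "modulation_table",
    "INCREASED",
    "DECREASED",
    "UNCHANGED",
]

INCREASED = "increased"
DECREASED = "decreased"
UNCHANGED = "unchanged"


@dataclass
class PermutationConfig:
    n_perm: int = 1000
    alpha: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ParameterError("n_perm must be >= 1")
        if not 0 < self.alpha < 1:
            raise ParameterError("alpha must lie in (0, 1)")


def welch_t(a: np.ndarray, b: np.ndarray) -> float:
    """Welch t statistic of b vs a (positive when b exceeds a)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    denom = np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
    if denom == 0:
        return 0.0
    return float((b.mean() - a.mean()) / denom)


def _welch_t_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Welch t of b vs a for (n_perm, n) group matrices."""
    na, nb = a.shape[1], b.shape[1]
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    denom = np.sqrt(va / na + vb / nb)
    num = b.mean(axis=1) - a.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = num / denom
        # 0/0 (both groups constant) is a null tie: score it 0; x/0 with
        # x != 0 stays +/-inf and always beats any finite observed t.
        t = np.where(denom == 0, np.where(num == 0, 0.0, np.sign(num) * np.inf), t)
    return t


def permutation_test(
    peaks_a,
    peaks_b,
    cfg: PermutationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Two-sided trial-identity permutation test on per-trial peaks.

    Parameters
    ----------
    peaks_a, peaks_b
        Per-trial peak responses under conditions A and B (>= 2 each).
    cfg
        Number of permutations, alpha and seed; defaults to 1,000 / 0.05 / 0.
    rng
        Optional generator overriding ``cfg.rng_seed`` (used by the batch
        driver so ROIs draw from one stream).

    Returns
    -------
    (t_obs, p_perm)
        Observed Welch t of B vs A and the add-one permutation p-value.
    """
    cfg = cfg or PermutationConfig()
    a = np.asarray(peaks_a, float)
    b = np.asarray(peaks_b, float)
    if a.size < 2 or b.size < 2:
        raise DataError("each condition needs at least 2 trials")
    t_obs = welch_t(a, b)
    pooled = np.concatenate([a, b])
    if pooled.std(ddof=1) == 0:
        return t_obs, 1.0
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    n = pooled.size
    idx = np.argsort(rng.random((cfg.n_perm, n)), axis=1)
    shuffled = pooled[idx]
    t_perm = _welch_t_matrix(shuffled[:, : a.size], shuffled[:, a.size :])
    exceed = int(np.count_nonzero(np.abs(t_perm) >= abs(t_obs)))
    p = (1 + exceed) / (cfg.n_perm + 1)
    return t_obs, float(p)


def benjamini_hochberg(pvals, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Step-up BH adjustment; returns (adjusted p, reject flags) in input order.

    Adjusted values are ``q_(i) = min over j >= i of p_(j) * m / j`` capped at
    1; rejection is strict (``q < alpha``). An empty input yields empty arrays.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ParameterError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    adj = np.empty(m)
    adj[order] = adj_sorted
    return adj, adj < alpha


def classify_modulation(t_obs: np.ndarray, p_adj: np.ndarray, alpha: float = 0.05):
    """Direction call per ROI from the signed statistic and adjusted p."""
    t_obs = np.asarray(t_obs, float)
    p_adj = np.asarray(p_adj, float)
    out = np.full(t_obs.shape, UNCHANGED, dtype=object)
    sig = p_adj < alpha
    out[sig & (t_obs > 0)] = INCREASED
    out[sig & (t_obs < 0)] = DECREASED
    return out


def modulation_table(
    peaks_a: np.ndarray,
    peaks_b: np.ndarray,
    roi_ids,
    cfg: PermutationConfig | None = None,
) -> pd.DataFrame:
    """Per-ROI permutation test + BH over a session pair.

    ``peaks_a`` and ``peaks_b`` are ``(n_trials, n_rois)`` per-trial peak
    matrices for the two conditions. Returns a DataFrame with columns
    ``roi_id, t_obs, p_perm, p_adj, direction``. A single seeded generator
    drives all ROIs, so results are reproducible given ``cfg.rng_seed``.
    """
    cfg = cfg or PermutationConfig()
    peaks_a = np.asarray(peaks_a, float)
    peaks_b = np.asarray(peaks_b, float)
    if peaks_a.shape[1] != peaks_b.shape[1]:
        raise DataError("conditions must cover the same ROIs")
    rng = np.random.default_rng(cfg.rng_seed)
    t_all = np.empty(peaks_a.shape[1])
    p_all = np.empty(peaks_a.shape[1])
    for r in range(peaks_a.shape[1]):
        t_all[r], p_all[r] = permutation_test(peaks_a[:, r], peaks_b[:, r], cfg, rng)
    p_adj, _ = benjamini_hochberg(p_all, cfg.alpha)
    direction = classify_modulation(t_all, p_adj, cfg.alpha)
    return pd.DataFrame(
        {
            "roi_id": np.asarray(roi_ids),
            "t_obs": t_all,
            "p_perm": p_all,
            "p_adj": p_adj,
            "direction": direction,
        }
    )
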