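"""Pipeline configuration: one YAML file, validated on load.

Defaults reproduce the analysis parameter set used throughout: 2-s baseline
window, 300-ms smoothing, 3x-SD responsiveness threshold, four-frame onset
run, 1,000 permutations at alpha = 0.05, and a 3-s response window opening
0.3 s after odor delivery. The colocalization radius has no principled
default and must be set explicitly before the coloc stage runs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ParameterError

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass
class PipelineConfig:
    baseline_s: float = 2.0
    smooth_ms: float = 300.0
    k_threshold: float = 3.0
    run_length: int = 4
    n_perm: int = 1000
    alpha: float = 0.05
    coloc_radius_px: float | None = None
    window_delay_s: float = 0.3
    window_dur_s: float = 3.0
    window_anchor: str = "offset"
    rng_seed: int = 0
    # +x lateral, +y anterior; angle counter-clockwise from +x
    axis_convention: str = "x_lateral_y_anterior"
    simulate: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.baseline_s <= 0:
            raise ParameterError("baseline_s must be > 0")
        if self.smooth_ms <= 0:
            raise ParameterError("smooth_ms must be > 0")
        if self.k_threshold < 0:
            raise ParameterError("k_threshold must be >= 0")
        if self.run_length < 1:
            raise ParameterError("run_length must be >= 1")
        if self.n_perm < 1:
            raise ParameterError("n_perm must be >= 1")
        if not 0 < self.alpha < 1:
            raise ParameterError("alpha must lie in (0, 1)")
        if self.coloc_radius_px is not None and self.coloc_radius_px < 0:
            raise ParameterError("coloc_radius_px must be >= 0")
        if self.window_delay_s < 0 or self.window_dur_s <= 0:
            raise ParameterError("response window must have delay >= 0, duration > 0")
        if self.window_anchor not in ("onset", "offset"):
            raise ParameterError("window_anchor must be 'onset' or 'offset'")

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ParameterError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


def save_config(cfg: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
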