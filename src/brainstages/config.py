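"""Run configuration: every analysis choice in one serializable object.

All the knobs the method leaves open (band mode, grid step, extrapolation
window, divergence rule, reference age, staging gap threshold, grouping
map) are surfaced here with their defaults, so sensitivity analyses are a
one-flag change and every run's manifest can state exactly what was done.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .staging import DEFAULT_ANATOMICAL_GROUPS, DEFAULT_GAP_THRESHOLD


@dataclass
class RunConfig:
    """Options for an end-to-end staging run.

    Attributes
    ----------
    band_mode
        'mean' for confidence bounds of the mean curve (default), or
        'observation' for new-observation prediction bounds.
    grid_step
        Age-grid resolution in years; onsets are reported at this precision.
    extrapolation_window
        Years the evaluation grid may extend past a model's training ages.
        The default (8) lets a patient window ending around 86 still cover
        the reference age 90 even when the oldest sampled patient falls a
        few years short of the window edge, as lifespan extrapolation
        requires.
    reference_age
        Age (years) at which the severity distance is read off.
    divergence_rule
        'sustained' (non-overlap must hold to the grid end) or 'first'.
    gap_threshold
        Maximum onset gap (years) merged into one stage.
    grouping
        'default' for the built-in anatomical map, 'none' for
        every-structure-its-own-group, or a path to a YAML/JSON map.
    """

    band_mode: str = "mean"
    level: float = 0.95
    grid_step: float = 0.5
    extrapolation_window: float = 8.0
    alpha: float = 0.05
    include_intercept_gate: bool = False
    reference_age: float = 90.0
    divergence_rule: str = "sustained"
    gap_threshold: float = DEFAULT_GAP_THRESHOLD
    grouping: str = "default"
    reference_group: str = "control"
    seed: int | None = None
    extras: dict = field(default_factory=dict)

    def grouping_map(self) -> dict[str, str] | None:
        if self.grouping == "default":
            return dict(DEFAULT_ANATOMICAL_GROUPS)
        if self.grouping in ("none", None):
            return None
        path = Path(self.grouping)
        raw = (json.loads(path.read_text()) if path.suffix == ".json"
               else yaml.safe_load(path.read_text()))
        return dict(raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        return cls(**known)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)
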