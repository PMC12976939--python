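"""Run configuration with reference defaults.

Defaults reproduce the reference study conditions: 4,050 px/mm calibration,
0.2 mm² HPF, 512 px windows at 30% overlap, 50% confidence and IOU
thresholds, and the median >= 5 per-HPF diagnosis rule. Config files are
flat YAML key-value documents; CLI flags override file values.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .errors import ValidationError


@dataclass
class RunConfig:
    px_per_mm: float = 4050.0
    hpf_area: float = 0.2
    window: int = 512
    overlap: float = 0.3
    confidence_threshold: float = 0.5
    iou_threshold: float = 0.5
    diagnosis_threshold: float = 5.0
    diagnosis_rule: str = "ge"
    exclude_uncertain: bool = True
    tile_size: int = 224
    target_size: int = 40
    mean_count_infected: float = 8.0
    mean_count_sterile: float = 2.0
    count_dispersion: float = 3.0
    n_hpf: int = 200
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValidationError(f"{path}: config must be a flat key-value mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"{path}: unknown config keys {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
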