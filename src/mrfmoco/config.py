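"""Pipeline configuration: YAML-backed, with desk and paper-scale presets.

Every protocol number is a default and can be overridden from a YAML file or
keyword arguments.  The "paper" preset mirrors the reference protocol
(160 matrix / 320 mm FOV / 1750 time points / window 50 / rank 10); the
"desk" preset is a small, fast configuration for development and CI.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "PRESETS"]


@dataclass
class PipelineConfig:
    # geometry
    matrix: int = 160
    fov_mm: float = 320.0
    n_samples: int | None = None  # per spoke; defaults to matrix
    # sequence
    n_timepoints: int = 1750
    tr_ms: float = 4.3
    te_ms: float = 1.23
    invert: bool = True
    fa_csv: str | None = None  # optional flip-angle schedule override
    slice_profile_points: int = 50
    # recon
    window: int = 50
    stride: int = 1
    cg_iters: int = 15
    rank: int = 10
    # registration
    bins: int = 32
    reference_stride: int = 100
    # dictionary (segments of (start, step, stop), ms)
    t1_grid: list = field(
        default_factory=lambda: [[0, 30, 200], [200, 10, 600], [600, 20, 1200], [1200, 30, 1600]]
    )
    t2_grid: list = field(
        default_factory=lambda: [[0, 2, 70], [70, 10, 120], [120, 5, 270]]
    )
    # simulation
    phantom: str = "brain"  # or "vials"
    n_coils: int = 4
    motion_kind: str = "none"  # none | abrupt | sinusoidal
    motion_event_timepoint: int = 250
    motion_tx_px: float = 8.0
    motion_ty_px: float = 2.0
    motion_theta_deg: float = 12.0
    motion_cycles: float = 3.0
    noise_sd: float = 0.0
    seed: int = 0
    # io
    out_dir: str = "mrfmoco_out"

    @property
    def pixel_mm(self) -> float:
        return self.fov_mm / self.matrix

    @property
    def samples_per_spoke(self) -> int:
        return self.n_samples if self.n_samples is not None else self.matrix

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        raw.update(overrides)
        return cls(**raw)

    @classmethod
    def preset(cls, name: str, **overrides) -> "PipelineConfig":
        if name not in PRESETS:
            raise ValueError(f"unknown preset {name!r}; options: {sorted(PRESETS)}")
        kw = dict(PRESETS[name])
        kw.update(overrides)
        return cls(**kw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


PRESETS = {
    # full-scale protocol
    "paper": {},
    # small fast configuration for development and CI
    "desk": {
        "matrix": 64,
        "n_timepoints": 500,
        "stride": 10,
        "n_coils": 4,
        "slice_profile_points": 5,
        "rank": 6,
        "t1_grid": [[100, 60, 2000], [2000, 500, 4500]],
        "t2_grid": [[10, 8, 120], [120, 60, 2100]],
    },
}
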