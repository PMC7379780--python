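"""Run configuration: stage parameters with the study's published defaults.

Every stage parameter defaults to the value the study states where one
exists: background threshold 500, plaque-selection distances 50 µm,
radial counting distances 10/20/40/60 µm, FISH ROI radius 50 µm with 4
background ROIs, network β = 10, minimum module size 44, merge cut
height 0.25, hub thresholds GS > 0.2 / MM > 0.8 with top-5 hubs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Configuration for the end-to-end pipeline run."""

    seed: int = 0
    outdir: str = "plaquekit_run"
    # inputs; empty means the simulate stage provides them
    stack_paths: list[str] = field(default_factory=list)
    channel_map: dict[str, int] | None = None
    voxel_size: tuple[float, float, float] | None = None
    # simulate stage
    simulate: dict = field(default_factory=lambda: {"n_plaques": 20, "zero_growth": True})
    # volumetry stage
    background_threshold: float = 500.0
    min_object_voxels: int = 10
    connectivity: int = 26
    min_edge_dist: float = 50.0
    min_neighbor_dist: float = 50.0
    apply_inclusion: bool = False
    # histology / FISH
    radial_distances: tuple[float, ...] = (10.0, 20.0, 40.0, 60.0)
    fish_radius: float = 50.0
    fish_n_background: int = 4
    # co-expression
    beta: float = 10.0
    min_module_size: int = 44
    merge_cut: float = 0.25
    gs_min: float = 0.2
    mm_min: float = 0.8
    top_hubs: int = 5
    stages: tuple[str, ...] = ("simulate", "volumetry", "stats")

    def __post_init__(self) -> None:
        if self.background_threshold < 0:
            raise ValueError("background_threshold must be >= 0")
        if self.min_edge_dist < 0 or self.min_neighbor_dist < 0:
            raise ValueError("selection distances must be >= 0")
        if list(self.radial_distances) != sorted(self.radial_distances):
            raise ValueError("radial_distances must be increasing")
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if not 0 <= self.merge_cut <= 1:
            raise ValueError("merge_cut must lie in [0, 1]")
        unknown = set(self.stages) - {"simulate", "volumetry", "stats"}
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for tup_key in ("voxel_size", "radial_distances", "stages"):
            if tup_key in payload and payload[tup_key] is not None:
                payload[tup_key] = tuple(payload[tup_key])
        return cls(**payload)

    def to_dict(self) -> dict:
        return asdict(self)
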