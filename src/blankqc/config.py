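"""Pipeline configuration: the analysis constants and stage parameters.

The screening thresholds (blank ratio > 9, coverage > 90%, QC RSD < 20%),
the permutation count m = 1000 and the FDR level 0.05 are the method's
fixed operating constants; everything else (grid resolutions, linkage,
reference selection) is an implementation knob with a documented default.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .simulate import SimulationConfig


@dataclass
class SvrcConfig:
    reference_j: int = 1  # pre-blank samples per cycle used as references
    n_eps: int = 8
    n_gamma: int = 26
    trend_floor_frac: float = 1e-6


@dataclass
class ScreenConfig:
    blank_ratio: float = 9.0
    coverage: float = 0.90
    qc_rsd: float = 20.0
    match_fraction: float = 1.0
    include_qc_as_samples: bool = False


@dataclass
class GpcaConfig:
    m: int = 1000
    seed: int = 0
    fdr_alpha: float = 0.05
    reference_position: int = 8


@dataclass
class ClusterConfig:
    k: int = 2
    linkage: str = "average"


@dataclass
class PipelineConfig:
    svrc: SvrcConfig = field(default_factory=SvrcConfig)
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    gpca: GpcaConfig = field(default_factory=GpcaConfig)
    clustering: ClusterConfig = field(default_factory=ClusterConfig)
    simulate: SimulationConfig | None = None

    def __post_init__(self):
        if not 0 < self.gpca.fdr_alpha < 1:
            raise ValueError("fdr_alpha must be in (0, 1)")
        for name in ("blank_ratio", "coverage", "qc_rsd"):
            if getattr(self.screen, name) <= 0:
                raise ValueError(f"screen threshold {name} must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.simulate is not None:
            d["simulate"]["decondition_params"] = {
                c: asdict(p) for c, p in self.simulate.decondition_params.items()
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d or {})
        kw = {}
        for name, sub in (
            ("svrc", SvrcConfig),
            ("screen", ScreenConfig),
            ("gpca", GpcaConfig),
            ("clustering", ClusterConfig),
        ):
            if name in d:
                kw[name] = sub(**d.pop(name))
        if d.get("simulate") is not None:
            kw["simulate"] = SimulationConfig.from_dict(d.pop("simulate"))
        else:
            d.pop("simulate", None)
        if d:
            raise ValueError(f"unknown config keys {sorted(d)}")
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(Path(path)) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
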