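"""Analysis configuration: every documented convention toggle in one place.

The YAML layout mirrors the sections below::

    preprocess:
      rate: 4.0
      interpolation: cubic        # or linear
      fence: multiplicative       # or tukey
    classa:
      short_window: 10.0
      long_window: 60.0
      step: 1.0
      tau: 7
      denominator: samples        # or points
    traditional:
      window: 300.0
      step: 1.0
      m_se: 2
      r_factor: 0.15
      m_pe: 6
    stats:
      pairwise_family_alpha: 0.05
      spearman_family_alpha: 0.05
    protocol:
      gap: 60.0
      epochs:
        - [rest, 900.0]
        - [arithmetic, 900.0]
        - [meditation1, 900.0]
        - [exercise, 900.0]
        - [meditation2, 900.0]
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "PreprocessConfig",
    "ClassAConfig",
    "TraditionalConfig",
    "StatsConfig",
    "AnalysisConfig",
]


@dataclass
class PreprocessConfig:
    rate: float = 4.0
    interpolation: str = "cubic"
    fence: str = "multiplicative"


@dataclass
class ClassAConfig:
    short_window: float = 10.0
    long_window: float = 60.0
    step: float = 1.0
    tau: int = 7
    denominator: str = "samples"


@dataclass
class TraditionalConfig:
    window: float = 300.0
    step: float = 1.0
    m_se: int = 2
    r_factor: float = 0.15
    m_pe: int = 6

    def entropy_params(self):
        from .traditional import EntropyParams

        return EntropyParams(m_se=self.m_se, r_factor=self.r_factor, m_pe=self.m_pe)


@dataclass
class StatsConfig:
    pairwise_family_alpha: float = 0.05
    spearman_family_alpha: float = 0.05


@dataclass
class AnalysisConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    classa: ClassAConfig = field(default_factory=ClassAConfig)
    traditional: TraditionalConfig = field(default_factory=TraditionalConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    protocol_epochs: list[tuple[str, float]] | None = None
    protocol_gap: float = 60.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(
            preprocess=PreprocessConfig(**raw.get("preprocess", {})),
            classa=ClassAConfig(**raw.get("classa", {})),
            traditional=TraditionalConfig(**raw.get("traditional", {})),
            stats=StatsConfig(**raw.get("stats", {})),
        )
        proto = raw.get("protocol")
        if proto:
            cfg.protocol_gap = float(proto.get("gap", 60.0))
            if "epochs" in proto:
                cfg.protocol_epochs = [
                    (str(label), float(dur)) for label, dur in proto["epochs"]
                ]
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "preprocess": asdict(self.preprocess),
            "classa": asdict(self.classa),
            "traditional": asdict(self.traditional),
            "stats": asdict(self.stats),
        }
        if self.protocol_epochs is not None:
            data["protocol"] = {
                "gap": self.protocol_gap,
                "epochs": [list(e) for e in self.protocol_epochs],
            }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    def protocol(self):
        from .pipeline import ProtocolConfig

        if self.protocol_epochs is None:
            return ProtocolConfig(gap=self.protocol_gap)
        return ProtocolConfig(epochs=list(self.protocol_epochs), gap=self.protocol_gap)
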