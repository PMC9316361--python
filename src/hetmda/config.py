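"""Run configuration: one YAML file covering the whole pipeline.

The file nests the model, restart-walk, protocol and generator parameters,
round-trips losslessly, and hashes canonically so every output artifact can
record exactly which configuration produced it.  All randomness flows from
the single top-level ``seed``, fanned out to named sub-streams inside the
modules.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .evaluation import CVProtocol
from .model import ModelConfig
from .rwr import RestartConfig
from .synthetic import SyntheticSpec

__all__ = ["RunConfig", "config_hash"]


@dataclass
class RunConfig:
    """Paths + nested component configurations for a pipeline run."""

    sm_path: str = "mirna_similarity.tsv"
    sd_path: str = "disease_similarity.tsv"
    assoc_path: str = "associations.tsv"
    output_dir: str = "output"
    seed: int = 0
    log_level: str = "INFO"
    model: ModelConfig = field(default_factory=ModelConfig)
    restart: RestartConfig = field(default_factory=RestartConfig)
    protocol: CVProtocol = field(default_factory=CVProtocol)
    synthetic: SyntheticSpec = field(default_factory=SyntheticSpec)

    def __post_init__(self) -> None:
        # the top-level seed is the single source of randomness
        self.model.seed = self.seed
        self.protocol.seed = self.seed
        self.synthetic.seed = self.seed

    def to_dict(self) -> dict:
        d = asdict(self)
        d["synthetic"]["block_assoc_prob"] = self.synthetic.block_assoc_prob.tolist()
        return d

    def dump(self, path: Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        model = ModelConfig(**d.pop("model", {}))
        restart = RestartConfig(**d.pop("restart", {}))
        protocol = CVProtocol(**d.pop("protocol", {}))
        synthetic = SyntheticSpec(**d.pop("synthetic", {}))
        return cls(model=model, restart=restart, protocol=protocol, synthetic=synthetic, **d)


def config_hash(cfg: RunConfig) -> str:
    """Short stable digest of the canonical JSON form."""
    canon = json.dumps(cfg.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
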