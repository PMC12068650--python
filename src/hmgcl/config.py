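"""Run configuration: validated YAML with strict key checking."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, fields

import yaml

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    d: int = 16                 # encoder hidden width
    heads: int = 2              # attention heads
    layers: int = 2             # message-passing rounds
    pool_ratio: float = 0.5     # SAGPool keep fraction r
    tau: float = 0.1            # contrastive temperature
    batch_size: int = 10        # N
    complement_size: int = 1    # n (random drug fills per batch)
    lr: float = 1e-3
    epochs: int = 200
    steps: int = 50             # pre-training steps
    d_kg: int = 16              # drug-KG embedding width
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d % self.heads:
            raise ValueError("d must be divisible by heads")
        if not 0 < self.pool_ratio <= 1:
            raise ValueError("pool_ratio must be in (0, 1]")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        logger.info("resolved config: %s", json.dumps(asdict(cfg)))
        return cfg

    def dump(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)
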