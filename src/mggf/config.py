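"""Run configuration: one serializable object for the full study pipeline.

Each stage (cohort draw, augmentation noise, split, model) carries its own
seed so stages are independently reproducible; there is no hidden global
randomness.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .augment import AugmentSpec
from .cohort import CohortSpec
from .fusion import MggfConfig


def _from_dict(cls, raw: dict):
    kwargs = {}
    for f in fields(cls):
        if f.name not in raw:
            continue
        v = raw[f.name]
        if isinstance(v, list):
            v = tuple(v)
        kwargs[f.name] = v
    return cls(**kwargs)


@dataclass
class RunConfig:
    cohort: CohortSpec = field(default_factory=CohortSpec)
    augment: AugmentSpec = field(default_factory=AugmentSpec)
    mggf: MggfConfig = field(default_factory=MggfConfig)
    split_ratio: float = 0.2   # test fraction (train:test = 4:1)
    split_seed: int = 0
    # group the split by source patient so augmentation copies never leak
    # across the train/test boundary; False reproduces a plain row split
    split_by_source: bool = True
    baseline_C: float = 1.0
    baseline_max_depth: int = 4
    mantel_permutations: int = 999

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "cohort" in kwargs:
            kwargs["cohort"] = _from_dict(CohortSpec, kwargs["cohort"])
        if "augment" in kwargs:
            kwargs["augment"] = _from_dict(AugmentSpec, kwargs["augment"])
        if "mggf" in kwargs:
            kwargs["mggf"] = _from_dict(MggfConfig, kwargs["mggf"])
        known = {f.name for f in fields(cls)}
        return cls(**{k: v for k, v in kwargs.items() if k in known})

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def with_seed(self, seed: int) -> "RunConfig":
        """Re-key every stage seed deterministically from one base seed."""
        cfg = RunConfig.from_dict(self.to_dict())
        cfg.cohort.seed = seed % (2 ** 31)
        cfg.augment.seed = (seed + 1) % (2 ** 31)
        cfg.split_seed = (seed + 2) % (2 ** 31)
        cfg.mggf.seed = (seed + 3) % (2 ** 31)
        return cfg
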