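"""Run configuration, seeding and provenance.

One global seed fans out to per-stage child seeds through
``numpy.random.SeedSequence((seed, stage_index))`` so each stage is
independently reproducible; the full configuration (plus its hash) is
serialized into every output's provenance block.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

__all__ = ["RunConfig", "child_seed", "config_hash", "SCHEMA_VERSION"]

SCHEMA_VERSION = "1"

_STAGES = ("imaging", "correction", "compare", "survival", "metabolomics", "gsea")


def child_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child of the global seed (< 2**31)."""
    if stage not in _STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence((int(seed), _STAGES.index(stage)))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (defaults run the demo workflow)."""

    seed: int = 0
    outdir: str = "dormaflux_run"
    # imaging demo: mice per phase group, image size
    n_mice_per_phase: int = 3
    image_size: int = 128
    probe: str = "TMRE"
    line: str = "fast"
    phases: tuple[str, ...] = ("primary", "regression")
    n_permutations: int = 1000
    # survival demo
    n_mice_survival: int = 30
    arms: tuple[str, ...] = ("control", "etomoxir")
    recurrence_delta: float = 0.10
    # metabolomics demo
    knn_k: int = 10
    # gsea demo
    n_genes: int = 2000
    geneset_size: int = 50
    expression_effect: float = 1.0

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        data = dict(data)
        for key in ("phases", "arms"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["phases"] = list(d["phases"])
        d["arms"] = list(d["arms"])
        d["schema_version"] = SCHEMA_VERSION
        return d


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
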