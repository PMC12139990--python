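"""Structured run configuration shared by all CLI stages."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Optional

import yaml

from .errors import ValidationError


@dataclass
class RunConfig:
    # input paths
    compounds: Optional[str] = None
    binding_sites: Optional[str] = None
    mapping: Optional[str] = None
    gold: Optional[str] = None
    # output directory; stage artifacts are written under it with fixed names
    outdir: str = "results"
    # fingerprinting / scoring
    fingerprint_width: int = 2048
    scoring_variant: str = "max-dice"
    # ranking / prediction
    cutoffs: list[int] = field(default_factory=lambda: [10, 25, 50, 100])
    prediction_cutoff: int = 100
    top_n: int = 100
    control_k: int = 24
    target_depth: int = 10
    jaccard_cutoff: int = 10
    include_approved: bool = False
    strict_loo_nia: bool = False
    matrix_precision: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scoring_variant not in ("max-dice", "max-product"):
            raise ValidationError(f"unknown scoring variant {self.scoring_variant!r}")
        if self.prediction_cutoff < 1 or self.top_n < 1:
            raise ValidationError("prediction_cutoff and top_n must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def hash(self) -> str:
        """Stable 12-hex-digit digest of the resolved configuration."""
        canonical = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]

    def path(self, name: str) -> Path:
        return Path(self.outdir) / name
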