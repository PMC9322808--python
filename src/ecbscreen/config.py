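"""Strict run configuration for the pipeline and CLI.

Every config level rejects unknown keys outright: silently defaulting a
misspelled key is the main source of irreproducible screens.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from ecbscreen.chem import FingerprintConfig
from ecbscreen.pairs import TrainingConfig
from ecbscreen.screening import FunnelStage


@dataclass(frozen=True)
class HomologyConfig:
    source: str = "identity_table"
    threshold: float = 0.4
    transitive: bool = False

    def __post_init__(self) -> None:
        if self.source not in {"pairwise_alignment", "identity_table", "family_label"}:
            raise ValueError(f"unknown homology source: {self.source!r}")
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError(f"threshold must be in [0,1], got {self.threshold}")

    def to_dict(self) -> dict:
        return {
            "source": self.source,
            "threshold": self.threshold,
            "transitive": self.transitive,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "HomologyConfig":
        unknown = set(d) - set(cls().to_dict())
        if unknown:
            raise ValueError(f"unknown homology config keys: {sorted(unknown)}")
        return cls(**dict(d))


@dataclass(frozen=True)
class PathsConfig:
    compounds: str | None = None
    activities: str | None = None
    identity: str | None = None
    targets_fasta: str | None = None
    references: str | None = None
    library: str | None = None

    def to_dict(self) -> dict:
        return {
            "compounds": self.compounds,
            "activities": self.activities,
            "identity": self.identity,
            "targets_fasta": self.targets_fasta,
            "references": self.references,
            "library": self.library,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PathsConfig":
        unknown = set(d) - set(cls().to_dict())
        if unknown:
            raise ValueError(f"unknown paths config keys: {sorted(unknown)}")
        return cls(**dict(d))


@dataclass(frozen=True)
class RunConfig:
    """Full pipeline configuration (train -> score -> funnel)."""

    focal_target: str = ""
    fingerprint: FingerprintConfig = field(default_factory=FingerprintConfig)
    homology: HomologyConfig = field(default_factory=HomologyConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    funnel: tuple[FunnelStage, ...] = ()
    paths: PathsConfig = field(default_factory=PathsConfig)

    def to_dict(self) -> dict:
        return {
            "focal_target": self.focal_target,
            "fingerprint": self.fingerprint.to_dict(),
            "homology": self.homology.to_dict(),
            "training": self.training.to_dict(),
            "funnel": [
                {
                    "kind": s.kind,
                    "name": s.name,
                    "score_cutoff": s.score_cutoff,
                    "top_k": s.top_k,
                    "keep_list": sorted(s.keep_list) if s.keep_list else None,
                }
                for s in self.funnel
            ],
            "paths": self.paths.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        allowed = {"focal_target", "fingerprint", "homology", "training", "funnel", "paths"}
        unknown = set(d) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(
            focal_target=str(d.get("focal_target", "")),
            fingerprint=FingerprintConfig.from_dict(d.get("fingerprint", {}) or {}),
            homology=HomologyConfig.from_dict(d.get("homology", {}) or {}),
            training=TrainingConfig.from_dict(d.get("training", {}) or {}),
            funnel=tuple(
                FunnelStage.from_dict(s) for s in (d.get("funnel", []) or [])
            ),
            paths=PathsConfig.from_dict(d.get("paths", {}) or {}),
        )

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def load_config_file(path: str | Path) -> dict:
    """Load a YAML or JSON mapping from *path*."""
    path = Path(path)
    text = path.read_text()
    data = (
        json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    )
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return data
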