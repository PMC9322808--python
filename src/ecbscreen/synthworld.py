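"""Synthetic compound/target/activity worlds with planted signal.

Worlds contain target families with tunable within/across-family sequence
identity, actives per target that carry a family-specific fingerprint
motif, and unrelated decoys.  Fingerprints are generated directly by
default (no chemistry parsing in tests); ``smiles_mode`` instead builds
small real molecules from a fragment grammar so the full CLI round-trips
through SMILES files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ecbscreen import metrics
from ecbscreen.chem import Compound, FingerprintConfig, compute_fingerprint
from ecbscreen.screening import ScreenResult
from ecbscreen.targets import ActivityTable, TargetProtein

logger = logging.getLogger(__name__)

# Fragment grammar for smiles_mode: each family shares one ring scaffold,
# decorated with a random acyclic tail; decoys are tails only.
_FAMILY_SCAFFOLDS = [
    "c1ccccc1",
    "c1ccncc1",
    "c1ccsc1",
    "c1ccoc1",
    "C1CCCCC1",
    "C1CCNCC1",
    "C1CCOCC1",
    "c1cnccn1",
]
_TAIL_ATOMS = ["C", "N", "O"]


@dataclass(frozen=True)
class WorldConfig:
    n_target_families: int = 2
    targets_per_family: int = 2
    within_family_identity: float = 0.8
    across_family_identity: float = 0.1
    actives_per_target: int = 5
    heldout_actives_per_target: int = 0
    n_decoys: int = 50
    motif_strength: float = 1.0
    fingerprint_length: int = 512
    motif_bits: int = 32
    background_rate: float = 0.02
    smiles_mode: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_target_families", "targets_per_family", "actives_per_target"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_decoys < 1:
            raise ValueError("n_decoys must be >= 1")
        for name in (
            "within_family_identity",
            "across_family_identity",
            "motif_strength",
            "background_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.within_family_identity <= self.across_family_identity:
            raise ValueError(
                "within_family_identity must exceed across_family_identity"
            )
        if self.fingerprint_length < 1 or self.motif_bits < 1:
            raise ValueError("fingerprint_length and motif_bits must be >= 1")
        if self.heldout_actives_per_target < 0:
            raise ValueError("heldout_actives_per_target must be >= 0")

    def to_dict(self) -> dict:
        return {
            "n_target_families": self.n_target_families,
            "targets_per_family": self.targets_per_family,
            "within_family_identity": self.within_family_identity,
            "across_family_identity": self.across_family_identity,
            "actives_per_target": self.actives_per_target,
            "heldout_actives_per_target": self.heldout_actives_per_target,
            "n_decoys": self.n_decoys,
            "motif_strength": self.motif_strength,
            "fingerprint_length": self.fingerprint_length,
            "motif_bits": self.motif_bits,
            "background_rate": self.background_rate,
            "smiles_mode": self.smiles_mode,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "WorldConfig":
        unknown = set(d) - set(cls().to_dict())
        if unknown:
            raise ValueError(f"unknown world config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class SyntheticWorld:
    config: WorldConfig
    compounds: list[Compound]
    targets: list[TargetProtein]
    identity_table: dict[frozenset, float]
    activities: ActivityTable
    ground_truth: set[str]  # true binders of the focal family
    focal_target: str
    family_motifs: list[np.ndarray] = field(default_factory=list)

    def compound(self, compound_id: str) -> Compound:
        for c in self.compounds:
            if c.compound_id == compound_id:
                return c
        raise KeyError(compound_id)


def _random_tail(rng: np.random.Generator) -> str:
    length = int(rng.integers(4, 10))
    return "".join(rng.choice(_TAIL_ATOMS, size=length))


def generate_world(config: WorldConfig) -> SyntheticWorld:
    """Generate a deterministic world from *config*.

    Family f gets a disjoint motif bit-set; each of its actives carries
    every motif bit with probability ``motif_strength`` on top of uniform
    background bits.  Decoys are background only.  The focal target is the
    first target of the first family; ground truth is every active of that
    family.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    L = cfg.fingerprint_length
    n_fam = cfg.n_target_families

    if cfg.smiles_mode:
        if n_fam > len(_FAMILY_SCAFFOLDS):
            raise ValueError(
                f"smiles_mode supports at most {len(_FAMILY_SCAFFOLDS)} families"
            )
        scaffolds = list(
            rng.choice(_FAMILY_SCAFFOLDS, size=n_fam, replace=False)
        )
        motifs: list[np.ndarray] = []
        fp_config = FingerprintConfig(radius=2, n_bits=L)
    else:
        if n_fam * cfg.motif_bits > L:
            raise ValueError(
                f"cannot plant {n_fam} disjoint motifs of {cfg.motif_bits} bits "
                f"in {L}-bit fingerprints"
            )
        perm = rng.permutation(L)
        motifs = [
            np.sort(perm[f * cfg.motif_bits : (f + 1) * cfg.motif_bits])
            for f in range(n_fam)
        ]
        scaffolds = []

    def background_fp() -> np.ndarray:
        return (rng.random(L) < cfg.background_rate).astype(np.uint8)

    def make_compound(cid: str, family: int | None, source: str) -> Compound:
        if cfg.smiles_mode:
            tail = _random_tail(rng)
            if family is not None and rng.random() < cfg.motif_strength:
                smiles = scaffolds[family] + tail
            else:
                smiles = tail
            return Compound(
                cid, smiles, compute_fingerprint(smiles, fp_config), source=source
            )
        fp = background_fp()
        if family is not None:
            motif = motifs[family]
            carry = rng.random(len(motif)) < cfg.motif_strength
            fp[motif[carry]] = 1
        return Compound(cid, "", fp, source=source)

    targets: list[TargetProtein] = []
    compounds: list[Compound] = []
    records: list[tuple[str, str, bool]] = []
    ground_truth: set[str] = set()
    for f in range(n_fam):
        for t in range(cfg.targets_per_family):
            tid = f"F{f}_T{t}"
            targets.append(TargetProtein(tid, family_label=f"F{f}"))
            for i in range(cfg.actives_per_target):
                cid = f"F{f}_T{t}_A{i}"
                compounds.append(make_compound(cid, f, "synthetic"))
                records.append((cid, tid, True))
                if f == 0:
                    ground_truth.add(cid)
            # held-out actives carry the motif but get no activity record,
            # so screens can be evaluated on compounds unseen in training
            for i in range(cfg.heldout_actives_per_target):
                cid = f"F{f}_T{t}_H{i}"
                compounds.append(make_compound(cid, f, "synthetic"))
                if f == 0:
                    ground_truth.add(cid)
    for i in range(cfg.n_decoys):
        compounds.append(make_compound(f"D{i:04d}", None, "synthetic"))

    identity_table = {
        frozenset((a.target_id, b.target_id)): (
            cfg.within_family_identity
            if a.family_label == b.family_label
            else cfg.across_family_identity
        )
        for i, a in enumerate(targets)
        for b in targets[i + 1 :]
    }

    world = SyntheticWorld(
        config=cfg,
        compounds=compounds,
        targets=targets,
        identity_table=identity_table,
        activities=ActivityTable(records),
        ground_truth=ground_truth,
        focal_target="F0_T0",
        family_motifs=motifs,
    )
    expected = (
        n_fam
        * cfg.targets_per_family
        * (cfg.actives_per_target + cfg.heldout_actives_per_target)
        + cfg.n_decoys
    )
    assert len(compounds) == expected
    return world


def write_world(world: SyntheticWorld, out_dir: str | Path) -> dict[str, Path]:
    """Write a world as CLI-consumable text files.

    Emits references.smi (ligands of the focal target), library.smi (all
    other compounds), activities.tsv, identity.tsv and truth.txt.
    Requires ``smiles_mode`` worlds: fingerprint-mode compounds have no
    real structures to serialize.
    """
    if not world.config.smiles_mode:
        raise ValueError("write_world requires a smiles_mode world")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ref_ids = world.activities.ligands_of(world.focal_target)
    paths = {
        "references": out_dir / "references.smi",
        "library": out_dir / "library.smi",
        "activities": out_dir / "activities.tsv",
        "identity": out_dir / "identity.tsv",
        "truth": out_dir / "truth.txt",
    }
    with open(paths["references"], "w") as ref_fh, open(
        paths["library"], "w"
    ) as lib_fh:
        for c in world.compounds:
            fh = ref_fh if c.compound_id in ref_ids else lib_fh
            fh.write(f"{c.smiles} {c.compound_id}\n")
    world.activities.to_tsv(paths["activities"])
    with open(paths["identity"], "w") as fh:
        fh.write("target_a\ttarget_b\tidentity\n")
        for pair in sorted(world.identity_table, key=sorted):
            a, b = sorted(pair)
            fh.write(f"{a}\t{b}\t{world.identity_table[pair]}\n")
    with open(paths["truth"], "w") as fh:
        for cid in sorted(world.ground_truth - ref_ids):
            fh.write(cid + "\n")
    return paths


def evaluate_enrichment(
    results: list[ScreenResult],
    truth: set[str],
    fraction: float = 0.1,
    k: int | None = None,
) -> dict[str, float]:
    """Ranking metrics of a screen against known actives.

    Returns AUROC (rank-sum with midrank ties), EF@*fraction*, and
    recall@k (k defaults to the number of actives).
    """
    if not truth:
        raise ValueError("truth set is empty")
    ids = {r.compound_id for r in results}
    missing = sorted(truth - ids)
    if missing:
        raise ValueError(f"truth ids missing from results: {missing}")
    if truth >= ids:
        raise ValueError("truth covers all compounds; metrics undefined")
    ordered = sorted(results, key=lambda r: r.rank)
    flags = np.array([r.compound_id in truth for r in ordered])
    scores = np.array([r.final_score for r in ordered])
    if k is None:
        k = int(flags.sum())
    return {
        "auroc": metrics.auroc(scores, flags),
        "enrichment_factor_at_fraction": metrics.enrichment_factor(flags, fraction),
        "recall_at_k": metrics.recall_at_k(flags, k),
    }
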