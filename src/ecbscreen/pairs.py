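"""Evolutionarily related chemical pairs (ERCPs) and the ECBS pair model.

Positive pairs are compounds whose binding targets are identical or
homologous to the focal target; negatives are sampled among compounds with
no related target in common.  A bootstrap ensemble of probabilistic
classifiers is trained on symmetric pair features and emits a similarity
score in [0, 1] interpreted as binding probability toward the focal
target.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier

from ecbscreen.chem import Compound, tanimoto
from ecbscreen.metrics import auroc
from ecbscreen.targets import ActivityTable, HomologyGraph, related_targets

logger = logging.getLogger(__name__)

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass(frozen=True)
class ChemicalPair:
    """An unordered compound pair with an ERCP label.

    Stored with compound_a < compound_b lexicographically so that (a, b)
    and (b, a) collide.
    """

    compound_a: str
    compound_b: str
    label: str
    context_target: str

    def __post_init__(self) -> None:
        if self.compound_a == self.compound_b:
            raise ValueError(f"self-pair: {self.compound_a!r}")
        if self.compound_a > self.compound_b:
            a, b = self.compound_b, self.compound_a
            object.__setattr__(self, "compound_a", a)
            object.__setattr__(self, "compound_b", b)
        if self.label not in {POSITIVE, NEGATIVE}:
            raise ValueError(f"bad label: {self.label!r}")

    @property
    def key(self) -> tuple[str, str]:
        return (self.compound_a, self.compound_b)


def enumerate_ercps(
    activities: ActivityTable,
    graph: HomologyGraph,
    focal_target: str,
    negative_ratio: float = 1.0,
    seed: int = 0,
) -> list[ChemicalPair]:
    """Enumerate labeled training pairs for *focal_target*.

    Positives are all unordered pairs within the ligand universe U of the
    focal target and its homologs.  Negatives pair a member of U with an
    outside compound that shares no related target with it, sampled
    uniformly without replacement down to
    ``round(negative_ratio * n_positives)``.
    """
    if not activities.records:
        raise ValueError("activity table is empty")
    if negative_ratio <= 0:
        raise ValueError(f"negative_ratio must be > 0, got {negative_ratio}")
    related = related_targets(graph, focal_target)
    universe = sorted(
        set().union(*(activities.ligands_of(t) for t in related))
    )
    if len(universe) < 2:
        raise ValueError(
            f"insufficient ligands for focal target {focal_target!r} "
            f"(universe size {len(universe)})"
        )

    pairs = [
        ChemicalPair(a, b, POSITIVE, focal_target)
        for a, b in itertools.combinations(universe, 2)
    ]
    n_positives = len(pairs)

    # Negative eligibility: an outside compound d qualifies against u when
    # no target of d is related to any target of u.
    universe_set = set(universe)
    outside = sorted(activities.compound_ids - universe_set)
    related_of: dict[str, set[str]] = {}

    def targets_related_to(cid: str) -> set[str]:
        if cid not in related_of:
            out: set[str] = set()
            for t in activities.targets_of(cid):
                out |= related_targets(graph, t)
            related_of[cid] = out
        return related_of[cid]

    eligible = [
        (u, d) if u < d else (d, u)
        for u in universe
        for d in outside
        if not (targets_related_to(u) & activities.targets_of(d))
    ]
    eligible = sorted(set(eligible))

    n_wanted = int(round(negative_ratio * n_positives))
    rng = np.random.default_rng(seed)
    if len(eligible) < n_wanted:
        logger.warning(
            "only %d eligible negative pairs for %d requested; using all",
            len(eligible),
            n_wanted,
        )
        chosen = eligible
    else:
        idx = rng.choice(len(eligible), size=n_wanted, replace=False)
        chosen = [eligible[i] for i in sorted(idx)]
    pairs.extend(ChemicalPair(a, b, NEGATIVE, focal_target) for a, b in chosen)
    return pairs


def featurize_pair(fp_a: np.ndarray, fp_b: np.ndarray) -> np.ndarray:
    """Symmetric pair features: AND block, XOR block, scalar block.

    The scalar block is {tanimoto, min popcount, max popcount, shared
    popcount}; min/max ordering keeps the vector invariant under argument
    swap.
    """
    a = np.asarray(fp_a, dtype=np.uint8)
    b = np.asarray(fp_b, dtype=np.uint8)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    return _featurize_batch(a[None, :], b[None, :])[0]


def _featurize_batch(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Vectorized featurize_pair over row-aligned fingerprint matrices."""
    A = A.astype(np.uint8)
    B = B.astype(np.uint8)
    both = A & B
    diff = A ^ B
    ca = A.sum(axis=1).astype(np.float64)
    cb = B.sum(axis=1).astype(np.float64)
    shared = both.sum(axis=1).astype(np.float64)
    union = ca + cb - shared
    with np.errstate(invalid="ignore"):
        tani = np.where(union > 0, shared / np.where(union > 0, union, 1.0), 0.0)
    scalars = np.column_stack(
        [tani, np.minimum(ca, cb), np.maximum(ca, cb), shared]
    )
    return np.hstack([both, diff, scalars]).astype(np.float64)


_LEARNERS = {"random_forest", "gradient_boosting"}


@dataclass(frozen=True)
class TrainingConfig:
    """Hyper-parameters for ECBS model training."""

    ensemble_size: int = 10
    learner: str = "random_forest"
    n_estimators: int = 50
    max_depth: int | None = None
    negative_ratio: float = 1.0
    test_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ensemble_size < 1:
            raise ValueError("ensemble_size must be >= 1")
        if self.learner not in _LEARNERS:
            raise ValueError(
                f"learner must be one of {sorted(_LEARNERS)}, got {self.learner!r}"
            )
        if not 0.0 <= self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in [0, 1)")

    def to_dict(self) -> dict:
        return {
            "ensemble_size": self.ensemble_size,
            "learner": self.learner,
            "n_estimators": self.n_estimators,
            "max_depth": self.max_depth,
            "negative_ratio": self.negative_ratio,
            "test_fraction": self.test_fraction,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TrainingConfig":
        unknown = set(d) - set(cls().to_dict())
        if unknown:
            raise ValueError(f"unknown training config keys: {sorted(unknown)}")
        return cls(**dict(d))


def _make_learner(config: TrainingConfig, seed: int):
    if config.learner == "gradient_boosting":
        return GradientBoostingClassifier(
            n_estimators=config.n_estimators,
            max_depth=config.max_depth or 3,
            random_state=seed,
        )
    return RandomForestClassifier(
        n_estimators=config.n_estimators,
        max_depth=config.max_depth,
        random_state=seed,
        n_jobs=1,
    )


@dataclass
class EcbsModel:
    """A trained target-specific ensemble pair-similarity model."""

    members: list = field(default_factory=list)
    config: TrainingConfig = field(default_factory=TrainingConfig)
    fingerprint_length: int = 2048
    focal_target: str = ""
    oos_auroc: float | None = None
    positive_index: int = 1

    def _check(self, length: int) -> None:
        if not self.members:
            raise ValueError("model has no trained ensemble members")
        if length != self.fingerprint_length:
            raise ValueError(
                f"fingerprint length {length} does not match model "
                f"({self.fingerprint_length})"
            )

    def score_features(self, X: np.ndarray) -> np.ndarray:
        # Sequential elementwise accumulation keeps scores bit-identical
        # across batch sizes (np.mean's pairwise summation does not).
        total = np.zeros(len(X), dtype=np.float64)
        for m in self.members:
            total += m.predict_proba(X)[:, self.positive_index]
        return np.clip(total / len(self.members), 0.0, 1.0)

    def score_pairs(self, A: np.ndarray, B: np.ndarray) -> np.ndarray:
        """Scores for row-aligned fingerprint matrices A and B."""
        A = np.atleast_2d(A)
        B = np.atleast_2d(B)
        self._check(A.shape[1])
        if A.shape != B.shape:
            raise ValueError("A and B must be row-aligned matrices")
        return self.score_features(_featurize_batch(A, B))

    def score(self, fp_a: np.ndarray, fp_b: np.ndarray) -> float:
        fp_a = np.asarray(fp_a)
        if fp_a.ndim != 1:
            raise ValueError("score() takes single fingerprints")
        return float(self.score_pairs(fp_a[None, :], np.asarray(fp_b)[None, :])[0])

    def save(self, path: str | Path) -> None:
        payload = {
            "members": self.members,
            "config": self.config.to_dict(),
            "fingerprint_length": self.fingerprint_length,
            "focal_target": self.focal_target,
            "oos_auroc": self.oos_auroc,
            "positive_index": self.positive_index,
        }
        joblib.dump(payload, path, compress=3)

    @classmethod
    def load(cls, path: str | Path) -> "EcbsModel":
        payload = joblib.load(path)
        try:
            return cls(
                members=payload["members"],
                config=TrainingConfig.from_dict(payload["config"]),
                fingerprint_length=payload["fingerprint_length"],
                focal_target=payload["focal_target"],
                oos_auroc=payload["oos_auroc"],
                positive_index=payload["positive_index"],
            )
        except (KeyError, TypeError) as exc:
            raise ValueError(f"corrupt model file {path}: {exc}") from exc


def ecbs_score(model: EcbsModel, fp_a: np.ndarray, fp_b: np.ndarray) -> float:
    """Pairwise ECBS score in [0, 1]; symmetric in its arguments."""
    return model.score(fp_a, fp_b)


def _pair_matrix(
    pairs: Sequence[ChemicalPair], fps: Mapping[str, np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    A = np.stack([fps[p.compound_a] for p in pairs])
    B = np.stack([fps[p.compound_b] for p in pairs])
    X = _featurize_batch(A, B)
    y = np.array([1 if p.label == POSITIVE else 0 for p in pairs])
    return X, y


def _fit_ensemble(
    X: np.ndarray, y: np.ndarray, config: TrainingConfig, rng: np.random.Generator
) -> list:
    members = []
    n = len(y)
    for _ in range(config.ensemble_size):
        idx = rng.integers(0, n, size=n)  # bootstrap resample of pairs
        if len(set(y[idx])) < 2:  # degenerate resample: fall back to full data
            idx = np.arange(n)
        learner = _make_learner(config, int(rng.integers(0, 2**31 - 1)))
        learner.fit(X[idx], y[idx])
        members.append(learner)
    return members


def train_ecbs_model(
    pairs: Sequence[ChemicalPair],
    compounds: Sequence[Compound],
    config: TrainingConfig | None = None,
    focal_target: str = "",
) -> EcbsModel:
    """Train a bootstrap ensemble on labeled pairs.

    Held-out performance is measured on a compound-disjoint split (no
    molecule appears on either side of both a training and a test pair),
    then the final ensemble is refit on all pairs.  Fully reproducible for
    a fixed config seed.
    """
    config = config or TrainingConfig()
    labels = {p.label for p in pairs}
    if labels != {POSITIVE, NEGATIVE}:
        raise ValueError(
            f"training needs both labels; got {sorted(labels) or 'none'}"
        )
    fps = {c.compound_id: c.fingerprint for c in compounds}
    referenced = sorted({cid for p in pairs for cid in p.key})
    missing = [cid for cid in referenced if cid not in fps]
    if missing:
        raise ValueError(f"unresolvable compound ids: {missing}")
    length = len(fps[referenced[0]])

    rng = np.random.default_rng(config.seed)
    oos = None
    if config.test_fraction > 0:
        shuffled = list(referenced)
        rng.shuffle(shuffled)
        n_test = max(1, int(round(config.test_fraction * len(shuffled))))
        test_compounds = set(shuffled[:n_test])
        train_pairs = [
            p
            for p in pairs
            if p.compound_a not in test_compounds and p.compound_b not in test_compounds
        ]
        test_pairs = [
            p
            for p in pairs
            if p.compound_a in test_compounds and p.compound_b in test_compounds
        ]
        if (
            len({p.label for p in train_pairs}) == 2
            and len({p.label for p in test_pairs}) == 2
        ):
            Xtr, ytr = _pair_matrix(train_pairs, fps)
            Xte, yte = _pair_matrix(test_pairs, fps)
            eval_members = _fit_ensemble(Xtr, ytr, config, rng)
            eval_model = EcbsModel(
                members=eval_members,
                config=config,
                fingerprint_length=length,
                focal_target=focal_target,
            )
            oos = auroc(eval_model.score_features(Xte), yte.astype(bool))
        else:
            logger.warning(
                "compound-disjoint split left a single-label side; "
                "skipping held-out evaluation"
            )

    X, y = _pair_matrix(pairs, fps)
    members = _fit_ensemble(X, y, config, rng)
    return EcbsModel(
        members=members,
        config=config,
        fingerprint_length=length,
        focal_target=focal_target,
        oos_auroc=oos,
    )
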