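"""Target proteins, pairwise homology, and the relatedness relation.

A :class:`HomologyGraph` keeps an edge between two targets when their
fractional sequence identity reaches a threshold; a target is always
related to itself.  Relatedness is one-hop by default (direct homologs of
the query), with an optional transitive-closure mode.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import Align, SeqIO

logger = logging.getLogger(__name__)

DEFAULT_IDENTITY_THRESHOLD = 0.4


@dataclass
class TargetProtein:
    target_id: str
    sequence: str | None = None
    family_label: str | None = None


@dataclass
class HomologyGraph:
    """Undirected graph over target ids with fractional-identity edges."""

    nodes: set[str]
    edges: dict[frozenset, float]  # pair -> identity, only pairs >= threshold
    threshold: float
    transitive: bool = False

    def neighbors(self, target_id: str) -> set[str]:
        if target_id not in self.nodes:
            raise KeyError(f"unknown target: {target_id!r}")
        return {
            other
            for pair in self.edges
            for other in pair
            if target_id in pair and other != target_id
        }


def _pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment identity: matches / alignment length."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -0.5
    alignment = aligner.align(seq_a.upper(), seq_b.upper())[0]
    matches = sum(
        1
        for ca, cb in zip(alignment[0], alignment[1])
        if ca == cb and ca != "-"
    )
    length = alignment.length
    return matches / length if length else 0.0


def read_target_fasta(path: str | Path) -> list[TargetProtein]:
    """Load targets from a FASTA file (record id becomes target_id)."""
    targets = [
        TargetProtein(rec.id, sequence=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not targets:
        raise ValueError(f"no FASTA records in {path}")
    ids = [t.target_id for t in targets]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate target ids in FASTA")
    return targets


def read_identity_table(path: str | Path) -> dict[frozenset, float]:
    """Read a TSV of (target_a, target_b, identity-fraction)."""
    df = pd.read_csv(path, sep="\t")
    required = {"target_a", "target_b", "identity"}
    if not required.issubset(df.columns):
        raise ValueError(f"identity table needs columns {sorted(required)}")
    table: dict[frozenset, float] = {}
    for row in df.itertuples(index=False):
        ident = float(row.identity)
        if not 0.0 <= ident <= 1.0:
            raise ValueError(
                f"identity out of [0,1] for {row.target_a}-{row.target_b}: {ident}"
            )
        table[frozenset((str(row.target_a), str(row.target_b)))] = ident
    return table


def build_homology_graph(
    targets: list[TargetProtein],
    identity_source: str = "pairwise_alignment",
    threshold: float = DEFAULT_IDENTITY_THRESHOLD,
    identity_table: dict[frozenset, float] | None = None,
    transitive: bool = False,
) -> HomologyGraph:
    """Build the homology graph over *targets*.

    identity_source is one of ``pairwise_alignment`` (align sequences),
    ``identity_table`` (use the supplied table; every pair must be
    present), or ``family_label`` (identity 1 within a family, 0 across).
    An edge is stored iff identity >= *threshold*; self-edges are never
    stored.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0,1], got {threshold}")
    ids = [t.target_id for t in targets]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate target ids")
    by_id = {t.target_id: t for t in targets}

    def identity_of(a: str, b: str) -> float:
        if identity_source == "family_label":
            fa, fb = by_id[a].family_label, by_id[b].family_label
            if fa is None or fb is None:
                raise ValueError(f"missing family_label for {a!r} or {b!r}")
            return 1.0 if fa == fb else 0.0
        if identity_source == "identity_table":
            raise AssertionError("handled below")  # pragma: no cover
        sa, sb = by_id[a].sequence, by_id[b].sequence
        if not sa or not sb:
            raise ValueError(f"missing sequence for {a!r} or {b!r}")
        return _pairwise_identity(sa, sb)

    edges: dict[frozenset, float] = {}
    pairs = list(itertools.combinations(sorted(ids), 2))
    if identity_source == "identity_table":
        if identity_table is None:
            raise ValueError("identity_table source requires an identity table")
        missing = [p for p in pairs if frozenset(p) not in identity_table]
        if missing:
            raise ValueError(
                "identity table is missing pairs: "
                + ", ".join(f"{a}-{b}" for a, b in missing)
            )
        for a, b in pairs:
            ident = identity_table[frozenset((a, b))]
            if ident >= threshold:
                edges[frozenset((a, b))] = ident
    elif identity_source in {"pairwise_alignment", "family_label"}:
        for a, b in pairs:
            ident = identity_of(a, b)
            if ident >= threshold:
                edges[frozenset((a, b))] = ident
    else:
        raise ValueError(f"unknown identity_source: {identity_source!r}")

    return HomologyGraph(
        nodes=set(ids), edges=edges, threshold=threshold, transitive=transitive
    )


def related_targets(graph: HomologyGraph, target_id: str) -> set[str]:
    """The query itself plus its homologs.

    One-hop neighbors by default; the full connected component when the
    graph was built with ``transitive=True``.
    """
    if target_id not in graph.nodes:
        raise KeyError(f"unknown target: {target_id!r}")
    if not graph.transitive:
        return {target_id} | graph.neighbors(target_id)
    component = {target_id}
    frontier = [target_id]
    while frontier:
        nxt = []
        for node in frontier:
            for nb in graph.neighbors(node):
                if nb not in component:
                    component.add(nb)
                    nxt.append(nb)
        frontier = nxt
    return component


@dataclass
class ActivityTable:
    """Compound-target binding records.

    Rows are (compound_id, target_id, active).  Duplicate
    (compound_id, target_id) rows are rejected.
    """

    records: list[tuple[str, str, bool]] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [(c, t) for c, t, _ in self.records]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValueError(f"duplicate activity rows: {dupes}")

    @property
    def compound_ids(self) -> set[str]:
        return {c for c, _, _ in self.records}

    @property
    def target_ids(self) -> set[str]:
        return {t for _, t, _ in self.records}

    def ligands_of(self, target_id: str, active_only: bool = True) -> set[str]:
        return {
            c
            for c, t, a in self.records
            if t == target_id and (a or not active_only)
        }

    def targets_of(self, compound_id: str, active_only: bool = True) -> set[str]:
        return {
            t
            for c, t, a in self.records
            if c == compound_id and (a or not active_only)
        }

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ActivityTable":
        df = pd.read_csv(path, sep="\t")
        required = {"compound_id", "target_id", "active"}
        if not required.issubset(df.columns):
            raise ValueError(f"activity table needs columns {sorted(required)}")
        records = [
            (str(r.compound_id), str(r.target_id), _parse_flag(r.active))
            for r in df.itertuples(index=False)
        ]
        return cls(records)

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.records, columns=["compound_id", "target_id", "active"])
        df["active"] = df["active"].astype(int)
        df.to_csv(path, sep="\t", index=False)


def _parse_flag(value) -> bool:
    if isinstance(value, str):
        v = value.strip().lower()
        if v in {"1", "true", "yes"}:
            return True
        if v in {"0", "false", "no"}:
            return False
        raise ValueError(f"unparsable active flag: {value!r}")
    return bool(int(value))
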