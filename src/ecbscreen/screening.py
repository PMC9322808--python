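"""Library screening: max-score aggregation, ranking, and the funnel.

Each library compound receives the maximum pairwise ECBS score over all
reference ligands as its final target-binding score, then an ordered list
of funnel stages (score cutoff, top-k, external keep-list) narrows the
ranked hit list.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from ecbscreen.chem import Compound, fingerprint_matrix
from ecbscreen.pairs import EcbsModel

logger = logging.getLogger(__name__)


@dataclass
class ScreenResult:
    compound_id: str
    smiles: str
    final_score: float
    best_reference: str
    rank: int = 0
    stage_flags: dict[str, bool] = field(default_factory=dict)


def screen_library(
    model: EcbsModel,
    references: Sequence[Compound],
    library: Sequence[Compound],
    batch_size: int = 262144,
) -> list[ScreenResult]:
    """Score every library compound against every reference ligand.

    final_score = max over references; best_reference is the
    lexicographically smallest reference id among score ties.  Results are
    sorted by descending score, then ascending compound_id, and assigned
    ranks 1..n in that order.
    """
    if not references:
        raise ValueError("reference ligand set is empty")
    if not library:
        return []

    # Lexicographic reference order makes the tie rule a plain argmax.
    refs = sorted(references, key=lambda c: c.compound_id)
    R = fingerprint_matrix(refs)
    L = fingerprint_matrix(library)
    n_lib, n_ref = len(library), len(refs)

    scores = np.empty((n_lib, n_ref), dtype=float)
    rows_per_chunk = max(1, batch_size // n_ref)
    for start in range(0, n_lib, rows_per_chunk):
        stop = min(start + rows_per_chunk, n_lib)
        block = L[start:stop]
        A = np.repeat(block, n_ref, axis=0)
        B = np.tile(R, (stop - start, 1))
        scores[start:stop] = model.score_pairs(A, B).reshape(stop - start, n_ref)

    results = []
    for i, comp in enumerate(library):
        best = int(np.argmax(scores[i]))  # first (lexicographic) argmax
        results.append(
            ScreenResult(
                compound_id=comp.compound_id,
                smiles=comp.smiles,
                final_score=float(scores[i, best]),
                best_reference=refs[best].compound_id,
            )
        )
    results.sort(key=lambda r: (-r.final_score, r.compound_id))
    for rank, r in enumerate(results, start=1):
        r.rank = rank
    return results


@dataclass(frozen=True)
class FunnelStage:
    """One narrowing rule: score_cutoff, top_k, or keep_list."""

    kind: str
    name: str = ""
    score_cutoff: float | None = None
    top_k: int | None = None
    keep_list: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if self.kind not in {"score_cutoff", "top_k", "keep_list"}:
            raise ValueError(f"unknown stage kind: {self.kind!r}")
        if self.kind == "score_cutoff" and self.score_cutoff is None:
            raise ValueError("score_cutoff stage needs a cutoff value")
        if self.kind == "top_k" and (self.top_k is None or self.top_k < 1):
            raise ValueError("top_k stage needs k >= 1")
        if self.kind == "keep_list" and self.keep_list is None:
            raise ValueError("keep_list stage needs an id list")
        if not self.name:
            object.__setattr__(self, "name", self.kind)

    @classmethod
    def from_dict(cls, d: Mapping) -> "FunnelStage":
        allowed = {"kind", "name", "score_cutoff", "top_k", "keep_list"}
        unknown = set(d) - allowed
        if unknown:
            raise ValueError(f"unknown funnel stage keys: {sorted(unknown)}")
        d = dict(d)
        if "keep_list" in d and d["keep_list"] is not None:
            d["keep_list"] = frozenset(str(x) for x in d["keep_list"])
        return cls(**d)


@dataclass
class FunnelSummary:
    stages: list[tuple[str, int, int]] = field(default_factory=list)  # name, in, out


def apply_funnel(
    results: Sequence[ScreenResult],
    stages: Sequence[FunnelStage],
    summary: FunnelSummary | None = None,
) -> list[ScreenResult]:
    """Apply stages in order; survivors keep their original ranking.

    Every input result's stage_flags record which stages it passed.  With
    an empty stage list the input is returned unchanged.
    """
    survivors = sorted(results, key=lambda r: r.rank)
    summary = summary if summary is not None else FunnelSummary()
    for stage in stages:
        n_in = len(survivors)
        if stage.kind == "score_cutoff":
            passed = [r for r in survivors if r.final_score >= stage.score_cutoff]
        elif stage.kind == "top_k":
            k = stage.top_k
            if k > n_in:
                logger.warning(
                    "stage %s: top_k=%d exceeds %d inputs; keeping all",
                    stage.name,
                    k,
                    n_in,
                )
            passed = survivors[:k]
        else:
            known = {r.compound_id for r in survivors}
            unknown = sorted(stage.keep_list - known)
            if unknown:
                logger.warning(
                    "stage %s: keep_list ids not in input: %s",
                    stage.name,
                    ", ".join(unknown),
                )
            passed = [r for r in survivors if r.compound_id in stage.keep_list]
        passed_ids = {r.compound_id for r in passed}
        for r in survivors:
            r.stage_flags[stage.name] = r.compound_id in passed_ids
        survivors = passed
        summary.stages.append((stage.name, n_in, len(survivors)))
        logger.info("funnel stage %s: %d -> %d", stage.name, n_in, len(survivors))
    return survivors


def write_results(
    results: Iterable[ScreenResult],
    path: str | Path,
    format: str = "tsv",
) -> None:
    """Write results as TSV/CSV: id, smiles, score (6 dp), best ref, rank,
    stage flags.  Byte-stable for fixed inputs."""
    if format not in {"tsv", "csv"}:
        raise ValueError(f"unsupported format: {format!r}")
    delim = "\t" if format == "tsv" else ","
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim, lineterminator="\n")
        writer.writerow(
            ["compound_id", "smiles", "final_score", "best_reference", "rank", "stage_flags"]
        )
        for r in results:
            flags = ";".join(
                f"{name}={'pass' if ok else 'fail'}"
                for name, ok in r.stage_flags.items()
            )
            writer.writerow(
                [
                    r.compound_id,
                    r.smiles,
                    f"{r.final_score:.6f}",
                    r.best_reference,
                    r.rank,
                    flags,
                ]
            )


def read_results(path: str | Path) -> list[ScreenResult]:
    """Read back a results file written by :func:`write_results`."""
    path = Path(path)
    delim = "," if path.suffix.lower() == ".csv" else "\t"
    results = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        for row in reader:
            flags = {}
            if row.get("stage_flags"):
                for item in row["stage_flags"].split(";"):
                    name, _, state = item.partition("=")
                    flags[name] = state == "pass"
            results.append(
                ScreenResult(
                    compound_id=row["compound_id"],
                    smiles=row["smiles"],
                    final_score=float(row["final_score"]),
                    best_reference=row["best_reference"],
                    rank=int(row["rank"]),
                    stage_flags=flags,
                )
            )
    return results
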