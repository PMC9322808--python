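"""Compound ingestion, canonicalization, fingerprinting, and similarity.

Compounds are represented by a canonical SMILES and a hashed circular
(Morgan) substructure fingerprint.  All fingerprints within one run share a
single :class:`FingerprintConfig`, so bit vectors are directly comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

logger = logging.getLogger(__name__)

# RDKit's C++-side parse chatter duplicates the warnings we log ourselves.
RDLogger.DisableLog("rdApp.error")


class StructureParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""


@dataclass(frozen=True)
class FingerprintConfig:
    """Parameters of the hashed circular substructure fingerprint.

    Attributes
    ----------
    radius : int
        Circular environment radius (default 2, i.e. ECFP4-like).
    n_bits : int
        Length of the hashed bit vector.
    """

    radius: int = 2
    n_bits: int = 2048

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError(f"radius must be >= 0, got {self.radius}")
        if self.n_bits < 1:
            raise ValueError(f"n_bits must be >= 1, got {self.n_bits}")

    def to_dict(self) -> dict:
        return {"radius": self.radius, "n_bits": self.n_bits}

    @classmethod
    def from_dict(cls, d: dict) -> "FingerprintConfig":
        unknown = set(d) - {"radius", "n_bits"}
        if unknown:
            raise ValueError(f"unknown fingerprint config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class Compound:
    """A chemical record: identifier, canonical SMILES, bit fingerprint.

    ``fingerprint`` is a dense uint8 0/1 vector; ``source`` is a free tag
    such as ``"library"``, ``"reference"`` or ``"synthetic"``.
    """

    compound_id: str
    smiles: str
    fingerprint: np.ndarray
    source: str = "library"

    def __post_init__(self) -> None:
        self.fingerprint = np.asarray(self.fingerprint, dtype=np.uint8)
        if self.fingerprint.ndim != 1:
            raise ValueError("fingerprint must be a 1-D bit vector")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Compound):
            return NotImplemented
        return (
            self.compound_id == other.compound_id
            and self.smiles == other.smiles
            and self.source == other.source
            and np.array_equal(self.fingerprint, other.fingerprint)
        )


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumAtoms() == 0:
        raise StructureParseError(f"cannot parse SMILES: {smiles!r}")
    return mol


def canonical_smiles(smiles: str) -> str:
    """Return RDKit's canonical form of *smiles*.

    Raises :class:`StructureParseError` for unparsable or empty input.
    """
    return Chem.MolToSmiles(_mol_from_smiles(smiles))


def compute_fingerprint(
    smiles: str, config: FingerprintConfig | None = None
) -> np.ndarray:
    """Hashed circular substructure fingerprint of *smiles*.

    Deterministic: the same SMILES and config always yield the identical
    bit vector.  Raises :class:`StructureParseError` on invalid SMILES.
    """
    config = config or FingerprintConfig()
    mol = _mol_from_smiles(smiles)
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=config.radius, fpSize=config.n_bits
    )
    return np.asarray(gen.GetFingerprint(mol), dtype=np.uint8)


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto similarity |a AND b| / |a OR b| of two bit vectors.

    Defined as 0.0 when both vectors are all-zero.  Raises ``ValueError``
    on length mismatch.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = int(np.logical_or(a, b).sum())
    if union == 0:
        return 0.0
    return int(np.logical_and(a, b).sum()) / union


@dataclass
class IngestionReport:
    """Counts and per-record errors from one ingestion run."""

    n_valid: int = 0
    n_skipped: int = 0
    errors: list[tuple[int, str]] = field(default_factory=list)  # (line/record no., msg)


def _ingest_records(
    records: Iterable[tuple[int, str, str]],
    config: FingerprintConfig,
    source: str,
    strict: bool,
    report: IngestionReport,
    what: str,
) -> list[Compound]:
    compounds: list[Compound] = []
    seen: set[str] = set()
    for recno, smiles, cid in records:
        try:
            smi = canonical_smiles(smiles)
            fp = compute_fingerprint(smi, config)
        except StructureParseError as exc:
            if strict:
                raise StructureParseError(f"{what} {recno}: {exc}") from exc
            report.n_skipped += 1
            report.errors.append((recno, str(exc)))
            logger.warning("skipping %s %d: %s", what, recno, exc)
            continue
        if cid in seen:
            raise ValueError(f"duplicate compound_id {cid!r} at {what} {recno}")
        seen.add(cid)
        compounds.append(Compound(cid, smi, fp, source=source))
        report.n_valid += 1
    return compounds


def read_compounds(
    path: str | Path,
    format: str | None = None,
    config: FingerprintConfig | None = None,
    source: str = "library",
    strict: bool = False,
    report: IngestionReport | None = None,
    id_property: str = "_Name",
) -> list[Compound]:
    """Read compounds from a ``.smi`` or SDF file.

    ``.smi`` files carry one ``SMILES<whitespace>identifier`` record per
    line; lines starting with ``#`` and blank lines are ignored.  SDF
    identifiers are taken from *id_property*, falling back to the title
    line.  Invalid records are skipped with a logged warning (or raised if
    *strict*); file order is preserved.  Pass an :class:`IngestionReport`
    to collect valid/skipped counts.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"compound file not found: {path}")
    if format is None:
        format = "sdf" if path.suffix.lower() in {".sdf", ".sd", ".mol"} else "smi"
    if format not in {"smi", "sdf"}:
        raise ValueError(f"unsupported compound format: {format!r}")
    config = config or FingerprintConfig()
    report = report if report is not None else IngestionReport()

    if format == "smi":
        records = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split(None, 1)
                smiles = parts[0]
                cid = parts[1].strip() if len(parts) > 1 else f"line{lineno}"
                records.append((lineno, smiles, cid))
        return _ingest_records(records, config, source, strict, report, "line")

    # SDF: pull the molblock apart via RDKit, identifier from a property.
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    records = []
    compounds: list[Compound] = []
    seen: set[str] = set()
    for recno, mol in enumerate(supplier, start=1):
        if mol is None or mol.GetNumAtoms() == 0:
            if strict:
                raise StructureParseError(f"record {recno}: unparsable SDF entry")
            report.n_skipped += 1
            report.errors.append((recno, "unparsable SDF entry"))
            logger.warning("skipping record %d: unparsable SDF entry", recno)
            continue
        if mol.HasProp(id_property) and mol.GetProp(id_property).strip():
            cid = mol.GetProp(id_property).strip()
        else:
            cid = f"record{recno}"
        if cid in seen:
            raise ValueError(f"duplicate compound_id {cid!r} at record {recno}")
        seen.add(cid)
        smi = Chem.MolToSmiles(mol)
        compounds.append(
            Compound(cid, smi, compute_fingerprint(smi, config), source=source)
        )
        report.n_valid += 1
    return compounds


def fingerprint_matrix(compounds: Sequence[Compound]) -> np.ndarray:
    """Stack compound fingerprints into an (n, L) uint8 matrix."""
    if not compounds:
        raise ValueError("no compounds given")
    return np.stack([c.fingerprint for c in compounds]).astype(np.uint8)
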