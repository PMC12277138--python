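"""Readers and writers for association lists, sequences, SMILES tables and run configs.

All tabular formats are tab-separated UTF-8 text.  The association list is a
three-column TSV ``circ_id <TAB> drug_id <TAB> label`` with an optional header
(auto-detected by a non-numeric third column).  circRNA sequences come as FASTA
(``U`` is normalised to ``T`` on read, since downstream k-mer featurisation works
in DNA space), drug structures as a two-column ``drug_id <TAB> smiles`` TSV.
"""

from __future__ import annotations

import csv
import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import yaml
from Bio import SeqIO

logger = logging.getLogger(__name__)

ENCODERS = ("gcn", "gat", "gin")
FEATURE_INITS = ("uniform", "normal", "onehot", "position", "sim")

__all__ = [
    "AssociationTable",
    "SequenceSet",
    "SmilesTable",
    "RunConfig",
    "read_associations",
    "read_sequences",
    "read_smiles",
    "write_predictions",
]


@dataclass(frozen=True)
class AssociationTable:
    """Labelled circRNA-drug pairs: the raw supervised data."""

    records: tuple[tuple[str, str, int], ...]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for circ, drug, label in self.records:
            if not circ or not drug:
                raise ValueError("association ids must be non-empty strings")
            if label not in (0, 1):
                raise ValueError(f"label for ({circ}, {drug}) must be 0 or 1, got {label!r}")
            if (circ, drug) in seen:
                raise ValueError(f"duplicate association pair ({circ}, {drug})")
            seen.add((circ, drug))

    def positives(self) -> list[tuple[str, str]]:
        return [(c, d) for c, d, y in self.records if y == 1]

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class SequenceSet:
    """circRNA id -> nucleotide sequence (DNA alphabet, U already mapped to T)."""

    entries: dict[str, str]

    def __post_init__(self) -> None:
        for cid, seq in self.entries.items():
            if not seq:
                raise ValueError(f"empty sequence for {cid}")
            bad = set(seq.upper()) - set("ACGTN")
            if bad:
                raise ValueError(f"sequence {cid} contains invalid characters {sorted(bad)}")


@dataclass(frozen=True)
class SmilesTable:
    """drug id -> SMILES string. Parsability is checked where fingerprints are built."""

    entries: dict[str, str]

    def __post_init__(self) -> None:
        for did, smi in self.entries.items():
            if not smi:
                raise ValueError(f"empty SMILES for {did}")


@dataclass
class RunConfig:
    """Flat run configuration.

    Defaults follow the tuned operating point: a 2-layer GCN encoder with
    128-dimensional hidden and output representations, position (adjacency-row)
    features, edge-centred subgraphs of order ``P = 1`` and simplicial complexes
    of dimension ``Q = 1``, torsion weighting enabled, 5-fold cross-validation.
    """

    encoder: str = "gcn"
    layers: int = 2
    hidden_dim: int = 128
    out_dim: int = 128
    feature_init: str = "position"
    subgraph_order: int = 1  # P
    complex_dim: int = 1  # Q
    torsion_enabled: bool = True
    folds: int = 5
    seed: int = 0
    lr: float = 1e-3
    epochs: int = 500
    kmer_k: int = 4

    def __post_init__(self) -> None:
        if self.encoder not in ENCODERS:
            raise ValueError(f"encoder must be one of {ENCODERS}, got {self.encoder!r}")
        if self.feature_init not in FEATURE_INITS:
            raise ValueError(
                f"feature_init must be one of {FEATURE_INITS}, got {self.feature_init!r}"
            )
        if self.layers < 1:
            raise ValueError("layers must be >= 1")
        if self.complex_dim not in (1, 2):
            raise ValueError("complex_dim (Q) must be 1 or 2")
        if self.subgraph_order not in (1, 2, 3):
            raise ValueError("subgraph_order (P) must be 1, 2 or 3")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.hidden_dim < 1 or self.out_dim < 1:
            raise ValueError("hidden_dim and out_dim must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.kmer_k < 1:
            raise ValueError("kmer_k must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ValueError("config must be a flat YAML mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _looks_like_header(fields: list[str]) -> bool:
    try:
        int(fields[2])
    except ValueError:
        return True
    return False


def read_associations(path: str | Path) -> AssociationTable:
    """Read a 3-column association TSV into an :class:`AssociationTable`.

    Duplicate (circ_id, drug_id) pairs and labels outside {0, 1} raise; an empty
    file yields an empty table with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"association file not found: {path}")
    records: list[tuple[str, str, int]] = []
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated columns, got {len(row)}")
            if lineno == 1 and _looks_like_header(row):
                continue
            circ, drug, raw_label = (f.strip() for f in row)
            try:
                label = int(raw_label)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: label {raw_label!r} is not an integer") from exc
            if label not in (0, 1):
                raise ValueError(f"{path}:{lineno}: label must be 0 or 1, got {label}")
            records.append((circ, drug, label))
    if not records:
        logger.warning("association file %s is empty", path)
    return AssociationTable(records=tuple(records))


def read_sequences(path: str | Path) -> SequenceSet:
    """Read circRNA sequences from FASTA; ids are headers up to first whitespace."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    entries: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in entries:
            raise ValueError(f"duplicate FASTA header {record.id!r} in {path}")
        seq = str(record.seq).upper().replace("U", "T")
        if not seq:
            raise ValueError(f"empty sequence body for {record.id!r} in {path}")
        entries[record.id] = seq
    return SequenceSet(entries=entries)


def read_smiles(path: str | Path) -> SmilesTable:
    """Read a two-column drug_id/SMILES TSV (optional header)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"SMILES file not found: {path}")
    entries: dict[str, str] = {}
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns, got {len(row)}")
            did, smi = (f.strip() for f in row)
            if lineno == 1 and did.lower() in ("drug_id", "drug", "id"):
                continue
            if did in entries:
                raise ValueError(f"{path}:{lineno}: duplicate drug id {did!r}")
            if not smi:
                raise ValueError(f"{path}:{lineno}: missing SMILES for {did!r}")
            entries[did] = smi
    return SmilesTable(entries=entries)


def write_predictions(
    pairs: Iterable[tuple[str, str, float]], path: str | Path
) -> None:
    """Write scored pairs as TSV, descending by score, ties broken lexicographically."""
    import math

    rows = list(pairs)
    for circ, drug, score in rows:
        if not math.isfinite(score):
            raise ValueError(f"non-finite score for ({circ}, {drug})")
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("circ_id\tdrug_id\tscore\n")
        for circ, drug, score in rows:
            fh.write(f"{circ}\t{drug}\t{score:.6g}\n")
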