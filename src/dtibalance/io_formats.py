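"""File formats and on-disk contracts for the DTI pipeline.

Proteins arrive as FASTA, drugs as a delimited table of (drug_id, smiles),
and interactions as TSV pair lists. Feature matrices persist as delimited
text with a header row of feature names and a leading pair-key column, so
every artifact stays inspectable with standard tools.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

#: The 20 standard amino acids, alphabetical single-letter order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_AA_SET = frozenset(AMINO_ACIDS)

#: Residue codes that are legal FASTA but outside the 20-letter alphabet.
NONSTANDARD_RESIDUES = frozenset("BJOUXZ*")


class FormatError(ValueError):
    """Raised for malformed or contract-violating input files."""


class Label(str, Enum):
    POSITIVE = "POSITIVE"
    UNKNOWN = "UNKNOWN"
    PREDICTED_NEGATIVE = "PREDICTED_NEGATIVE"


@dataclass(frozen=True)
class DrugRecord:
    """A drug identified by an opaque key with a SMILES structure string."""

    drug_id: str
    smiles: str

    def __post_init__(self) -> None:
        if not self.drug_id:
            raise FormatError("drug_id must be non-empty")
        if not self.smiles:
            raise FormatError(f"drug {self.drug_id!r}: empty SMILES")


@dataclass(frozen=True)
class ProteinRecord:
    """A protein identified by an opaque key with an amino-acid sequence."""

    protein_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise FormatError("protein_id must be non-empty")
        if len(self.sequence) < 2:
            raise FormatError(
                f"protein {self.protein_id!r}: sequence shorter than 2 residues"
            )


@dataclass
class InteractionSet:
    """A set of (drug_id, protein_id, label) pairs with a disjoint label partition."""

    pairs: list[tuple[str, str, Label]] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [(d, p) for d, p, _ in self.pairs]
        if len(set(keys)) != len(keys):
            raise FormatError("duplicate (drug_id, protein_id) pair in interaction set")

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[tuple[str, str, Label]]:
        return iter(self.pairs)

    def keys(self) -> list[tuple[str, str]]:
        return [(d, p) for d, p, _ in self.pairs]

    def with_label(self, label: Label) -> list[tuple[str, str]]:
        return [(d, p) for d, p, lab in self.pairs if lab is label]

    def count(self, label: Label) -> int:
        return sum(1 for _, _, lab in self.pairs if lab is label)


def read_fasta(path: str | Path, *, residue_policy: str = "reject") -> list[ProteinRecord]:
    """Read protein records from FASTA.

    Sequences are uppercased. Residues outside the 20-letter alphabet are
    handled per ``residue_policy``: ``"reject"`` (default) raises,
    ``"drop"`` removes the offending residues.
    """
    if residue_policy not in ("reject", "drop"):
        raise ValueError(f"unknown residue_policy {residue_policy!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    with open(path) as handle:
        first = handle.readline()
        if not first:
            raise FormatError(f"{path}: empty FASTA file")
        if not first.startswith(">"):
            raise FormatError(f"{path}: line 1: expected FASTA header starting with '>'")
    for rec in SeqIO.parse(str(path), "fasta"):
        pid = rec.id
        if pid in seen:
            raise FormatError(f"{path}: duplicate protein id {pid!r}")
        seen.add(pid)
        seq = str(rec.seq).upper()
        bad = sorted(set(seq) - _AA_SET)
        if bad:
            if residue_policy == "reject":
                raise FormatError(
                    f"{path}: protein {pid!r} contains non-standard residue(s) "
                    f"{', '.join(repr(b) for b in bad)}"
                )
            seq = "".join(c for c in seq if c in _AA_SET)
        records.append(ProteinRecord(pid, seq))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Sequence[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.protein_id}\n{rec.sequence}\n")


def read_drug_table(path: str | Path, *, sep: str | None = None) -> list[DrugRecord]:
    """Read a delimited drug table with columns ``drug_id`` and ``smiles``.

    The delimiter is sniffed from the extension (.csv -> comma, otherwise
    tab) unless given explicitly. Duplicate ids and empty SMILES are errors.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = {"drug_id", "smiles"} - set(df.columns)
    if missing:
        raise FormatError(
            f"{path}: missing required column(s): {', '.join(sorted(missing))}"
        )
    if df["drug_id"].duplicated().any():
        dup = df.loc[df["drug_id"].duplicated(), "drug_id"].iloc[0]
        raise FormatError(f"{path}: duplicate drug_id {dup!r}")
    records = []
    for row in df.itertuples(index=False):
        if not row.smiles:
            raise FormatError(f"{path}: drug {row.drug_id!r}: empty smiles field")
        records.append(DrugRecord(row.drug_id, row.smiles))
    return records


def write_drug_table(records: Sequence[DrugRecord], path: str | Path) -> None:
    pd.DataFrame(
        {"drug_id": [r.drug_id for r in records], "smiles": [r.smiles for r in records]}
    ).to_csv(path, sep="\t", index=False)


def read_interactions(path: str | Path, *, default_label: Label = Label.POSITIVE) -> InteractionSet:
    """Read a TSV pair list (drug_id, protein_id[, label]) with a header line."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = {"drug_id", "protein_id"} - set(df.columns)
    if missing:
        raise FormatError(
            f"{path}: missing required column(s): {', '.join(sorted(missing))}"
        )
    pairs = []
    for row in df.itertuples(index=False):
        label = Label(row.label) if "label" in df.columns else default_label
        pairs.append((row.drug_id, row.protein_id, label))
    return InteractionSet(pairs)


def write_interactions(interactions: InteractionSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("drug_id\tprotein_id\tlabel\n")
        for d, p, lab in interactions:
            fh.write(f"{d}\t{p}\t{lab.value}\n")


def pair_grid_size(n_drugs: int, n_proteins: int) -> int:
    """Size of the full drug x protein candidate grid."""
    return n_drugs * n_proteins


def unknown_pair_count(n_drugs: int, n_proteins: int, n_positives: int) -> int:
    """Number of unlabeled pairs left after removing positives from the grid.

    Pure arithmetic on the counts, so it is usable at scales where the
    grid itself is never materialized.
    """
    total = pair_grid_size(n_drugs, n_proteins)
    if n_positives > total:
        raise ValueError(
            f"{n_positives} positives exceed the {total}-pair grid"
        )
    return total - n_positives


def iter_unknown_pairs(
    drugs: Sequence[DrugRecord],
    proteins: Sequence[ProteinRecord],
    positives: InteractionSet,
    *,
    chunk_size: int = 100_000,
) -> Iterator[list[tuple[str, str]]]:
    """Stream the unknown pairs of the grid in chunks of ``chunk_size``.

    The grid can be far larger than memory at realistic scales, so the
    universe is never materialized at once.
    """
    drug_ids = [d.drug_id for d in drugs]
    prot_ids = [p.protein_id for p in proteins]
    known_drugs = set(drug_ids)
    known_prots = set(prot_ids)
    positive_keys = set()
    for d, p, _ in positives:
        if d not in known_drugs:
            raise FormatError(f"positive pair references unloaded drug {d!r}")
        if p not in known_prots:
            raise FormatError(f"positive pair references unloaded protein {p!r}")
        positive_keys.add((d, p))
    chunk: list[tuple[str, str]] = []
    for key in itertools.product(drug_ids, prot_ids):
        if key in positive_keys:
            continue
        chunk.append(key)
        if len(chunk) >= chunk_size:
            yield chunk
            chunk = []
    if chunk:
        yield chunk


def enumerate_unknown_pairs(
    drugs: Sequence[DrugRecord],
    proteins: Sequence[ProteinRecord],
    positives: InteractionSet,
    *,
    chunk_size: int = 100_000,
) -> InteractionSet:
    """Materialize the grid minus positives as an UNKNOWN-labeled set.

    Intended for desk-scale grids; use :func:`iter_unknown_pairs` to stream
    larger universes.
    """
    pairs = [
        (d, p, Label.UNKNOWN)
        for chunk in iter_unknown_pairs(drugs, proteins, positives, chunk_size=chunk_size)
        for d, p in chunk
    ]
    expected = unknown_pair_count(len(drugs), len(proteins), len(positives))
    assert len(pairs) == expected
    return InteractionSet(pairs)


def write_feature_matrix(
    path: str | Path,
    pair_keys: Sequence[tuple[str, str]],
    matrix: np.ndarray,
    feature_names: Sequence[str],
) -> None:
    """Persist a pair-aligned feature matrix as TSV with a pair-key column."""
    if matrix.shape != (len(pair_keys), len(feature_names)):
        raise ValueError(
            f"matrix shape {matrix.shape} does not match "
            f"{len(pair_keys)} pairs x {len(feature_names)} features"
        )
    df = pd.DataFrame(matrix, columns=list(feature_names))
    df.insert(0, "pair_key", [f"{d}|{p}" for d, p in pair_keys])
    df.to_csv(path, sep="\t", index=False)


def read_feature_matrix(
    path: str | Path,
) -> tuple[list[tuple[str, str]], np.ndarray, list[str]]:
    """Inverse of :func:`write_feature_matrix`."""
    df = pd.read_csv(path, sep="\t")
    if "pair_key" not in df.columns:
        raise FormatError(f"{path}: missing pair_key column")
    keys = [tuple(k.split("|", 1)) for k in df["pair_key"]]
    names = [c for c in df.columns if c != "pair_key"]
    return keys, df[names].to_numpy(dtype=float), names
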