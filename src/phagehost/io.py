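"""Readers and writers for every on-disk artifact the pipeline touches.

All formats are plain text: FASTA for sequences, TSV for count tables and
two-column mappings, CSV for binary adjacency matrices, JSON for result
records.  Readers validate strictly and name the offending record, cell or
key in their error; every writer/reader pair is an exact inverse on valid
data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "SequenceRecord",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_count_table",
    "write_count_table",
    "read_adjacency_csv",
    "write_adjacency_csv",
    "read_mapping_tsv",
    "write_mapping_tsv",
    "write_json",
    "read_json",
]

_DNA_ALPHABET = frozenset("ACGTN")

MAPPING_KINDS = ("contig_to_vc", "spacer_to_genus", "sample_to_location")


class FormatError(ValueError):
    """Malformed input file; the message names the offending location."""


@dataclass(frozen=True)
class SequenceRecord:
    """An identified DNA sequence (contig, spacer, or repeat).

    ``seq`` is uppercase over the alphabet {A, C, G, T, N} and non-empty;
    ``id`` is a non-empty whitespace-free token.
    """

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"invalid sequence id: {self.id!r}")
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.seq) - _DNA_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r}: characters outside ACGTN: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> str:
        return str(Seq(self.seq).reverse_complement())


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Parse a FASTA file into validated :class:`SequenceRecord` objects.

    Lowercase bases and CRLF line endings are tolerated; sequences are
    uppercased and concatenated across lines.  Duplicate ids, empty files
    and empty sequences are format errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        try:
            records.append(SequenceRecord(id=rec.id, seq=seq, description=desc))
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path, width: int = 70) -> None:
    """Write records as FASTA, sequence lines wrapped at ``width``."""
    if width < 1:
        raise ValueError("width must be positive")
    path = Path(path)
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w", newline="\n") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def read_count_table(path: str | Path) -> "AbundanceTable":
    """Read a taxon-by-sample TSV count table.

    First column must be named ``taxon``; remaining column headers are
    sample ids; cells are non-negative integers.
    """
    from .community import AbundanceTable

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\r\n").split("\t")
    if not header or header[0] != "taxon":
        raise FormatError(f"{path}: first column must be 'taxon', got {header[:1]!r}")
    samples = header[1:]
    if len(set(samples)) != len(samples):
        raise FormatError(f"{path}: duplicate sample id in header")
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = header
    taxa = df["taxon"].tolist()
    dupes = df["taxon"][df["taxon"].duplicated()].tolist()
    if dupes:
        raise FormatError(f"{path}: duplicate taxon id {dupes[0]!r}")
    counts = np.zeros((len(taxa), len(samples)), dtype=np.int64)
    for j, s in enumerate(samples):
        for i, raw in enumerate(df[s]):
            try:
                v = int(raw)
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}: non-integer cell {raw!r} at taxon {taxa[i]!r}, sample {s!r}"
                ) from None
            if v < 0:
                raise ValueError(
                    f"{path}: negative count {v} at taxon {taxa[i]!r}, sample {s!r}"
                )
            counts[i, j] = v
    return AbundanceTable(taxa=taxa, samples=samples, counts=counts)


def write_count_table(table: "AbundanceTable", path: str | Path) -> None:
    df = pd.DataFrame(table.counts, index=pd.Index(table.taxa, name="taxon"),
                      columns=table.samples)
    df.to_csv(path, sep="\t")


def read_adjacency_csv(path: str | Path) -> "BipartiteMatrix":
    """Read a binary genus x virus-cluster adjacency matrix from CSV.

    Header row holds virus-cluster ids, first column holds genus names,
    cells are 0/1.
    """
    from .network import BipartiteMatrix

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, index_col=0, dtype=str)
    rows = list(df.index.astype(str))
    cols = list(df.columns.astype(str))
    if len(set(rows)) != len(rows):
        raise FormatError(f"{path}: duplicate row label")
    if len(set(cols)) != len(cols):
        raise FormatError(f"{path}: duplicate column label")
    A = np.zeros((len(rows), len(cols)), dtype=np.int8)
    for i, r in enumerate(rows):
        for j, c in enumerate(cols):
            raw = df.iat[i, j]
            if raw not in ("0", "1"):
                raise ValueError(
                    f"{path}: non-binary cell {raw!r} at row {r!r}, column {c!r}"
                )
            A[i, j] = int(raw)
    return BipartiteMatrix(A=A, row_labels=rows, col_labels=cols)


def write_adjacency_csv(M: "BipartiteMatrix", path: str | Path) -> None:
    df = pd.DataFrame(M.A, index=M.row_labels, columns=M.col_labels)
    df.to_csv(path)


def read_mapping_tsv(path: str | Path, kind: str) -> dict[str, str]:
    """Read a two-column header-less TSV into a key -> value map.

    ``kind`` is one of ``contig_to_vc``, ``spacer_to_genus``,
    ``sample_to_location``.  Repeated consistent lines collapse; a key
    mapped to two different values is a format error naming the key.
    """
    if kind not in MAPPING_KINDS:
        raise ValueError(f"unknown mapping kind {kind!r}; expected one of {MAPPING_KINDS}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 tab-separated fields")
            key, value = parts
            if key in mapping and mapping[key] != value:
                raise FormatError(
                    f"{path}:{lineno}: conflicting values for key {key!r}: "
                    f"{mapping[key]!r} vs {value!r}"
                )
            mapping[key] = value
    return mapping


def write_mapping_tsv(mapping: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        for k, v in mapping.items():
            fh.write(f"{k}\t{v}\n")


def write_json(obj, path: str | Path) -> None:
    """Serialize a result record (dataclass or plain dict) to JSON."""
    from dataclasses import asdict, is_dataclass

    def default(o):
        if is_dataclass(o) and not isinstance(o, type):
            return asdict(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
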