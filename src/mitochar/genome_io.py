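"""Sequence and feature-table I/O for annotated mitogenomes.

Coordinates follow the convention of published mitogenome annotation
tables: 1-based, fully closed intervals on the heavy (H) strand.  Features
on the light (L) strand are recorded by their H-strand coordinates and
extracted as reverse complements.  Circularity is recorded on the genome
but wrap-around features are rejected (a documented limitation).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

from Bio import SeqIO

PathLike = Union[str, Path]

VALID_ALPHABET = frozenset("ACGTN")
CATEGORIES = ("PCG", "tRNA", "rRNA", "control")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class ParseError(ValueError):
    """Raised when an input file violates the format contract."""


@dataclass(frozen=True)
class GeneFeature:
    """One annotated feature: a PCG, tRNA, rRNA or the control region."""

    name: str
    category: str
    start: int  # 1-based, inclusive
    end: int    # 1-based, inclusive, >= start
    anticodon: str | None = None  # 5'->3' RNA triplet, tRNA only
    strand: str = "H"

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"{self.name}: unknown category {self.category!r}")
        if self.strand not in ("H", "L"):
            raise ValueError(f"{self.name}: unknown strand {self.strand!r}")
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"{self.name}: invalid interval [{self.start}, {self.end}]"
            )
        if self.anticodon is not None:
            if self.category != "tRNA":
                raise ValueError(f"{self.name}: anticodon on non-tRNA feature")
            ac = self.anticodon.upper()
            if len(ac) != 3 or any(b not in "ACGU" for b in ac):
                raise ValueError(f"{self.name}: bad anticodon {self.anticodon!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class Mitogenome:
    """A (typically circular) mitochondrial genome with ordered features."""

    id: str
    sequence: str
    circular: bool = True
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = normalize_sequence(self.sequence, record=self.id)
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"{self.id}: duplicate feature names {dupes}")
        for f in self.features:
            if f.end > len(self.sequence):
                raise ValueError(
                    f"{self.id}: feature {f.name} [{f.start},{f.end}] exceeds "
                    f"genome length {len(self.sequence)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


def normalize_sequence(seq: str, record: str = "<sequence>") -> str:
    """Uppercase, map U->T, and reject characters outside {A,C,G,T,N}."""
    s = seq.upper().replace("U", "T")
    for i, ch in enumerate(s):
        if ch not in VALID_ALPHABET:
            raise ParseError(
                f"record {record!r}: illegal character {ch!r} at position {i + 1}"
            )
    return s


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; N maps to N."""
    s = normalize_sequence(seq)
    return s.translate(_COMPLEMENT)[::-1]


def read_fasta(path: PathLike) -> list[tuple[str, str]]:
    """Read a FASTA file into (id, sequence) pairs.

    Sequences are uppercased, U is normalized to T and characters outside
    {A,C,G,T,N} raise :class:`ParseError` naming the offending record.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        out.append((rec.id, normalize_sequence(str(rec.seq), record=rec.id)))
    return out


def write_fasta(records: Iterable[tuple[str, str]], path: PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


_TABLE_COLUMNS = ("name", "category", "from", "to", "anticodon", "strand")


def _parse_feature_row(fields: list[str], lineno: int) -> GeneFeature:
    if len(fields) != len(_TABLE_COLUMNS):
        raise ParseError(
            f"row {lineno}: expected {len(_TABLE_COLUMNS)} tab-separated "
            f"fields, got {len(fields)}"
        )
    name, category, start_s, end_s, anticodon, strand = (f.strip() for f in fields)
    try:
        start, end = int(start_s), int(end_s)
    except ValueError:
        raise ParseError(f"row {lineno} ({name}): non-integer coordinates "
                         f"{start_s!r}/{end_s!r}") from None
    ac = anticodon if anticodon not in ("", ".") else None
    try:
        return GeneFeature(name=name, category=category, start=start, end=end,
                           anticodon=ac, strand=strand)
    except ValueError as exc:
        raise ParseError(f"row {lineno}: {exc}") from None


def read_feature_table(path_or_text: PathLike | io.StringIO) -> list[GeneFeature]:
    """Read a tab-separated feature table (header: name category from to anticodon strand)."""
    if isinstance(path_or_text, io.StringIO):
        lines = path_or_text.getvalue().splitlines()
        src = "<string>"
    else:
        lines = Path(path_or_text).read_text().splitlines()
        src = str(path_or_text)
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise ParseError(f"{src}: empty feature table")
    header = tuple(h.strip() for h in lines[0].split("\t"))
    if header != _TABLE_COLUMNS:
        raise ParseError(f"{src}: bad header {header}, expected {_TABLE_COLUMNS}")
    features = [_parse_feature_row(ln.split("\t"), i + 2)
                for i, ln in enumerate(lines[1:])]
    names = [f.name for f in features]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ParseError(f"{src}: duplicate feature names {dupes}")
    return features


def write_feature_table(features: Sequence[GeneFeature],
                        path: PathLike | None = None) -> str:
    """Serialize features as TSV; round-trips through :func:`read_feature_table`."""
    out = ["\t".join(_TABLE_COLUMNS)]
    for f in features:
        out.append("\t".join([
            f.name, f.category, str(f.start), str(f.end),
            f.anticodon if f.anticodon is not None else ".", f.strand,
        ]))
    text = "\n".join(out) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def extract_feature(genome: Mitogenome, feature: GeneFeature) -> str:
    """Coding-strand sequence of a feature.

    H-strand features are the plain substring [start, end]; L-strand
    features are the reverse complement of that substring, so the returned
    sequence always reads 5'->3' on the coding strand.
    """
    if feature.end > len(genome.sequence) or feature.start < 1:
        raise ValueError(
            f"feature {feature.name} [{feature.start},{feature.end}] out of "
            f"bounds for genome of length {len(genome.sequence)}"
        )
    sub = genome.sequence[feature.start - 1 : feature.end]
    return reverse_complement(sub) if feature.strand == "L" else sub
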