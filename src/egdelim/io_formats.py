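"""Alignment container, FASTA I/O and haplotype collapsing.

The :class:`Alignment` is the in-memory form every downstream stage consumes:
an ordered list of uniquely-labelled, equal-length nucleotide sequences over
the alphabet ``{A, C, G, T, -, N}``.  IUPAC ambiguity codes other than ``N``
are degraded to ``N`` on read (real chromatogram-derived COI data contains
them), gaps and ``N`` are retained so that their treatment can be decided
per-distance later.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

__all__ = [
    "Alignment",
    "AlignmentError",
    "read_fasta",
    "write_fasta",
    "collapse_haplotypes",
    "write_haplotype_map",
]

_ALPHABET = set("ACGT-N")
# IUPAC nucleotide ambiguity codes that are degraded to N.
_AMBIGUOUS = set("RYSWKMBDHVU")


class AlignmentError(ValueError):
    """Raised when sequences do not form a valid alignment."""


def _clean_sequence(label: str, seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - _ALPHABET
    if bad:
        unknown = bad - _AMBIGUOUS
        if unknown:
            raise AlignmentError(
                f"record {label!r} contains non-nucleotide characters: {sorted(unknown)}"
            )
        warnings.warn(
            f"record {label!r}: ambiguity codes {sorted(bad)} mapped to N",
            stacklevel=3,
        )
        seq = "".join("N" if c in _AMBIGUOUS else c for c in seq)
    return seq


@dataclass(frozen=True)
class Alignment:
    """An ordered, validated multiple sequence alignment."""

    records: tuple[tuple[str, str], ...]
    length: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentError("alignment has no records")
        cleaned = []
        seen: set[str] = set()
        length = len(self.records[0][1])
        if length < 1:
            raise AlignmentError(f"record {self.records[0][0]!r} is empty")
        for label, seq in self.records:
            if not label:
                raise AlignmentError("empty sequence label")
            if label in seen:
                raise AlignmentError(f"duplicate label {label!r}")
            seen.add(label)
            seq = _clean_sequence(label, seq)
            if len(seq) != length:
                raise AlignmentError(
                    f"record {label!r} has length {len(seq)}, expected {length}"
                )
            cleaned.append((label, seq))
        object.__setattr__(self, "records", tuple(cleaned))
        object.__setattr__(self, "length", length)

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str]]) -> "Alignment":
        return cls(tuple((str(l), str(s)) for l, s in records))

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(label for label, _ in self.records)

    @property
    def n(self) -> int:
        return len(self.records)

    def sequence(self, label: str) -> str:
        for lab, seq in self.records:
            if lab == label:
                return seq
        raise KeyError(label)

    def subset(self, labels: Iterable[str]) -> "Alignment":
        """Sub-alignment restricted to *labels* (alignment order preserved)."""
        wanted = set(labels)
        missing = wanted - set(self.labels)
        if missing:
            raise KeyError(f"labels not in alignment: {sorted(missing)}")
        return Alignment(tuple(r for r in self.records if r[0] in wanted))

    def drop(self, labels: Iterable[str]) -> "Alignment":
        unwanted = set(labels)
        return Alignment(tuple(r for r in self.records if r[0] not in unwanted))


def read_fasta(path: str | Path) -> Alignment:
    """Read a multi-FASTA file into an :class:`Alignment`.

    Wrapped and unwrapped sequence lines are both accepted.  Record order is
    preserved; unequal lengths, duplicate labels and empty files raise
    :class:`AlignmentError`.
    """
    path = Path(path)
    records = [(rec.description or rec.id, str(rec.seq)) for rec in SeqIO.parse(path, "fasta")]
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    return Alignment.from_records(records)


def write_fasta(aln: Alignment, path: str | Path) -> None:
    """Write *aln* as unwrapped multi-FASTA; round-trips through read_fasta."""
    path = Path(path)
    with path.open("w") as fh:
        for label, seq in aln.records:
            fh.write(f">{label}\n{seq}\n")


def collapse_haplotypes(aln: Alignment) -> tuple[Alignment, dict[str, str]]:
    """Collapse identical sequences onto one representative (first wins).

    Returns the pruned alignment together with a mapping from every original
    label to the label of its representative.  Idempotent.
    """
    reps: dict[str, str] = {}
    kept: list[tuple[str, str]] = []
    mapping: dict[str, str] = {}
    for label, seq in aln.records:
        if seq in reps:
            mapping[label] = reps[seq]
        else:
            reps[seq] = label
            mapping[label] = label
            kept.append((label, seq))
    return Alignment(tuple(kept)), mapping


def write_haplotype_map(mapping: Mapping[str, str], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["label", "representative"])
        for label, rep in mapping.items():
            writer.writerow([label, rep])
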