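"""Sequence I/O and elementary sequence operations.

All coordinates throughout the package are 0-based, half-open, on the
forward strand of the stored sequence.  DNA records are restricted to the
five-letter alphabet {A, C, G, T, N}; degenerate IUPAC codes are rejected
at ingest because the array detector and the aligner assume an unambiguous
alphabet.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pysam
from Bio import SeqIO
from Bio.Seq import Seq

DNA_ALPHABET = frozenset("ACGTN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYBZX*U")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FastaFormatError(ValueError):
    """Malformed FASTA input (empty header or empty sequence body)."""


class AlphabetError(ValueError):
    """Residues outside the declared alphabet."""


@dataclass(frozen=True)
class SequenceRecord:
    """One sequence with its identifier and optional free-text description."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaFormatError("record id must be non-empty")
        if not self.seq:
            raise FastaFormatError(f"record {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ReadMapping:
    """One read-to-reference alignment reduced to its reference footprint."""

    read_id: str
    ref_id: str
    ref_start: int
    ref_end: int
    aligned_bases: int

    def __post_init__(self) -> None:
        if not 0 <= self.ref_start < self.ref_end:
            raise ValueError("require 0 <= ref_start < ref_end")
        if self.aligned_bases > self.ref_end - self.ref_start:
            raise ValueError("aligned_bases exceeds reference span")


def _check_alphabet(seq: str, alphabet: str, record_id: str) -> None:
    allowed = DNA_ALPHABET if alphabet == "dna" else PROTEIN_ALPHABET
    bad = set(seq) - allowed
    if bad:
        raise AlphabetError(
            f"record {record_id!r}: characters {sorted(bad)} outside "
            f"{alphabet} alphabet"
        )


def read_fasta(path: str | Path, alphabet: str = "dna") -> list[SequenceRecord]:
    """Read a (multi-)FASTA file.

    Wrapped lines are concatenated and case is folded to upper.  An empty
    sequence body or an empty header is a format error naming the record.
    ``alphabet`` is ``"dna"`` (A/C/G/T/N only) or ``"protein"``.
    """
    records: list[SequenceRecord] = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        seq = str(rec.seq).upper()
        if not rec.id:
            raise FastaFormatError(f"record #{i} has an empty header")
        if not seq:
            raise FastaFormatError(f"record {rec.id!r} (#{i}) has an empty body")
        _check_alphabet(seq, alphabet, rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SequenceRecord(id=rec.id, seq=seq, description=desc))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


def read_fastq(path: str | Path) -> list[SequenceRecord]:
    """Read FASTQ; qualities are discarded (the pipeline is not quality-aware)."""
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        seq = str(rec.seq).upper()
        _check_alphabet(seq, "dna", rec.id)
        out.append(SequenceRecord(id=rec.id, seq=seq))
    return out


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string; N maps to N."""
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise AlphabetError(f"non-DNA characters {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def translate(seq: str, frame: int = 0, strand: str = "+") -> str:
    """Translate one reading frame with the standard genetic code.

    Stops are rendered as ``*``; a trailing partial codon is dropped.  A
    sequence with no complete codon in the chosen frame yields ``""``.
    """
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    if strand not in "+-":
        raise ValueError("strand must be '+' or '-'")
    s = reverse_complement(seq) if strand == "-" else seq
    sub = s[frame:]
    sub = sub[: len(sub) - len(sub) % 3]
    if not sub:
        return ""
    return str(Seq(sub).translate())


def gc_content(seq: str) -> float:
    """(G+C) / (A+C+G+T); N is excluded from the denominator."""
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise AlphabetError(f"non-DNA characters {sorted(bad)}")
    gc = seq.count("G") + seq.count("C")
    denom = gc + seq.count("A") + seq.count("T")
    if denom == 0:
        raise ValueError("GC content undefined for an all-N sequence")
    return gc / denom


def interval_depth(mappings: Iterable[ReadMapping], ref_id: str,
                   start: int, end: int,
                   ref_lengths: dict[str, int] | None = None) -> float:
    """Mean per-position read depth over ``[start, end)`` of one reference.

    Depth at a position is the number of mappings whose reference span
    covers it.  If ``ref_lengths`` is supplied the reference must be known
    and the interval must lie within it.
    """
    if ref_lengths is not None:
        if ref_id not in ref_lengths:
            raise KeyError(f"unknown reference {ref_id!r}")
        if not 0 <= start < end <= ref_lengths[ref_id]:
            raise ValueError("interval outside reference")
    if start >= end:
        raise ValueError("require start < end")
    length = end - start
    total = 0
    for m in mappings:
        if m.ref_id != ref_id:
            continue
        lo = max(m.ref_start, start)
        hi = min(m.ref_end, end)
        if hi > lo:
            total += hi - lo
    return total / length


# reference-consuming CIGAR ops: M, D, =, X (N/H/P and insertions do not
# advance both sequences in the way coverage needs)
_REF_CONSUMING = {0, 2, 7, 8}
_MATCH_OPS = {0, 7, 8}


def read_sam(path: str | Path) -> tuple[list[ReadMapping], dict[str, int]]:
    """Read mapped, primary records from a SAM file.

    Only @SQ header lines, mapped primary records and CIGAR M/=/X/D/I/S ops
    are honored; the aligned span is derived from the CIGAR.  Returns the
    mappings and the reference-length table.
    """
    mappings: list[ReadMapping] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        ref_lengths = dict(zip(sam.references, sam.lengths))
        for aln in sam:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.cigartuples is None:
                continue
            span = sum(n for op, n in aln.cigartuples if op in _REF_CONSUMING)
            matched = sum(n for op, n in aln.cigartuples if op in _MATCH_OPS)
            if span == 0:
                continue
            start = aln.reference_start
            mappings.append(ReadMapping(
                read_id=aln.query_name,
                ref_id=aln.reference_name,
                ref_start=start,
                ref_end=start + span,
                aligned_bases=matched,
            ))
    return mappings, ref_lengths


def read_coverage_tsv(path: str | Path) -> dict[tuple[str, int, int], float]:
    """Read a per-interval coverage table: ref_id, start, end, mean_depth."""
    out: dict[tuple[str, int, int], float] = {}
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        for row in reader:
            if not row or row[0].startswith("#") or row[0] == "ref_id":
                continue
            ref, start, end, depth = row[0], int(row[1]), int(row[2]), float(row[3])
            out[(ref, start, end)] = depth
    return out
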