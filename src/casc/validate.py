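"""Validation of candidate CRISPR arrays ("bona fide" classification).

A candidate array is deemed bona fide if it meets:

  (i)   the source sequence has a translated-search hit to a known Cas
        protein (E <= 1e-12),
  (ii)  the consensus repeat has a nucleotide hit to a known CRISPR repeat
        (E <= 1e-5, word size 4, either orientation), or
  (iii) the standard deviation of spacer lengths is <= 2 bp.

Conservative mode requires (i) or (ii); liberal mode accepts (i), (ii) or
(iii).  Validation is pure classification: it never alters array
coordinates or sequences.

The module also computes the positional nucleotide profile of repeat sets
(a position frequency matrix with per-column information content), the
diagnostic that separates bona fide repeats from random decoys.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .detect import CrisprArray
from .homology import Hsp, SearchDatabase, search_nt, search_translated
from .seqio import SequenceRecord, reverse_complement

logger = logging.getLogger(__name__)

_BASES = "ACGT"


@dataclass(frozen=True)
class ValidationThresholds:
    cas_e_max: float = 1e-12
    repeat_e_max: float = 1e-5
    repeat_word_size: int = 4
    spacer_sd_max: float = 2.0

    def __post_init__(self) -> None:
        if min(self.cas_e_max, self.repeat_e_max, self.spacer_sd_max) <= 0 \
                or self.repeat_word_size <= 0:
            raise ValueError("all thresholds must be positive")


@dataclass
class ValidationEvidence:
    """Condition outcomes and mode verdicts for one array."""

    array: CrisprArray
    cas_hit: Hsp | None
    repeat_hit: Hsp | None
    spacer_sd: float
    bona_fide_liberal: bool
    bona_fide_conservative: bool
    single_spacer: bool = False  # sd trivially 0; flagged so users can filter


@dataclass
class RepeatPfm:
    """Position frequency matrix over a set of equal-length repeats."""

    orientation: str
    counts: np.ndarray  # (4, L) base counts per position, rows A,C,G,T
    n_repeats: int
    info_content: np.ndarray  # per-column bits, in [0, 2]


def spacer_length_sd(array: CrisprArray) -> float:
    """Population standard deviation (divide by n) of spacer lengths."""
    lengths = array.spacer_lengths()
    if not lengths:
        raise ValueError("array has no spacers")
    return float(np.std(lengths))


def validate_array(array: CrisprArray, source: SequenceRecord,
                   cas_db: SearchDatabase | None,
                   repeat_db: SearchDatabase | None,
                   thresholds: ValidationThresholds | None = None
                   ) -> ValidationEvidence:
    """Evaluate conditions (i)-(iii) for one array.

    Condition (i) searches the entire source sequence (not a window around
    the array) in six translated frames against the Cas database.  An empty
    or missing database makes the corresponding condition false with a
    logged warning, not an error.
    """
    thresholds = thresholds or ValidationThresholds()

    cas_hit: Hsp | None = None
    if cas_db is None or cas_db.total_length == 0:
        logger.warning("empty Cas database: condition (i) evaluated as false")
    else:
        hits = search_translated(source, cas_db, e_max=thresholds.cas_e_max)
        cas_hit = hits[0] if hits else None

    repeat_hit: Hsp | None = None
    if repeat_db is None or repeat_db.total_length == 0:
        logger.warning("empty repeat database: condition (ii) evaluated as false")
    else:
        cons = SequenceRecord(id=f"{array.seq_id}|array{array.array_index}"
                                 "|consensus",
                              seq=array.consensus_repeat)
        hits = search_nt(cons, repeat_db,
                         word_size=thresholds.repeat_word_size,
                         e_max=thresholds.repeat_e_max)
        repeat_hit = hits[0] if hits else None

    sd = spacer_length_sd(array)
    cons_mode = cas_hit is not None or repeat_hit is not None
    lib_mode = cons_mode or sd <= thresholds.spacer_sd_max
    return ValidationEvidence(
        array=array, cas_hit=cas_hit, repeat_hit=repeat_hit, spacer_sd=sd,
        bona_fide_liberal=lib_mode, bona_fide_conservative=cons_mode,
        single_spacer=array.n_spacers == 1)


def validate_all(arrays: Sequence[CrisprArray],
                 sources: dict[str, SequenceRecord],
                 cas_db: SearchDatabase | None,
                 repeat_db: SearchDatabase | None,
                 thresholds: ValidationThresholds | None = None
                 ) -> list[ValidationEvidence]:
    return [validate_array(a, sources[a.seq_id], cas_db, repeat_db, thresholds)
            for a in arrays]


def extract_bona_fide_spacers(evidence: Iterable[ValidationEvidence],
                              mode: str = "conservative"
                              ) -> list[SequenceRecord]:
    """Spacers of arrays whose verdict under ``mode`` is true, stable order."""
    if mode not in ("liberal", "conservative"):
        raise ValueError("mode must be 'liberal' or 'conservative'")
    out: list[SequenceRecord] = []
    for ev in evidence:
        ok = (ev.bona_fide_conservative if mode == "conservative"
              else ev.bona_fide_liberal)
        if not ok:
            continue
        a = ev.array
        for j, (_, sseq) in enumerate(a.spacers, start=1):
            out.append(SequenceRecord(
                id=f"{a.seq_id}|array{a.array_index}|spacer{j}", seq=sseq))
    return out


def repeat_pfm(repeats: Sequence[str], orientation: str = "forward"
               ) -> RepeatPfm:
    """Positional base counts and information content of a repeat set.

    Repeats longer than the modal length are truncated to it; shorter ones
    are dropped.  Information content of column c with base frequencies
    f_bc is 2 + sum_b f_bc log2 f_bc (with 0 log 0 := 0).
    """
    if not repeats:
        raise ValueError("empty repeat set")
    if orientation not in ("forward", "revcomp"):
        raise ValueError("orientation must be 'forward' or 'revcomp'")
    seqs = [reverse_complement(r) if orientation == "revcomp" else r
            for r in repeats]
    lengths = [len(s) for s in seqs]
    # modal length; ties resolved toward the shorter
    counts = {}
    for L in lengths:
        counts[L] = counts.get(L, 0) + 1
    modal = min(sorted(counts), key=lambda L: (-counts[L], L))
    kept = [s[:modal] for s in seqs if len(s) >= modal]
    mat = np.zeros((4, modal), dtype=int)
    for s in kept:
        for c, b in enumerate(s):
            if b in _BASES:
                mat[_BASES.index(b), c] += 1
    n = len(kept)
    freq = mat / np.maximum(mat.sum(axis=0), 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freq > 0, freq * np.log2(freq), 0.0)
    info = 2.0 + plogp.sum(axis=0)
    return RepeatPfm(orientation=orientation, counts=mat, n_repeats=n,
                     info_content=info)


def write_validation_tsv(evidence: Iterable[ValidationEvidence],
                         path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\tarray\tn_repeats\tn_spacers\tspacer_sd\t"
                 "cas_hit_evalue\trepeat_hit_evalue\tliberal\tconservative\t"
                 "single_spacer\n")
        for ev in evidence:
            a = ev.array
            cas_e = f"{ev.cas_hit.evalue:.3g}" if ev.cas_hit else "NA"
            rep_e = f"{ev.repeat_hit.evalue:.3g}" if ev.repeat_hit else "NA"
            fh.write(f"{a.seq_id}\t{a.array_index}\t{a.n_repeats}\t"
                     f"{a.n_spacers}\t{ev.spacer_sd:.3f}\t{cas_e}\t{rep_e}\t"
                     f"{int(ev.bona_fide_liberal)}\t"
                     f"{int(ev.bona_fide_conservative)}\t"
                     f"{int(ev.single_spacer)}\n")
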