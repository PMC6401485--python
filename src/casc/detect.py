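"""CRT-style detection of candidate repeat-spacer (CRISPR) arrays.

The preliminary search scans each sequence with an exact-match word window:
a word recurring at spacings compatible with a repeat-spacer period seeds a
candidate array, which is then extended column-by-column while a consensus
fraction of the repeat instances agree.  Candidates violating any length
invariant are trimmed, split or discarded, so that every emitted array
satisfies the CrisprArray contract by construction.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .seqio import SequenceRecord

_BASE_ORDER = "ACGT"


@dataclass(frozen=True)
class DetectionParams:
    """Tunable thresholds of the preliminary array search.

    ``search_window`` is the exact-match seed word length; repeat/spacer
    length bounds are in bp; ``column_consensus_min`` is the fraction of
    repeat instances that must agree with the column consensus during
    extension, and ``boundary_consensus_min`` the (stricter) agreement the
    outermost repeat columns must reach after extension — boundary columns
    below it are trimmed back, which pins repeat/spacer boundaries on
    near-identical repeats instead of letting them drift into spacers.

    ``max_spacer_identity`` rejects candidates whose spacers resemble each
    other (mean pairwise identity over the shorter spacer above the
    threshold): true spacers are mutually diverse, whereas tandem-repeat
    loci masquerading as arrays have near-identical inter-repeat segments.
    """

    search_window: int = 8
    min_repeats: int = 3
    repeat_len_min: int = 19
    repeat_len_max: int = 38
    spacer_len_min: int = 19
    spacer_len_max: int = 48
    column_consensus_min: float = 0.75
    boundary_consensus_min: float = 0.9
    min_instance_identity: float = 0.9
    max_spacer_identity: float = 0.6

    def __post_init__(self) -> None:
        if not 2 <= self.search_window <= self.repeat_len_min:
            raise ValueError("require 2 <= search_window <= repeat_len_min")
        if self.min_repeats < 2:
            raise ValueError("min_repeats must be >= 2")
        if not (self.repeat_len_min <= self.repeat_len_max
                and self.spacer_len_min <= self.spacer_len_max):
            raise ValueError("length bounds must be ordered")


@dataclass
class CrisprArray:
    """A detected repeat-spacer locus on one source sequence.

    ``repeats`` and ``spacers`` strictly alternate (R S R S ... R), are
    non-overlapping and ascending; ``start``/``end`` span the first to the
    last repeat.
    """

    seq_id: str
    start: int
    end: int
    repeats: list[tuple[int, str]]
    spacers: list[tuple[int, str]]
    consensus_repeat: str
    array_index: int = 0  # 1-based index within the source sequence

    @property
    def n_repeats(self) -> int:
        return len(self.repeats)

    @property
    def n_spacers(self) -> int:
        return len(self.spacers)

    def spacer_lengths(self) -> list[int]:
        return [len(s) for _, s in self.spacers]

    def check_invariants(self, params: DetectionParams) -> None:
        assert len(self.repeats) == len(self.spacers) + 1
        last_end = -1
        for k, (rs, rseq) in enumerate(self.repeats):
            assert rs > last_end or k == 0
            assert params.repeat_len_min <= len(rseq) <= params.repeat_len_max
            assert "N" not in rseq
            last_end = rs + len(rseq)
            if k < len(self.spacers):
                ss, sseq = self.spacers[k]
                assert ss == last_end
                assert params.spacer_len_min <= len(sseq) <= params.spacer_len_max
                assert ss + len(sseq) == self.repeats[k + 1][0]
        assert self.start == self.repeats[0][0]
        assert self.end == self.repeats[-1][0] + len(self.repeats[-1][1])


def consensus_repeat(repeats: Sequence[str]) -> str:
    """Per-column majority base; ties broken by fixed base order A<C<G<T."""
    if not repeats:
        raise ValueError("need at least one repeat")
    lengths = {len(r) for r in repeats}
    if len(lengths) != 1:
        raise ValueError("repeat instances must have equal lengths")
    out = []
    for col in zip(*repeats):
        counts = Counter(b for b in col if b in _BASE_ORDER)
        if not counts:
            out.append("N")
            continue
        best = max(counts.values())
        out.append(min((b for b, c in counts.items() if c == best),
                       key=_BASE_ORDER.index))
    return "".join(out)


def _column_agreement(seq: str, positions: list[int], offset: int
                      ) -> tuple[str, float]:
    """Consensus base and agreement fraction at one repeat column."""
    col = [seq[p + offset] for p in positions]
    counts = Counter(b for b in col if b in _BASE_ORDER)
    if not counts:
        return "N", 0.0
    best = max(counts.values())
    base = min((b for b, c in counts.items() if c == best),
               key=_BASE_ORDER.index)
    return base, best / len(col)


def _build_chains(positions: list[int], gap_min: int, gap_max: int,
                  min_repeats: int) -> list[list[int]]:
    """Greedy chains of word occurrences with periodic spacing."""
    chains = []
    chain: list[int] = []
    for p in positions:
        if not chain:
            chain = [p]
            continue
        gap = p - chain[-1]
        if gap < gap_min:
            continue
        if gap <= gap_max:
            chain.append(p)
        else:
            if len(chain) >= min_repeats:
                chains.append(chain)
            chain = [p]
    if len(chain) >= min_repeats:
        chains.append(chain)
    return chains


def _extend_seed(seq: str, positions: list[int], params: DetectionParams
                 ) -> tuple[int, int, list[int]] | None:
    """Column-consensus extension of a seed; returns (left, right, positions).

    ``left``/``right`` are offsets relative to the seed word start such
    that each repeat instance occupies seq[p + left : p + right).
    """
    w = params.search_window
    left, right = 0, w

    def spacer_ok(l: int, r: int) -> bool:
        return all(positions[k + 1] + l - (positions[k] + r)
                   >= params.spacer_len_min
                   for k in range(len(positions) - 1))

    # extend right, then left, one column at a time
    while (right - left) < params.repeat_len_max:
        p_last = positions[-1]
        if p_last + right >= len(seq) or not spacer_ok(left, right + 1):
            break
        base, frac = _column_agreement(seq, positions, right)
        if base == "N" or frac < params.column_consensus_min:
            break
        right += 1
    while (right - left) < params.repeat_len_max:
        if positions[0] + left - 1 < 0 or not spacer_ok(left - 1, right):
            break
        base, frac = _column_agreement(seq, positions, left - 1)
        if base == "N" or frac < params.column_consensus_min:
            break
        left -= 1

    # trim low-agreement boundary columns
    changed = True
    while changed and right - left > 0:
        changed = False
        _, frac = _column_agreement(seq, positions, right - 1)
        if frac < params.boundary_consensus_min:
            right -= 1
            changed = True
        if right - left > 0:
            _, frac = _column_agreement(seq, positions, left)
            if frac < params.boundary_consensus_min:
                left += 1
                changed = True

    if right - left < params.repeat_len_min:
        return None
    return left, right, positions


def _make_array(seq_id: str, seq: str, positions: list[int], left: int,
                right: int, params: DetectionParams) -> CrisprArray | None:
    rep_len = right - left
    instances = [seq[p + left:p + right] for p in positions]
    if any("N" in inst for inst in instances):
        return None
    cons = consensus_repeat(instances)
    # drop poorly matching instances from the ends only
    lo, hi = 0, len(instances)
    def identity(s: str) -> float:
        return sum(a == b for a, b in zip(s, cons)) / rep_len
    while lo < hi and identity(instances[lo]) < params.min_instance_identity:
        lo += 1
    while hi > lo and identity(instances[hi - 1]) < params.min_instance_identity:
        hi -= 1
    if hi - lo < params.min_repeats:
        return None
    if any(identity(instances[k]) < params.min_instance_identity
           for k in range(lo, hi)):
        return None  # interior outlier: not a coherent array
    positions = positions[lo:hi]
    instances = instances[lo:hi]
    cons = consensus_repeat(instances)

    repeats = [(p + left, inst) for p, inst in zip(positions, instances)]
    spacers = []
    for k in range(len(repeats) - 1):
        s_start = repeats[k][0] + rep_len
        s_end = repeats[k + 1][0]
        s_len = s_end - s_start
        if not params.spacer_len_min <= s_len <= params.spacer_len_max:
            return None  # caller splits chains before this point
        spacers.append((s_start, seq[s_start:s_end]))
    if len(spacers) >= 2:
        idents = []
        for x in range(len(spacers)):
            for y in range(x + 1, len(spacers)):
                a, b = spacers[x][1], spacers[y][1]
                m = min(len(a), len(b))
                idents.append(sum(c == d for c, d in zip(a, b)) / m)
        if sum(idents) / len(idents) > params.max_spacer_identity:
            return None  # tandem repeat, not a CRISPR array
    arr = CrisprArray(
        seq_id=seq_id, start=repeats[0][0],
        end=repeats[-1][0] + rep_len,
        repeats=repeats, spacers=spacers, consensus_repeat=cons)
    arr.check_invariants(params)
    return arr


def _split_by_spacer_bounds(positions: list[int], left: int, right: int,
                            params: DetectionParams) -> list[list[int]]:
    """Split a chain wherever the implied spacer violates the length bounds."""
    segments: list[list[int]] = [[positions[0]]]
    for prev, cur in zip(positions, positions[1:]):
        s_len = (cur + left) - (prev + right)
        if params.spacer_len_min <= s_len <= params.spacer_len_max:
            segments[-1].append(cur)
        else:
            segments.append([cur])
    return [s for s in segments if len(s) >= params.min_repeats]


def find_arrays(record: SequenceRecord,
                params: DetectionParams | None = None) -> list[CrisprArray]:
    """Detect candidate repeat-spacer arrays on one sequence.

    Returns non-overlapping arrays in coordinate order; an empty list is
    the no-find result.  Overlapping candidates are resolved keeping the
    one with more repeats, then the longer, then the leftmost.
    """
    params = params or DetectionParams()
    seq = record.seq
    w = params.search_window
    gap_min = params.spacer_len_min + params.repeat_len_min
    gap_max = params.spacer_len_max + params.repeat_len_max

    word_positions: dict[str, list[int]] = {}
    word_order: list[str] = []
    for i in range(len(seq) - w + 1):
        word = seq[i:i + w]
        if "N" in word:
            continue
        if word not in word_positions:
            word_positions[word] = []
            word_order.append(word)
        word_positions[word].append(i)

    candidates: list[CrisprArray] = []
    seen_keys: set[tuple] = set()
    for word in word_order:
        positions = word_positions[word]
        if len(positions) < params.min_repeats:
            continue
        for chain in _build_chains(positions, gap_min, gap_max,
                                   params.min_repeats):
            ext = _extend_seed(seq, chain, params)
            if ext is None:
                continue
            left, right, chain = ext
            for segment in _split_by_spacer_bounds(chain, left, right, params):
                arr = _make_array(record.id, seq, segment, left, right, params)
                if arr is None:
                    continue
                key = (arr.start, arr.end, arr.n_repeats,
                       len(arr.consensus_repeat))
                if key in seen_keys:
                    continue
                seen_keys.add(key)
                candidates.append(arr)

    # overlap resolution: more repeats, then longer, then leftmost
    candidates.sort(key=lambda a: (-a.n_repeats, -(a.end - a.start), a.start))
    kept: list[CrisprArray] = []
    for cand in candidates:
        if all(cand.end <= k.start or k.end <= cand.start for k in kept):
            kept.append(cand)
    kept.sort(key=lambda a: a.start)
    for i, arr in enumerate(kept, start=1):
        arr.array_index = i
    return kept


def find_arrays_multi(records: Iterable[SequenceRecord],
                      params: DetectionParams | None = None
                      ) -> list[CrisprArray]:
    """Run the detector over many records; results concatenate per record."""
    out: list[CrisprArray] = []
    for rec in records:
        out.extend(find_arrays(rec, params))
    return out


# ---------------------------------------------------------------------------
# exports

def spacer_records(array: CrisprArray) -> list[SequenceRecord]:
    """Spacers of one array as records, ids '{seq_id}|array{i}|spacer{j}'."""
    return [SequenceRecord(
        id=f"{array.seq_id}|array{array.array_index}|spacer{j}",
        seq=sseq)
        for j, (_, sseq) in enumerate(array.spacers, start=1)]


def write_arrays_tsv(arrays: Iterable[CrisprArray], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\tarray\tstart\tend\tn_repeats\tn_spacers\t"
                 "consensus_repeat\n")
        for a in arrays:
            fh.write(f"{a.seq_id}\t{a.array_index}\t{a.start}\t{a.end}\t"
                     f"{a.n_repeats}\t{a.n_spacers}\t{a.consensus_repeat}\n")


def write_arrays_gff3(arrays: Iterable[CrisprArray], path: str | Path) -> None:
    """One repeat_region feature per array with repeat/spacer children."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for a in arrays:
            aid = f"{a.seq_id}.array{a.array_index}"
            fh.write(f"{a.seq_id}\tcasc\trepeat_region\t{a.start + 1}\t"
                     f"{a.end}\t.\t+\t.\tID={aid}\n")
            for k, (rs, rseq) in enumerate(a.repeats, start=1):
                fh.write(f"{a.seq_id}\tcasc\tdirect_repeat\t{rs + 1}\t"
                         f"{rs + len(rseq)}\t.\t+\t.\t"
                         f"ID={aid}.repeat{k};Parent={aid}\n")
            for k, (ss, sseq) in enumerate(a.spacers, start=1):
                fh.write(f"{a.seq_id}\tcasc\tbinding_site\t{ss + 1}\t"
                         f"{ss + len(sseq)}\t.\t+\t.\t"
                         f"ID={aid}.spacer{k};Parent={aid}\n")
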