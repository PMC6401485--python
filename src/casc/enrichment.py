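"""Functional annotation of ORFs and fold-change enrichment of targets.

An ORF is annotated to the function whose hits accumulate the highest
total bit score (so eight weak "phage protein" hits totaling 50 bits lose
to two terminase hits totaling 100).  Expected counts for the spacer-
matched ORF set come from the database-wide annotation frequencies:
expected_a = n_matched * freq_a, and fold change = actual / expected.

Free-text database functions are collapsed into reporting categories by an
ordered keyword map (first case-insensitive substring match wins); the
default map covers the fifteen standard virioplankton categories and is
fully configurable — the grouping is an explicit, reproducible choice, not
a database fact.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .homology import Hsp

NO_HITS = "no hits"
OTHER = "Other annotations"

# Ordered: specific categories must precede the generic "phage protein"
# catch-all, and "tail fiber"/"tape measure" must precede plain "tail".
DEFAULT_KEYWORD_MAP: list[tuple[str, str]] = [
    ("terminase", "Phage terminase"),
    ("methyltransferase", "Methyltransferase"),
    ("capsid", "Phage capsid protein"),
    ("tail fiber", "Phage tail fiber"),
    ("tape measure", "Phage tape measure protein"),
    ("tail", "Phage tail protein"),
    ("polymerase", "DNA polymerase"),
    ("recombinase", "Phage-associated recombinase"),
    ("integrase", "Phage-associated recombinase"),
    ("portal", "Phage portal protein"),
    ("ssdna-binding", "ssDNA-binding protein"),
    ("single-stranded dna-binding", "ssDNA-binding protein"),
    ("single stranded dna binding", "ssDNA-binding protein"),
    ("helicase", "Phage DNA helicase"),
    ("reductase", "Reductase"),
    ("peptidase", "Peptidase"),
    ("protease", "Peptidase"),
    ("glycosyltransferase", "Glycotransferase"),
    ("glycotransferase", "Glycotransferase"),
    ("glycosyl transferase", "Glycotransferase"),
    ("phage protein", "Phage protein"),
    ("hypothetical", "Phage protein"),
]


@dataclass(frozen=True)
class AnnotationAssignment:
    orf_id: str
    annotation: str
    cumulative_bit_score: float
    n_hits: int

    def __post_init__(self) -> None:
        no_hit = self.annotation == NO_HITS
        if no_hit != (self.n_hits == 0) or no_hit != (
                self.cumulative_bit_score == 0):
            raise ValueError("'no hits' must coincide with zero hits/bits")


@dataclass(frozen=True)
class EnrichmentRow:
    annotation: str
    actual: int
    expected: float
    fold_change: float | None  # None when 0/0; inf when expected == 0

    @property
    def fold_change_printed(self) -> str:
        return format_fold(self.fold_change)


@dataclass
class Background:
    """Annotation frequencies over ALL database ORFs, incl. 'no hits'."""

    frequencies: dict[str, float]
    total_orfs: int

    def __post_init__(self) -> None:
        total = sum(self.frequencies.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"frequencies sum to {total}, not 1")

    @classmethod
    def from_assignments(cls, assignments: Sequence[AnnotationAssignment]
                         ) -> "Background":
        if not assignments:
            raise ValueError("cannot build a background from zero ORFs")
        counts: dict[str, int] = defaultdict(int)
        for a in assignments:
            counts[a.annotation] += 1
        n = len(assignments)
        return cls(frequencies={k: v / n for k, v in counts.items()},
                   total_orfs=n)


def normalize_label(raw_function: str,
                    keyword_map: Sequence[tuple[str, str]] | None = None
                    ) -> str:
    """First case-insensitive substring match wins; unmatched pass through."""
    keyword_map = DEFAULT_KEYWORD_MAP if keyword_map is None else keyword_map
    low = raw_function.lower()
    for pattern, category in keyword_map:
        if pattern.lower() in low:
            return category
    return raw_function


def annotate_orf(orf_id: str, hits: Sequence[tuple[Hsp, str]],
                 e_max: float = 1e-3,
                 keyword_map: Sequence[tuple[str, str]] | None = None
                 ) -> AnnotationAssignment:
    """Best-cumulative-bit-score annotation of one ORF.

    ``hits`` pairs each HSP with the raw function label of its subject.
    Ties on total bit score break toward more hits, then the
    lexicographically smaller label.  Order of ``hits`` never matters.
    """
    groups: dict[str, list[float]] = defaultdict(list)
    for hsp, raw in hits:
        if hsp.evalue <= e_max:
            groups[normalize_label(raw, keyword_map)].append(hsp.bit_score)
    if not groups:
        return AnnotationAssignment(orf_id=orf_id, annotation=NO_HITS,
                                    cumulative_bit_score=0.0, n_hits=0)
    best = min(groups.items(),
               key=lambda kv: (-sum(kv[1]), -len(kv[1]), kv[0]))
    return AnnotationAssignment(orf_id=orf_id, annotation=best[0],
                                cumulative_bit_score=float(sum(best[1])),
                                n_hits=len(best[1]))


def expected_counts(background: Background, n_matched: int
                    ) -> dict[str, float]:
    """expected_a = n_matched * freq_a for every annotation."""
    if n_matched < 0:
        raise ValueError("n_matched must be >= 0")
    return {a: n_matched * f for a, f in background.frequencies.items()}


def fold_change(actual: int, expected: float) -> float | None:
    """actual / expected; inf when expected is 0 and actual > 0, None on 0/0."""
    if expected < 0:
        raise ValueError("expected must be >= 0")
    if expected == 0:
        return math.inf if actual > 0 else None
    return actual / expected


def format_fold(fold: float | None) -> str:
    """One decimal, rounded half away from zero; blank/inf flags preserved."""
    if fold is None:
        return ""
    if math.isinf(fold):
        return "inf"
    return str(Decimal(repr(fold)).quantize(Decimal("0.1"),
                                            rounding=ROUND_HALF_UP))


def enrichment_table(assignments: Sequence[AnnotationAssignment],
                     background: Background,
                     collapse_after: int | None = None
                     ) -> list[EnrichmentRow]:
    """Actual vs expected counts for the spacer-matched ORF set.

    Rows cover every annotation with actual > 0 plus 'no hits', sorted by
    actual count descending (ties by label).  With ``collapse_after`` = k,
    annotations ranked below the top k (excluding 'no hits') merge into
    one 'Other annotations' row whose expected count pools the same
    annotations' expectations.
    """
    if not assignments:
        return []
    actual: dict[str, int] = defaultdict(int)
    for a in assignments:
        actual[a.annotation] += 1
    expected = expected_counts(background, len(assignments))

    labels = sorted((l for l in actual if l != NO_HITS),
                    key=lambda l: (-actual[l], l))
    if collapse_after is not None and len(labels) > collapse_after:
        head, tail = labels[:collapse_after], labels[collapse_after:]
        other_actual = sum(actual[l] for l in tail)
        other_expected = sum(expected.get(l, 0.0) for l in tail)
        rows = [(l, actual[l], expected.get(l, 0.0)) for l in head]
        rows.append((f"{OTHER} ({len(tail)})", other_actual, other_expected))
    else:
        rows = [(l, actual[l], expected.get(l, 0.0)) for l in labels]
    rows.append((NO_HITS, actual.get(NO_HITS, 0), expected.get(NO_HITS, 0.0)))
    return [EnrichmentRow(annotation=l, actual=n, expected=e,
                          fold_change=fold_change(n, e))
            for l, n, e in rows]


def enrichment_dataframe(rows: Sequence[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame([{
        "annotation": r.annotation, "actual": r.actual,
        "expected": r.expected, "fold_change": r.fold_change,
        "fold_change_printed": r.fold_change_printed} for r in rows])


def write_enrichment_tsv(rows: Sequence[EnrichmentRow],
                         path: str | Path) -> None:
    enrichment_dataframe(rows).to_csv(path, sep="\t", index=False,
                                      float_format="%.6g")


def write_background_tsv(background: Background, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("annotation\tcount\tfrequency\n")
        for a in sorted(background.frequencies):
            f = background.frequencies[a]
            fh.write(f"{a}\t{round(f * background.total_orfs)}\t{f:.8g}\n")


def read_background_tsv(path: str | Path) -> Background:
    df = pd.read_csv(path, sep="\t")
    total = int(df["count"].sum())
    freqs = {row.annotation: row["count"] / total for _, row in df.iterrows()}
    return Background(frequencies=freqs, total_orfs=total)
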