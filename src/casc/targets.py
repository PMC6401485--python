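"""Spacer-to-virome target identification and the match network.

The workflow mirrors the field protocol: virome sequences that themselves
carry (liberal-mode bona fide) CRISPR arrays are removed first, spacers
are matched permissively (word size 7, E <= 0.1), ORFs are called only on
contigs that received a match, matches are assigned to overlapping ORFs
(detecting the rare spacers that span two adjacent genes), and the
resulting many-to-many network is summarized by degree histograms and by
great-circle distances between the sampling sites of spacer and target.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .detect import DetectionParams, find_arrays
from .homology import Hsp, ScoringScheme, SearchDatabase, search_nt
from .seqio import SequenceRecord, reverse_complement, translate
from .validate import ValidationThresholds, validate_array

EARTH_RADIUS_KM = 6371.0088

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class OrfRecord:
    """One called ORF; coordinates are forward-strand, 0-based half-open."""

    contig_id: str
    orf_id: str
    start: int
    end: int
    strand: str
    protein: str

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3 != 0:
            raise ValueError("ORF length must be divisible by 3")


@dataclass
class SpacerTargetMatch:
    """One spacer-to-virome link; the edges of the match network."""

    spacer_id: str
    contig_id: str
    hsp: Hsp
    orf_ids: list[str]
    spans_two_orfs: bool


@dataclass(frozen=True)
class Site:
    sample_id: str
    lat: float
    lon: float

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude {self.lat} out of range")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"longitude {self.lon} out of range")


def great_circle_km(a: Site, b: Site) -> float:
    """Haversine distance on a sphere of radius 6371.0088 km."""
    la1, lo1, la2, lo2 = map(math.radians, (a.lat, a.lon, b.lat, b.lon))
    h = (math.sin((la2 - la1) / 2) ** 2
         + math.cos(la1) * math.cos(la2) * math.sin((lo2 - lo1) / 2) ** 2)
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def remove_array_bearing_sequences(
        virome: Sequence[SequenceRecord],
        cas_db: SearchDatabase | None = None,
        repeat_db: SearchDatabase | None = None,
        params: DetectionParams | None = None,
        thresholds: ValidationThresholds | None = None,
) -> tuple[list[SequenceRecord], list[str]]:
    """Drop virome sequences carrying a liberal-mode bona fide array.

    Returns (survivors, dropped ids).  Idempotent: survivors contain no
    detectable array, so a second application is the identity.
    """
    survivors: list[SequenceRecord] = []
    dropped: list[str] = []
    import logging
    for rec in virome:
        arrays = find_arrays(rec, params)
        bona_fide = False
        for arr in arrays:
            ev = validate_array(arr, rec, cas_db, repeat_db, thresholds)
            if ev.bona_fide_liberal:
                bona_fide = True
                break
        if bona_fide:
            dropped.append(rec.id)
        else:
            survivors.append(rec)
    if not survivors:
        logging.getLogger(__name__).warning(
            "all %d virome sequences carry arrays; nothing left to search",
            len(dropped))
    return survivors, dropped


def match_spacers(spacers: Sequence[SequenceRecord],
                  virome_db: SearchDatabase,
                  word_size: int = 7, e_max: float = 0.1,
                  scheme: ScoringScheme | None = None) -> list[Hsp]:
    """Permissive spacer-vs-virome search; best HSP per (spacer, contig).

    Keeping only the best-E-value hit per contig prevents a spacer from
    being double-counted against overlapping ORF calls on one sequence.
    """
    out: list[Hsp] = []
    for spacer in spacers:
        hits = search_nt(spacer, virome_db, word_size=word_size,
                         e_max=e_max, scheme=scheme)
        best: dict[str, Hsp] = {}
        for h in hits:  # hits sorted by ascending evalue
            if h.subject_id not in best:
                best[h.subject_id] = h
        out.extend(best[sid] for sid in sorted(best))
    return out


def call_orfs(contig: SequenceRecord, min_aa: int = 30) -> list[OrfRecord]:
    """All maximal ATG-to-stop frames on both strands, protein >= min_aa.

    A transparent substitute for a trained gene caller: adequate here
    because ORFs only serve to assign match coordinates to genes.  ORFs
    require a stop codon; overlaps are allowed.  Output is sorted by
    forward-strand start and numbered '{contig_id}|orf{k}'.
    """
    L = len(contig.seq)
    found: list[tuple[int, int, str, str]] = []
    for strand in "+-":
        s = contig.seq if strand == "+" else reverse_complement(contig.seq)
        for frame in range(3):
            atg: int | None = None
            for pos in range(frame, L - 2, 3):
                codon = s[pos:pos + 3]
                if codon in _STOPS:
                    if atg is not None:
                        aa_len = (pos - atg) // 3
                        if aa_len >= min_aa:
                            start_s, end_s = atg, pos + 3
                            if strand == "+":
                                fs, fe = start_s, end_s
                            else:
                                fs, fe = L - end_s, L - start_s
                            prot = translate(s[start_s:end_s - 3])
                            found.append((fs, fe, strand, prot))
                        atg = None
                elif codon == "ATG" and atg is None:
                    atg = pos
    found.sort(key=lambda t: (t[0], t[1], t[2]))
    return [OrfRecord(contig_id=contig.id,
                      orf_id=f"{contig.id}|orf{k}",
                      start=fs, end=fe, strand=strand, protein=prot)
            for k, (fs, fe, strand, prot) in enumerate(found, start=1)]


def assign_matches(hsps: Sequence[Hsp],
                   orfs_by_contig: Mapping[str, Sequence[OrfRecord]]
                   ) -> list[SpacerTargetMatch]:
    """Assign each spacer HSP to the ORFs its subject interval overlaps.

    Overlap of >= 1 nt counts.  Exactly two overlapped ORFs that are
    adjacent in the contig's start-sorted ORF list set the spanning flag;
    zero overlapped ORFs yield an intergenic record with empty orf_ids.
    """
    out: list[SpacerTargetMatch] = []
    for h in hsps:
        orfs = sorted(orfs_by_contig.get(h.subject_id, ()),
                      key=lambda o: (o.start, o.end))
        touched = [(k, o) for k, o in enumerate(orfs)
                   if o.start < h.s_end and h.s_start < o.end]
        spans = (len(touched) == 2
                 and touched[1][0] == touched[0][0] + 1)
        out.append(SpacerTargetMatch(
            spacer_id=h.query_id, contig_id=h.subject_id, hsp=h,
            orf_ids=[o.orf_id for _, o in touched],
            spans_two_orfs=spans))
    return out


def degree_distributions(matches: Sequence[SpacerTargetMatch]
                         ) -> tuple[Counter, Counter]:
    """(spacer-degree histogram, ORF-degree histogram) over degrees >= 1.

    Spacer degree is the number of distinct ORFs a spacer matches; ORF
    degree the number of distinct spacers matching an ORF.  Intergenic
    matches contribute to neither.
    """
    spacer_orfs: dict[str, set[str]] = {}
    orf_spacers: dict[str, set[str]] = {}
    for m in matches:
        for oid in m.orf_ids:
            spacer_orfs.setdefault(m.spacer_id, set()).add(oid)
            orf_spacers.setdefault(oid, set()).add(m.spacer_id)
    spacer_hist = Counter(len(v) for v in spacer_orfs.values())
    orf_hist = Counter(len(v) for v in orf_spacers.values())
    return spacer_hist, orf_hist


def write_matches_tsv(matches: Iterable[SpacerTargetMatch], path: str | Path,
                      spacer_sites: Mapping[str, Site] | None = None,
                      contig_sites: Mapping[str, Site] | None = None) -> None:
    """Matches table; distance_km filled when both sampling sites are known."""
    with open(path, "w") as fh:
        fh.write("spacer_id\tcontig_id\tevalue\tbit_score\tmismatches\t"
                 "gaps\torf_ids\tspans_two_orfs\tdistance_km\n")
        for m in matches:
            dist = ""
            if spacer_sites and contig_sites:
                a = spacer_sites.get(m.spacer_id)
                b = contig_sites.get(m.contig_id)
                if a is not None and b is not None:
                    dist = f"{great_circle_km(a, b):.1f}"
            fh.write(f"{m.spacer_id}\t{m.contig_id}\t{m.hsp.evalue:.3g}\t"
                     f"{m.hsp.bit_score:.1f}\t{m.hsp.mismatches}\t"
                     f"{m.hsp.gaps}\t{','.join(m.orf_ids)}\t"
                     f"{int(m.spans_two_orfs)}\t{dist}\n")


def write_orfs_fasta(orfs: Iterable[OrfRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for o in orfs:
            fh.write(f">{o.orf_id} {o.contig_id}:{o.start}-{o.end}({o.strand})\n")
            fh.write(o.protein + "\n")


def write_orfs_gff3(orfs: Iterable[OrfRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for o in orfs:
            fh.write(f"{o.contig_id}\tcasc\tCDS\t{o.start + 1}\t{o.end}\t.\t"
                     f"{o.strand}\t0\tID={o.orf_id}\n")
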