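"""Synthetic metagenomes with planted CRISPR arrays, and truth-based scoring.

The generator emulates the published validation design: bacterial-sized
random genomes, a subset carrying planted repeat-spacer arrays (with
tandem-repeat decoy loci as confounders), and shotgun reads with normally
distributed lengths and a 3'-increasing substitution error ramp
approximating a pyrosequencing-style error profile.  Desk-scale defaults
(10 genomes x 100 kb, thousands of reads) stand in for the original
multi-million-read simulations; every size is a parameter.

Scoring follows the 100%-identity rule: a predicted spacer is a true
positive iff its sequence equals a planted spacer or its reverse
complement; sub-unit identity thresholds use greedy length-sorted
clustering (cd-hit style) with identity measured over the shorter
sequence.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import Align

from .seqio import SequenceRecord, reverse_complement, write_fasta

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class PlantedArraySpec:
    """One planted array: a repeat, spacer lengths and the genome offset."""

    repeat: str
    spacer_lengths: tuple[int, ...]
    genome_offset: int

    @property
    def n_units(self) -> int:
        return len(self.spacer_lengths) + 1

    @property
    def total_length(self) -> int:
        return self.n_units * len(self.repeat) + sum(self.spacer_lengths)


@dataclass(frozen=True)
class DecoySpec:
    """A zero-gap tandem repeat locus (CRISPR look-alike confounder)."""

    unit: str
    n_copies: int
    genome_offset: int

    @property
    def total_length(self) -> int:
        return len(self.unit) * self.n_copies


@dataclass(frozen=True)
class TruthSpacer:
    genome_id: str
    array_index: int
    spacer_index: int
    start: int
    end: int
    seq: str


@dataclass
class ReadSimParams:
    """Shotgun read simulation settings.

    Substitution probability rises linearly from ``p0`` at the read start
    to ``p1`` at the read end (indels off); read lengths are
    Normal(mean, sd) truncated to [50, genome length].
    """

    read_length_mean: float = 450.0
    read_length_sd: float = 50.0
    n_reads: int = 20_000
    paired: bool = False
    insert: int = 300
    p0: float = 0.0
    p1: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p0 <= self.p1 < 0.1:
            raise ValueError("require 0 <= p0 <= p1 < 0.1")


@dataclass
class EvalResult:
    tp: int
    fp: int
    fn: int
    sensitivity: float
    precision: float | None  # None when no predictions were made


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def make_genomes(n_with_arrays: int, n_without: int, genome_len: int,
                 specs: Sequence[PlantedArraySpec], seed: int,
                 decoys: Sequence[tuple[int, DecoySpec]] = (),
                 ) -> tuple[list[SequenceRecord], list[TruthSpacer]]:
    """Seeded random genomes with planted arrays and decoy loci.

    ``specs[i]`` is planted into genome i (the first ``n_with_arrays``
    genomes); ``decoys`` pairs a genome index with a DecoySpec.  Spacer
    sequences are drawn uniformly at random.  Returns the genome records
    (ids genome00, genome01, ...) and the truth table of planted spacers.
    """
    if len(specs) != n_with_arrays:
        raise ValueError("need one PlantedArraySpec per array-bearing genome")
    rng = np.random.default_rng(seed)
    n_total = n_with_arrays + n_without
    loci: dict[int, list[tuple[int, int]]] = {i: [] for i in range(n_total)}

    def claim(gi: int, start: int, length: int) -> None:
        if start < 0 or start + length > genome_len:
            raise ValueError(f"locus [{start}, {start + length}) outside "
                             f"genome of length {genome_len}")
        for s, e in loci[gi]:
            if start < e and s < start + length:
                raise ValueError(f"planted loci overlap in genome {gi}")
        loci[gi].append((start, start + length))

    for gi, spec in enumerate(specs):
        claim(gi, spec.genome_offset, spec.total_length)
    for gi, dec in decoys:
        claim(gi, dec.genome_offset, dec.total_length)

    genomes: list[SequenceRecord] = []
    truth: list[TruthSpacer] = []
    for gi in range(n_total):
        gid = f"genome{gi:02d}"
        seq = list(_random_dna(rng, genome_len))
        if gi < n_with_arrays:
            spec = specs[gi]
            pos = spec.genome_offset
            for j, slen in enumerate(spec.spacer_lengths, start=1):
                seq[pos:pos + len(spec.repeat)] = spec.repeat
                pos += len(spec.repeat)
                spacer = _random_dna(rng, slen)
                seq[pos:pos + slen] = spacer
                truth.append(TruthSpacer(genome_id=gid, array_index=1,
                                         spacer_index=j, start=pos,
                                         end=pos + slen, seq=spacer))
                pos += slen
            seq[pos:pos + len(spec.repeat)] = spec.repeat
        for dgi, dec in decoys:
            if dgi == gi:
                unit = dec.unit * dec.n_copies
                seq[dec.genome_offset:dec.genome_offset + len(unit)] = unit
        genomes.append(SequenceRecord(id=gid, seq="".join(seq)))
    return genomes, truth


def simulate_reads(genomes: Sequence[SequenceRecord],
                   params: ReadSimParams) -> list[SequenceRecord]:
    """Shotgun reads: starts uniform over total genome length, random strand.

    With ``p0 = p1 = 0`` every read is an exact substring (or reverse
    complement) of a genome.  Read ids encode their origin
    (read{i}|{genome}|{start}|{strand}[/1|/2]) for downstream truth checks.
    """
    if not genomes:
        raise ValueError("genome set is empty")
    rng = np.random.default_rng(params.seed)
    lengths = np.array([len(g) for g in genomes], dtype=float)
    probs = lengths / lengths.sum()
    reads: list[SequenceRecord] = []

    def mutate(seq: str) -> str:
        L = len(seq)
        if params.p1 == 0.0 or L == 0:
            return seq
        ramp = params.p0 + (params.p1 - params.p0) * (
            np.arange(L) / max(L - 1, 1))
        hits = np.nonzero(rng.random(L) < ramp)[0]
        if hits.size == 0:
            return seq
        out = list(seq)
        for i in hits:
            alternatives = [b for b in "ACGT" if b != out[i]]
            out[i] = alternatives[rng.integers(3)]
        return "".join(out)

    for i in range(params.n_reads):
        gi = int(rng.choice(len(genomes), p=probs))
        g = genomes[gi].seq
        rl = int(round(rng.normal(params.read_length_mean,
                                  params.read_length_sd)))
        rl = max(50, min(rl, len(g)))
        if params.paired:
            frag = max(rl, params.insert)
            start = int(rng.integers(0, len(g) - frag + 1))
            fwd = g[start:start + rl]
            rev = reverse_complement(g[start + frag - rl:start + frag])
            strand = "+"
            reads.append(SequenceRecord(
                id=f"read{i}|{genomes[gi].id}|{start}|{strand}/1",
                seq=mutate(fwd)))
            reads.append(SequenceRecord(
                id=f"read{i}|{genomes[gi].id}|{start}|{strand}/2",
                seq=mutate(rev)))
        else:
            start = int(rng.integers(0, len(g) - rl + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            frag = g[start:start + rl]
            if strand == "-":
                frag = reverse_complement(frag)
            reads.append(SequenceRecord(
                id=f"read{i}|{genomes[gi].id}|{start}|{strand}",
                seq=mutate(frag)))
    return reads


def write_fastq(reads: Iterable[SequenceRecord], path: str | Path,
                quality_char: str = "I") -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{quality_char * len(r.seq)}\n")


# ---------------------------------------------------------------------------
# truth-based scoring

def _global_identity(a: str, b: str, aligner: Align.PairwiseAligner) -> float:
    """Identities of the best global alignment, over the shorter sequence."""
    best = 0
    for cand in (b, reverse_complement(b)):
        aln = aligner.align(a, cand)[0]
        best = max(best, int(aln.counts().identities))
    return best / min(len(a), len(b))


def _make_global_aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 1
    al.mismatch_score = -1
    al.open_gap_score = -2
    al.extend_gap_score = -1
    return al


def cluster_at_identity(predicted: Sequence[SequenceRecord],
                        known: Sequence[SequenceRecord],
                        identity: float = 1.0) -> dict[str, str]:
    """Match predicted spacers to known spacers at an identity threshold.

    At identity 1.0 a prediction matches iff its string equals a known
    string or its reverse complement.  Below 1.0, predictions and known
    spacers are pooled and clustered greedily in descending length order
    (each sequence joins the first cluster whose representative reaches
    the identity threshold over the shorter sequence); a prediction
    matches if its cluster contains a known spacer.  Returns a mapping
    predicted_id -> known_id.
    """
    if not 0.0 < identity <= 1.0:
        raise ValueError("identity must be in (0, 1]")
    if identity == 1.0:
        lookup: dict[str, str] = {}
        for k in known:
            lookup.setdefault(k.seq, k.id)
            lookup.setdefault(reverse_complement(k.seq), k.id)
        return {p.id: lookup[p.seq] for p in predicted if p.seq in lookup}

    aligner = _make_global_aligner()
    pool = ([("known", k) for k in known]
            + [("pred", p) for p in predicted])
    pool.sort(key=lambda t: (-len(t[1].seq), t[1].id))
    clusters: list[tuple[SequenceRecord, list[tuple[str, SequenceRecord]]]] = []
    for kind, rec in pool:
        placed = False
        for rep, members in clusters:
            if _global_identity(rep.seq, rec.seq, aligner) >= identity:
                members.append((kind, rec))
                placed = True
                break
        if not placed:
            clusters.append((rec, [(kind, rec)]))
    matching: dict[str, str] = {}
    for _, members in clusters:
        knowns = [r for kind, r in members if kind == "known"]
        if not knowns:
            continue
        for kind, r in members:
            if kind == "pred":
                matching[r.id] = knowns[0].id
    return matching


def evaluate(predicted: Sequence[SequenceRecord],
             truth: Sequence[TruthSpacer] | Sequence[SequenceRecord],
             identity: float = 1.0) -> EvalResult:
    """Sensitivity and precision of predicted spacers against planted truth.

    tp = predictions matched to a truth spacer, fp = unmatched
    predictions, fn = truth spacers never matched; sensitivity =
    tp / (tp + fn), precision = tp / (tp + fp) (None when nothing was
    predicted).
    """
    known = [t if isinstance(t, SequenceRecord)
             else SequenceRecord(id=f"{t.genome_id}|array{t.array_index}"
                                    f"|truth{t.spacer_index}", seq=t.seq)
             for t in truth]
    matching = cluster_at_identity(predicted, known, identity)
    tp = len(matching)
    fp = len(predicted) - tp
    matched_known = set(matching.values())
    fn = sum(1 for k in known if k.id not in matched_known)
    sensitivity = tp / (tp + fn) if (tp + fn) else 0.0
    precision = tp / (tp + fp) if predicted else None
    return EvalResult(tp=tp, fp=fp, fn=fn,
                      sensitivity=sensitivity, precision=precision)


def write_truth_tsv(truth: Iterable[TruthSpacer], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("genome_id\tarray\tspacer\tstart\tend\tseq\n")
        for t in truth:
            fh.write(f"{t.genome_id}\t{t.array_index}\t{t.spacer_index}\t"
                     f"{t.start}\t{t.end}\t{t.seq}\n")


def read_truth_tsv(path: str | Path) -> list[TruthSpacer]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            g, a, s, st, en, seq = line.rstrip("\n").split("\t")
            out.append(TruthSpacer(g, int(a), int(s), int(st), int(en), seq))
    return out


# ---------------------------------------------------------------------------
# the packaged benchmark fixture

def packaged_repeat_db_path() -> Path:
    return Path(importlib.resources.files("casc.data")
                / "synthetic_repeat_db.fasta")


def packaged_cas_db_path() -> Path:
    return Path(importlib.resources.files("casc.data") / "synthetic_cas_db.faa")


def benchmark_fixture(seed: int, n_genomes: int = 10,
                      genome_len: int = 100_000,
                      n_arrays: int | None = None,
                      n_decoys: int | None = None, n_units: int = 6
                      ) -> tuple[list[SequenceRecord], list[TruthSpacer],
                                 list[str]]:
    """The standard scaled-down benchmark metagenome.

    ``n_arrays`` genomes carry one planted array each (6 repeat units = 5
    spacers by default), using the first ``n_arrays`` repeats of the
    packaged repeat database so that validation condition (ii) can fire;
    ``n_decoys`` of the remaining genomes carry a zero-gap tandem-repeat
    decoy locus.  Returns (genomes, truth, planted repeat sequences).
    """
    from .seqio import read_fasta
    repeat_records = read_fasta(packaged_repeat_db_path())
    if n_arrays is None:
        n_arrays = min(n_genomes // 2 + n_genomes % 2, len(repeat_records))
    if n_decoys is None:
        n_decoys = n_genomes - n_arrays
    if n_arrays > len(repeat_records):
        raise ValueError("not enough packaged repeats")
    if n_arrays > n_genomes:
        raise ValueError("more arrays than genomes")
    lo, hi = genome_len // 5, genome_len * 3 // 5
    rng = np.random.default_rng(seed)
    planted = [r.seq for r in repeat_records[:n_arrays]]
    specs = []
    for repeat in planted:
        slens = tuple(int(x) for x in rng.integers(30, 37, size=n_units - 1))
        offset = int(rng.integers(lo, hi))
        specs.append(PlantedArraySpec(repeat=repeat, spacer_lengths=slens,
                                      genome_offset=offset))
    decoys = []
    for k in range(n_decoys):
        gi = n_arrays + (k % max(n_genomes - n_arrays, 1))
        unit = _random_dna(rng, 26)
        decoys.append((gi, DecoySpec(unit=unit, n_copies=6,
                                     genome_offset=int(
                                         rng.integers(lo, hi)))))
    genomes, truth = make_genomes(
        n_with_arrays=n_arrays, n_without=n_genomes - n_arrays,
        genome_len=genome_len, specs=specs,
        seed=int(rng.integers(0, 2**31 - 1)), decoys=decoys)
    return genomes, truth, planted
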