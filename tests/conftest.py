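"""Shared fixtures and the independent local-alignment oracle.

The oracle is a full (unseeded, unwindowed) affine-gap Smith-Waterman
implemented with a per-row prefix-scan recurrence — a different algorithm
and code path from the package's seeded search, so score agreement between
the two is a meaningful cross-check.
"""

from __future__ import annotations

import numpy as np
import pytest

from casc import (SearchDatabase, SequenceRecord, read_fasta,
                  packaged_cas_db_path, packaged_repeat_db_path)

BASES = np.frombuffer(b"ACGT", dtype="S1")

NEG = -1_000_000_000


def random_dna(rng: np.random.Generator, n: int) -> str:
    return rng.choice(BASES, size=n).tobytes().decode()


def mutate_substitutions(rng: np.random.Generator, seq: str,
                         positions: list[int]) -> str:
    out = list(seq)
    for p in positions:
        out[p] = rng.choice([b for b in "ACGT" if b != out[p]])
    return "".join(out)


def sw_score(a: str, b: str, score_fn, gap_open: int, gap_extend: int) -> int:
    """Optimal local alignment score, gap of length g costing open + g*extend.

    Row-wise dynamic program: the horizontal-gap state is resolved with a
    running-maximum prefix scan over M[i][k] + k*extend, so each row is a
    handful of vectorized numpy operations.
    """
    m, n = len(a), len(b)
    sub = np.array([[score_fn(x, y) for y in b] for x in a], dtype=np.int64)
    M = np.zeros(n + 1, dtype=np.int64)
    Ix = np.full(n + 1, NEG, dtype=np.int64)
    Iy = np.full(n + 1, NEG, dtype=np.int64)
    best = 0
    ge, go = gap_extend, gap_open
    j_idx = np.arange(1, n + 1, dtype=np.int64)
    for i in range(1, m + 1):
        prev_best = np.maximum(np.maximum(M, Ix), Iy)  # row i-1
        M_new = np.zeros(n + 1, dtype=np.int64)
        M_new[1:] = np.maximum(0, prev_best[:-1] + sub[i - 1])
        Ix_new = np.full(n + 1, NEG, dtype=np.int64)
        Ix_new[1:] = np.maximum(M[1:] - go - ge, Ix[1:] - ge)
        # horizontal gaps within row i: Iy[j] = max_{k<j} M_new[k] - go - (j-k)*ge
        T = np.full(n + 1, NEG, dtype=np.int64)
        T[:] = M_new + np.arange(n + 1) * ge
        runmax = np.maximum.accumulate(T)
        Iy_new = np.full(n + 1, NEG, dtype=np.int64)
        Iy_new[1:] = runmax[:-1] - go - j_idx * ge
        M, Ix, Iy = M_new, Ix_new, Iy_new
        best = max(best, int(M.max()), int(Ix.max()), int(Iy.max()))
    return best


def sw_score_nt(a: str, b: str, match: int = 1, mismatch: int = -2,
                gap_open: int = 2, gap_extend: int = 1) -> int:
    return sw_score(a, b, lambda x, y: match if x == y else mismatch,
                    gap_open, gap_extend)


@pytest.fixture(scope="session")
def blosum62():
    from Bio.Align import substitution_matrices
    return substitution_matrices.load("BLOSUM62")


@pytest.fixture(scope="session")
def repeat_db() -> SearchDatabase:
    return SearchDatabase(read_fasta(packaged_repeat_db_path()))


@pytest.fixture(scope="session")
def cas_db() -> SearchDatabase:
    return SearchDatabase(
        read_fasta(packaged_cas_db_path(), alphabet="protein"),
        alphabet="protein")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def make_planted_genome(rng: np.random.Generator, repeat: str,
                        spacer_lengths: list[int], flank: int = 1000
                        ) -> tuple[str, int, list[str]]:
    """Random genome with one planted array; returns (seq, start, spacers)."""
    spacers = [random_dna(rng, n) for n in spacer_lengths]
    insert = repeat + "".join(s + repeat for s in spacers)
    left = random_dna(rng, flank)
    right = random_dna(rng, flank)
    return left + insert + right, flank, spacers
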