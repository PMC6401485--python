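"""Synthetic metagenome generation, read simulation, truth-based scoring."""

import numpy as np
import pytest

from casc import (DecoySpec, PlantedArraySpec, ReadSimParams, SequenceRecord,
                  cluster_at_identity, evaluate, extract_bona_fide_spacers,
                  find_arrays, make_genomes, reverse_complement,
                  simulate_reads, validate_array)
from conftest import random_dna


def spec(rng, n_spacers=3, offset=2000, rep_len=28):
    return PlantedArraySpec(repeat=random_dna(rng, rep_len),
                            spacer_lengths=tuple(
                                int(x) for x in
                                rng.integers(28, 40, size=n_spacers)),
                            genome_offset=offset)


class TestMakeGenomes:
    def test_truth_table_counts_and_coordinates(self, rng):
        s = spec(rng)
        genomes, truth = make_genomes(1, 0, 10_000, [s], seed=5)
        assert len(truth) == 3
        for t in truth:
            assert genomes[0].seq[t.start:t.end] == t.seq

    def test_array_free_genomes_have_empty_truth(self, rng):
        genomes, truth = make_genomes(0, 5, 5_000, [], seed=1)
        assert len(genomes) == 5 and truth == []

    def test_same_seed_is_byte_identical(self, rng):
        s = spec(rng)
        g1, t1 = make_genomes(1, 1, 8_000, [s], seed=9)
        g2, t2 = make_genomes(1, 1, 8_000, [s], seed=9)
        assert [g.seq for g in g1] == [g.seq for g in g2]
        assert t1 == t2

    def test_overlapping_loci_rejected(self, rng):
        s = spec(rng, offset=1000)
        d = (0, DecoySpec(unit=random_dna(rng, 26), n_copies=6,
                          genome_offset=1010))
        with pytest.raises(ValueError, match="overlap"):
            make_genomes(1, 0, 10_000, [s], seed=1, decoys=[d])

    def test_out_of_bounds_locus_rejected(self, rng):
        s = spec(rng, offset=9_900)
        with pytest.raises(ValueError, match="outside"):
            make_genomes(1, 0, 10_000, [s], seed=1)


class TestSimulateReads:
    def test_error_free_reads_are_genome_substrings(self, rng):
        genomes, _ = make_genomes(1, 1, 6_000, [spec(rng)], seed=3)
        reads = simulate_reads(genomes, ReadSimParams(
            read_length_mean=200, read_length_sd=20, n_reads=200, seed=4))
        by_id = {g.id: g.seq for g in genomes}
        for r in reads:
            _, gid, start, strand = r.id.split("|")
            seq = r.seq if strand == "+" else reverse_complement(r.seq)
            assert by_id[gid][int(start):int(start) + len(seq)] == seq

    def test_zero_sd_gives_constant_length(self, rng):
        genomes, _ = make_genomes(0, 1, 5_000, [], seed=2)
        reads = simulate_reads(genomes, ReadSimParams(
            read_length_mean=150, read_length_sd=0, n_reads=50, seed=1))
        assert {len(r.seq) for r in reads} == {150}

    def test_error_ramp_mean_rate(self):
        """With p0 = 0 and p1 = 0.02 the mean per-read error rate is the
        ramp average, 1% of read length, within 10%."""
        genomes, _ = make_genomes(0, 1, 50_000, [], seed=11)
        params = ReadSimParams(read_length_mean=450, read_length_sd=0,
                               n_reads=3000, p0=0.0, p1=0.02, seed=12)
        reads = simulate_reads(genomes, params)
        g = genomes[0].seq
        total_err = 0
        total_len = 0
        for r in reads:
            _, gid, start, strand = r.id.split("|")
            seq = r.seq if strand == "+" else reverse_complement(r.seq)
            ref = g[int(start):int(start) + len(seq)]
            total_err += sum(a != b for a, b in zip(seq, ref))
            total_len += len(seq)
        rate = total_err / total_len
        assert rate == pytest.approx(0.01, rel=0.10)

    def test_paired_mode_emits_proper_mates(self, rng):
        genomes, _ = make_genomes(0, 1, 5_000, [], seed=6)
        params = ReadSimParams(read_length_mean=150, read_length_sd=0,
                               n_reads=30, paired=True, insert=300, seed=7)
        reads = simulate_reads(genomes, params)
        assert len(reads) == 60
        g = genomes[0].seq
        for fwd, rev in zip(reads[::2], reads[1::2]):
            start = int(fwd.id.split("|")[2])
            assert g[start:start + 150] == fwd.seq
            assert g[start + 300 - 150:start + 300] == \
                   reverse_complement(rev.seq)


class TestClusterAndEvaluate:
    def _recs(self, seqs, prefix):
        return [SequenceRecord(f"{prefix}{i}", s) for i, s in enumerate(seqs)]

    def test_identical_strings_match_at_full_identity(self, rng):
        seqs = [random_dna(rng, 32) for _ in range(5)]
        m = cluster_at_identity(self._recs(seqs, "p"), self._recs(seqs, "k"),
                                1.0)
        assert len(m) == 5

    def test_revcomp_matches_at_full_identity(self, rng):
        seqs = [random_dna(rng, 32) for _ in range(4)]
        preds = self._recs([reverse_complement(s) for s in seqs], "p")
        assert len(cluster_at_identity(preds, self._recs(seqs, "k"), 1.0)) == 4

    def test_single_mismatch_needs_sub_unit_threshold(self, rng):
        known = random_dna(rng, 32)
        mutated = ("A" if known[10] != "A" else "C").join(
            [known[:10], known[11:]])
        pred = [SequenceRecord("p0", mutated)]
        k = [SequenceRecord("k0", known)]
        assert cluster_at_identity(pred, k, 1.0) == {}
        assert cluster_at_identity(pred, k, 0.96) == {"p0": "k0"}

    def test_evaluate_perfect_predictions(self, rng):
        seqs = [random_dna(rng, 33) for _ in range(6)]
        res = evaluate(self._recs(seqs, "p"), self._recs(seqs, "k"))
        assert (res.sensitivity, res.precision) == (1.0, 1.0)

    def test_evaluate_half_recovered(self, rng):
        seqs = [random_dna(rng, 33) for _ in range(8)]
        res = evaluate(self._recs(seqs[:4], "p"), self._recs(seqs, "k"))
        assert res.sensitivity == pytest.approx(0.5)
        assert res.precision == 1.0

    def test_evaluate_with_decoy_predictions(self, rng):
        seqs = [random_dna(rng, 33) for _ in range(8)]
        preds = self._recs(seqs + [random_dna(rng, 33),
                                   random_dna(rng, 33)], "p")
        res = evaluate(preds, self._recs(seqs, "k"))
        assert res.sensitivity == 1.0
        assert res.precision == pytest.approx(0.8)

    def test_empty_predictions(self, rng):
        res = evaluate([], self._recs([random_dna(rng, 30)], "k"))
        assert res.precision is None and res.sensitivity == 0.0


class TestErrorDegradation:
    def test_read_errors_degrade_detection_monotonically(self, repeat_db,
                                                         cas_db):
        """Raising the substitution ramp lowers precision and sensitivity
        of read-level spacer discovery under the 100%-identity rule."""
        rng = np.random.default_rng(31)
        specs = [PlantedArraySpec(
            repeat=repeat_db.records[i].seq,
            spacer_lengths=tuple(int(x)
                                 for x in rng.integers(30, 37, size=5)),
            genome_offset=int(rng.integers(3_000, 12_000)))
            for i in range(2)]
        genomes, truth = make_genomes(2, 0, 20_000, specs, seed=32)
        results = []
        for level, p1 in enumerate((0.0, 0.02, 0.05)):
            reads = simulate_reads(genomes, ReadSimParams(
                n_reads=1200, p0=0.0, p1=p1, seed=33))
            evidence = []
            for read in reads:
                for arr in find_arrays(read):
                    evidence.append(validate_array(arr, read, cas_db,
                                                   repeat_db))
            preds = extract_bona_fide_spacers(evidence, mode="liberal")
            results.append(evaluate(preds, truth, identity=1.0))
        precisions = [r.precision for r in results]
        sensitivities = [r.sensitivity for r in results]
        # Read-level precision sits below 1 even without errors (short reads
        # expose few repeat instances, so array boundaries are less pinned);
        # the property under test is monotone degradation with error rate.
        tol = 0.02
        assert precisions[0] >= precisions[1] - tol >= precisions[2] - 2 * tol
        assert sensitivities[0] >= sensitivities[1] - tol \
               >= sensitivities[2] - 2 * tol
        assert precisions[2] < precisions[0]
        assert sensitivities[2] < sensitivities[0]


class TestEndToEndContigs:
    def test_error_free_contigs_perfect_recovery(self, repeat_db, cas_db):
        """Detection plus liberal validation recovers exactly the planted
        spacers on a small error-free contig metagenome with decoys."""
        rng = np.random.default_rng(77)
        specs = [PlantedArraySpec(
            repeat=repeat_db.records[i].seq,
            spacer_lengths=tuple(int(x)
                                 for x in rng.integers(30, 37, size=4)),
            genome_offset=9_000) for i in range(2)]
        decoys = [(2, DecoySpec(unit=random_dna(rng, 26), n_copies=6,
                                genome_offset=8_000)),
                  (3, DecoySpec(unit=random_dna(rng, 24), n_copies=7,
                                genome_offset=14_000))]
        genomes, truth = make_genomes(2, 2, 30_000, specs, seed=78,
                                      decoys=decoys)
        evidence = []
        for g in genomes:
            for arr in find_arrays(g):
                evidence.append(validate_array(arr, g, cas_db, repeat_db))
        preds = extract_bona_fide_spacers(evidence, mode="liberal")
        res = evaluate(preds, truth, identity=1.0)
        assert res.precision == 1.0
        assert res.sensitivity == 1.0
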