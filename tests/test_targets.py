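"""ORF calling, spacer-target assignment, network degrees, distances."""

import math

import numpy as np
import pytest

from casc import (SearchDatabase, SequenceRecord, Site, assign_matches,
                  call_orfs, degree_distributions, great_circle_km,
                  match_spacers, remove_array_bearing_sequences,
                  reverse_complement)
from casc.targets import EARTH_RADIUS_KM
from conftest import make_planted_genome, random_dna


def _coding(n_codons, rng):
    """Random codons avoiding stops and internal ATG (clean single ORF)."""
    safe = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
            if a + b + c not in ("TAA", "TAG", "TGA", "ATG")]
    return "".join(rng.choice(safe) for _ in range(n_codons))


class TestGreatCircle:
    def test_zero_for_identical_points(self):
        s = Site("a", 12.5, -30.0)
        assert great_circle_km(s, s) == 0.0

    def test_antipodal_half_circumference(self):
        d = great_circle_km(Site("a", 0, 0), Site("b", 0, 180))
        assert d == pytest.approx(math.pi * EARTH_RADIUS_KM, abs=0.1)
        assert d == pytest.approx(20015.1, abs=0.1)

    def test_pole_quarter_circumference(self):
        d = great_circle_km(Site("a", 0, 0), Site("b", 90, 0))
        assert d == pytest.approx(10007.5, abs=0.1)

    def test_symmetric_bounded_nonnegative(self, rng):
        for _ in range(50):
            a = Site("a", float(rng.uniform(-90, 90)),
                     float(rng.uniform(-180, 180)))
            b = Site("b", float(rng.uniform(-90, 90)),
                     float(rng.uniform(-180, 180)))
            d = great_circle_km(a, b)
            assert d == pytest.approx(great_circle_km(b, a))
            assert 0 <= d <= math.pi * EARTH_RADIUS_KM + 1e-6

    def test_out_of_range_coordinates_rejected(self):
        with pytest.raises(ValueError):
            Site("a", 91.0, 0.0)
        with pytest.raises(ValueError):
            Site("a", 0.0, 181.0)


class TestCallOrfs:
    def test_single_planted_orf(self, rng):
        body = _coding(31, rng)
        contig = "C" * 90 + "ATG" + body + "TAA" + random_dna(rng, 90)
        orfs = [o for o in call_orfs(SequenceRecord("c", contig))
                if o.strand == "+"]
        assert any(len(o.protein) == 32 and o.start == 90
                   and o.end == 90 + 99 for o in orfs)

    def test_poly_n_contig_has_no_orfs(self):
        assert call_orfs(SequenceRecord("c", "N" * 300)) == []

    def test_minus_strand_orf_in_forward_coordinates(self, rng):
        body = _coding(35, rng)
        fwd_gene = "ATG" + body + "TAG"
        contig = random_dna(rng, 60) + reverse_complement(fwd_gene) \
            + random_dna(rng, 60)
        orfs = [o for o in call_orfs(SequenceRecord("c", contig))
                if o.strand == "-"]
        assert any(o.start == 60 and o.end == 60 + len(fwd_gene)
                   and len(o.protein) == 36 for o in orfs)
        for o in orfs:
            assert (o.end - o.start) % 3 == 0

    def test_min_aa_threshold(self, rng):
        contig = "CCC" * 10 + "ATG" + _coding(10, rng) + "TAA" + "CCC" * 10
        assert call_orfs(SequenceRecord("c", contig), min_aa=30) == []
        short = call_orfs(SequenceRecord("c", contig), min_aa=5)
        assert any(len(o.protein) == 11 for o in short)


def _hsp(spacer, contig, s_start, s_end):
    from casc.homology import Hsp
    return Hsp(query_id=spacer, subject_id=contig, q_start=0,
               q_end=s_end - s_start, s_start=s_start, s_end=s_end,
               strand_or_frame="+", raw_score=s_end - s_start,
               bit_score=30.0, evalue=1e-5,
               identities=s_end - s_start, mismatches=0, gap_openings=0)


class TestAssignMatches:
    def _orfs(self, rng):
        g = ("AAA" * 30 + "ATG" + _coding(40, rng) + "TAA"
             + "ATG" + _coding(40, rng) + "TAG" + "AAA" * 30)
        contig = SequenceRecord("c1", g)
        orfs = [o for o in call_orfs(contig) if o.strand == "+"
                and o.start >= 90]
        assert len(orfs) >= 2
        return contig, sorted(orfs, key=lambda o: o.start)[:2]

    def test_inside_one_orf(self, rng):
        contig, orfs = self._orfs(rng)
        h = _hsp("sp1", "c1", orfs[0].start + 6, orfs[0].start + 38)
        (m,) = assign_matches([h], {"c1": orfs})
        assert m.orf_ids == [orfs[0].orf_id] and not m.spans_two_orfs

    def test_spanning_two_adjacent_orfs(self, rng):
        contig, orfs = self._orfs(rng)
        h = _hsp("sp1", "c1", orfs[0].end - 16, orfs[1].start + 16)
        (m,) = assign_matches([h], {"c1": orfs})
        assert len(m.orf_ids) == 2 and m.spans_two_orfs

    def test_intergenic_match(self, rng):
        contig, orfs = self._orfs(rng)
        h = _hsp("sp1", "c1", 5, 37)  # in the AAA-homopolymer flank
        (m,) = assign_matches([h], {"c1": orfs})
        assert m.orf_ids == [] and not m.spans_two_orfs

    def test_contig_without_orfs_is_intergenic(self):
        (m,) = assign_matches([_hsp("s", "cX", 0, 30)], {})
        assert m.orf_ids == []


class TestDegrees:
    def test_one_spacer_three_orfs(self):
        hsps = [_hsp("sp1", f"c{i}", 10, 40) for i in range(3)]
        orfs = {f"c{i}": [type("O", (), {"orf_id": f"c{i}|orf1",
                                         "start": 0, "end": 60})()]
                for i in range(3)}
        matches = assign_matches(hsps, orfs)
        sp_hist, orf_hist = degree_distributions(matches)
        assert sp_hist == {3: 1}
        assert orf_hist == {1: 3}

    def test_empty(self):
        sp, orf = degree_distributions([])
        assert sp == {} and orf == {}

    def test_handshake_identity(self, rng):
        matches = []
        for i in range(40):
            sp = f"sp{rng.integers(0, 15)}"
            c = f"c{rng.integers(0, 10)}"
            orfs = {c: [type("O", (), {"orf_id": f"{c}|orf{k}",
                                       "start": 100 * k,
                                       "end": 100 * k + 90})()
                        for k in range(3)]}
            matches.extend(assign_matches(
                [_hsp(sp, c, int(rng.integers(0, 250)),
                      int(rng.integers(0, 250)) + 30)], orfs))
        sp_hist, orf_hist = degree_distributions(matches)
        edges_from_spacers = sum(d * c for d, c in sp_hist.items())
        edges_from_orfs = sum(d * c for d, c in orf_hist.items())
        assert edges_from_spacers == edges_from_orfs


class TestMatchSpacers:
    def test_exact_spacer_in_contig(self, rng):
        contig = random_dna(rng, 600)
        db = SearchDatabase([SequenceRecord("v1", contig)])
        sp = SequenceRecord("sp1", contig[200:234])
        (h,) = match_spacers([sp], db)
        assert h.mismatches == 0 and h.subject_id == "v1"

    def test_no_shared_7mer_no_match(self):
        db = SearchDatabase([SequenceRecord("v1", "A" * 400)])
        assert match_spacers([SequenceRecord("sp", "C" * 32)], db) == []

    def test_best_hit_per_contig(self, rng):
        seg = random_dna(rng, 34)
        contig = random_dna(rng, 200) + seg + random_dna(rng, 200) + seg \
            + random_dna(rng, 100)
        db = SearchDatabase([SequenceRecord("v1", contig)])
        hits = match_spacers([SequenceRecord("sp", seg)], db)
        assert len(hits) == 1  # two placements, one reported


class TestRemoveArrayBearing:
    def test_planted_array_sequence_dropped(self, rng, repeat_db, cas_db):
        repeat = repeat_db.records[0].seq
        genome, _, _ = make_planted_genome(rng, repeat, [30, 32, 31],
                                           flank=400)
        virome = [SequenceRecord(f"v{i}", random_dna(rng, 1200))
                  for i in range(9)]
        virome.append(SequenceRecord("v9", genome))
        kept, dropped = remove_array_bearing_sequences(virome, cas_db,
                                                       repeat_db)
        assert dropped == ["v9"] and len(kept) == 9

    def test_idempotent(self, rng, repeat_db, cas_db):
        virome = [SequenceRecord(f"v{i}", random_dna(rng, 1000))
                  for i in range(5)]
        once, _ = remove_array_bearing_sequences(virome, cas_db, repeat_db)
        twice, dropped2 = remove_array_bearing_sequences(once, cas_db,
                                                         repeat_db)
        assert [r.id for r in twice] == [r.id for r in once]
        assert dropped2 == []

    def test_all_records_carrying_arrays_yields_empty(self, rng, repeat_db,
                                                      cas_db):
        repeat = repeat_db.records[1].seq
        virome = []
        for i in range(3):
            genome, _, _ = make_planted_genome(rng, repeat, [30, 31, 33],
                                               flank=300)
            virome.append(SequenceRecord(f"v{i}", genome))
        kept, dropped = remove_array_bearing_sequences(virome, cas_db,
                                                       repeat_db)
        assert kept == [] and len(dropped) == 3
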