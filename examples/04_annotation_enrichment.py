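"""Cumulative-bit-score annotation and actual/expected fold changes.

Reproduces the canonical worked example (eight weak phage-protein hits vs
two strong terminase hits) and builds a small enrichment table from a
synthetic background.
"""

from casc import Background, annotate_orf
from casc.enrichment import NO_HITS, AnnotationAssignment, enrichment_table
from casc.homology import Hsp


def hit(function, bits):
    h = Hsp(query_id="ORF_1", subject_id="db", q_start=0, q_end=30,
            s_start=0, s_end=30, strand_or_frame=0, raw_score=int(bits),
            bit_score=bits, evalue=1e-6, identities=30, mismatches=0,
            gap_openings=0)
    return (h, function)


hits = [hit("phage protein", 50 / 8)] * 8 + [hit("terminase", 100 / 2)] * 2
a = annotate_orf("ORF_1", hits)
print(f"ORF_1 -> {a.annotation} (cumulative bit score "
      f"{a.cumulative_bit_score:.0f} from {a.n_hits} hits)")
# 100 terminase bits beat 50 phage-protein bits even though phage protein
# had four times as many hits.


def assignment(orf_id, label):
    return AnnotationAssignment(
        orf_id=orf_id, annotation=label,
        cumulative_bit_score=0.0 if label == NO_HITS else 42.0,
        n_hits=0 if label == NO_HITS else 1)


matched = ([assignment(f"t{i}", "Phage terminase") for i in range(6)]
           + [assignment(f"p{i}", "Phage protein") for i in range(10)]
           + [assignment(f"n{i}", NO_HITS) for i in range(4)])
bg = Background(frequencies={"Phage terminase": 0.05, "Phage protein": 0.55,
                             NO_HITS: 0.40}, total_orfs=2000)
print(f"{'annotation':24s} {'actual':>6s} {'expected':>8s} {'fold':>5s}")
for row in enrichment_table(matched, bg):
    print(f"{row.annotation:24s} {row.actual:6d} {row.expected:8.1f} "
          f"{row.fold_change_printed:>5s}")
# Fold > 1 means the function is targeted more often than its abundance
# in the whole database predicts.
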