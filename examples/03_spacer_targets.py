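"""Match spacers to a small virome, assign ORFs, and measure distances.

Plants two spacer protospacers inside a virome contig's genes, runs the
permissive nucleotide search (word size 7, E <= 0.1), calls ORFs on the
matched contig only, assigns matches to overlapping ORFs, and computes
the great-circle distance between the sampling sites of spacer and target.
"""

import numpy as np

from casc import (SearchDatabase, SequenceRecord, Site, assign_matches,
                  call_orfs, degree_distributions, great_circle_km,
                  match_spacers, remove_array_bearing_sequences)

rng = np.random.default_rng(4)
bases = np.frombuffer(b"ACGT", dtype="S1")
dna = lambda n: rng.choice(bases, size=n).tobytes().decode()

# a virome contig with one clean forward gene (no internal stops/ATG)
safe = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
        if a + b + c not in ("TAA", "TAG", "TGA", "ATG")]
gene = "ATG" + "".join(rng.choice(safe) for _ in range(60)) + "TAA"
contig = SequenceRecord("virome_c1", "C" * 150 + gene + dna(200))
virome = [contig, SequenceRecord("virome_c2", dna(600))]

virome, dropped = remove_array_bearing_sequences(virome)
print(f"virome sequences kept: {len(virome)}, dropped (carry arrays): "
      f"{len(dropped)}")

spacer_inside = SequenceRecord("sampleA|array1|spacer1",
                               contig.seq[160:194])
spacer_elsewhere = SequenceRecord("sampleA|array1|spacer2", dna(34))
db = SearchDatabase(virome)
hsps = match_spacers([spacer_inside, spacer_elsewhere], db)
print(f"spacer matches: {len(hsps)} "
      f"(mismatches={hsps[0].mismatches}, E={hsps[0].evalue:.2g})")

orfs = {c.id: call_orfs(c) for c in virome
        if c.id in {h.subject_id for h in hsps}}
matches = assign_matches(hsps, orfs)
for m in matches:
    print(f"{m.spacer_id} -> {m.contig_id} orfs={m.orf_ids} "
          f"spans_two={m.spans_two_orfs}")

spacer_deg, orf_deg = degree_distributions(matches)
print(f"spacer-degree histogram: {dict(spacer_deg)}, "
      f"orf-degree histogram: {dict(orf_deg)}")

d = great_circle_km(Site("sampleA", -12.0, 96.9),
                    Site("virome_site", 36.5, -122.0))
print(f"spacer-to-virome sampling distance: {d:.0f} km")
# Matches far from the spacer's own sample are the rule, not the
# exception, in ocean surveys.
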