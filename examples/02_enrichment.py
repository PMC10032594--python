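"""Enrichment of STR-encoded residues in disordered regions.

Generates annotation tracks with a planted residue-level log odds ratio of
2.0 for the disorder track, builds the 2x2 contingency table over all
residues, and runs the two-sided exact test.  The estimated log OR should
land close to the planted value.
"""

import math

from strhab.enrich import build_contingency, fisher_exact
from strhab.synth import generate_annotation_tracks, generate_cds_with_tracts

seqs, truth = generate_cds_with_tracts(300, [("Q", 8), ("N", 6)] * 150, seed=5)
proteins = {}
for r in truth.itertuples():
    length = len(seqs[r.protein_id]) // 3 - 1
    _, res = proteins.get(r.protein_id, (length, set()))
    proteins[r.protein_id] = (length, res | set(range(r.protein_start, r.protein_end + 1)))

tracks, planted = generate_annotation_tracks(proteins, {"idr": 2.0}, seed=6)

universe, tract_res, region = set(), set(), set()
for pid, (length, res) in proteins.items():
    universe |= {(pid, i) for i in range(1, length + 1)}
    tract_res |= {(pid, i) for i in res}
    region |= {(pid, i) for i in tracks.idr[pid]}

tab = build_contingency(tract_res, region, universe)
oddsr, p = fisher_exact(tab, sided="two")
print(f"contingency (a,b,c,d) = ({tab.a}, {tab.b}, {tab.c}, {tab.d})")
print(f"planted log OR = {planted['idr']:.1f}; estimated log OR = {math.log(oddsr):.2f}; "
      f"two-sided exact p = {p:.2e}")
print("-> STR-encoded residues are overrepresented inside the disorder track, "
      "recovering the planted enrichment.")
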