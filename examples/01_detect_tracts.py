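"""Detect homopolymer tracts in coding sequences.

Builds a tiny coding sequence with an embedded poly-glutamine repeat plus a
synthetic mini-proteome with known tract coordinates, runs the detector, and
checks it against the generator's truth table.
"""

from strhab.synth import generate_cds_with_tracts
from strhab.tracts import detect_coding_strs

# a hand-made CDS: start codon, seven CAA codons (poly-Q), stop
cds = {"demo_transcript": "ATG" + "CAA" * 7 + "TGA"}
(tract,) = detect_coding_strs(cds, min_units=4)
print(f"{tract.transcript_id}: poly-{tract.amino_acid} x{tract.unit_count}, "
      f"residues {tract.protein_interval[0]}-{tract.protein_interval[1]}, "
      f"CDS {tract.cds_interval[0]}-{tract.cds_interval[1]} ({tract.repeat_unit})")

# a 50-protein synthetic proteome with mixed embedded tracts
spec = [("Q", 7), ("N", 4), ("E", 10), ("S", 5), ("Q", 3)] * 10
seqs, truth = generate_cds_with_tracts(50, spec, seed=1)
detected = detect_coding_strs(seqs, min_units=4)
print(f"\n{len(detected)} tracts detected in {len(seqs)} proteins "
      f"(truth table lists {int(truth['detectable'].sum())} at >=4 units; "
      f"the {int((~truth['detectable']).sum())} shorter tracts fall below the detection floor)")
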