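"""Detection of in-frame trinucleotide repeats and mapping to homopolymer tracts.

Only codon-aligned repeats produce homopolymers, so detection walks the CDS
codon by codon.  Coordinates follow two conventions, converted centrally:
nucleotide intervals are 0-based half-open (BED style), residue intervals are
1-based inclusive (protein style).
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from Bio.Data import CodonTable

logger = logging.getLogger(__name__)

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
_NUCS = frozenset("ACGT")


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a codon; '*' for stop."""
    if codon in _STANDARD.stop_codons:
        return "*"
    return _STANDARD.forward_table[codon]


@dataclass
class HomopolymerTract:
    """A run of >=1 identical residues encoded by an in-frame trinucleotide repeat.

    ``cds_interval`` is 0-based half-open on the coding sequence;
    ``protein_interval`` is 1-based inclusive on the translated protein.
    ``genomic_interval`` is populated by :func:`map_tract_coordinates`.
    """

    locus_id: str
    transcript_id: str
    amino_acid: str
    unit_count: int
    cds_interval: tuple[int, int]
    protein_interval: tuple[int, int]
    repeat_unit: str
    genomic_interval: tuple[int, int] | None = None
    chrom: str | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        s, e = self.cds_interval
        if e - s != 3 * self.unit_count:
            raise ValueError("cds_interval length must be 3 x unit_count")
        ps, pe = self.protein_interval
        if pe - ps + 1 != self.unit_count:
            raise ValueError("protein span must equal unit_count")
        if s % 3 != 0:
            raise ValueError("tract must start on a codon boundary")
        if translate_codon(self.repeat_unit) != self.amino_acid:
            raise ValueError("repeat_unit must translate to amino_acid")

    @property
    def residues(self) -> set[int]:
        """1-based residue indices covered by the tract."""
        ps, pe = self.protein_interval
        return set(range(ps, pe + 1))


@dataclass
class AnnotationTrackSet:
    """Per-protein binary residue tracks (1-based residue indices).

    ``ppi_tools`` holds one track per protein-binding predictor (three in the
    standard setup); ``idr``/``dpi``/``rpi`` are single consensus tracks.
    """

    idr: dict[str, set[int]] = field(default_factory=dict)
    ppi_tools: list[dict[str, set[int]]] = field(default_factory=lambda: [{}, {}, {}])
    dpi: dict[str, set[int]] = field(default_factory=dict)
    rpi: dict[str, set[int]] = field(default_factory=dict)
    protein_lengths: dict[str, int] = field(default_factory=dict)

    def named_tracks(self) -> dict[str, dict[str, set[int]]]:
        out = {"idr": self.idr, "dpi": self.dpi, "rpi": self.rpi}
        for i, t in enumerate(self.ppi_tools, start=1):
            out[f"ppi_{i}"] = t
        return out


@dataclass
class TractFeatureVector:
    """Per-tract structural features used downstream in the meta-regression."""

    locus_id: str
    amino_acid: str
    in_disorder: int
    protein_binding: int  # ordinal 0-3: number of PPI tools overlapping
    dna_binding: int
    rna_binding: int
    overlap_counts: dict[str, int] = field(default_factory=dict)


def _codons(seq: str) -> list[str]:
    return [seq[i : i + 3] for i in range(0, len(seq) - len(seq) % 3, 3)]


def detect_coding_strs(
    cds: Mapping[str, str] | Iterable[tuple[str, str]],
    min_units: int = 4,
    merge_synonymous: bool = True,
) -> list[HomopolymerTract]:
    """Detect maximal in-frame trinucleotide repeats encoding homopolymer tracts.

    Parameters
    ----------
    cds
        Mapping (or iterable of pairs) transcript id -> coding sequence.
    min_units
        Minimum number of repeated amino acids for a tract to be reported
        (default 4, the conventional detection floor for coding STRs).
    merge_synonymous
        If True (default), adjacent perfect runs of synonymous codons encoding
        the same amino acid are merged into one tract, i.e. a tract is a
        maximal run of codons translating to the same residue.  If False only
        runs of literally identical codons are reported.

    Trailing partial codons are ignored with a warning.  Records containing
    non-nucleotide characters are skipped with a log entry.
    """
    items = cds.items() if isinstance(cds, Mapping) else cds
    tracts: list[HomopolymerTract] = []
    for tid, seq in items:
        seq = str(seq).upper()
        if len(seq) % 3:
            logger.warning("%s: length %d not divisible by 3; trailing partial codon ignored", tid, len(seq))
        if not _NUCS.issuperset(seq):
            logger.error("%s: non-nucleotide characters; record skipped", tid)
            continue
        codons = _codons(seq)
        aas = [translate_codon(c) for c in codons]
        i = 0
        n = len(codons)
        while i < n:
            if aas[i] == "*":
                i += 1
                continue
            j = i + 1
            if merge_synonymous:
                while j < n and aas[j] == aas[i]:
                    j += 1
            else:
                while j < n and codons[j] == codons[i]:
                    j += 1
            units = j - i
            if units >= min_units:
                unit = Counter(codons[i:j]).most_common(1)[0][0]
                tracts.append(
                    HomopolymerTract(
                        locus_id=f"{tid}:{3 * i}:{aas[i]}",
                        transcript_id=tid,
                        amino_acid=aas[i],
                        unit_count=units,
                        cds_interval=(3 * i, 3 * j),
                        protein_interval=(i + 1, j),
                        repeat_unit=unit,
                    )
                )
            # with merge_synonymous the run [i, j) is maximal in amino-acid
            # space; without it, identical-codon runs of the same amino acid
            # may abut, so restart at j either way (runs are maximal per mode)
            i = j
    return tracts


# ---------------------------------------------------------------------------
# gene models and coordinate mapping


@dataclass
class GeneModel:
    """CDS exon structure of one transcript.

    ``exons`` are genomic 0-based half-open intervals in *transcription*
    order (for minus-strand transcripts the first exon has the highest
    genomic coordinates).
    """

    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError("strand must be '+' or '-'")
        for s, e in self.exons:
            if e <= s:
                raise ValueError("empty exon interval")

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def cds_to_genomic(self, pos: int) -> int:
        """Genomic position (0-based) of CDS position ``pos`` (0-based)."""
        if not 0 <= pos < self.cds_length:
            raise IndexError(f"CDS position {pos} outside [0, {self.cds_length})")
        off = pos
        for s, e in self.exons:
            ln = e - s
            if off < ln:
                return s + off if self.strand == "+" else e - 1 - off
            off -= ln
        raise AssertionError("unreachable")

    def genomic_to_cds(self, gpos: int) -> int:
        """Inverse of :meth:`cds_to_genomic`."""
        off = 0
        for s, e in self.exons:
            if s <= gpos < e:
                return off + (gpos - s if self.strand == "+" else e - 1 - gpos)
            off += e - s
        raise IndexError(f"genomic position {gpos} not in CDS of {self.transcript_id}")


def map_tract_coordinates(tract: HomopolymerTract, genes: Mapping[str, GeneModel]) -> HomopolymerTract:
    """Project a tract's CDS interval to genomic coordinates.

    Returns a copy with ``genomic_interval`` (the spanning 0-based half-open
    interval, covering introns for spliced tracts), ``chrom`` and ``strand``
    populated.  The projection is exact per base; the round trip
    genome -> CDS -> genome is the identity for every covered base.
    """
    if tract.transcript_id not in genes:
        raise KeyError(f"transcript {tract.transcript_id!r} absent from gene model")
    gm = genes[tract.transcript_id]
    s, e = tract.cds_interval
    if e > gm.cds_length:
        raise ValueError(f"{tract.locus_id}: CDS interval exceeds model CDS length (frame inconsistency)")
    gpos = [gm.cds_to_genomic(p) for p in range(s, e)]
    return replace(
        tract,
        genomic_interval=(min(gpos), max(gpos) + 1),
        chrom=gm.chrom,
        strand=gm.strand,
    )


# ---------------------------------------------------------------------------
# annotation tracks


def consensus_disorder(per_tool_tracks: Sequence[set[int]], agreement: float = 0.75) -> set[int]:
    """Consensus residue set: residue kept iff >= ceil(agreement * n_tools) tools flag it.

    Mirrors the d2p2-style rule that 75% of predictors should agree to
    designate disorder.
    """
    if not per_tool_tracks:
        raise ValueError("need at least one track")
    need = math.ceil(agreement * len(per_tool_tracks))
    counts: Counter[int] = Counter()
    for t in per_tool_tracks:
        counts.update(t)
    return {r for r, c in counts.items() if c >= need}


def intersect_tracts(
    tracts: Sequence[HomopolymerTract],
    tracks: AnnotationTrackSet,
    min_overlap: int = 1,
) -> list[TractFeatureVector]:
    """Per-tract feature vectors from residue-level intersection with tracks.

    A tract counts as overlapping a track when they share at least
    ``min_overlap`` residues; ``protein_binding`` is the number of PPI tool
    tracks overlapping (ordinal 0-3).  Residue-level intersection counts are
    retained in ``overlap_counts`` for enrichment contingency tables.
    Proteins missing from the track set yield all-zero features with a
    logged warning.
    """
    out: list[TractFeatureVector] = []
    known = set(tracks.idr) | set(tracks.dpi) | set(tracks.rpi) | set(tracks.protein_lengths)
    for t in tracks.ppi_tools:
        known |= set(t)
    for tr in tracts:
        pid = tr.transcript_id
        res = tr.residues
        if pid not in known:
            logger.warning("%s: protein %s missing from track set; features default to 0", tr.locus_id, pid)
        counts = {
            name: len(res & track.get(pid, set()))
            for name, track in tracks.named_tracks().items()
        }
        pb = sum(counts[f"ppi_{i}"] >= min_overlap for i in range(1, len(tracks.ppi_tools) + 1))
        out.append(
            TractFeatureVector(
                locus_id=tr.locus_id,
                amino_acid=tr.amino_acid,
                in_disorder=int(counts["idr"] >= min_overlap),
                protein_binding=pb,
                dna_binding=int(counts["dpi"] >= min_overlap),
                rna_binding=int(counts["rpi"] >= min_overlap),
                overlap_counts=counts,
            )
        )
    return out
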