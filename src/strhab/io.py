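"""Readers and writers for the standard formats the pipeline consumes.

FASTA goes through Biopython; BED files are 0-based half-open with the
protein id in the chrom column for residue-space tracks (residue r occupies
[r-1, r)); GFF3 parsing extracts CDS exon structure per transcript.
"""

from __future__ import annotations

import logging
from pathlib import Path
from urllib.parse import unquote

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from strhab.tracts import AnnotationTrackSet, GeneModel, HomopolymerTract

logger = logging.getLogger(__name__)


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# BED (residue space): chrom = protein id, interval [r-1, r) per residue r


def write_track_bed(track: dict[str, set[int]], path, name: str = ".") -> None:
    rows = []
    for pid in sorted(track):
        residues = sorted(track[pid])
        if not residues:
            continue
        start = prev = residues[0]
        for r in residues[1:] + [None]:
            if r is None or r != prev + 1:
                rows.append((pid, start - 1, prev, name))
                if r is not None:
                    start = r
            prev = r if r is not None else prev
    pd.DataFrame(rows, columns=["chrom", "start", "end", "name"]).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_track_bed(path) -> dict[str, set[int]]:
    track: dict[str, set[int]] = {}
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    for chrom, start, end in zip(df[0], df[1], df[2]):
        track.setdefault(str(chrom), set()).update(range(int(start) + 1, int(end) + 1))
    return track


def read_track_dir(path) -> AnnotationTrackSet:
    """Load idr/dpi/rpi/ppi_1..3 BED files from a directory (missing -> empty)."""
    path = Path(path)
    tracks = AnnotationTrackSet()
    for name in ("idr", "dpi", "rpi"):
        f = path / f"{name}.bed"
        if f.exists():
            setattr(tracks, name, read_track_bed(f))
    for i in (1, 2, 3):
        f = path / f"ppi_{i}.bed"
        if f.exists():
            tracks.ppi_tools[i - 1] = read_track_bed(f)
    return tracks


def write_track_set(tracks: AnnotationTrackSet, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, track in tracks.named_tracks().items():
        write_track_bed(track, outdir / f"{name}.bed", name=name)


def write_tracts_bed(tracts: list[HomopolymerTract], path) -> None:
    """Tract BED in protein residue space; name = locus_id|aa|units."""
    rows = [
        (
            t.transcript_id,
            t.protein_interval[0] - 1,
            t.protein_interval[1],
            f"{t.locus_id}|{t.amino_acid}|{t.unit_count}",
        )
        for t in tracts
    ]
    pd.DataFrame(rows, columns=["chrom", "start", "end", "name"]).to_csv(
        path, sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------------------
# GFF3 gene models


def read_gff3_gene_models(path) -> dict[str, GeneModel]:
    """CDS exon structure per transcript from a GFF3 file.

    Transcript ids come from the CDS ``Parent`` attribute (falling back to
    ``ID``).  Exons are returned in transcription order.
    """
    by_tid: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 8 or f[2] != "CDS":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            ) if len(f) > 8 else {}
            tid = unquote(attrs.get("Parent", attrs.get("ID", "")))
            if not tid:
                logger.warning("CDS feature without Parent/ID skipped")
                continue
            rec = by_tid.setdefault(tid, {"chrom": f[0], "strand": f[6], "exons": []})
            rec["exons"].append((int(f[3]) - 1, int(f[4])))  # GFF is 1-based inclusive
    models = {}
    for tid, rec in by_tid.items():
        exons = sorted(rec["exons"], reverse=rec["strand"] == "-")
        models[tid] = GeneModel(transcript_id=tid, chrom=rec["chrom"], strand=rec["strand"], exons=exons)
    return models
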