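"""Readers and writers for the plain-text formats the pipeline touches.

GTF is 1-based inclusive on disk and converted to the internal 0-based
half-open convention on read (internal start = GTF start - 1); the writer
inverts the shift so a GTF -> internal -> GTF round trip is exact.
bedGraph and BED are 0-based half-open already and pass through unshifted.
"""

from __future__ import annotations

import re
from typing import Dict, Iterable, List, Sequence, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import AnnotationSet, ConservationTrack, GenomicInterval, TranscriptModel

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


class GtfError(ValueError):
    """Malformed GTF content, carrying the offending line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


def parse_gtf_attributes(field: str) -> Dict[str, str]:
    return dict(_ATTR_RE.findall(field))


def read_gtf(path, source_label: str = "assembled") -> List[TranscriptModel]:
    """Read exon features from a GTF file into transcript models.

    Only ``exon`` features are used.  Every exon line must carry
    ``transcript_id`` and ``gene_id`` attributes; a missing transcript_id
    rejects the whole file (there is no safe way to group the exon).
    Strand "." is preserved as unknown.
    """
    exons_by_tid: Dict[str, List[GenomicInterval]] = {}
    meta: Dict[str, Tuple[str, str, str]] = {}  # tid -> (gene, chrom, strand)
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfError(f"expected 9 tab-separated fields, got {len(fields)}", lineno)
            chrom, _src, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            try:
                start_1based, end = int(start_s), int(end_s)
            except ValueError:
                raise GtfError(f"non-integer coordinates {start_s!r}/{end_s!r}", lineno)
            attributes = parse_gtf_attributes(attrs)
            tid = attributes.get("transcript_id")
            if not tid:
                raise GtfError("exon feature missing transcript_id", lineno)
            gene = attributes.get("gene_id", tid)
            if strand not in ("+", "-", "."):
                raise GtfError(f"invalid strand {strand!r}", lineno)
            try:
                interval = GenomicInterval(chrom, start_1based - 1, end, strand)
            except ValueError as exc:
                raise GtfError(str(exc), lineno)
            exons_by_tid.setdefault(tid, []).append(interval)
            meta.setdefault(tid, (gene, chrom, strand))
    models = []
    for tid, exons in exons_by_tid.items():
        gene, chrom, strand = meta[tid]
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gene,
                chrom=chrom,
                strand=strand,
                exons=exons,
                source=source_label,
            )
        )
    return models


def write_gtf(models: Iterable[TranscriptModel], path, source_field: str = "novelscope") -> None:
    """Write transcript exon chains as GTF (shifting back to 1-based starts)."""
    with open(path, "w") as handle:
        for t in models:
            for i, e in enumerate(t.exons, start=1):
                attrs = (
                    f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                    f'exon_number "{i}";'
                )
                handle.write(
                    "\t".join(
                        [
                            t.chrom,
                            source_field,
                            "exon",
                            str(e.start + 1),
                            str(e.end),
                            ".",
                            t.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


def build_annotation_set(models: Iterable[TranscriptModel]) -> AnnotationSet:
    """Merge reference models into an AnnotationSet (empty input is valid)."""
    return AnnotationSet(models)


def read_bedgraph(path) -> Tuple[ConservationTrack, int]:
    """Read a 4-column bedGraph into a per-base track.

    Returns (track, n_rejected): records with values outside [0, 1] are
    skipped and counted rather than aborting the load.  Overlapping records
    follow the documented last-record-wins rule.
    """
    track = ConservationTrack()
    rejected = 0
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start_s, end_s, value_s = line.split("\t")[:4]
            value = float(value_s)
            if not (0.0 <= value <= 1.0):
                rejected += 1
                continue
            track.set_range(chrom, int(start_s), int(end_s), value)
    return track, rejected


def write_bedgraph(track: ConservationTrack, path) -> None:
    with open(path, "w") as handle:
        for chrom, start, end, value in track.iter_records():
            handle.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


def write_bed(records: Sequence[Tuple], path) -> None:
    """Write BED rows (tuples of up to 6 fields, already half-open)."""
    with open(path, "w") as handle:
        for rec in records:
            handle.write("\t".join(str(x) for x in rec) + "\n")


def read_bed(path) -> List[Tuple]:
    rows = []
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            fields[1], fields[2] = int(fields[1]), int(fields[2])
            if len(fields) >= 5:
                fields[4] = int(fields[4])
            rows.append(tuple(fields))
    return rows


def read_expression(path, design_path) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Read a transcript x sample TPM matrix and its sample design table.

    The design TSV maps sample -> (stage, replicate).  Every matrix column
    must appear in the design; an unmapped sample rejects the load.
    """
    matrix = pd.read_csv(path, sep="\t", index_col=0)
    design = pd.read_csv(design_path, sep="\t", index_col=0)
    missing = [s for s in matrix.columns if s not in design.index]
    if missing:
        raise ValueError(f"samples missing from design table: {missing}")
    if (matrix.values < 0).any():
        raise ValueError("negative TPM values in expression matrix")
    return matrix, design


def write_expression(matrix: pd.DataFrame, design: pd.DataFrame, path, design_path) -> None:
    matrix.to_csv(path, sep="\t")
    design.to_csv(design_path, sep="\t")


def read_fasta(path) -> Dict[str, str]:
    """Read FASTA into {id: sequence}, uppercasing bases."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")
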