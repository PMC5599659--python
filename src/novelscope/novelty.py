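"""Novelty scoring and known / PNT / CNT classification.

The novelty score (NS) of an assembled transcript is the percentage of its
exonic length not covered by the reference annotation's exonic union:

    NS = (1 - overlap_bases / exonic_length) * 100

Novel transcripts split at 70%: partially novel (PNT, NS < 70) and
completely novel (CNT, NS >= 70; the boundary belongs to CNT).  "Known"
is stricter than NS = 0: it requires an exact exon-chain match against
some reference transcript, so an annotated-exon fragment with NS = 0 is
still a PNT.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List

import pandas as pd

from .models import AnnotationSet, TranscriptModel

CNT_CUTOFF = 70.0  # NS >= cutoff -> completely novel


@dataclass
class NoveltyRecord:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exonic_length: int
    overlap_bases: int
    novelty_score: float
    class_label: str  # known | PNT | CNT


def exonic_overlap(
    transcript: TranscriptModel,
    annotation: AnnotationSet,
    strand_mode: str = "agnostic",
) -> int:
    """Exonic bases of ``transcript`` covered by the annotation union.

    Per-base counting with no double counting; a chromosome absent from
    the annotation simply contributes zero.  ``strand_mode`` is "agnostic"
    (default: assembled models often carry strand ".") or "same-strand".
    """
    if strand_mode not in ("agnostic", "same-strand"):
        raise ValueError(f"invalid strand_mode {strand_mode!r}")
    same = strand_mode == "same-strand"
    return sum(annotation.covered_bases(e, same_strand=same) for e in transcript.exons)


def novelty_score(
    transcript: TranscriptModel,
    annotation: AnnotationSet,
    strand_mode: str = "agnostic",
    length_mode: str = "exonic",
) -> float:
    """NS in [0, 100]; 0 iff fully covered, 100 iff zero overlap.

    ``length_mode`` selects the denominator: "exonic" (mature transcript
    length, default) or "span" (genomic footprint, for sensitivity checks;
    the overlap is then counted over the span too).
    """
    if length_mode == "exonic":
        length = transcript.exonic_length
        overlap = exonic_overlap(transcript, annotation, strand_mode)
    elif length_mode == "span":
        span = transcript.span
        length = span.length()
        overlap = annotation.covered_bases(span, same_strand=strand_mode == "same-strand")
    else:
        raise ValueError(f"invalid length_mode {length_mode!r}")
    if length <= 0:
        raise ValueError(f"transcript {transcript.transcript_id} has zero length")
    return (1.0 - overlap / length) * 100.0


def classify(
    transcript: TranscriptModel,
    annotation: AnnotationSet,
    strand_mode: str = "agnostic",
    cnt_cutoff: float = CNT_CUTOFF,
) -> str:
    """Return "known", "PNT" or "CNT" (exactly one label per transcript)."""
    if annotation.has_exact_chain(transcript):
        return "known"
    ns = novelty_score(transcript, annotation, strand_mode=strand_mode)
    return "CNT" if ns >= cnt_cutoff else "PNT"


def score_transcripts(
    transcripts: Iterable[TranscriptModel],
    annotation: AnnotationSet,
    strand_mode: str = "agnostic",
    cnt_cutoff: float = CNT_CUTOFF,
) -> List[NoveltyRecord]:
    records = []
    for t in transcripts:
        overlap = exonic_overlap(t, annotation, strand_mode)
        length = t.exonic_length
        ns = (1.0 - overlap / length) * 100.0
        if annotation.has_exact_chain(t):
            label = "known"
            ns = 0.0
            overlap = length
        else:
            label = "CNT" if ns >= cnt_cutoff else "PNT"
        span = t.span
        records.append(
            NoveltyRecord(
                transcript_id=t.transcript_id,
                gene_id=t.gene_id,
                chrom=t.chrom,
                strand=t.strand,
                start=span.start,
                end=span.end,
                exonic_length=length,
                overlap_bases=overlap,
                novelty_score=ns,
                class_label=label,
            )
        )
    return records


def novelty_table(records: Iterable[NoveltyRecord]) -> pd.DataFrame:
    """Tabular form mirroring the high-confidence transcript listings:
    ids, coordinates, exonic length, overlap, NS and class."""
    return pd.DataFrame(
        [
            {
                "transcript_id": r.transcript_id,
                "gene_id": r.gene_id,
                "coordinates": f"{r.chrom}:{r.start}-{r.end}",
                "strand": r.strand,
                "exonic_length": r.exonic_length,
                "overlap_bases": r.overlap_bases,
                "novelty_score": r.novelty_score,
                "class_label": r.class_label,
            }
            for r in records
        ]
    )
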