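"""Exon- and transcript-level conservation (phastCons-style) aggregation.

Per-base scores in [0, 1] are averaged within each exon, and the
transcript score (PS) is the *unweighted* mean of the exon means — a
short conserved exon counts as much as a long one.  Exons with no data
are excluded (not imputed as zero, which would bias sparsely scored
regions downward); ``covered_fraction`` reports how much exonic sequence
actually had data so callers can filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional

import pandas as pd

from .models import ConservationTrack, GenomicInterval, TranscriptModel


@dataclass
class ConservationRecord:
    transcript_id: str
    exon_scores: List[Optional[float]]  # None for exons without data
    transcript_score: Optional[float]  # PS, None if no exon had data
    covered_fraction: float  # fraction of exonic bases with data

    @property
    def n_exons_scored(self) -> int:
        return sum(1 for s in self.exon_scores if s is not None)


def exon_mean_score(track: ConservationTrack, interval: GenomicInterval) -> Optional[float]:
    """Arithmetic mean over bases with data; None if the exon has none."""
    scores = track.scores_in(interval)
    if not scores:
        return None
    return sum(scores) / len(scores)


def transcript_conservation(
    transcript: TranscriptModel,
    track: ConservationTrack,
    length_weighted: bool = False,
) -> ConservationRecord:
    """PS for one transcript.

    ``length_weighted=True`` switches to a base-weighted mean across the
    scored exons (for comparison with the default unweighted definition).
    """
    exon_scores: List[Optional[float]] = []
    covered_bases = 0
    weighted_sum = 0.0
    for exon in transcript.exons:
        scores = track.scores_in(exon)
        if scores:
            exon_scores.append(sum(scores) / len(scores))
            covered_bases += len(scores)
            weighted_sum += sum(scores)
        else:
            exon_scores.append(None)
    scored = [s for s in exon_scores if s is not None]
    if not scored:
        ps: Optional[float] = None
    elif length_weighted:
        ps = weighted_sum / covered_bases
    else:
        ps = sum(scored) / len(scored)
    return ConservationRecord(
        transcript_id=transcript.transcript_id,
        exon_scores=exon_scores,
        transcript_score=ps,
        covered_fraction=covered_bases / transcript.exonic_length,
    )


def conservation_table(
    transcripts: Iterable[TranscriptModel],
    track: ConservationTrack,
    length_weighted: bool = False,
) -> pd.DataFrame:
    rows = []
    for t in transcripts:
        rec = transcript_conservation(t, track, length_weighted=length_weighted)
        rows.append(
            {
                "transcript_id": rec.transcript_id,
                "transcript_score": rec.transcript_score,
                "covered_fraction": rec.covered_fraction,
                "n_exons_scored": rec.n_exons_scored,
            }
        )
    return pd.DataFrame(rows)
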