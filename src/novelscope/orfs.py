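"""Six-frame open-reading-frame detection with non-canonical starts.

All six frames are scanned: three codon offsets on the given sequence
and three on its reverse complement.  Within a frame, the sequence is
segmented at stop codons; one ORF opens at the first start codon of each
segment (``all_starts=True`` additionally emits every nested start) and
closes at the segment's stop.  Codons containing N never match a start
or a stop.  The default start set is ATG plus the near-cognate NTG
family (CTG, GTG, TTG).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Set, Tuple

CANONICAL_START = frozenset({"ATG"})
NONCANONICAL_STARTS = frozenset({"CTG", "GTG", "TTG"})
DEFAULT_STARTS = CANONICAL_START | NONCANONICAL_STARTS
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

DEFAULT_MIN_CODONS = 25

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class OrfHit:
    """One ORF; offsets are 0-based half-open on the scanned strand's
    sequence (the reverse complement for strand "-"), cover start codon
    through last sense codon, and exclude the stop."""

    transcript_id: str
    strand: str  # "+" | "-"
    frame: int  # 0 | 1 | 2
    start_offset: int
    end_offset: int
    start_codon: str
    length_codons: int  # includes start, excludes stop
    has_stop: bool = True

    def __post_init__(self) -> None:
        if (self.end_offset - self.start_offset) % 3 != 0:
            raise ValueError("ORF span not a codon multiple")
        if (self.end_offset - self.start_offset) // 3 != self.length_codons:
            raise ValueError("length_codons inconsistent with offsets")


def _scan_frame(
    seq: str,
    strand: str,
    frame: int,
    start_set: Set[str],
    min_codons: int,
    require_stop: bool,
    all_starts: bool,
    transcript_id: str,
) -> List[OrfHit]:
    hits: List[OrfHit] = []
    open_starts: List[Tuple[int, str]] = []  # (offset, codon) of pending starts
    for pos in range(frame, len(seq) - 2, 3):
        codon = seq[pos : pos + 3]
        if "N" in codon:
            continue
        if codon in STOP_CODONS:
            for start_pos, start_codon in open_starts:
                n_codons = (pos - start_pos) // 3
                if n_codons >= min_codons:
                    hits.append(
                        OrfHit(transcript_id, strand, frame, start_pos, pos,
                               start_codon, n_codons)
                    )
            open_starts = []
        elif codon in start_set and (all_starts or not open_starts):
            open_starts.append((pos, codon))
    if open_starts and not require_stop:
        # open-ended 3' ORF: runs to the last complete codon
        seg_end = frame + 3 * ((len(seq) - frame) // 3)
        for start_pos, start_codon in open_starts:
            n_codons = (seg_end - start_pos) // 3
            if n_codons >= min_codons:
                hits.append(
                    OrfHit(transcript_id, strand, frame, start_pos, seg_end,
                           start_codon, n_codons, has_stop=False)
                )
    return hits


def find_orfs(
    sequence: str,
    start_set: Iterable[str] = DEFAULT_STARTS,
    min_codons: int = DEFAULT_MIN_CODONS,
    require_stop: bool = True,
    all_starts: bool = False,
    transcript_id: str = "",
) -> List[OrfHit]:
    """All ORFs of >= ``min_codons`` codons across the six frames."""
    if min_codons < 1:
        raise ValueError("min_codons must be >= 1")
    sequence = sequence.upper()
    if not sequence:
        return []
    bad = set(sequence) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence contains invalid characters {sorted(bad)}")
    start_set = {s.upper() for s in start_set}
    hits: List[OrfHit] = []
    for strand, seq in (("+", sequence), ("-", revcomp(sequence))):
        for frame in range(3):
            hits.extend(
                _scan_frame(seq, strand, frame, start_set, min_codons,
                            require_stop, all_starts, transcript_id)
            )
    return hits


def longest_orf(hits: List[OrfHit]) -> Optional[OrfHit]:
    """Longest hit; ties go to + before -, then lower frame, then lower start."""
    if not hits:
        return None
    return min(
        hits,
        key=lambda h: (-h.length_codons, h.strand != "+", h.frame, h.start_offset),
    )


def orf_table(sequences: Dict[str, str], **kwargs) -> "pd.DataFrame":
    """Per-transcript ORF scan as a flat table (one row per hit)."""
    import pandas as pd

    rows = []
    for tid, seq in sequences.items():
        for h in find_orfs(seq, transcript_id=tid, **kwargs):
            rows.append(
                {
                    "transcript_id": tid,
                    "strand": h.strand,
                    "frame": h.frame,
                    "start_offset": h.start_offset,
                    "end_offset": h.end_offset,
                    "start_codon": h.start_codon,
                    "length_codons": h.length_codons,
                    "has_stop": h.has_stop,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "transcript_id", "strand", "frame", "start_offset", "end_offset",
            "start_codon", "length_codons", "has_stop",
        ],
    )
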