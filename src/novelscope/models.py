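"""Core genomic domain types.

All coordinates are 0-based half-open ([start, end), length = end - start),
the convention used by BED and bedGraph.  GTF input (1-based inclusive) is
converted on read and restored on write by :mod:`novelscope.io_formats`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

from intervaltree import IntervalTree

# Strand is one of "+", "-", or "." (unknown).  "." is a first-class value:
# StringTie emits it for mono-exonic models and it is never coerced to "+".
STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class TranscriptModel:
    """A chromosome-anchored exon chain.

    ``source`` distinguishes reference-annotation models from assembled
    (e.g. StringTie) models.  Exons are stored sorted by start and must be
    pairwise non-overlapping; construction enforces both.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: List[GenomicInterval]
    source: str = "assembled"  # "reference" | "assembled"

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.source not in ("reference", "assembled"):
            raise ValueError(f"invalid source {self.source!r}")
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        exons = sorted(self.exons, key=lambda e: (e.start, e.end))
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping exons "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )
        for e in exons:
            if e.chrom != self.chrom:
                raise ValueError(
                    f"transcript {self.transcript_id}: exon on {e.chrom}, "
                    f"transcript on {self.chrom}"
                )
        self.exons = exons

    @property
    def exonic_length(self) -> int:
        return sum(e.length() for e in self.exons)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    def exon_chain(self) -> Tuple[Tuple[int, int], ...]:
        """Hashable (start, end) tuple of the exon chain, for exact matching."""
        return tuple((e.start, e.end) for e in self.exons)


def merge_intervals(pairs: Iterable[Tuple[int, int]]) -> List[Tuple[int, int]]:
    """Merge possibly-overlapping (start, end) pairs into disjoint sorted runs.

    Adjacent runs ([0,10) + [10,20)) are coalesced; a merged union therefore
    has the minimal number of intervals covering the same base set.
    """
    out: List[Tuple[int, int]] = []
    for start, end in sorted(pairs):
        if out and start <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], end))
        else:
            out.append((start, end))
    return out


class AnnotationSet:
    """Reference transcripts plus their merged exonic union.

    The union is kept both strand-agnostic (default for overlap queries,
    matching the "." strands throughout assembled output) and partitioned
    by strand for the same-strand overlap mode.
    """

    def __init__(self, transcripts: Iterable[TranscriptModel]):
        self.transcripts: List[TranscriptModel] = list(transcripts)
        for t in self.transcripts:
            if t.source != "reference":
                raise ValueError(
                    f"AnnotationSet requires reference models, got {t.transcript_id}"
                )
        by_chrom: Dict[str, List[Tuple[int, int]]] = {}
        by_chrom_strand: Dict[Tuple[str, str], List[Tuple[int, int]]] = {}
        for t in self.transcripts:
            for e in t.exons:
                by_chrom.setdefault(t.chrom, []).append((e.start, e.end))
                by_chrom_strand.setdefault((t.chrom, t.strand), []).append(
                    (e.start, e.end)
                )
        self.exonic_union: Dict[str, List[Tuple[int, int]]] = {
            c: merge_intervals(v) for c, v in by_chrom.items()
        }
        self.exonic_union_stranded: Dict[Tuple[str, str], List[Tuple[int, int]]] = {
            k: merge_intervals(v) for k, v in by_chrom_strand.items()
        }
        self._trees: Dict[str, IntervalTree] = {
            c: IntervalTree.from_tuples(v) for c, v in self.exonic_union.items() if v
        }
        self._trees_stranded: Dict[Tuple[str, str], IntervalTree] = {
            k: IntervalTree.from_tuples(v)
            for k, v in self.exonic_union_stranded.items()
            if v
        }
        self._chains = {t.exon_chain(): t.transcript_id for t in self.transcripts}

    def union_length(self, chrom: Optional[str] = None) -> int:
        chroms = [chrom] if chrom is not None else list(self.exonic_union)
        return sum(
            e - s for c in chroms for (s, e) in self.exonic_union.get(c, [])
        )

    def covered_bases(self, interval: GenomicInterval, same_strand: bool = False) -> int:
        """Number of bases of ``interval`` inside the exonic union."""
        if same_strand:
            tree = self._trees_stranded.get((interval.chrom, interval.strand))
        else:
            tree = self._trees.get(interval.chrom)
        if tree is None:
            return 0
        covered = 0
        for hit in tree.overlap(interval.start, interval.end):
            covered += min(hit.end, interval.end) - max(hit.begin, interval.start)
        # union intervals are disjoint, so clipped hits never double count
        return covered

    def has_exact_chain(self, transcript: TranscriptModel) -> bool:
        """True if some reference transcript on the same chromosome has the
        identical exon chain (all boundaries equal)."""
        tid = self._chains.get(transcript.exon_chain())
        if tid is None:
            return False
        ref = next(t for t in self.transcripts if t.transcript_id == tid)
        return ref.chrom == transcript.chrom


class ConservationTrack:
    """Sparse per-base conservation scores in [0, 1] per chromosome.

    Later assignments overwrite earlier ones (the documented bedGraph
    overlap rule).  Bases without data are simply absent.
    """

    def __init__(self) -> None:
        self._scores: Dict[str, Dict[int, float]] = {}

    def set_range(self, chrom: str, start: int, end: int, value: float) -> None:
        if not (0.0 <= value <= 1.0):
            raise ValueError(f"conservation score {value} outside [0, 1]")
        chrom_map = self._scores.setdefault(chrom, {})
        for base in range(start, end):
            chrom_map[base] = value

    def set_bases(self, chrom: str, start: int, values) -> None:
        """Assign per-base scores for [start, start + len(values))."""
        chrom_map = self._scores.setdefault(chrom, {})
        for base, value in zip(range(start, start + len(values)), values):
            chrom_map[base] = float(value)

    def get(self, chrom: str, base: int) -> Optional[float]:
        return self._scores.get(chrom, {}).get(base)

    def scores_in(self, interval: GenomicInterval) -> List[float]:
        chrom_map = self._scores.get(interval.chrom)
        if not chrom_map:
            return []
        return [
            chrom_map[b]
            for b in range(interval.start, interval.end)
            if b in chrom_map
        ]

    def n_bases(self) -> int:
        return sum(len(m) for m in self._scores.values())

    def iter_records(self) -> Iterable[Tuple[str, int, int, float]]:
        """Yield maximal constant-value runs as (chrom, start, end, value)."""
        for chrom in sorted(self._scores):
            chrom_map = self._scores[chrom]
            run_start = run_end = None
            run_val = None
            for base in sorted(chrom_map):
                val = chrom_map[base]
                if run_start is not None and base == run_end and val == run_val:
                    run_end = base + 1
                else:
                    if run_start is not None:
                        yield chrom, run_start, run_end, run_val
                    run_start, run_end, run_val = base, base + 1, val
            if run_start is not None:
                yield chrom, run_start, run_end, run_val
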