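"""Synthetic developmental-transcriptome generator with planted ground truth.

Emulates the inputs of a lens-style developmental RNA-seq analysis on a
toy genome: a reference annotation, an assembled transcript set with
three planted classes (known copies, partially novel transcripts with an
exact planted exonic-overlap fraction, completely novel transcripts in
annotation-free regions), class-dependent per-base conservation, class-
and stage-dependent log-normal TPM with replicates, binomial junction
counts around true PSI values, and transcript sequences with planted
ORFs on stop-salted backgrounds.

Everything is deterministic for a fixed seed, and every planted quantity
is recorded in a :class:`GroundTruth` so downstream estimates can be
checked exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .models import AnnotationSet, ConservationTrack, GenomicInterval, TranscriptModel
from .splicing import EventCounts, SpliceEvent

logger = logging.getLogger(__name__)

DEFAULT_STAGES = ("E15", "E18", "P0", "P3", "P6", "P9")

# Stop-salt unit: contains a stop codon in every forward frame class
# (TAA at offsets 0/4/8) and, via reverse complement, in every reverse
# frame class (TTA -> TAA at offsets 12/16/20), wherever it is inserted.
# Its 3-mers contain no ATG/CTG/GTG/TTG, so it never opens an ORF either.
STOP_SALT = "TAACTAACTAACTTACTTACTTAC"
_SALT_PERIOD = 18 + len(STOP_SALT)  # random filler + salt; caps stop-free
# runs at 14 codons in every frame, below the default 25-codon ORF floor.


@dataclass
class SimulationConfig:
    seed: int = 0
    n_known: int = 100
    n_pnt: int = 100
    n_cnt: int = 100
    n_genes: int = 80
    stages: Tuple[str, ...] = DEFAULT_STAGES
    replicates_per_stage: int = 2
    chrom_length: int = 1_000_000
    n_chroms: int = 3
    # class-level conservation means (per-base beta distributions)
    class_conservation_means: Dict[str, float] = field(
        default_factory=lambda: {"known": 0.67, "PNT": 0.76, "CNT": 0.13}
    )
    conservation_concentration: float = 10.0
    # class-level expression: mean of log TPM
    class_expression_logmean: Dict[str, float] = field(
        default_factory=lambda: {"known": 2.0, "PNT": 3.0, "CNT": 0.5}
    )
    expression_sigma: float = 0.5  # between-transcript spread of log TPM
    replicate_sigma: float = 0.25  # replicate noise on log TPM (truncated)
    # CNT expression-pattern mix (stage-specific / all-stage / remainder random)
    frac_cnt_stage_specific: float = 0.10
    frac_cnt_all_stages: float = 0.47
    # minority of CNTs planted with 70 <= NS < 100 rather than NS = 100
    frac_cnt_partial_ns: float = 0.10
    # splicing
    psi_truth: Optional[Dict[str, Dict[str, float]]] = None
    read_depth: int = 100_000
    # sequences
    frac_cnt_with_orf: float = 0.5
    orf_codon_range: Tuple[int, int] = (30, 80)

    def __post_init__(self) -> None:
        for name in ("n_known", "n_pnt", "n_cnt", "n_genes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for m in self.class_conservation_means.values():
            if not (0.0 <= m <= 1.0):
                raise ValueError("conservation means must lie in [0, 1]")
        if self.psi_truth is not None:
            for stage_map in self.psi_truth.values():
                for v in stage_map.values():
                    if not (0.0 <= v <= 1.0):
                        raise ValueError("psi truth values must lie in [0, 1]")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


def default_psi_truth(stages: Sequence[str] = DEFAULT_STAGES) -> Dict[str, Dict[str, float]]:
    """Default planted events: an Srsf2-like skipped exon whose inclusion
    rises from 0.0535 (E15) to 0.245 (P9), a constitutive-like event, and
    a balanced event."""
    n = len(stages)
    srsf2 = {
        s: 0.0535 + (0.245 - 0.0535) * i / (n - 1) for i, s in enumerate(stages)
    }
    srsf2[stages[0]], srsf2[stages[-1]] = 0.0535, 0.245
    return {
        "SE_srsf2like": srsf2,
        "SE_balanced": {s: 0.5 for s in stages},
        "RI_constitutive": {s: 1.0 for s in stages},
    }


@dataclass
class PlantedOrf:
    strand: str
    frame: int
    start_offset: int
    end_offset: int
    length_codons: int
    start_codon: str = "ATG"


@dataclass
class GroundTruth:
    """Planted values for every generated transcript and event."""

    class_by_transcript: Dict[str, str] = field(default_factory=dict)
    overlap_fraction: Dict[str, float] = field(default_factory=dict)
    expressed_pattern: Dict[str, FrozenSet[str]] = field(default_factory=dict)
    psi_truth: Dict[str, Dict[str, float]] = field(default_factory=dict)
    orfs: Dict[str, Optional[PlantedOrf]] = field(default_factory=dict)


class _Allocator:
    """Sequential placement on the toy genome.

    Each chromosome is split into an annotation zone (first 60%) and an
    annotation-free zone (last 35%); running out of space logs a report
    and transparently grows the genome with an extra chromosome.
    """

    def __init__(self, chrom_length: int, n_chroms: int):
        self.chrom_length = chrom_length
        self.chroms = [f"chr{i + 1}" for i in range(n_chroms)]
        self._ann_cursor = {c: 5_000 for c in self.chroms}
        self._free_cursor = {c: int(chrom_length * 0.65) for c in self.chroms}
        self._ann_limit = int(chrom_length * 0.60)
        self._turn = 0

    def _grow(self) -> str:
        name = f"chr{len(self.chroms) + 1}"
        logger.warning("toy genome exhausted; adding %s", name)
        self.chroms.append(name)
        self._ann_cursor[name] = 5_000
        self._free_cursor[name] = int(self.chrom_length * 0.65)
        return name

    def place(self, span: int, zone: str, gap: int) -> Tuple[str, int]:
        cursors = self._ann_cursor if zone == "annotation" else self._free_cursor
        limit = self._ann_limit if zone == "annotation" else self.chrom_length - 1_000
        for _ in range(len(self.chroms) + 1):
            chrom = self.chroms[self._turn % len(self.chroms)]
            self._turn += 1
            start = cursors[chrom]
            if start + span <= limit:
                cursors[chrom] = start + span + gap
                return chrom, start
        self._grow()
        return self.place(span, zone, gap)


def generate_annotation(
    config: SimulationConfig,
) -> Tuple[AnnotationSet, List[TranscriptModel], _Allocator]:
    """Reference annotation: multi-exon genes with realistic intron gaps.

    First exons always abut an intergenic gap of >= 3 kb upstream, which
    the PNT planter uses to extend novel exons into annotation-free space.
    """
    rng = config.rng(stream=1)
    alloc = _Allocator(config.chrom_length, config.n_chroms)
    models: List[TranscriptModel] = []
    for g in range(config.n_genes):
        n_exons = int(rng.integers(2, 9))
        exon_lens = rng.integers(300, 601, size=n_exons)
        intron_lens = rng.integers(300, 2001, size=max(n_exons - 1, 0))
        span = int(exon_lens.sum() + intron_lens.sum())
        gap = int(rng.integers(3_000, 5_001))
        chrom, start = alloc.place(span, "annotation", gap)
        strand = "+" if rng.random() < 0.5 else "-"
        exons = []
        cursor = start
        for i, length in enumerate(exon_lens):
            exons.append(GenomicInterval(chrom, cursor, cursor + int(length), strand))
            cursor += int(length)
            if i < len(intron_lens):
                cursor += int(intron_lens[i])
        gene_id = f"GSYN.{g + 1}"
        models.append(
            TranscriptModel(
                transcript_id=f"{gene_id}.t1",
                gene_id=gene_id,
                chrom=chrom,
                strand=strand,
                exons=exons,
                source="reference",
            )
        )
    return AnnotationSet(models), models, alloc


def generate_assembled(
    config: SimulationConfig,
    annotation: AnnotationSet,
    allocator: Optional[_Allocator] = None,
) -> Tuple[List[TranscriptModel], GroundTruth]:
    """Assembled transcripts with planted class labels and overlap fractions.

    - known: exact copies of reference exon chains (overlap fraction 1);
    - PNT: one novel exon covering exactly ``o`` bases of a reference
      first exon and extending ``L - o`` bases into the upstream
      intergenic gap, with o/L > 0.3 so NS < 70;
    - CNT: one- or two-exon models in the annotation-free zone (NS = 100),
      plus a configurable minority planted with 0 < o/L <= 0.3 so
      70 <= NS < 100.
    """
    rng = config.rng(stream=2)
    if allocator is None:
        allocator = _Allocator(config.chrom_length, config.n_chroms)
    refs = annotation.transcripts
    if (config.n_known or config.n_pnt) and not refs:
        raise ValueError("known/PNT planting requires a non-empty annotation")
    truth = GroundTruth()
    out: List[TranscriptModel] = []

    for k in range(config.n_known):
        ref = refs[int(rng.integers(len(refs)))]
        tid = f"ASM.K{k + 1}.1"
        out.append(
            TranscriptModel(tid, f"ASM.K{k + 1}", ref.chrom, ref.strand,
                            list(ref.exons), source="assembled")
        )
        truth.class_by_transcript[tid] = "known"
        truth.overlap_fraction[tid] = 1.0

    for p in range(config.n_pnt):
        ref = refs[int(rng.integers(len(refs)))]
        first = ref.exons[0]
        total = int(rng.integers(100, 301))
        frac = rng.uniform(0.35, 0.95)
        overlap = int(round(frac * total))
        overlap = max(overlap, math.floor(0.3 * total) + 1)  # keep NS < 70
        overlap = min(overlap, first.length(), total)
        ext = total - overlap
        if ext == 0:  # fully-covered novel exon still classifies as PNT
            exon = GenomicInterval(first.chrom, first.start, first.start + overlap, ".")
        else:
            exon = GenomicInterval(
                first.chrom, first.start - ext, first.start + overlap, "."
            )
        tid = f"ASM.P{p + 1}.1"
        out.append(
            TranscriptModel(tid, f"ASM.P{p + 1}", first.chrom, ".", [exon],
                            source="assembled")
        )
        truth.class_by_transcript[tid] = "PNT"
        truth.overlap_fraction[tid] = overlap / total

    n_partial = int(round(config.frac_cnt_partial_ns * config.n_cnt))
    for c in range(config.n_cnt):
        tid = f"ASM.C{c + 1}.1"
        if c < n_partial and refs:
            # 70 <= NS < 100: small overlap with an annotated first exon
            ref = refs[int(rng.integers(len(refs)))]
            first = ref.exons[0]
            total = int(rng.integers(300, 601))
            frac = rng.uniform(0.05, 0.30)
            overlap = int(round(frac * total))
            overlap = min(max(overlap, 1), math.floor(0.3 * total))
            ext = total - overlap
            exon = GenomicInterval(
                first.chrom, first.start - ext, first.start + overlap, "."
            )
            out.append(
                TranscriptModel(tid, f"ASM.C{c + 1}", first.chrom, ".", [exon],
                                source="assembled")
            )
            truth.overlap_fraction[tid] = overlap / total
        else:
            n_exons = 1 if rng.random() < 0.6 else 2
            exon_lens = rng.integers(300, 601, size=n_exons)
            intron = int(rng.integers(200, 1001)) if n_exons == 2 else 0
            span = int(exon_lens.sum()) + intron
            chrom, start = allocator.place(span, "free", gap=int(rng.integers(500, 1500)))
            exons = [GenomicInterval(chrom, start, start + int(exon_lens[0]), ".")]
            if n_exons == 2:
                s2 = start + int(exon_lens[0]) + intron
                exons.append(GenomicInterval(chrom, s2, s2 + int(exon_lens[1]), "."))
            out.append(
                TranscriptModel(tid, f"ASM.C{c + 1}", chrom, ".", exons,
                                source="assembled")
            )
            truth.overlap_fraction[tid] = 0.0
        truth.class_by_transcript[tid] = "CNT"
    return out, truth


def generate_conservation(
    config: SimulationConfig,
    transcripts: Sequence[TranscriptModel],
    truth: GroundTruth,
) -> ConservationTrack:
    """Per-base scores over the exons of every transcript, beta-distributed
    with the configured class mean and fixed concentration (beta keeps the
    bounded [0, 1] support of phastCons-style scores)."""
    rng = config.rng(stream=3)
    kappa = config.conservation_concentration
    track = ConservationTrack()
    for t in transcripts:
        mean = config.class_conservation_means[truth.class_by_transcript[t.transcript_id]]
        for exon in t.exons:
            n = exon.length()
            if mean <= 0.0 or mean >= 1.0 or kappa <= 0:
                scores = np.full(n, float(round(mean)))
            else:
                scores = rng.beta(mean * kappa, (1.0 - mean) * kappa, size=n)
            track.set_bases(exon.chrom, exon.start, scores)
    return track


def _sample_names(config: SimulationConfig) -> List[str]:
    return [
        f"{stage}_r{rep}"
        for stage in config.stages
        for rep in range(1, config.replicates_per_stage + 1)
    ]


def make_design(config: SimulationConfig) -> pd.DataFrame:
    rows = [
        {"sample": f"{stage}_r{rep}", "stage": stage, "replicate": rep}
        for stage in config.stages
        for rep in range(1, config.replicates_per_stage + 1)
    ]
    return pd.DataFrame(rows).set_index("sample")


def generate_expression(
    config: SimulationConfig,
    truth: GroundTruth,
    transcripts: Sequence[TranscriptModel],
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Transcript x sample TPM with log-normal class effects.

    Expected ordering PNT > known > CNT.  Planted CNT patterns are hard
    guarantees at the default TPM > 1 call: stage-specific transcripts are
    positive (>= 2 TPM before bounded replicate noise) in exactly one
    stage and zero elsewhere; all-stage transcripts are >= 2 TPM
    everywhere.  Replicate noise is log-normal truncated to +/-0.4 in log
    space so replicate means cannot cross the threshold.
    """
    rng = config.rng(stream=4)
    design = make_design(config)
    samples = _sample_names(config)
    stages = list(config.stages)
    cnts = [t.transcript_id for t in transcripts
            if truth.class_by_transcript[t.transcript_id] == "CNT"]
    n_specific = int(round(config.frac_cnt_stage_specific * len(cnts)))
    n_all = int(round(config.frac_cnt_all_stages * len(cnts)))
    pattern: Dict[str, FrozenSet[str]] = {}
    for i, tid in enumerate(cnts):
        if i < n_specific:
            pattern[tid] = frozenset({stages[int(rng.integers(len(stages)))]})
        elif i < n_specific + n_all:
            pattern[tid] = frozenset(stages)
        else:
            k = int(rng.integers(2, len(stages)))
            chosen = rng.choice(len(stages), size=k, replace=False)
            pattern[tid] = frozenset(stages[j] for j in chosen)
    rows = {}
    for t in transcripts:
        tid = t.transcript_id
        label = truth.class_by_transcript[tid]
        mu = config.class_expression_logmean[label] + rng.normal(0, config.expression_sigma)
        stage_tpm = {}
        planted = pattern.get(tid, frozenset(stages))
        for stage in stages:
            if stage not in planted:
                stage_tpm[stage] = 0.0
            else:
                base = math.exp(mu + rng.normal(0, 0.3))
                if tid in pattern:  # planted patterns are guaranteed calls
                    base = max(base, 2.0)
                stage_tpm[stage] = base
        noise = np.clip(
            rng.normal(0, config.replicate_sigma, size=len(samples)), -0.4, 0.4
        )
        row = []
        for j, sample in enumerate(samples):
            stage = design.loc[sample, "stage"]
            base = stage_tpm[stage]
            row.append(0.0 if base == 0.0 else base * math.exp(noise[j]))
        rows[tid] = row
        truth.expressed_pattern[tid] = planted
    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    return matrix, design


def generate_splice_counts(
    config: SimulationConfig,
) -> Tuple[Dict[str, SpliceEvent], Dict[str, List[EventCounts]], GroundTruth]:
    """Binomial junction counts around the planted PSI values.

    Inclusion reads ~ Binomial(depth, g(psi)) with g the length-weighted
    inclusion probability g = psi*lI / (psi*lI + (1-psi)*lS), so the
    density-ratio PSI estimator is consistent for the planted psi.
    """
    rng = config.rng(stream=5)
    psi_truth = config.psi_truth or default_psi_truth(config.stages)
    truth = GroundTruth(psi_truth=psi_truth)
    events: Dict[str, SpliceEvent] = {}
    counts: Dict[str, List[EventCounts]] = {}
    cursor = 10_000
    for event_id, stage_map in psi_truth.items():
        prefix = event_id.split("_")[0]
        etype = prefix if prefix in ("SE", "RI", "MXE", "A5SS", "A3SS") else "SE"
        up = GenomicInterval("chrSIM", cursor, cursor + 200, "+")
        target = GenomicInterval("chrSIM", cursor + 500, cursor + 650, "+")
        down = GenomicInterval("chrSIM", cursor + 1000, cursor + 1200, "+")
        cursor += 5_000
        li, ls = (2, 1) if etype != "RI" else (3, 1)
        events[event_id] = SpliceEvent(event_id, etype, f"gene_{event_id}",
                                       target, (up, down), "+")
        per_sample = []
        for stage in config.stages:
            psi_val = stage_map[stage]
            g = psi_val * li / (psi_val * li + (1 - psi_val) * ls)
            for rep in range(1, config.replicates_per_stage + 1):
                inc = int(rng.binomial(config.read_depth, g))
                per_sample.append(
                    EventCounts(f"{stage}_r{rep}", inc, config.read_depth - inc, li, ls)
                )
        counts[event_id] = per_sample
    return events, counts, truth


def _salted_filler(rng: np.random.Generator, n_blocks: int) -> str:
    bases = "ACGT"
    parts = []
    for _ in range(n_blocks):
        filler = "".join(bases[i] for i in rng.integers(0, 4, size=18))
        parts.append(filler + STOP_SALT)
    return "".join(parts)


def build_orf_sequence(
    rng: np.random.Generator,
    n_codons: int,
    strand: str,
    pad: int,
    prefix_blocks: int = 2,
    suffix_blocks: int = 2,
) -> Tuple[str, PlantedOrf]:
    """Stop-salted sequence with a single planted ORF of ``n_codons``.

    The ORF body is ATG + cycled AAC/TAC/CTA/ACT codons + TAA.  That
    codon cycle is stop-free and start-free in the planted frame but
    places a stop within every 12 nt in each of the other five frames,
    so no spurious ORF above the salt ceiling (14 codons) can cross the
    body: the planted ORF is the unique hit above the default 25-codon
    floor and is reported at exactly the planted offsets.  ``strand="-"``
    stores the reverse complement of the constructed sense sequence.
    """
    prefix = _salted_filler(rng, prefix_blocks) + "C" * pad
    cycle = ("AAC", "TAC", "CTA", "ACT")
    interior = "".join(cycle[i % 4] for i in range(n_codons - 1))
    body = "ATG" + interior + "TAA"
    suffix = _salted_filler(rng, suffix_blocks)
    sense = prefix + body + suffix
    start = len(prefix)
    orf = PlantedOrf(
        strand=strand,
        frame=start % 3,
        start_offset=start,
        end_offset=start + 3 * n_codons,
        length_codons=n_codons,
    )
    return (sense if strand == "+" else _revcomp(sense)), orf


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def generate_sequences(
    config: SimulationConfig,
    transcripts: Sequence[TranscriptModel],
    truth: GroundTruth,
) -> Dict[str, str]:
    """Sequences for CNTs: a configurable fraction carries one planted ORF,
    the rest are stop-salted decoys with no ORF of >= 15 codons in any
    of the six frames (guaranteed by the salt period)."""
    rng = config.rng(stream=6)
    sequences: Dict[str, str] = {}
    cnts = [t for t in transcripts
            if truth.class_by_transcript[t.transcript_id] == "CNT"]
    n_orf = int(round(config.frac_cnt_with_orf * len(cnts)))
    lo, hi = config.orf_codon_range
    for i, t in enumerate(cnts):
        tid = t.transcript_id
        if i < n_orf:
            n_codons = int(rng.integers(lo, hi + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            pad = int(rng.integers(0, 3))
            seq, orf = build_orf_sequence(rng, n_codons, strand, pad)
            sequences[tid] = seq
            truth.orfs[tid] = orf
        else:
            n_blocks = max(2, t.exonic_length // _SALT_PERIOD)
            sequences[tid] = _salted_filler(rng, int(n_blocks))
            truth.orfs[tid] = None
    return sequences


def simulate_novelty_shift(
    rng: np.random.Generator,
    n_per_group: int,
    shift: float = 1.85,
    base_median: float = 9.04,
    sigma: float = 0.5,
) -> Tuple[np.ndarray, np.ndarray]:
    """Embryonic- vs postnatal-style novelty-score samples.

    The postnatal group is log-normal with the configured median; the
    embryonic group is an independent draw location-shifted upward (the
    published medians differ by ~1.85 novelty-score units, 10.89 vs
    9.04).  Scores are clipped to [0, 100].
    """
    post = np.clip(rng.lognormal(math.log(base_median), sigma, n_per_group), 0, 100)
    emb = np.clip(
        rng.lognormal(math.log(base_median), sigma, n_per_group) + shift, 0, 100
    )
    return emb, post


@dataclass
class SimulatedBundle:
    """Everything one simulation run produces, in memory."""

    config: SimulationConfig
    annotation: AnnotationSet
    reference_models: List[TranscriptModel]
    assembled: List[TranscriptModel]
    truth: GroundTruth
    conservation: ConservationTrack
    expression: pd.DataFrame
    design: pd.DataFrame
    events: Dict[str, SpliceEvent]
    event_counts: Dict[str, List[EventCounts]]
    sequences: Dict[str, str]


def simulate_bundle(config: SimulationConfig) -> SimulatedBundle:
    """Run every generator stage under one seed."""
    annotation, ref_models, alloc = generate_annotation(config)
    assembled, truth = generate_assembled(config, annotation, alloc)
    track = generate_conservation(config, assembled, truth)
    matrix, design = generate_expression(config, truth, assembled)
    events, counts, splice_truth = generate_splice_counts(config)
    truth.psi_truth = splice_truth.psi_truth
    sequences = generate_sequences(config, assembled, truth)
    return SimulatedBundle(
        config=config,
        annotation=annotation,
        reference_models=ref_models,
        assembled=assembled,
        truth=truth,
        conservation=track,
        expression=matrix,
        design=design,
        events=events,
        event_counts=counts,
        sequences=sequences,
    )
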