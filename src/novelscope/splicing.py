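"""Percent-spliced-in (PSI) estimation, stage summaries, a simple
significance screen, and browser-track export.

For one splicing event with inclusion reads I, skip reads S and effective
lengths lI, lS, the length-normalized read-density estimate is

    psi = (I / lI) / (I / lI + S / lS)

Stage-level psi averages the per-replicate estimates; delta-psi and fold
changes compare stages.  The significance *screen* is a Fisher exact test
on pooled (I, S) counts between two stages with Benjamini-Hochberg FDR —
deliberately a simple screen, not a reimplementation of the hierarchical
replicate model used by dedicated splicing callers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .models import GenomicInterval

logger = logging.getLogger(__name__)

EVENT_TYPES = ("SE", "RI", "MXE", "A5SS", "A3SS")


@dataclass
class SpliceEvent:
    """Geometry of one alternative-splicing event.

    ``target`` is the alternative region (the skipped exon for SE, the
    retained intron for RI, ...); ``flanks`` are the constitutive exons.
    For SE the target must lie strictly between its flanks.
    """

    event_id: str
    event_type: str
    gene: str
    target: GenomicInterval
    flanks: Tuple[GenomicInterval, GenomicInterval]
    strand: str = "."

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")
        up, down = self.flanks
        if self.event_type in ("SE", "RI", "MXE"):
            if not (up.end <= self.target.start and self.target.end <= down.start):
                raise ValueError(
                    f"event {self.event_id}: target not between flanks"
                )


@dataclass(frozen=True)
class EventCounts:
    """Per-sample junction support for one event."""

    sample: str
    inclusion_reads: int
    skip_reads: int
    inclusion_length: int = 2  # junction-count form for SE: two inclusion junctions
    skip_length: int = 1

    def __post_init__(self) -> None:
        if self.inclusion_reads < 0 or self.skip_reads < 0:
            raise ValueError("negative read counts")
        if self.inclusion_length < 1 or self.skip_length < 1:
            raise ValueError("effective lengths must be >= 1")


def psi(counts: EventCounts) -> Optional[float]:
    """Length-normalized PSI in [0, 1]; None when I = S = 0."""
    i, s = counts.inclusion_reads, counts.skip_reads
    if i == 0 and s == 0:
        return None
    di = i / counts.inclusion_length
    ds = s / counts.skip_length
    return di / (di + ds)


def stage_psi(
    sample_psi: Dict[str, Optional[float]],
    design: pd.DataFrame,
    excluded_stages: Optional[set] = None,
) -> Dict[str, Optional[float]]:
    """Per-stage PSI = unweighted mean over replicates with a defined
    estimate; stages with none defined report None (NA)."""
    from .expression import DEFAULT_EXCLUDED_STAGES

    if excluded_stages is None:
        excluded_stages = set(DEFAULT_EXCLUDED_STAGES)
    stages: List[str] = []
    for sample in sample_psi:
        stage = design.loc[sample, "stage"]
        if stage not in stages and stage not in excluded_stages:
            stages.append(stage)
    out: Dict[str, Optional[float]] = {}
    for stage in stages:
        vals = [
            v
            for s, v in sample_psi.items()
            if design.loc[s, "stage"] == stage and v is not None
        ]
        out[stage] = sum(vals) / len(vals) if vals else None
    return out


def delta_psi(
    stage_values: Dict[str, Optional[float]], stage_a: str, stage_b: str
) -> Tuple[Optional[float], Optional[float]]:
    """(delta, fold) for a stage pair: delta = psi_b - psi_a, fold =
    psi_b / psi_a (fold None when psi_a is 0 or either is NA)."""
    a, b = stage_values.get(stage_a), stage_values.get(stage_b)
    if a is None or b is None:
        return None, None
    fold = b / a if a > 0 else None
    return b - a, fold


def psi_matrix(
    events_counts: Dict[str, List[EventCounts]],
    design: pd.DataFrame,
    excluded_stages: Optional[set] = None,
) -> pd.DataFrame:
    """Events x stages PSI table (NaN for stages with no defined estimate)."""
    rows = {}
    for event_id, counts in events_counts.items():
        per_sample = {c.sample: psi(c) for c in counts}
        stage_vals = stage_psi(per_sample, design, excluded_stages)
        rows[event_id] = {
            k: (np.nan if v is None else v) for k, v in stage_vals.items()
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def screen_events(
    pooled_counts: Dict[str, Tuple[Tuple[int, int], Tuple[int, int]]],
    alpha_fdr: float = 0.01,
) -> pd.DataFrame:
    """Fisher exact screen between two stages with BH FDR.

    ``pooled_counts`` maps event_id -> ((I_a, S_a), (I_b, S_b)) of counts
    pooled over replicates per stage.  Degenerate tables (a zero margin)
    get p = q = 1.  Returns a frame with p, q and a ``flagged`` column at
    q < alpha_fdr.  This is a screen, not a replicate-aware model.
    """
    event_ids = list(pooled_counts)
    pvals = []
    for eid in event_ids:
        (ia, sa), (ib, sb) = pooled_counts[eid]
        table = np.array([[ia, sa], [ib, sb]])
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            pvals.append(1.0)
        else:
            pvals.append(stats.fisher_exact(table)[1])
    qvals = benjamini_hochberg(pvals)
    return pd.DataFrame(
        {
            "event_id": event_ids,
            "p_value": pvals,
            "q_value": qvals,
            "flagged": [q < alpha_fdr for q in qvals],
        }
    ).set_index("event_id")


def benjamini_hochberg(pvals: Sequence[float]) -> List[float]:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    n = len(pvals)
    if n == 0:
        return []
    order = np.argsort(pvals)
    adjusted = np.empty(n)
    running_min = 1.0
    for rank_from_top, idx in enumerate(reversed(order), start=0):
        rank = n - rank_from_top
        running_min = min(running_min, pvals[idx] * n / rank)
        adjusted[idx] = running_min
    return adjusted.tolist()


def events_to_bed(
    psi_table: pd.DataFrame,
    events: Dict[str, SpliceEvent],
    stage: str,
) -> List[Tuple[str, int, int, str, int, str]]:
    """BED6 rows for one stage; score = round(psi * 1000) in [0, 1000],
    name encodes event_id|type|stage|psi.  Events with undefined PSI for
    the stage are skipped (logged)."""
    records = []
    for event_id in psi_table.index:
        value = psi_table.loc[event_id, stage]
        if pd.isna(value):
            logger.info("event %s: PSI undefined at %s, skipped", event_id, stage)
            continue
        ev = events[event_id]
        score = int(round(float(value) * 1000))
        name = f"{event_id}|{ev.event_type}|{stage}|{float(value):.4g}"
        records.append(
            (ev.target.chrom, ev.target.start, ev.target.end, name, score, ev.strand)
        )
    return records
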