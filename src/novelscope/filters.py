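"""Compound high-confidence filters over scored transcript tables.

A record table carries one row per transcript with columns ``length``
(exonic bp), ``ps`` (transcript conservation score), ``ns`` (novelty
score), ``class_label`` and, when expression predicates are used, one
column per developmental stage of mean TPM.

Comparison strictness follows the published convention for these
filters: length bounds are inclusive, conservation and TPM cuts are
strict.  Two length/conservation/expression filters produce the broadly
expressed and stage-specific high-confidence CNT lists; a conservation
cut of PS > 0.8 produces the conserved-PNT gene set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterSpec:
    name: str = "custom"
    min_length: Optional[int] = None  # inclusive
    max_length: Optional[int] = None  # inclusive
    min_ps: Optional[float] = None  # strict >
    min_mean_tpm: Optional[float] = None  # strict >, used for stage counting
    min_stages_expressed: Optional[int] = None
    max_stages_expressed: Optional[int] = None
    required_class: Optional[str] = None
    required_ns: Optional[float] = None  # exact NS required (e.g. 100)

    def __post_init__(self) -> None:
        if (
            self.min_length is not None
            and self.max_length is not None
            and self.min_length > self.max_length
        ):
            raise ValueError("min_length > max_length")
        if self.min_ps is not None and not (0.0 <= self.min_ps <= 1.0):
            raise ValueError("min_ps outside [0, 1]")

    def stage_threshold(self) -> float:
        """TPM cut used when counting expressed stages: the configured
        mean-TPM floor, or bare positivity when no floor is set."""
        return self.min_mean_tpm if self.min_mean_tpm is not None else 0.0


def _check_record(row: pd.Series, spec: FilterSpec, stage_columns: Sequence[str]) -> Optional[str]:
    """Return None if the row survives, else the failing predicate name."""
    if spec.required_class is not None:
        if pd.isna(row.get("class_label")):
            return "missing class_label"
        if row["class_label"] != spec.required_class:
            return "class"
    if spec.required_ns is not None:
        if pd.isna(row.get("ns")):
            return "missing ns"
        if abs(row["ns"] - spec.required_ns) > 1e-9:
            return "ns"
    if spec.min_length is not None or spec.max_length is not None:
        if pd.isna(row.get("length")):
            return "missing length"
        if spec.min_length is not None and row["length"] < spec.min_length:
            return "min_length"
        if spec.max_length is not None and row["length"] > spec.max_length:
            return "max_length"
    if spec.min_ps is not None:
        if pd.isna(row.get("ps")):
            return "missing ps"
        if not row["ps"] > spec.min_ps:
            return "min_ps"
    if spec.min_stages_expressed is not None or spec.max_stages_expressed is not None:
        if not stage_columns:
            return "missing stage expression"
        thr = spec.stage_threshold()
        n_expressed = int(sum(row[c] > thr for c in stage_columns))
        if spec.min_stages_expressed is not None and n_expressed < spec.min_stages_expressed:
            return "min_stages_expressed"
        if spec.max_stages_expressed is not None and n_expressed > spec.max_stages_expressed:
            return "max_stages_expressed"
    return None


def apply_filter(
    records: pd.DataFrame,
    spec: FilterSpec,
    stage_columns: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Rows surviving every configured predicate of ``spec``.

    ``stage_columns`` names the per-stage mean-TPM columns (required only
    when the spec has stage-count predicates).  Rows missing a required
    field are excluded with a logged reason, never silently dropped.
    """
    stage_columns = list(stage_columns or [])
    keep = []
    for idx, row in records.iterrows():
        reason = _check_record(row, spec, stage_columns)
        if reason is None:
            keep.append(idx)
        elif reason.startswith("missing"):
            logger.warning("record %s excluded by %s: %s", idx, spec.name, reason)
    return records.loc[keep]


def builtin_specs() -> Dict[str, FilterSpec]:
    """The named filter catalog.

    - ``cnt_broad``: 100% novel, 300-10000 bp, PS > 0.95, mean TPM > 5 in
      at least four stages (broadly expressed high-confidence CNTs).
    - ``cnt_specific``: same length/PS/NS cuts, no TPM floor, expressed
      (TPM > 0) in at most two stages (stage-specific CNTs).
    - ``pnt_conserved``: PNTs with PS > 0.8 (conserved-PNT gene set).
    - ``cnt_conserved_expressed``: CNTs with PS > 0.8 expressed in at
      least one stage (heatmap input set).
    """
    return {
        "cnt_broad": FilterSpec(
            name="cnt_broad",
            min_length=300,
            max_length=10000,
            min_ps=0.95,
            min_mean_tpm=5.0,
            min_stages_expressed=4,
            required_class="CNT",
            required_ns=100.0,
        ),
        "cnt_specific": FilterSpec(
            name="cnt_specific",
            min_length=300,
            max_length=10000,
            min_ps=0.95,
            max_stages_expressed=2,
            required_class="CNT",
            required_ns=100.0,
        ),
        "pnt_conserved": FilterSpec(
            name="pnt_conserved",
            min_ps=0.8,
            required_class="PNT",
        ),
        "cnt_conserved_expressed": FilterSpec(
            name="cnt_conserved_expressed",
            min_ps=0.8,
            min_stages_expressed=1,
            required_class="CNT",
        ),
    }
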