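"""Stage-wise expression summarization.

Works on a transcript x sample TPM matrix plus a sample design table
(columns ``stage`` and ``replicate``, sample names as index).  Replicates
are averaged per developmental stage; the E15.5 stage — which originates
from a different study than the rest of the series — is excluded from
stage summaries by default to avoid its batch effect.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

DEFAULT_STAGES = ["E15", "E18", "P0", "P3", "P6", "P9"]
DEFAULT_EXCLUDED_STAGES = {"E15.5"}

#: headline threshold for calling a transcript expressed in a stage (TPM)
DEFAULT_EXPRESSED_TPM = 1.0


def stage_means(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    excluded_stages: Optional[Set[str]] = None,
) -> pd.DataFrame:
    """Mean TPM over replicates per stage (transcripts x stages).

    Stage column order follows first appearance in the design.  A stage
    left with zero samples after exclusion is an error only if it was
    requested; excluded stages are silently dropped.
    """
    if excluded_stages is None:
        excluded_stages = set(DEFAULT_EXCLUDED_STAGES)
    missing = [s for s in matrix.columns if s not in design.index]
    if missing:
        raise ValueError(f"samples missing from design: {missing}")
    stages: List[str] = []
    for sample in matrix.columns:
        stage = design.loc[sample, "stage"]
        if stage not in stages and stage not in excluded_stages:
            stages.append(stage)
    out = {}
    for stage in stages:
        samples = [s for s in matrix.columns if design.loc[s, "stage"] == stage]
        if not samples:
            raise ValueError(f"stage {stage} has no samples")
        out[stage] = matrix[samples].mean(axis=1)
    return pd.DataFrame(out, index=matrix.index)


def class_proportions(
    means: pd.DataFrame,
    classes: Dict[str, str],
    threshold: float = DEFAULT_EXPRESSED_TPM,
) -> pd.DataFrame:
    """Known vs novel (PNT + CNT) percentage per stage among transcripts
    with stage mean TPM strictly above ``threshold``.

    Returns a stage-indexed frame with columns known_pct / novel_pct /
    n_expressed; stages where nothing passes get NaN percentages.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    labels = means.index.to_series().map(classes)
    rows = []
    for stage in means.columns:
        expressed = means.index[means[stage] > threshold]
        n = len(expressed)
        if n == 0:
            rows.append({"stage": stage, "known_pct": np.nan, "novel_pct": np.nan, "n_expressed": 0})
            continue
        n_known = int((labels.loc[expressed] == "known").sum())
        rows.append(
            {
                "stage": stage,
                "known_pct": 100.0 * n_known / n,
                "novel_pct": 100.0 * (n - n_known) / n,
                "n_expressed": n,
            }
        )
    return pd.DataFrame(rows).set_index("stage")


def proportion_sweep(
    means: pd.DataFrame,
    classes: Dict[str, str],
    thresholds: Sequence[float] = (0.5, 1.0, 2.0, 5.0),
) -> pd.DataFrame:
    """class_proportions at each TPM threshold, one row per (threshold, stage)."""
    frames = []
    for thr in thresholds:
        f = class_proportions(means, classes, thr).reset_index()
        f.insert(0, "threshold", thr)
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


def expressed_stages(
    means: pd.DataFrame, threshold: float = DEFAULT_EXPRESSED_TPM
) -> Dict[str, Set[str]]:
    """Per transcript, the set of stages with mean TPM strictly above threshold."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    out: Dict[str, Set[str]] = {}
    passing = means > threshold
    for tid in means.index:
        out[tid] = set(means.columns[passing.loc[tid]])
    return out


def n_stages_expressed(
    means: pd.DataFrame, threshold: float = DEFAULT_EXPRESSED_TPM
) -> pd.Series:
    """Vectorized count of stages above threshold per transcript."""
    return (means > threshold).sum(axis=1)


def max_normalize(means: pd.DataFrame) -> pd.DataFrame:
    """Divide each row by its maximum; all-zero rows stay all-zero."""
    row_max = means.max(axis=1)
    safe = row_max.replace(0, 1.0)
    return means.div(safe, axis=0)


def hierarchical_order(
    profiles: pd.DataFrame,
    metric: str = "correlation",
    linkage: str = "average",
) -> Tuple[List[int], np.ndarray]:
    """Deterministic agglomerative row ordering for heatmap display.

    Defaults mimic the Cluster 3.0 conventions (centered Pearson
    correlation distance, average linkage).  Rows that are constant make
    correlation distance undefined; the whole clustering then falls back
    to Euclidean distance (a warning-level event for the caller to log).
    Returns (leaf order as row positions, scipy linkage matrix).
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 rows to cluster")
    values = profiles.to_numpy(dtype=float)
    used_metric = metric
    if metric == "correlation" and (values.std(axis=1) == 0).any():
        used_metric = "euclidean"
    from scipy.spatial.distance import pdist

    dists = pdist(values, metric=used_metric)
    z = hierarchy.linkage(dists, method=linkage)
    order = hierarchy.leaves_list(z)
    return [int(i) for i in order], z
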