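"""Two-sample distribution comparisons used across the pipeline.

Kolmogorov-Smirnov for novelty-score distribution shifts between stages
and Wilcoxon/Mann-Whitney rank-sum for conservation and expression
differences between transcript classes.  Exact small-sample p-values are
used when n1 * n2 <= 10^4, asymptotic otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence

import numpy as np
import pandas as pd
from scipy import stats

EXACT_LIMIT = 10_000

#: default stage grouping (after the E15.5 batch exclusion); P0 counts as
#: postnatal.
EMBRYONIC_STAGES = ("E15", "E18")
POSTNATAL_STAGES = ("P0", "P3", "P6", "P9")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n1: int
    n2: int
    test_name: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def _method(n1: int, n2: int) -> str:
    return "exact" if n1 * n2 <= EXACT_LIMIT else "asymp"


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided two-sample KS test (D = sup ECDF difference)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty sample")
    res = stats.ks_2samp(x, y, method=_method(len(x), len(y)))
    return TestResult(float(res.statistic), float(res.pvalue), len(x), len(y), "ks")


def ranksum(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney rank-sum with tie correction.

    When every value across both samples is tied the test carries no
    information and p = 1 is returned directly.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty sample")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return TestResult(len(x) * len(y) / 2.0, 1.0, len(x), len(y), "ranksum")
    method = "exact" if _method(len(x), len(y)) == "exact" and not _has_ties(pooled) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(float(res.statistic), float(res.pvalue), len(x), len(y), "ranksum")


def _has_ties(values: np.ndarray) -> bool:
    return len(np.unique(values)) < len(values)


def stage_pair_novelty_scan(
    novelty_by_stage: Dict[str, Sequence[float]],
    embryonic: Sequence[str] = EMBRYONIC_STAGES,
    postnatal: Sequence[str] = POSTNATAL_STAGES,
) -> pd.DataFrame:
    """KS comparison of novelty-score distributions for every stage pair,
    plus a pooled embryonic-vs-postnatal row; medians reported per group.

    Stages with fewer than 2 values are skipped (they cannot anchor an
    ECDF comparison).  Raw p-values are reported (no correction).
    """
    usable = {s: np.asarray(v, float) for s, v in novelty_by_stage.items() if len(v) >= 2}
    rows = []
    stages = list(usable)
    for i, a in enumerate(stages):
        for b in stages[i + 1:]:
            res = ks_two_sample(usable[a], usable[b])
            rows.append(
                {
                    "group1": a,
                    "group2": b,
                    "n1": res.n1,
                    "n2": res.n2,
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                    "median1": float(np.median(usable[a])),
                    "median2": float(np.median(usable[b])),
                }
            )
    emb = np.concatenate([usable[s] for s in embryonic if s in usable]) if any(
        s in usable for s in embryonic
    ) else np.array([])
    post = np.concatenate([usable[s] for s in postnatal if s in usable]) if any(
        s in usable for s in postnatal
    ) else np.array([])
    if len(emb) >= 2 and len(post) >= 2:
        res = ks_two_sample(emb, post)
        rows.append(
            {
                "group1": "embryonic",
                "group2": "postnatal",
                "n1": res.n1,
                "n2": res.n2,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "median1": float(np.median(emb)),
                "median2": float(np.median(post)),
            }
        )
    return pd.DataFrame(rows)
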