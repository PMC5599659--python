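"""Stage-wise expression summaries, normalization and clustering order."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy

from novelscope import (
    class_proportions,
    expressed_stages,
    hierarchical_order,
    max_normalize,
    n_stages_expressed,
    proportion_sweep,
    stage_means,
)


def make_matrix(rows, samples):
    return pd.DataFrame(rows["values"], index=rows["ids"], columns=samples)


@pytest.fixture
def design():
    samples = ["E15_r1", "E15_r2", "E18_r1", "E18_r2", "X_r1"]
    return pd.DataFrame(
        {"stage": ["E15", "E15", "E18", "E18", "E15.5"], "replicate": [1, 2, 1, 2, 1]},
        index=pd.Index(samples, name="sample"),
    )


class TestStageMeans:
    def test_replicates_averaged(self, design):
        matrix = pd.DataFrame(
            [[2.0, 4.0, 1.0, 2.0, 9.0]], index=["t1"], columns=design.index
        )
        means = stage_means(matrix, design)
        assert means.loc["t1", "E15"] == pytest.approx(3.0)
        assert means.loc["t1", "E18"] == pytest.approx(1.5)

    def test_excluded_stage_dropped_by_default(self, design):
        matrix = pd.DataFrame(
            [[1, 1, 1, 1, 99.0]], index=["t1"], columns=design.index
        )
        means = stage_means(matrix, design)
        assert "E15.5" not in means.columns

    def test_excluded_stage_includable(self, design):
        matrix = pd.DataFrame(
            [[1, 1, 1, 1, 99.0]], index=["t1"], columns=design.index
        )
        means = stage_means(matrix, design, excluded_stages=set())
        assert means.loc["t1", "E15.5"] == pytest.approx(99.0)

    def test_three_replicates(self):
        design = pd.DataFrame(
            {"stage": ["P0"] * 3, "replicate": [1, 2, 3]},
            index=pd.Index(["a", "b", "c"], name="sample"),
        )
        matrix = pd.DataFrame([[1.0, 2.0, 6.0]], index=["t1"], columns=design.index)
        assert stage_means(matrix, design).loc["t1", "P0"] == pytest.approx(3.0)


class TestClassProportions:
    @pytest.fixture
    def means(self):
        return pd.DataFrame(
            {"E15": [5.0, 5.0, 5.0, 5.0, 0.1], "E18": [0.1, 0.1, 0.1, 0.1, 0.1]},
            index=[f"t{i}" for i in range(5)],
        )

    def test_known_novel_split(self, means):
        classes = {"t0": "known", "t1": "known", "t2": "known", "t3": "PNT", "t4": "CNT"}
        props = class_proportions(means, classes, threshold=1.0)
        assert props.loc["E15", "known_pct"] == pytest.approx(75.0)
        assert props.loc["E15", "novel_pct"] == pytest.approx(25.0)

    def test_percentages_sum_to_100_when_defined(self, small_bundle):
        means = stage_means(small_bundle.expression, small_bundle.design)
        classes = small_bundle.truth.class_by_transcript
        for thr in (0.5, 1.0, 2.0, 5.0):
            props = class_proportions(means, classes, thr)
            defined = props.dropna()
            np.testing.assert_allclose(
                defined["known_pct"] + defined["novel_pct"], 100.0
            )

    def test_no_transcript_passing_reports_undefined(self, means):
        props = class_proportions(means, {f"t{i}": "known" for i in range(5)}, 1.0)
        assert np.isnan(props.loc["E18", "known_pct"])
        assert props.loc["E18", "n_expressed"] == 0

    def test_sweep_emits_row_per_threshold_per_stage(self, means):
        classes = {f"t{i}": "known" for i in range(5)}
        sweep = proportion_sweep(means, classes, thresholds=(0.5, 1, 2, 5))
        assert len(sweep) == 4 * 2
        assert set(sweep["threshold"]) == {0.5, 1, 2, 5}


class TestExpressedStages:
    def test_direct_threshold_calls(self):
        means = pd.DataFrame(
            [[0.0, 1.2, 0.0, 0.0, 6.0, 0.0]],
            index=["t1"],
            columns=["E15", "E18", "P0", "P3", "P6", "P9"],
        )
        assert expressed_stages(means, 1.0)["t1"] == {"E18", "P6"}
        assert n_stages_expressed(means, 1.0)["t1"] == 2

    def test_monotone_in_threshold(self, small_bundle):
        means = stage_means(small_bundle.expression, small_bundle.design)
        lo = expressed_stages(means, 0.5)
        hi = expressed_stages(means, 5.0)
        for tid in means.index:
            assert hi[tid] <= lo[tid]


class TestMaxNormalize:
    def test_scaling(self):
        means = pd.DataFrame([[1.0, 2.0, 4.0]], index=["t1"], columns=list("abc"))
        out = max_normalize(means)
        np.testing.assert_allclose(out.loc["t1"], [0.25, 0.5, 1.0])

    def test_all_zero_row_stays_zero(self):
        means = pd.DataFrame([[0.0, 0.0]], index=["t1"], columns=list("ab"))
        assert (max_normalize(means) == 0).all().all()

    def test_idempotent(self, small_bundle):
        means = stage_means(small_bundle.expression, small_bundle.design)
        once = max_normalize(means)
        pd.testing.assert_frame_equal(once, max_normalize(once))

    def test_single_stage_maps_to_one(self):
        means = pd.DataFrame([[5.0]], index=["t1"], columns=["P0"])
        assert max_normalize(means).iloc[0, 0] == 1.0


def naive_average_linkage(points):
    """O(n^3) reference agglomeration with average linkage on Euclidean
    distances, emitting a scipy-style linkage matrix."""
    points = np.asarray(points, float)
    n = len(points)
    clusters = {i: [i] for i in range(n)}
    next_id = n
    z = []
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                d = np.mean(
                    [
                        np.linalg.norm(points[i] - points[j])
                        for i in clusters[a]
                        for j in clusters[b]
                    ]
                )
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        z.append([a, b, d, len(clusters[a]) + len(clusters[b])])
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return np.array(z)


class TestHierarchicalOrder:
    def test_identical_rows_merge_at_zero(self):
        profiles = pd.DataFrame([[1.0, 2.0], [1.0, 2.0]], index=["a", "b"])
        _, z = hierarchical_order(profiles, metric="euclidean")
        assert z[0, 2] == pytest.approx(0.0)

    def test_identical_pair_merges_before_outlier(self):
        profiles = pd.DataFrame(
            [[1.0, 2.0, 3.0], [9.0, 9.0, 9.0], [1.0, 2.0, 3.0]], index=list("abc")
        )
        _, z = hierarchical_order(profiles, metric="euclidean")
        assert sorted(z[0, :2]) == [0, 2]

    def test_matches_naive_agglomeration_oracle(self):
        rng = np.random.default_rng(5)
        points = rng.normal(size=(5, 3))
        profiles = pd.DataFrame(points, index=[f"t{i}" for i in range(5)])
        order, z = hierarchical_order(profiles, metric="euclidean", linkage="average")
        z_ref = naive_average_linkage(points)
        np.testing.assert_allclose(z[:, 2], z_ref[:, 2], rtol=1e-10)
        assert order == list(hierarchy.leaves_list(z_ref))

    def test_constant_rows_fall_back_from_correlation(self):
        profiles = pd.DataFrame(
            [[1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [3.0, 2.0, 1.0]], index=list("abc")
        )
        order, _ = hierarchical_order(profiles, metric="correlation")
        assert sorted(order) == [0, 1, 2]

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            hierarchical_order(pd.DataFrame([[1.0, 2.0]], index=["a"]))


def test_planted_expression_ordering_recovered(small_bundle):
    """Stage-wise rank-sum comparisons recover PNT > known > CNT."""
    from novelscope import ranksum

    means = stage_means(small_bundle.expression, small_bundle.design)
    truth = small_bundle.truth.class_by_transcript
    stage = means.columns[0]
    groups = {
        label: means.loc[[t for t in means.index if truth[t] == label], stage]
        for label in ("known", "PNT", "CNT")
    }
    assert float(np.median(groups["PNT"])) > float(np.median(groups["known"]))
    assert ranksum(groups["PNT"], groups["CNT"]).p_value < 1e-4
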