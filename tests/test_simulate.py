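"""Determinism and planted-truth guarantees of the synthetic generator."""

import numpy as np
import pytest

from novelscope import (
    SimulationConfig,
    expressed_stages,
    simulate_bundle,
    stage_means,
    write_bundle,
)
from novelscope.simulate import (
    build_orf_sequence,
    generate_annotation,
    generate_assembled,
    generate_conservation,
)


class TestDeterminism:
    def test_same_seed_byte_identical_outputs(self, tmp_path):
        config = SimulationConfig(seed=3, n_known=10, n_pnt=10, n_cnt=10, n_genes=15)
        a = write_bundle(simulate_bundle(config), tmp_path / "a")
        b = write_bundle(simulate_bundle(config), tmp_path / "b")
        for name in a:
            assert a[name].read_bytes() == b[name].read_bytes(), name

    def test_different_seed_differs(self, tmp_path):
        c1 = SimulationConfig(seed=3, n_known=5, n_pnt=5, n_cnt=5, n_genes=10)
        c2 = SimulationConfig(seed=4, n_known=5, n_pnt=5, n_cnt=5, n_genes=10)
        p1 = write_bundle(simulate_bundle(c1), tmp_path / "a")
        p2 = write_bundle(simulate_bundle(c2), tmp_path / "b")
        assert p1["assembled_gtf"].read_bytes() != p2["assembled_gtf"].read_bytes()


class TestAnnotation:
    def test_empty_config_gives_empty_annotation(self):
        config = SimulationConfig(seed=1, n_genes=0)
        ann, models, _ = generate_annotation(config)
        assert models == [] and ann.union_length() == 0

    def test_generated_models_satisfy_invariants(self):
        config = SimulationConfig(seed=1, n_genes=25)
        _, models, _ = generate_annotation(config)
        assert len(models) == 25
        for m in models:
            assert m.exonic_length > 0
            for a, b in zip(m.exons, m.exons[1:]):
                assert a.end <= b.start  # sorted, non-overlapping


@pytest.fixture(scope="module")
def planted():
    config = SimulationConfig(seed=6, n_known=20, n_pnt=40, n_cnt=40, n_genes=30)
    ann, _, alloc = generate_annotation(config)
    assembled, truth = generate_assembled(config, ann, alloc)
    return config, ann, assembled, truth


class TestAssembled:
    def test_planted_overlap_fraction_is_exact(self, planted):
        from novelscope import exonic_overlap

        _, ann, assembled, truth = planted
        for t in assembled:
            frac = exonic_overlap(t, ann) / t.exonic_length
            assert frac == pytest.approx(truth.overlap_fraction[t.transcript_id], abs=1e-12)

    def test_pnt_scores_strictly_inside_zero_seventy(self, planted):
        _, _, assembled, truth = planted
        for t in assembled:
            if truth.class_by_transcript[t.transcript_id] == "PNT":
                ns = (1 - truth.overlap_fraction[t.transcript_id]) * 100
                assert 0 < ns < 70

    def test_cnt_scores_at_least_seventy(self, planted):
        _, _, assembled, truth = planted
        cnt_ns = [
            (1 - truth.overlap_fraction[t.transcript_id]) * 100
            for t in assembled
            if truth.class_by_transcript[t.transcript_id] == "CNT"
        ]
        assert all(ns >= 70 for ns in cnt_ns)
        assert any(ns == 100 for ns in cnt_ns)
        assert any(ns < 100 for ns in cnt_ns)  # the planted partial minority

    def test_requires_annotation_when_planting_known(self):
        from novelscope import build_annotation_set

        config = SimulationConfig(seed=1, n_known=1, n_pnt=0, n_cnt=0)
        with pytest.raises(ValueError, match="non-empty annotation"):
            generate_assembled(config, build_annotation_set([]))


class TestConservation:
    def test_class_medians_near_configured_means(self, small_bundle):
        from novelscope import transcript_conservation

        by_class = {"known": [], "PNT": [], "CNT": []}
        for t in small_bundle.assembled:
            rec = transcript_conservation(t, small_bundle.conservation)
            by_class[small_bundle.truth.class_by_transcript[t.transcript_id]].append(
                rec.transcript_score
            )
        for label, target in (("known", 0.67), ("PNT", 0.76), ("CNT", 0.13)):
            assert float(np.median(by_class[label])) == pytest.approx(target, abs=0.05)

    def test_degenerate_zero_mean_gives_all_zero(self):
        config = SimulationConfig(
            seed=2, n_known=0, n_pnt=0, n_cnt=3, n_genes=5,
            class_conservation_means={"known": 0.0, "PNT": 0.0, "CNT": 0.0},
        )
        ann, _, alloc = generate_annotation(config)
        assembled, truth = generate_assembled(config, ann, alloc)
        track = generate_conservation(config, assembled, truth)
        for t in assembled:
            assert all(v == 0.0 for v in track.scores_in(t.exons[0]))


class TestExpressionPlanting:
    def test_stage_specific_cnts_expressed_in_exactly_one_stage(self, small_bundle):
        means = stage_means(small_bundle.expression, small_bundle.design)
        calls = expressed_stages(means, 1.0)
        truth = small_bundle.truth
        planted_specific = [
            t for t, stages in truth.expressed_pattern.items()
            if truth.class_by_transcript[t] == "CNT" and len(stages) == 1
        ]
        assert planted_specific
        for tid in planted_specific:
            assert calls[tid] == set(truth.expressed_pattern[tid])

    def test_all_stage_cnts_expressed_everywhere(self, small_bundle):
        means = stage_means(small_bundle.expression, small_bundle.design)
        calls = expressed_stages(means, 1.0)
        truth = small_bundle.truth
        planted_all = [
            t for t, stages in truth.expressed_pattern.items()
            if truth.class_by_transcript[t] == "CNT" and len(stages) == 6
        ]
        assert planted_all
        for tid in planted_all:
            assert calls[tid] == set(small_bundle.config.stages)

    def test_matrix_nonnegative_with_unique_labels(self, small_bundle):
        m = small_bundle.expression
        assert (m.values >= 0).all()
        assert m.index.is_unique and m.columns.is_unique


class TestSpliceCounts:
    def test_true_half_with_equal_lengths_estimates_half(self):
        from novelscope import psi as psi_fn

        config = SimulationConfig(
            seed=9,
            psi_truth={"SE_half": {s: 0.5 for s in SimulationConfig().stages}},
            read_depth=100_000,
        )
        from novelscope.simulate import generate_splice_counts

        _, counts, _ = generate_splice_counts(config)
        for c in counts["SE_half"]:
            est = psi_fn(c)
            assert est == pytest.approx(0.5, abs=0.01)

    def test_true_one_never_emits_skip_reads(self):
        from novelscope.simulate import generate_splice_counts

        config = SimulationConfig(
            seed=9,
            psi_truth={"SE_full": {s: 1.0 for s in SimulationConfig().stages}},
        )
        _, counts, _ = generate_splice_counts(config)
        assert all(c.skip_reads == 0 for c in counts["SE_full"])


class TestOrfConstruction:
    def test_planted_offsets_are_frame_consistent(self):
        rng = np.random.default_rng(0)
        for strand in "+-":
            for pad in range(3):
                seq, orf = build_orf_sequence(rng, 30, strand, pad)
                assert orf.frame == orf.start_offset % 3
                assert (orf.end_offset - orf.start_offset) == 90
                sense = seq if strand == "+" else _revcomp(seq)
                assert sense[orf.start_offset : orf.start_offset + 3] == "ATG"
                stop = sense[orf.end_offset : orf.end_offset + 3]
                assert stop == "TAA"


def _revcomp(s):
    return s.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]
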