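import pytest

from novelscope import SimulationConfig, simulate_bundle
from novelscope.models import GenomicInterval, TranscriptModel


@pytest.fixture(scope="session")
def small_bundle():
    """One modest simulation shared across tests (seed fixed)."""
    config = SimulationConfig(seed=11, n_known=30, n_pnt=30, n_cnt=30, n_genes=30)
    return simulate_bundle(config)


@pytest.fixture
def make_transcript():
    def _make(exon_pairs, chrom="chr1", strand=".", tid="t1", source="assembled"):
        exons = [GenomicInterval(chrom, s, e, strand) for s, e in exon_pairs]
        return TranscriptModel(tid, f"g_{tid}", chrom, strand, exons, source=source)

    return _make


def brute_force_overlap(transcript, reference_exons):
    """Per-base membership oracle: count exonic bases of the transcript
    covered by any reference exon (chromosome-aware, strand-agnostic)."""
    ref_bases = set()
    for chrom, start, end in reference_exons:
        for b in range(start, end):
            ref_bases.add((chrom, b))
    count = 0
    for e in transcript.exons:
        for b in range(e.start, e.end):
            if (transcript.chrom, b) in ref_bases:
                count += 1
    return count
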