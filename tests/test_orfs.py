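"""Six-frame ORF detection against translation/enumeration oracles."""

import numpy as np
import pytest
from Bio.Seq import Seq

from novelscope import find_orfs, longest_orf, revcomp
from novelscope.orfs import OrfHit, STOP_CODONS

STARTS_ALL = {"ATG", "CTG", "GTG", "TTG"}


def oracle_orfs(sequence, start_set, min_codons, require_stop=True):
    """Enumeration oracle: for each of the six frames list every in-frame
    start codon, close it at the next in-frame stop, and keep only the
    first start of each stop-delimited segment."""
    hits = set()
    for strand, seq in (("+", sequence), ("-", revcomp(sequence))):
        for frame in range(3):
            codons = [
                (i, seq[i : i + 3])
                for i in range(frame, len(seq) - 2, 3)
            ]
            stops = [i for i, c in codons if "N" not in c and c in STOP_CODONS]
            starts = [i for i, c in codons if "N" not in c and c in start_set]
            prev_stop = frame - 3
            for stop in stops + ([None] if not require_stop else []):
                seg_starts = [
                    s for s in starts
                    if s > prev_stop and (stop is None or s < stop)
                ]
                if seg_starts:
                    s = seg_starts[0]
                    end = stop if stop is not None else frame + 3 * ((len(seq) - frame) // 3)
                    n = (end - s) // 3
                    if n >= min_codons:
                        hits.add((strand, frame, s, end))
                if stop is not None:
                    prev_stop = stop
    return hits


def translation_oracle(sequence, min_codons):
    """Canonical-start oracle via Biopython translation: first M after
    each stop in every frame."""
    hits = set()
    for strand, seq in (("+", sequence), ("-", revcomp(sequence))):
        for frame in range(3):
            trimmed = seq[frame : frame + 3 * ((len(seq) - frame) // 3)]
            protein = str(Seq(trimmed).translate())
            pos = 0
            for chunk in protein.split("*")[:-1]:
                m = chunk.find("M")
                if m >= 0 and len(chunk) - m >= min_codons:
                    start = frame + 3 * (pos + m)
                    end = frame + 3 * (pos + len(chunk))
                    hits.add((strand, frame, start, end))
                pos += len(chunk) + 1
    return hits


def as_tuples(hits):
    return {(h.strand, h.frame, h.start_offset, h.end_offset) for h in hits}


class TestFindOrfs:
    def test_minimal_atg_orf(self):
        hits = find_orfs("ATGAAATAA", min_codons=1, start_set={"ATG"})
        plus = [h for h in hits if h.strand == "+"]
        assert len(plus) == 1
        h = plus[0]
        assert (h.frame, h.start_offset, h.end_offset, h.length_codons) == (0, 0, 6, 2)
        assert h.start_codon == "ATG"

    def test_reverse_strand_hit(self):
        # revcomp("TTACATGGGTTA") contains an ORF on the minus strand
        seq = "TTACATGTA"  # revcomp = TACATGTAA -> ATG TAA at offset 3
        hits = find_orfs(seq, min_codons=1, start_set={"ATG"})
        minus = [h for h in hits if h.strand == "-"]
        assert minus
        h = minus[0]
        assert revcomp(seq)[h.start_offset : h.start_offset + 3] == "ATG"

    def test_start_set_contract(self):
        seq = "CTGAAATAA"
        assert find_orfs(seq, start_set={"ATG"}, min_codons=1) == [] or all(
            h.strand == "-" for h in find_orfs(seq, start_set={"ATG"}, min_codons=1)
        )
        hits = [h for h in find_orfs(seq, start_set=STARTS_ALL, min_codons=1)
                if h.strand == "+"]
        assert len(hits) == 1
        assert hits[0].start_codon == "CTG"
        assert hits[0].length_codons == 2

    def test_empty_sequence(self):
        assert find_orfs("") == []

    def test_n_codons_never_match(self):
        # TAN is not a stop, ANG not a start
        hits = find_orfs("ATGNNNTAA", start_set={"ATG"}, min_codons=1)
        plus = [h for h in hits if h.strand == "+"]
        assert plus and plus[0].length_codons == 2  # ATG + NNN, stop at TAA

    def test_open_ended_orf_only_without_require_stop(self):
        seq = "ATGAAAAAA"  # no stop
        assert find_orfs(seq, start_set={"ATG"}, min_codons=1) == []
        hits = find_orfs(seq, start_set={"ATG"}, min_codons=1, require_stop=False)
        plus = [h for h in hits if h.strand == "+"]
        assert plus and not plus[0].has_stop

    def test_all_starts_emits_nested(self):
        seq = "ATGATGAAATAA"
        first_only = [h for h in find_orfs(seq, start_set={"ATG"}, min_codons=1)
                      if h.strand == "+"]
        nested = [h for h in find_orfs(seq, start_set={"ATG"}, min_codons=1,
                                       all_starts=True) if h.strand == "+"]
        assert len(first_only) == 1 and first_only[0].start_offset == 0
        assert {h.start_offset for h in nested} == {0, 3}

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_enumeration_oracle_noncanonical(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=1000))
        ours = find_orfs(seq, start_set=STARTS_ALL, min_codons=10)
        assert as_tuples(ours) == oracle_orfs(seq, STARTS_ALL, 10)

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_translation_oracle_canonical(self, seed):
        rng = np.random.default_rng(100 + seed)
        seq = "".join(rng.choice(list("ACGT"), size=1000))
        ours = find_orfs(seq, start_set={"ATG"}, min_codons=5)
        assert as_tuples(ours) == translation_oracle(seq, 5)

    def test_no_internal_stops_ever(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), size=600))
            for h in find_orfs(seq, min_codons=5):
                scan = seq if h.strand == "+" else revcomp(seq)
                codons = [scan[i:i + 3] for i in range(h.start_offset, h.end_offset, 3)]
                assert not any(c in STOP_CODONS for c in codons)

    def test_strand_symmetry(self):
        rng = np.random.default_rng(9)
        seq = "".join(rng.choice(list("ACGT"), size=900))
        fwd = as_tuples(find_orfs(seq, min_codons=8))
        rev = as_tuples(find_orfs(revcomp(seq), min_codons=8))
        flipped = {("+" if s == "-" else "-", f, a, b) for (s, f, a, b) in fwd}
        assert flipped == rev

    def test_orf_count_monotone_in_min_codons(self):
        rng = np.random.default_rng(17)
        seqs = ["".join(rng.choice(list("ACGT"), size=800)) for _ in range(10)]
        counts = []
        for mc in (5, 10, 20, 40):
            counts.append(sum(bool(find_orfs(s, min_codons=mc)) for s in seqs))
        assert counts == sorted(counts, reverse=True)


class TestLongestOrf:
    def make(self, strand, frame, start, n):
        return OrfHit("t", strand, frame, start, start + 3 * n, "ATG", n)

    def test_picks_longest(self):
        assert longest_orf([self.make("+", 0, 0, 10), self.make("-", 1, 3, 40)]).length_codons == 40

    def test_empty_returns_none(self):
        assert longest_orf([]) is None

    def test_tie_break_plus_strand_lower_frame(self):
        a = self.make("-", 1, 0, 40)
        b = self.make("+", 0, 0, 40)
        assert longest_orf([a, b]) is b
        c = self.make("+", 2, 0, 40)
        assert longest_orf([b, c]) is b


def test_planted_orfs_recovered_and_decoys_clean(small_bundle):
    truth = small_bundle.truth
    for tid, planted in truth.orfs.items():
        hits = find_orfs(small_bundle.sequences[tid], transcript_id=tid)
        if planted is None:
            assert hits == []
        else:
            best = longest_orf(hits)
            assert (best.strand, best.frame, best.start_offset,
                    best.end_offset, best.length_codons) == (
                planted.strand, planted.frame, planted.start_offset,
                planted.end_offset, planted.length_codons)
            assert best.start_codon == "ATG"
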