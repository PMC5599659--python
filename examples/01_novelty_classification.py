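"""Score assembled transcripts against a reference annotation and classify
them as known / partially novel (PNT) / completely novel (CNT).

The novelty score NS = (1 - overlap/length) * 100 measures the fraction of
a transcript's exonic sequence absent from the annotation; the 70% cut
separates PNTs from CNTs.
"""

from collections import Counter

import novelscope as ns

config = ns.SimulationConfig(seed=7, n_known=30, n_pnt=30, n_cnt=30, n_genes=40)
bundle = ns.simulate_bundle(config)

records = ns.score_transcripts(bundle.assembled, bundle.annotation)
print(ns.novelty_table(records).head(8).to_string(index=False))

counts = Counter(r.class_label for r in records)
recovered = sum(
    r.class_label == bundle.truth.class_by_transcript[r.transcript_id] for r in records
)
print(f"\nclass counts: {dict(counts)}")
print(f"planted labels recovered: {recovered}/{len(records)}")
# NS = 0 for exact annotation copies, 100 for transcripts in annotation-free
# regions, and in between for transcripts straddling annotated exons; a
# perfect recovery confirms classification is exact on planted overlaps.
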