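"""Aggregate per-base conservation scores (phastCons-style, in [0,1]) to
exon means and then to an unweighted per-transcript score PS.

In the lens study the three transcript classes separate cleanly: PNTs are
the most conserved (median ~0.76), then known transcripts (~0.67), with
CNTs far lower (~0.13); the synthetic track plants the same levels.
"""

import numpy as np

import novelscope as ns

config = ns.SimulationConfig(seed=7, n_known=100, n_pnt=100, n_cnt=100, n_genes=60)
bundle = ns.simulate_bundle(config)

by_class = {"known": [], "PNT": [], "CNT": []}
for t in bundle.assembled:
    record = ns.transcript_conservation(t, bundle.conservation)
    by_class[bundle.truth.class_by_transcript[t.transcript_id]].append(
        record.transcript_score
    )

for label, scores in by_class.items():
    print(f"{label:>6}: median PS = {np.median(scores):.3f}  (n = {len(scores)})")

test = ns.ranksum(by_class["PNT"], by_class["CNT"])
print(f"\nPNT vs CNT rank-sum p = {test.p_value:.2e}")
# A tiny p-value means conservation alone distinguishes the partially novel
# class (which overlaps real annotated exons) from fully novel calls.
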