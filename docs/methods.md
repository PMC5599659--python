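# Methods

This note documents the models, conventions and design choices behind
`novelscope`, and what the synthetic-data generator does and does not
emulate.

## Coordinates and formats

All internal coordinates are 0-based half-open, so `length = end − start`.
GTF input (1-based inclusive) is shifted on read (`start − 1`) and shifted
back on write; a GTF → internal → GTF round trip is exact. bedGraph and
BED are half-open on disk and pass through unshifted. The bundled
published coordinate tables already satisfy `end − start = length` for
every row, so their printed pairs are ingested as-is into half-open
intervals. Strand `.` is a first-class *unknown* value — assemblers emit
it for mono-exonic models — and is never coerced to `+`.

## Novelty score and classification

For an assembled transcript, overlap is counted per exonic base against
the annotation's merged exonic union (no double counting), and
NS = (1 − overlap/length) × 100. Two deliberate choices:

- **Denominator = exonic (mature) length** by default. The published
  high-confidence lists print lengths equal to `end − start` of
  single-exon entries, consistent with exonic length; a `span` mode using
  the genomic footprint is provided for sensitivity analysis.
- **Strand-agnostic overlap** by default, because novel models routinely
  carry strand `.`; a same-strand mode exists.

*Known* requires an exact exon-chain match (all boundaries equal) against
some reference transcript — stricter than NS = 0, which a contained
fragment also achieves; such fragments are labeled PNT. The 70% class
boundary is inclusive to CNT (NS ≥ 70 → CNT).

## Conservation aggregation

Exon score = arithmetic mean of per-base scores with data; transcript
score PS = *unweighted* mean of exon means (a length-weighted variant is
available behind a flag). Exons with no data are excluded rather than
imputed as zero — zero-imputation would systematically depress scores for
transcripts in sparsely scored regions, which is exactly where completely
novel transcripts live. `covered_fraction` reports how much exonic
sequence had data so users can filter low-coverage records. On bedGraph
overlap the last record wins (documented, deterministic).

## Stage expression

Stage values are arithmetic means over biological replicates. The E15.5
stage, which originates from a different study than the rest of the
series, is excluded from stage summaries by default (batch effect) and
includable by flag. "Expressed" defaults to mean TPM > 1 (the headline
threshold; the proportion sweep also reports 0.5/2/5). Max-normalization
divides each transcript's stage vector by its maximum, leaving all-zero
rows untouched; it is idempotent. Heatmap ordering uses agglomerative
clustering with centered-correlation distance and average linkage
(Cluster 3.0 conventions); constant rows make correlation distance
undefined, in which case the clustering falls back to Euclidean distance.

## High-confidence filters

Predicate strictness: length bounds inclusive, PS and TPM cuts strict.
The two published CNT filters are shipped as named specs: `cnt_broad`
(300–10000 bp, PS > 0.95, NS = 100, mean TPM > 5 in ≥ 4 stages) and
`cnt_specific` (same length/PS/NS, no TPM floor, expressed — TPM > 0 —
in ≤ 2 stages). Stage counting uses the spec's TPM floor when one is set
and bare positivity otherwise; with these settings the two filters are
provably disjoint. Two conservation cuts appear in the source material
for "highly conserved" novel sets (PS > 0.76 and PS > 0.8); both are
shipped as named specs (`pnt_conserved`, `cnt_conserved_expressed` use
0.8) rather than silently reconciled. Records missing a required field
are excluded with a logged reason, never silently dropped.

## ORF detection

Six frames = three codon offsets × both strands (reverse via reverse
complement; minus-strand offsets refer to the reverse-complemented
sequence). Within a frame the sequence is segmented at stop codons
(TAA/TAG/TGA); one ORF opens at the first start codon of each segment and
closes at the segment's stop (`all_starts` additionally emits nested
starts). Codons containing N match nothing. Defaults — start set
ATG + CTG/GTG/TTG (the near-cognate NTG family), minimum 25 codons,
3′-open ORFs excluded — are package choices, all exposed as parameters.
Length counts the start codon and excludes the stop.

## PSI and the significance screen

ψ = (I/ℓI) / (I/ℓI + S/ℓS); undefined at I = S = 0 (reported NA).
Effective lengths default to the junction-count form (ℓI = 2, ℓS = 1 for
skipped exons; retained introns use a body-length-flavored ℓI = 3),
overridable per event. Stage ψ is the unweighted replicate mean; Δψ and
fold changes compare stages, with the fold undefined from ψ = 0.

The screen for differential events is deliberately simple: Fisher's exact
test on stage-pooled (I, S) 2×2 tables with Benjamini–Hochberg control at
q < 0.01. It is labeled a *screen* in all outputs: it ignores replicate
structure and read-length modeling, and is not a reimplementation of
hierarchical replicate-aware splicing models. Degenerate tables (a zero
margin) receive q = 1. BED export encodes ψ as `round(ψ × 1000)` in the
score column, with name `event|type|stage|ψ`.

## Distribution statistics

KS (two-sided) and Mann–Whitney rank-sum delegate to scipy; exact
small-sample p-values are used when n₁·n₂ ≤ 10⁴ (rank-sum additionally
requires no ties), asymptotic otherwise. The stage-pair scan compares
novelty-score distributions for every stage pair plus pooled embryonic
({E15, E18}) vs postnatal ({P0, P3, P6, P9}) groups — P0 is grouped as
postnatal — reporting medians and raw p-values (no correction across the
scan, matching how such scans are conventionally reported).

## Synthetic data: what it emulates, and what it does not

The generator builds a toy genome (3 chromosomes of 1 Mb by default, each
split into an annotation zone and an annotation-free zone; the genome
grows automatically if space runs out) and plants:

- **Classes with exact overlaps.** Known = exact chain copies. PNTs are
  single exons covering exactly *o* bases of an annotated first exon and
  extending into the upstream intergenic gap, with o/L > 0.3 enforced at
  the base level (no rounding drift), so NS < 70 exactly. CNTs sit in
  annotation-free space (NS = 100), with a 10% minority planted at
  0 < o/L ≤ 0.3 (70 ≤ NS < 100).
- **Conservation** per base from Beta(mκ, (1−m)κ) with class means
  m = 0.67/0.76/0.13 (the published class medians) and concentration
  κ = 10 — Beta keeps the bounded [0, 1] support of phastCons-style
  scores. Degenerate means (0 or 1) produce constants.
- **Expression**: log-normal TPM with class log-means ordering
  PNT > known > CNT, stage noise σ = 0.3, and replicate noise σ = 0.25
  truncated at ±0.4 in log space. Planted CNT patterns (10%
  stage-specific, 47% all-stage, mirroring the published proportions) are
  hard guarantees at the TPM > 1 call: pattern stages are floored at
  2 TPM, off-pattern stages are exactly 0, and the truncation ensures
  replicate means cannot cross the threshold.
- **Junction counts**: I ~ Binomial(depth, g(ψ)) with
  g = ψℓI/(ψℓI + (1−ψ)ℓS), making the density-ratio estimator consistent.
  Default depth 10⁵; default events include an Srsf2-like skipped exon
  rising 0.0535 → 0.245 across stages.
- **Sequences**: decoys are "stop-salted" — a 24-nt salt unit containing
  a stop in every forward frame class and (via reverse complement) every
  reverse frame class is inserted every 42 nt, capping stop-free runs at
  14 codons in all six frames, below the 25-codon floor, regardless of
  the random filler. Planted ORFs use a codon cycle (AAC/TAC/CTA/ACT)
  that is clean in the sense frame but places a stop within 12 nt in each
  of the other five frames, so the planted ORF is the unique hit and is
  reported at exactly the planted offsets.
- **Novelty-shift sampling** for power studies: postnatal scores
  log-normal with median 9.04 and σ = 0.5 (log-scale), embryonic an
  independent draw shifted by +1.85 (the published median gap), clipped
  to [0, 100].

Not emulated: read-level (FASTQ) data, alignment artifacts, overlapping
gene models, multi-isoform loci sharing exons, chromosome-scale
conservation tracks, and biological correlation between conservation,
expression and splicing. Passing tests therefore demonstrate the
*correctness of the computations* on inputs with known truth, not the
biological findings themselves, which depend on real sequencing data.

## Problem sizes and numerics

The test and acceptance runs use 1000 synthetic transcripts (≈ 334 per
class), 100 KS power replicates at n = 500 per group, 1000 null screen
events at pooled depth 400, and 100 random 1-kb sequences for the ORF
oracle — sizes at which all stochastic properties are stable across
seeds while brute-force per-base and enumeration oracles stay feasible.
Novelty scores are exact rationals times 100 (asserted to 1e-9);
conservation means are plain arithmetic means; clustering ties are broken
by input order via the scipy linkage conventions.

## Known limitations

- The exact-test screen is intentionally weaker than replicate-aware
  splicing models; it controls FDR on pooled counts only.
- `known` status requires exact boundary equality; assemblers that
  jitter terminal exon ends will push true re-assemblies into the PNT
  class (NS ≈ 0), which the strict definition makes visible rather than
  hiding.
- Conservation aggregation ignores exon weighting by default by design;
  for transcripts with very uneven exon lengths the two definitions can
  differ noticeably (the flag exists for exactly that comparison).
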