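"""Bundled reference tables from the published mouse-lens developmental
RNA-seq study this pipeline models.

These small tables are used as fixtures and sanity anchors:

- ``lens_rnaseq_runs``: SRA run metadata (stage, read type/length, read
  and base counts, alignment rate) for the E15-P9 series;
- ``highconf_cnt_broad`` / ``highconf_cnt_specific``: the two published
  high-confidence completely-novel-transcript lists (genomic mm10
  coordinates, length, strand, phastCons score PS, novelty score NS)
  produced by the broadly-expressed and stage-specific filters.

Headline counts from the same study, used for ratio checks:
90689 assembled transcripts of which 22523 were novel; of 654 conserved
100%-novel transcripts scanned, 202 carried predicted ORFs and 121 had
at least one Pfam domain hit.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

HEADLINE_COUNTS = {
    "total_transcripts": 90689,
    "novel_transcripts": 22523,
    "annotated_transcripts": 68166,
    "pnt_transcripts": 13207,
    "cnt_transcripts": 9316,
    "orf_scanned_cnts": 654,
    "orf_positive_cnts": 202,
    "pfam_hit_cnts": 121,
}

#: published Srsf2 skipped-exon PSI pair (E15 -> P9)
SRSF2_PSI = {"E15": 0.0535, "P9": 0.245}


def _load(name: str) -> pd.DataFrame:
    with resources.files("novelscope.data").joinpath(name).open() as handle:
        return pd.read_csv(handle, sep="\t")


def lens_rnaseq_runs() -> pd.DataFrame:
    """RNA-seq run metadata; base_count = n_reads * mates * read_length."""
    return _load("lens_rnaseq_runs.tsv")


def highconf_cnt_broad() -> pd.DataFrame:
    """Published broadly-expressed high-confidence CNT list (25 rows)."""
    return _load("highconf_cnt_broad.tsv")


def highconf_cnt_specific() -> pd.DataFrame:
    """Published stage-specific high-confidence CNT list (19 rows)."""
    return _load("highconf_cnt_specific.tsv")


def mate_count(read_type: str) -> int:
    if read_type == "PE":
        return 2
    if read_type == "SE":
        return 1
    raise ValueError(f"unknown read type {read_type!r}")


def expected_base_counts(runs: pd.DataFrame) -> pd.Series:
    """reads x mate-count x read-length accounting for each run."""
    mates = runs["read_type"].map(mate_count)
    return runs["n_reads"] * mates * runs["read_length"]


def parse_coordinates(coord: str) -> tuple:
    """Split a "chrom:start-end" coordinate string (half-open)."""
    chrom, rest = coord.split(":")
    start, end = rest.split("-")
    return chrom, int(start), int(end)
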