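"""End-to-end orchestration: inputs on disk in, result tables out.

``run_full`` chains the stages in a fixed order — novelty scoring,
conservation, stage expression profiles, high-confidence filters, ORF
scan, PSI matrix, BED tracks, distribution statistics — writing one TSV
(or BED) per stage plus a flat-text manifest recording the package
version, seed, input checksums and every output produced.  Stages whose
inputs are absent (e.g. no conservation track) are skipped with an
explicit notice; a stage failure halts the run, renaming any partial
output with a ``.partial`` suffix.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd

from . import __version__
from . import expression as expr
from . import filters as hcf
from . import io_formats as io
from . import novelty as nov
from . import splicing as spl
from . import stage_stats as sst
from .conservation import conservation_table
from .orfs import orf_table

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    annotation_gtf: Path
    assembled_gtf: Path
    out_dir: Path
    conservation_bedgraph: Optional[Path] = None
    expression_tsv: Optional[Path] = None
    design_tsv: Optional[Path] = None
    counts_tsv: Optional[Path] = None
    events_tsv: Optional[Path] = None
    sequences_fasta: Optional[Path] = None
    cnt_cutoff: float = 70.0
    tpm_threshold: float = 1.0
    novelty_tpm_threshold: float = 5.0  # stage novelty-scan expression cut
    filter_specs: Sequence[str] = ("cnt_broad", "cnt_specific")
    excluded_stages: frozenset = frozenset({"E15.5"})
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("annotation_gtf", "assembled_gtf"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p}")


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def read_event_counts(path: Path) -> Dict[str, List[spl.EventCounts]]:
    frame = pd.read_csv(path, sep="\t")
    counts: Dict[str, List[spl.EventCounts]] = {}
    for _, row in frame.iterrows():
        counts.setdefault(row["event_id"], []).append(
            spl.EventCounts(
                sample=row["sample"],
                inclusion_reads=int(row["inclusion_reads"]),
                skip_reads=int(row["skip_reads"]),
                inclusion_length=int(row["inclusion_length"]),
                skip_length=int(row["skip_length"]),
            )
        )
    return counts


def read_events(path: Path) -> Dict[str, spl.SpliceEvent]:
    from .models import GenomicInterval

    frame = pd.read_csv(path, sep="\t")
    events = {}
    for _, row in frame.iterrows():
        chrom = row["chrom"]
        events[row["event_id"]] = spl.SpliceEvent(
            event_id=row["event_id"],
            event_type=row["event_type"],
            gene=row["gene"],
            target=GenomicInterval(chrom, int(row["target_start"]), int(row["target_end"]), row["strand"]),
            flanks=(
                GenomicInterval(chrom, int(row["up_start"]), int(row["up_end"]), row["strand"]),
                GenomicInterval(chrom, int(row["down_start"]), int(row["down_end"]), row["strand"]),
            ),
            strand=row["strand"],
        )
    return events


def run_full(config: RunConfig) -> Dict[str, Path]:
    """Run every stage the configured inputs allow; return {output: path}."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: Dict[str, Path] = {}
    notices: List[str] = []
    current_partial: Optional[Path] = None

    def write_tsv(frame: pd.DataFrame, name: str, index: bool = False) -> Path:
        nonlocal current_partial
        path = out_dir / name
        current_partial = path
        frame.to_csv(path, sep="\t", index=index)
        current_partial = None
        return path

    def run_stage(stage_name, fn):
        nonlocal current_partial
        logger.info("[%s] running", stage_name)
        try:
            fn()
        except Exception as exc:  # halt with stage name; keep partial output
            if current_partial is not None and current_partial.exists():
                current_partial.rename(current_partial.with_suffix(
                    current_partial.suffix + ".partial"))
            raise StageError(stage_name, exc) from exc

    annotation = io.build_annotation_set(
        io.read_gtf(config.annotation_gtf, source_label="reference")
    )
    assembled = io.read_gtf(config.assembled_gtf, source_label="assembled")
    records = nov.score_transcripts(assembled, annotation, cnt_cutoff=config.cnt_cutoff)
    ntable = nov.novelty_table(records)

    def novelty_stage():
        outputs["novelty"] = write_tsv(ntable, "novelty.tsv")

    run_stage("novelty", novelty_stage)

    classes = dict(zip(ntable["transcript_id"], ntable["class_label"]))
    merged = ntable.rename(
        columns={"exonic_length": "length", "novelty_score": "ns"}
    ).set_index("transcript_id")

    if config.conservation_bedgraph and Path(config.conservation_bedgraph).exists():
        def conservation_stage():
            track, rejected = io.read_bedgraph(config.conservation_bedgraph)
            if rejected:
                notices.append(f"conservation: {rejected} records outside [0,1] rejected")
            ctable = conservation_table(assembled, track)
            outputs["conservation"] = write_tsv(ctable, "conservation.tsv")
            merged["ps"] = ctable.set_index("transcript_id")["transcript_score"]

        run_stage("conservation", conservation_stage)
    else:
        notices.append("conservation track missing: conservation and filter stages skipped")

    means: Optional[pd.DataFrame] = None
    if config.expression_tsv and config.design_tsv and Path(config.expression_tsv).exists():
        def expression_stage():
            nonlocal means
            matrix, design = io.read_expression(config.expression_tsv, config.design_tsv)
            means = expr.stage_means(matrix, design, set(config.excluded_stages))
            profile = expr.max_normalize(means)
            outputs["stage_means"] = write_tsv(means, "stage_means.tsv", index=True)
            outputs["stage_profiles"] = write_tsv(profile, "stage_profiles.tsv", index=True)
            props = expr.proportion_sweep(means, classes)
            outputs["class_proportions"] = write_tsv(props, "class_proportions.tsv")

        run_stage("expression", expression_stage)
    else:
        notices.append("expression matrix missing: expression-dependent stages skipped")

    if "ps" in merged.columns:
        def filter_stage():
            table = merged.copy()
            stage_cols: List[str] = []
            if means is not None:
                common = means.reindex(table.index)
                for col in means.columns:
                    table[col] = common[col]
                stage_cols = list(means.columns)
            specs = hcf.builtin_specs()
            for name in config.filter_specs:
                survivors = hcf.apply_filter(table, specs[name], stage_cols)
                cols = [c for c in ("gene_id", "coordinates", "length", "strand", "ps", "ns", "class_label") if c in survivors.columns]
                outputs[f"filter_{name}"] = write_tsv(
                    survivors[cols].reset_index(), f"filter_{name}.tsv"
                )

        run_stage("filters", filter_stage)

    if config.sequences_fasta and Path(config.sequences_fasta).exists():
        def orf_stage():
            sequences = io.read_fasta(config.sequences_fasta)
            outputs["orfs"] = write_tsv(orf_table(sequences), "orfs.tsv")

        run_stage("orf", orf_stage)
    else:
        notices.append("sequences missing: ORF stage skipped")

    if (
        config.counts_tsv and config.events_tsv and config.design_tsv
        and Path(config.counts_tsv).exists()
    ):
        def psi_stage():
            counts = read_event_counts(config.counts_tsv)
            events = read_events(config.events_tsv)
            _, design = None, pd.read_csv(config.design_tsv, sep="\t", index_col=0)
            table = spl.psi_matrix(counts, design, set(config.excluded_stages))
            outputs["psi"] = write_tsv(table, "psi_matrix.tsv", index=True)
            for stage in table.columns:
                bed = spl.events_to_bed(table, events, stage)
                path = out_dir / f"tracks_{stage}.bed"
                io.write_bed(bed, path)
                outputs[f"tracks_{stage}"] = path

        run_stage("psi", psi_stage)
    else:
        notices.append("junction counts missing: PSI and track stages skipped")

    if means is not None:
        def stats_stage():
            novel = ntable[ntable["class_label"] != "known"]
            ns_by_stage = {}
            for stage in means.columns:
                expressed = means.index[means[stage] > config.novelty_tpm_threshold]
                sub = novel[novel["transcript_id"].isin(expressed)]
                ns_by_stage[stage] = sub["novelty_score"].to_numpy()
            scan = sst.stage_pair_novelty_scan(ns_by_stage)
            outputs["stats"] = write_tsv(scan, "stats.tsv")

        run_stage("stats", stats_stage)

    manifest = out_dir / "manifest.txt"
    with open(manifest, "w") as handle:
        handle.write(f"novelscope_version\t{__version__}\n")
        handle.write(f"seed\t{config.seed}\n")
        for name in ("annotation_gtf", "assembled_gtf", "conservation_bedgraph",
                     "expression_tsv", "design_tsv", "counts_tsv", "events_tsv",
                     "sequences_fasta"):
            path = getattr(config, name)
            if path and Path(path).exists():
                handle.write(f"input\t{name}\t{Path(path).name}\t{_sha256(Path(path))}\n")
        for key in sorted(outputs):
            handle.write(f"output\t{key}\t{outputs[key].name}\n")
        for note in notices:
            handle.write(f"notice\t{note}\n")
    outputs["manifest"] = manifest
    return outputs


def write_bundle(bundle, out_dir: Path) -> Dict[str, Path]:
    """Write a simulated bundle to disk in the pipeline's input formats."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}
    paths["annotation_gtf"] = out_dir / "annotation.gtf"
    io.write_gtf(bundle.reference_models, paths["annotation_gtf"])
    paths["assembled_gtf"] = out_dir / "assembled.gtf"
    io.write_gtf(bundle.assembled, paths["assembled_gtf"])
    paths["conservation_bedgraph"] = out_dir / "conservation.bedgraph"
    io.write_bedgraph(bundle.conservation, paths["conservation_bedgraph"])
    paths["expression_tsv"] = out_dir / "expression.tsv"
    paths["design_tsv"] = out_dir / "design.tsv"
    io.write_expression(bundle.expression, bundle.design,
                        paths["expression_tsv"], paths["design_tsv"])
    paths["sequences_fasta"] = out_dir / "sequences.fasta"
    io.write_fasta(bundle.sequences, paths["sequences_fasta"])
    counts_rows = []
    for event_id, clist in bundle.event_counts.items():
        for c in clist:
            counts_rows.append(
                {"event_id": event_id, "sample": c.sample,
                 "inclusion_reads": c.inclusion_reads, "skip_reads": c.skip_reads,
                 "inclusion_length": c.inclusion_length, "skip_length": c.skip_length}
            )
    paths["counts_tsv"] = out_dir / "event_counts.tsv"
    pd.DataFrame(counts_rows).to_csv(paths["counts_tsv"], sep="\t", index=False)
    event_rows = []
    for ev in bundle.events.values():
        event_rows.append(
            {"event_id": ev.event_id, "event_type": ev.event_type, "gene": ev.gene,
             "chrom": ev.target.chrom, "target_start": ev.target.start,
             "target_end": ev.target.end, "up_start": ev.flanks[0].start,
             "up_end": ev.flanks[0].end, "down_start": ev.flanks[1].start,
             "down_end": ev.flanks[1].end, "strand": ev.strand}
        )
    paths["events_tsv"] = out_dir / "events.tsv"
    pd.DataFrame(event_rows).to_csv(paths["events_tsv"], sep="\t", index=False)
    truth_rows = [
        {"transcript_id": tid, "class_label": label,
         "overlap_fraction": bundle.truth.overlap_fraction.get(tid, float("nan"))}
        for tid, label in bundle.truth.class_by_transcript.items()
    ]
    paths["ground_truth_tsv"] = out_dir / "ground_truth.tsv"
    pd.DataFrame(truth_rows).to_csv(paths["ground_truth_tsv"], sep="\t", index=False)
    return paths
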