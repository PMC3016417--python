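"""End-to-end orchestration: simulate -> map -> quantify -> test -> discover
-> annotate, as one reproducible run.

Every threshold default equals the analysis constants used throughout the
package (2 mismatches / 3 bp indel, 40-bp SEJ flanks, RPKM >= 2 and length
>= 100 bp retention, 1% FDR, 20-aa ORF cutoff, CHASTITY 0.6, 100-bp coverage
bins, 5% saturation tolerance).  All randomness flows from the single config
seed; re-running with the same config reproduces byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__, _refs
from . import synthetic_data as sd
from .annotation_model import build_sej, read_gff3, write_gff3, write_sej_fasta
from .diffexpr import de_table
from .discovery import (discover_fragments, write_fragments_bed12,
                        write_fragments_gff3)
from .orf_annot import categorize, longest_orf, orf_report, translated_search
from .quantifier import (coverage_track, cumulative_coverage,
                         expression_table, saturation_analysis,
                         write_bedgraph)
from .read_mapper import (AlignmentClass, ReferenceIndex, align_reads,
                          classify_unmapped, mapping_stats, write_alignment_tsv,
                          write_mapping_stats_tsv, write_sam)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunResult", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending record."""


@dataclass
class RunConfig:
    """Configuration of one two-condition run."""

    out_dir: str = "rnapile_run"
    seed: int = 0
    simulation: sd.SimulationConfig = None
    # alignment
    max_mismatch: int = 2
    max_indel: int = 3
    sej_flank: int = 40
    min_bridge_overlap: int = 1
    # quantification / reporting
    min_read_overlap: int = 18
    coverage_bin: int = 100
    saturation_tolerance: float = 0.05
    n_increments: int = 4
    # discovery
    min_depth: int = 1
    min_junction_reads: int = 1
    min_rpkm: float = 2.0
    min_length: int = 100
    # differential expression
    fdr_alpha: float = 0.01
    # ORF categorisation
    min_orf_aa: int = 20
    orf_min_identity: float = 0.40
    orf_min_aln_aa: int = 30
    # quality filter threshold (applied when raw intensities are simulated)
    chastity: float = 0.6

    def __post_init__(self) -> None:
        if self.simulation is None:
            self.simulation = sd.SimulationConfig(seed=self.seed)

    def to_yaml(self, path: str | os.PathLike) -> None:
        d = dataclasses.asdict(self)
        d["simulation"]["exon_count_range"] = list(
            d["simulation"]["exon_count_range"])
        d["simulation"]["exon_length_range"] = list(
            d["simulation"]["exon_length_range"])
        d["simulation"]["intron_length_range"] = list(
            d["simulation"]["intron_length_range"])
        d["simulation"]["fold_change_spec"] = [
            list(x) for x in d["simulation"]["fold_change_spec"]]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        sim = d.pop("simulation", None)
        if sim is not None:
            for key in ("exon_count_range", "exon_length_range",
                        "intron_length_range"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            if "fold_change_spec" in sim:
                sim["fold_change_spec"] = [tuple(x)
                                           for x in sim["fold_change_spec"]]
            sim = sd.SimulationConfig(**sim)
        return cls(simulation=sim, **d)


@dataclass
class RunResult:
    """In-memory handles on everything a run produced (files are also on disk)."""

    out_dir: str
    genome: dict = field(default_factory=dict)
    annotated: list = field(default_factory=list)
    hidden: list = field(default_factory=list)
    expression_truth: pd.DataFrame | None = None
    reads: list = field(default_factory=list)        # per condition
    truth: list = field(default_factory=list)        # per condition
    alignments: list = field(default_factory=list)   # per condition
    stats: dict = field(default_factory=dict)
    unmapped_categories: dict = field(default_factory=dict)
    expression: pd.DataFrame | None = None
    de: pd.DataFrame | None = None
    fragments: list = field(default_factory=list)
    fragment_expr: pd.DataFrame | None = None
    orf_categories: pd.DataFrame | None = None
    orf_counts: dict = field(default_factory=dict)
    orf_results: dict = field(default_factory=dict)
    saturation: pd.DataFrame | None = None
    cumulative: list = field(default_factory=list)
    sej_records: list = field(default_factory=list)


def _stage(name: str):
    def decorate(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name}: {exc}") from exc
        return wrapped
    return decorate


def run_pipeline(config: RunConfig) -> RunResult:
    """Run the full synthetic-study pipeline; returns in-memory results and
    writes the report files into ``config.out_dir``."""
    os.makedirs(config.out_dir, exist_ok=True)
    out = lambda name: os.path.join(config.out_dir, name)
    res = RunResult(out_dir=config.out_dir)
    sim = config.simulation

    _run_simulation(config, res)
    sej_gene_of = _run_annotation(config, res)
    _run_mapping(config, res, sej_gene_of)
    _run_quantification(config, res, sej_gene_of)
    _run_discovery(config, res)
    _run_orf(config, res)

    config.to_yaml(out("config.yaml"))
    with open(out("run.log"), "w") as fh:
        fh.write(f"rnapile {__version__}\nseed: {config.seed}\n")
        for f in dataclasses.fields(config):
            if f.name not in ("out_dir", "simulation"):
                fh.write(f"{f.name}: {getattr(config, f.name)}\n")
        fh.write(f"simulation: {sim}\n")
    logger.info("run complete: %s", config.out_dir)
    return res


@_stage("synthetic_data")
def _run_simulation(config: RunConfig, res: RunResult) -> None:
    sim = config.simulation
    out = lambda name: os.path.join(config.out_dir, name)
    res.genome = sd.generate_genome(sim)
    res.annotated, res.hidden = sd.generate_gene_models(res.genome, sim)
    models = res.annotated + res.hidden
    res.expression_truth = sd.generate_expression(models, sim)
    sd.write_fasta(res.genome, out("genome.fa"))
    write_gff3(res.annotated, out("annotation.gff3"))
    res.expression_truth.to_csv(out("expression_truth.tsv"), sep="\t")
    from .util import kmer_census
    census = kmer_census(res.genome, sim.read_length)
    for cond in (0, 1):
        reads, truth = sd.simulate_reads(res.genome, models,
                                         res.expression_truth, sim, cond,
                                         census=census)
        res.reads.append(reads)
        res.truth.append(truth)
        sd.write_fastq(reads, out(f"reads_c{cond}.fq"))
        truth.to_csv(out(f"read_truth_c{cond}.tsv"), sep="\t", index=False)
    sd.write_contaminant_refs(config.out_dir)


@_stage("annotation_model")
def _run_annotation(config: RunConfig, res: RunResult) -> dict[str, str]:
    out = lambda name: os.path.join(config.out_dir, name)
    gff = out("annotation.gff3")
    if not os.path.exists(gff):
        raise FileNotFoundError(f"annotation file missing: {gff}")
    annotated = read_gff3(gff, genome=res.genome)
    res.annotated = annotated
    res.sej_records = build_sej(annotated, res.genome, flank=config.sej_flank)
    write_sej_fasta(res.sej_records, out("sej.fa"))
    tid_to_gene = {m.transcript_id: m.gene_id for m in annotated}
    return {r.junction_id: tid_to_gene[r.transcript_id]
            for r in res.sej_records}


@_stage("read_mapper")
def _run_mapping(config: RunConfig, res: RunResult, sej_gene_of) -> None:
    out = lambda name: os.path.join(config.out_dir, name)
    index = ReferenceIndex(res.genome, res.sej_records,
                           max_mismatch=config.max_mismatch,
                           max_indel=config.max_indel,
                           min_bridge_overlap=config.min_bridge_overlap)
    chrom_lengths = {c: len(s) for c, s in res.genome.items()}
    stats = {}
    unmapped_reads = []
    for cond in (0, 1):
        alignments = align_reads(res.reads[cond], index)
        res.alignments.append(alignments)
        stats[f"condition_{cond}"] = mapping_stats(alignments)
        reads_by_id = dict(res.reads[cond])
        write_sam(alignments, reads_by_id, chrom_lengths, out(f"aln_c{cond}.sam"))
        write_alignment_tsv(alignments, out(f"aln_c{cond}.tsv"))
        unmapped_reads.extend(
            (a.read_id, reads_by_id[a.read_id]) for a in alignments
            if a.category is AlignmentClass.UNMAPPED)
    res.stats = stats
    write_mapping_stats_tsv(stats, out("mapping_stats.tsv"))
    res.unmapped_categories = classify_unmapped(
        unmapped_reads, {"adapter": _refs.ADAPTER}, {"rrna": _refs.RRNA},
        {"foreign": _refs.FOREIGN})
    with open(out("unmapped_classes.tsv"), "w") as fh:
        fh.write("read_id\tcategory\n")
        for rid in sorted(res.unmapped_categories):
            fh.write(f"{rid}\t{res.unmapped_categories[rid]}\n")


@_stage("quantifier")
def _run_quantification(config: RunConfig, res: RunResult, sej_gene_of) -> None:
    out = lambda name: os.path.join(config.out_dir, name)
    chrom_lengths = {c: len(s) for c, s in res.genome.items()}
    res.expression = expression_table(res.alignments, res.annotated,
                                      sej_gene_of, config.min_read_overlap)
    res.expression.to_csv(out("expression.tsv"), sep="\t",
                          float_format="%.6g")
    res.de = de_table(res.expression, alpha=config.fdr_alpha)
    de_out = res.de.reset_index()
    de_out["ratio"] = de_out["ratio"].map(
        lambda r: "-" if r is None or pd.isna(r) else f"{r:.1f}")
    de_out.to_csv(out("de_table.tsv"), sep="\t", index=False,
                  float_format="%.6g")
    for cond in (0, 1):
        track = coverage_track(res.alignments[cond], chrom_lengths,
                               config.coverage_bin)
        write_bedgraph(track, config.coverage_bin, chrom_lengths,
                       out(f"coverage_c{cond}.bedgraph"))
    # saturation + cumulative coverage on condition-0 reads in k increments
    aln0 = res.alignments[0]
    k = config.n_increments
    bounds = np.linspace(0, len(aln0), k + 1).astype(int)
    increments = [aln0[bounds[i]:bounds[i + 1]] for i in range(k)]
    sat = saturation_analysis(increments, res.annotated,
                              tolerance=config.saturation_tolerance,
                              min_overlap=config.min_read_overlap)
    res.saturation = sat
    sat.to_csv(out("saturation.tsv"), sep="\t", index=False,
               float_format="%.6g")
    targets = [(m.chrom, s, e) for m in res.annotated for s, e in m.exons]
    res.cumulative = cumulative_coverage(increments, targets, chrom_lengths)
    with open(out("cumulative_coverage.tsv"), "w") as fh:
        fh.write("increment\tfraction_annotated_covered\n")
        for i, frac in enumerate(res.cumulative, 1):
            fh.write(f"{i}\t{frac:.6g}\n")


@_stage("discovery")
def _run_discovery(config: RunConfig, res: RunResult) -> None:
    out = lambda name: os.path.join(config.out_dir, name)
    chrom_lengths = {c: len(s) for c, s in res.genome.items()}
    res.fragments, res.fragment_expr = discover_fragments(
        res.alignments, res.annotated, chrom_lengths,
        min_depth=config.min_depth,
        min_junction_reads=config.min_junction_reads,
        min_rpkm=config.min_rpkm, min_length=config.min_length)
    write_fragments_gff3(res.fragments, res.fragment_expr, out("fragments.gff3"))
    write_fragments_bed12(res.fragments, out("fragments.bed12"))


@_stage("orf_annot")
def _run_orf(config: RunConfig, res: RunResult) -> None:
    out = lambda name: os.path.join(config.out_dir, name)
    sim = config.simulation
    models = res.annotated + res.hidden
    proteins = sd.make_protein_reference(res.genome, models, sim)
    sd.write_protein_fasta(proteins, out("proteins.fa"))
    unannotated = [f for f in res.fragments if f.category == "unannotated"]
    orfs, hits = {}, {}
    for f in unannotated:
        seq = "".join(res.genome[f.chrom][s:e] for s, e in f.blocks)
        orfs[f.fragment_id] = longest_orf(seq)
        hits[f.fragment_id] = translated_search(
            seq, proteins, min_identity=config.orf_min_identity,
            min_aln_aa=config.orf_min_aln_aa)
    res.orf_results = orfs
    res.orf_categories, res.orf_counts = categorize(
        [f.fragment_id for f in unannotated], hits, orfs,
        min_orf_aa=config.min_orf_aa)
    if len(res.orf_categories):
        orf_report(res.orf_categories, res.fragment_expr, out("orf_report.tsv"))
    else:
        with open(out("orf_report.tsv"), "w") as fh:
            fh.write("fragment_id\tnt_length\tRPKM_0\tRPKM_1\tratio\t"
                     "aa_length\tcategory\tdescription\n")
    n_ann = sum(f.category == "annotated-locus" for f in res.fragments)
    n_unann = len(unannotated)
    with open(out("discovery_summary.tsv"), "w") as fh:
        fh.write("category\tcount\n")
        fh.write(f"transcripts_on_annotated_loci\t{n_ann}\n")
        fh.write(f"transcripts_on_unannotated_region\t{n_unann}\n")
        fh.write(f"  orfs_with_similarity_hit\t{res.orf_counts.get('similarity-hit', 0)}\n")
        fh.write(f"  orfs_ge_20aa_no_hit\t{res.orf_counts.get('orf-ge-20-no-hit', 0)}\n")
        fh.write(f"  no_orf_or_lt_20aa\t{res.orf_counts.get('no-orf-or-lt-20', 0)}\n")
        fh.write(f"total\t{n_ann + n_unann}\n")
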