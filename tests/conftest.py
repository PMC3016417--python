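"""Shared fixtures: a small single-chromosome study for unit tests, the
default-scale error-free study for recovery checks, and one full pipeline run."""

from __future__ import annotations

from dataclasses import dataclass, field

import pytest
from hypothesis import settings

import rnapile.synthetic_data as sd
from rnapile.annotation_model import build_sej
from rnapile.pipeline import RunConfig, run_pipeline
from rnapile.read_mapper import ReferenceIndex, align_reads
from rnapile.util import kmer_census

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@dataclass
class Study:
    """A simulated study bundled with its mapping results."""

    config: sd.SimulationConfig
    genome: dict
    annotated: list
    hidden: list
    models: list
    expression: object
    reads: list = field(default_factory=list)     # [condition][...]
    truth: list = field(default_factory=list)
    sej: list = field(default_factory=list)
    index: ReferenceIndex = None
    alignments: list = field(default_factory=list)

    @property
    def chrom_lengths(self):
        return {c: len(s) for c, s in self.genome.items()}

    @property
    def sej_gene_of(self):
        tid_to_gene = {m.transcript_id: m.gene_id for m in self.annotated}
        return {r.junction_id: tid_to_gene[r.transcript_id] for r in self.sej}

    @property
    def hidden_tids(self):
        return {m.transcript_id for m in self.hidden}


def _run_study(config: sd.SimulationConfig) -> Study:
    genome = sd.generate_genome(config)
    annotated, hidden = sd.generate_gene_models(genome, config)
    models = annotated + hidden
    expression = sd.generate_expression(models, config)
    study = Study(config, genome, annotated, hidden, models, expression)
    census = kmer_census(genome, config.read_length)
    for cond in (0, 1):
        reads, truth = sd.simulate_reads(genome, models, expression, config,
                                         cond, census=census)
        study.reads.append(reads)
        study.truth.append(truth)
    study.sej = build_sej(annotated, genome)
    study.index = ReferenceIndex(genome, study.sej)
    for cond in (0, 1):
        study.alignments.append(align_reads(study.reads[cond], study.index))
    return study


@pytest.fixture(scope="session")
def small_study() -> Study:
    """Single 30-kb chromosome, 15 genes, 8k reads/condition, default error
    rates — quick enough for per-module tests."""
    return _run_study(sd.SimulationConfig(
        seed=7, n_chromosomes=1, chromosome_length=30_000, n_genes=15,
        n_reads_per_condition=8_000))


@pytest.fixture(scope="session")
def errorfree_study() -> Study:
    """The default-scale study with sequencing errors switched off: the
    fixture for junction recall, quantification recovery and hidden-gene
    discovery checks."""
    return _run_study(sd.SimulationConfig(
        seed=5, mismatch_rate=0.0, indel_rate=0.0))


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full default-configuration pipeline run (errors on)."""
    out = tmp_path_factory.mktemp("pipeline")
    cfg = RunConfig(out_dir=str(out), seed=3)
    res = run_pipeline(cfg)
    return cfg, res
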