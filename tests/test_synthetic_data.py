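"""Generator contracts: determinism, planted structure, truth bookkeeping,
and the CHASTITY purity filter."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import rnapile.synthetic_data as sd
from rnapile.annotation_model import GeneModel


def tiny_cfg(**kw):
    defaults = dict(seed=11, n_chromosomes=1, chromosome_length=12_000,
                    n_genes=5, n_reads_per_condition=500)
    defaults.update(kw)
    return sd.SimulationConfig(**defaults)


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        dict(exon_length_range=(300, 120)),
        dict(exon_count_range=(0, 3)),
        dict(read_length=0),
        dict(fraction_hidden=1.5),
        dict(contaminant_fractions={"adapter": 0.6, "random": 0.6}),
        dict(contaminant_fractions={"adapter": -0.1}),
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(sd.ConfigurationError):
            tiny_cfg(**kw)


class TestGenome:
    def test_lengths_and_determinism(self):
        cfg = sd.SimulationConfig(seed=1, n_chromosomes=2,
                                  chromosome_length=50_000)
        g1 = sd.generate_genome(cfg)
        g2 = sd.generate_genome(cfg)
        assert sorted(g1) == ["chr1", "chr2"]
        assert all(len(s) == 50_000 for s in g1.values())
        assert g1 == g2

    def test_planted_repeat_by_exhaustive_kmer_census(self):
        # brute-force 36-mer census must find at least one duplicated 36-mer
        genome = sd.generate_genome(tiny_cfg())
        counts = {}
        for seq in genome.values():
            for i in range(len(seq) - 35):
                kmer = seq[i:i + 36]
                counts[kmer] = counts.get(kmer, 0) + 1
        assert max(counts.values()) >= 2


class TestGeneModels:
    def test_hidden_count_floor_rule(self):
        cfg = sd.SimulationConfig(seed=2, n_chromosomes=2,
                                  chromosome_length=120_000, n_genes=100,
                                  fraction_hidden=0.1)
        genome = sd.generate_genome(cfg)
        annotated, hidden = sd.generate_gene_models(genome, cfg)
        assert len(annotated) == 90 and len(hidden) == 10

    def test_no_hidden_when_fraction_zero(self):
        cfg = tiny_cfg(fraction_hidden=0.0)
        annotated, hidden = sd.generate_gene_models(sd.generate_genome(cfg), cfg)
        assert hidden == [] and len(annotated) == cfg.n_genes

    def test_exons_within_bounds_and_loci_disjoint(self):
        cfg = tiny_cfg()
        genome = sd.generate_genome(cfg)
        annotated, hidden = sd.generate_gene_models(genome, cfg)
        by_chrom = {}
        for m in annotated + hidden:
            n = len(genome[m.chrom])
            for s, e in m.exons:
                assert 0 <= s < e <= n
            lo, hi = m.extent
            by_chrom.setdefault(m.chrom, []).append((lo, hi))
            for s, e in zip(m.exons, m.exons[1:]):
                intron = e[0] - s[1]
                assert cfg.intron_length_range[0] <= intron <= cfg.intron_length_range[1]
        for extents in by_chrom.values():
            extents.sort()
            for (a0, a1), (b0, b1) in zip(extents, extents[1:]):
                assert a1 <= b0

    def test_genome_too_small_raises(self):
        cfg = tiny_cfg(chromosome_length=3_000, n_genes=20)
        with pytest.raises(sd.PlacementError):
            sd.generate_gene_models(sd.generate_genome(cfg), cfg)


class TestReadSimulation:
    def test_zero_abundance_zero_contaminants_yields_no_reads(self):
        cfg = tiny_cfg(contaminant_fractions={})
        genome = sd.generate_genome(cfg)
        annotated, hidden = sd.generate_gene_models(genome, cfg)
        models = annotated + hidden
        expr = sd.generate_expression(models, cfg)
        expr[["abundance_0", "abundance_1"]] = 0.0
        reads, truth = sd.simulate_reads(genome, models, expr, cfg, 0)
        assert reads == [] and len(truth) == 0

    def test_abundance_ratio_recovered_within_3_sigma(self):
        # two equal-length transcripts at abundance 1:4 -> binomial bound
        genome = {"chr1": sd.generate_genome(tiny_cfg())["chr1"]}
        models = [
            GeneModel("gA", "gA.1", "chr1", "+", [(100, 1100)]),
            GeneModel("gB", "gB.1", "chr1", "+", [(2000, 3000)]),
        ]
        cfg = tiny_cfg(n_reads_per_condition=20_000, contaminant_fractions={},
                       mismatch_rate=0, indel_rate=0)
        expr = pd.DataFrame({
            "gene_id": ["gA", "gB"], "abundance_0": [1.0, 4.0],
            "abundance_1": [1.0, 4.0],
        }, index=pd.Index(["gA.1", "gB.1"], name="transcript_id"))
        reads, truth = sd.simulate_reads(genome, models, expr, cfg, 0)
        counts = truth.transcript_id.value_counts()
        n = counts.sum()
        p = 0.2  # expected share of gA.1
        sigma = np.sqrt(n * p * (1 - p))
        assert abs(counts["gA.1"] - n * p) < 3 * sigma

    def test_junction_reads_flagged_by_construction(self, small_study):
        truth = small_study.truth[0]
        models = {m.transcript_id: m for m in small_study.models}
        jr = truth[truth.true_class == "junction-spanning"]
        assert len(jr) > 0
        for row in jr.itertuples():
            m = models[row.transcript_id]
            span = 36 + (0 if row.indel_len == 0 else 3)  # upper bound
            assert any(row.offset < b < row.offset + span
                       for b in m.exon_boundaries())

    def test_determinism_byte_identical_fastq(self, tmp_path):
        cfg = tiny_cfg()
        genome = sd.generate_genome(cfg)
        annotated, hidden = sd.generate_gene_models(genome, cfg)
        models = annotated + hidden
        expr = sd.generate_expression(models, cfg)
        paths = []
        for i in (1, 2):
            reads, truth = sd.simulate_reads(genome, models, expr, cfg, 1)
            p = tmp_path / f"r{i}.fq"
            sd.write_fastq(reads, p)
            truth.to_csv(tmp_path / f"t{i}.tsv", sep="\t", index=False)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()
        assert (tmp_path / "t1.tsv").read_bytes() == (tmp_path / "t2.tsv").read_bytes()

    def test_truth_partitions_reads(self, small_study):
        for cond in (0, 1):
            reads = small_study.reads[cond]
            truth = small_study.truth[cond]
            assert len(truth) == len(reads)
            assert truth.read_id.is_unique
            assert set(truth.read_id) == {rid for rid, _ in reads}
            n_cont = (truth.true_class == "contaminant").sum()
            n_tx = (truth.origin == "transcript").sum()
            assert n_cont + n_tx == len(reads)

    def test_read_counts_proportional_to_abundance_times_length(self, errorfree_study):
        # abundance-recovery invariant: counts / (abundance * length) is
        # constant across transcripts, within sampling error
        expr = errorfree_study.expression
        expected = 0.0
        counts = None
        for cond in (0, 1):
            truth = errorfree_study.truth[cond]
            c = truth[truth.origin == "transcript"].transcript_id.value_counts()
            counts = c if counts is None else counts.add(c, fill_value=0)
            w = expr[f"abundance_{cond}"] * expr.length
            expected = expected + w / w.sum() * c.sum()
        for tid, exp in expected.items():
            if exp < 200:
                continue
            obs = counts.get(tid, 0)
            assert abs(obs - exp) < 5 * np.sqrt(exp), tid


class TestChastity:
    def test_worked_single_cycle_examples(self):
        r = sd.chastity_filter(np.array([[10.0, 2.0, 1.0, 0.0]]))
        assert r.passed and r.chastity[0] == pytest.approx(10 / 12)
        assert not sd.chastity_filter(np.array([[5.0, 5.0, 0.0, 0.0]])).passed

    def test_threshold_boundary_inclusive(self):
        # chastity exactly 0.6 passes the >= 0.6 filter
        r = sd.chastity_filter(np.array([[6.0, 4.0, 0.0, 0.0]]), threshold=0.6)
        assert r.chastity[0] == pytest.approx(0.6)
        assert r.passed

    def test_uncallable_cycle_fails(self):
        r = sd.chastity_filter(np.array([[1.0, 0, 0, 0], [0.0, 0, 0, 0]]))
        assert not r.passed and r.reason == "uncallable"

    def test_all_cycles_must_pass(self):
        arr = np.array([[10.0, 1, 0, 0], [5.0, 5.0, 0, 0]])
        assert not sd.chastity_filter(arr).passed

    @given(st.lists(st.tuples(*[st.floats(0.01, 100)] * 4), min_size=1, max_size=36))
    def test_formula_matches_direct_computation(self, cycles):
        arr = np.array(cycles)
        r = sd.chastity_filter(arr, threshold=0.6)
        expected = []
        for row in cycles:
            top = sorted(row, reverse=True)
            expected.append(top[0] / (top[0] + top[1]))
        assert np.allclose(r.chastity, expected)
        assert r.passed == all(c >= 0.6 for c in expected)

    def test_simulated_intensities_recover_call(self):
        rng = np.random.default_rng(0)
        arr = sd.simulate_intensities("ACGTACGT", rng, noise=0.1)
        assert sd.chastity_filter(arr).passed
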