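"""RPKM arithmetic, read-to-gene assignment, coverage tracks, cumulative
coverage and saturation analysis."""

import numpy as np
import pytest

from rnapile.annotation_model import GeneModel
from rnapile.quantifier import (count_reads_per_gene, coverage_track,
                                cumulative_coverage, expression_table,
                                library_size, rpkm, saturation_analysis,
                                saturation_from_counts)
from rnapile.read_mapper import AlignmentClass, Hit, ReadAlignment


def mk_aln(rid, chrom, start, span=36, category=AlignmentClass.UNIQUE_GENOME,
           blocks=(), target="chr1", kind="genome"):
    h = Hit(kind, target, chrom, start, "+", 0, 0, span, tuple(blocks))
    return ReadAlignment(rid, category, [h])


class TestRPKM:
    def test_worked_example(self):
        assert rpkm(1000, 2000, 10_000_000) == pytest.approx(50.0)

    def test_zero_count(self):
        assert rpkm(0, 500, 1_000_000) == 0.0

    def test_doubling_library_halves_rpkm(self):
        assert rpkm(100, 1000, 2_000_000) == pytest.approx(
            rpkm(100, 1000, 1_000_000) / 2)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            rpkm(1, 100, 0)
        with pytest.raises(ValueError):
            rpkm(1, 0, 100)


class TestCounting:
    GENE = GeneModel("g1", "g1.1", "chr1", "+", [(1000, 1400), (1700, 2100)])

    def test_exonic_read_counted_intronic_not(self):
        alns = [mk_aln("a", "chr1", 1100),            # exonic
                mk_aln("b", "chr1", 1500),            # fully intronic
                mk_aln("c", "chr1", 1390)]            # 10 bp exon overlap < 18
        counts, amb = count_reads_per_gene(alns, [self.GENE])
        assert counts["g1"] == 1 and amb == 0

    def test_bridged_read_assigned_to_junction_gene(self):
        a = mk_aln("r", "chr1", 0, category=AlignmentClass.UNIQUE_BRIDGED,
                   blocks=[(1380, 1400), (1700, 1716)], target="sej_00000",
                   kind="sej")
        counts, _ = count_reads_per_gene([a], [self.GENE],
                                         sej_gene_of={"sej_00000": "g1"})
        assert counts["g1"] == 1

    def test_multi_gene_read_discarded(self):
        g2 = GeneModel("g2", "g2.1", "chr1", "+", [(2100, 2400)])
        a = mk_aln("r", "chr1", 2082)  # 18 bp on g1 exon, 18 bp on g2 exon
        counts, amb = count_reads_per_gene([a], [self.GENE, g2])
        assert counts.sum() == 0 and amb == 1

    def test_multiple_and_unmapped_never_counted(self):
        alns = [ReadAlignment("m", AlignmentClass.MULTIPLE,
                              [Hit("genome", "chr1", "chr1", 1100, "+", 0, 0, 36)]),
                ReadAlignment("u", AlignmentClass.UNMAPPED)]
        counts, _ = count_reads_per_gene(alns, [self.GENE])
        assert counts.sum() == 0

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(ValueError):
            count_reads_per_gene([mk_aln("r", "chrX", 0)], [self.GENE])

    def test_errorfree_counts_match_truth(self, errorfree_study):
        """With no sequencing errors, per-gene counts equal the counts
        implied by the read truth table (up to junction reads whose sequence
        also matches the genome contiguously)."""
        s = errorfree_study
        counts, _ = count_reads_per_gene(s.alignments[0], s.annotated,
                                         s.sej_gene_of)
        truth = s.truth[0]
        tx = truth[truth.origin == "transcript"]
        gene_of = {m.transcript_id: m.gene_id for m in s.annotated}
        expected = {}
        slack = {}
        for row in tx.itertuples():
            g = gene_of.get(row.transcript_id)
            if g is None:       # hidden gene
                continue
            if row.true_class == "repeat":
                continue
            expected[g] = expected.get(g, 0) + 1
            if row.true_class == "junction-spanning" and row.contiguous_match:
                slack[g] = slack.get(g, 0) + 1
        for m in s.annotated:
            g = m.gene_id
            exp = expected.get(g, 0)
            assert abs(int(counts[g]) - exp) <= slack.get(g, 0), g

    def test_count_rpkm_identity_on_expression_table(self, small_study):
        expr = expression_table(small_study.alignments, small_study.annotated,
                                small_study.sej_gene_of)
        for i in (0, 1):
            back = (expr[f"RPKM_{i}"] * expr[f"N_{i}"] * expr["length"]) / 1e9
            assert np.allclose(back, expr[f"C_{i}"], atol=1e-9)
            assert (expr[f"C_{i}"] <= expr[f"N_{i}"]).all()


class TestCoverageTrack:
    def test_read_spanning_bin_boundary(self):
        track = coverage_track([mk_aln("r", "chr1", 80)], {"chr1": 1000},
                               bin_size=100, N=1_000_000)
        assert track["chr1"][0] == pytest.approx(1.0)
        assert track["chr1"][1] == pytest.approx(1.0)
        assert track["chr1"][2:].sum() == 0

    def test_bridged_read_skips_intronic_bins(self):
        a = mk_aln("r", "chr1", 0, category=AlignmentClass.UNIQUE_BRIDGED,
                   blocks=[(320, 340), (720, 736)], kind="sej")
        track = coverage_track([a], {"chr1": 1000}, bin_size=100, N=1_000_000)
        assert track["chr1"][3] == pytest.approx(1.0)
        assert track["chr1"][7] == pytest.approx(1.0)
        assert track["chr1"][[4, 5, 6]].sum() == 0

    def test_no_reads_all_zero(self):
        track = coverage_track([], {"chr1": 500}, bin_size=100, N=1)
        assert (track["chr1"] == 0).all()

    def test_bin_size_validated(self):
        with pytest.raises(ValueError):
            coverage_track([], {"chr1": 500}, bin_size=0)

    def test_coverage_conservation(self, small_study):
        alns = small_study.alignments[0]
        N = library_size(alns)
        bin_size = 100
        track = coverage_track(alns, small_study.chrom_lengths, bin_size, N)
        total_bins = sum(t.sum() for t in track.values()) * N / 1e6
        expected = 0
        for a in alns:
            if a.category not in (AlignmentClass.UNIQUE_GENOME,
                                  AlignmentClass.UNIQUE_BRIDGED):
                continue
            from rnapile.quantifier import alignment_blocks
            for bs, be in alignment_blocks(a):
                expected += (be - 1) // bin_size - bs // bin_size + 1
        assert total_bins == pytest.approx(expected)


class TestCumulativeCoverage:
    def test_zero_reads_then_single_read(self):
        targets = [("chr1", 100, 1000)]
        fr = cumulative_coverage([[], [mk_aln("r", "chr1", 200)]],
                                 targets, {"chr1": 2000})
        assert fr[0] == 0.0
        assert fr[1] == pytest.approx(36 / 900)

    def test_empty_target_rejected(self):
        with pytest.raises(ValueError):
            cumulative_coverage([[]], [], {"chr1": 100})

    def test_monotone_on_synthetic_increments(self, small_study):
        alns = small_study.alignments[0]
        k = 5
        bounds = np.linspace(0, len(alns), k + 1).astype(int)
        incs = [alns[bounds[i]:bounds[i + 1]] for i in range(k)]
        targets = [(m.chrom, s, e)
                   for m in small_study.annotated for s, e in m.exons]
        fr = cumulative_coverage(incs, targets, small_study.chrom_lengths)
        assert all(b >= a for a, b in zip(fr, fr[1:]))
        assert 0 < fr[-1] <= 1


class TestSaturation:
    def test_hand_built_five_gene_example(self):
        # two increments of 100 uniquely mapped reads each; prefix RPKM is
        # within 5% of final iff 2*c1/(c1+c2) is in [0.95, 1.05]
        counts = np.array([[10, 5, 0, 8, 2],
                           [10, 5, 0, 8, 50]])
        lengths = [1e7, 1e7, 1e7, 1e6, 1e5]
        df = saturation_from_counts(counts, [100, 100], lengths)
        first = df[df.cumulative_reads == 100].set_index("expression_class")
        # final RPKM: g0 = 10, g1 = 5 (class 3-30); g3 = 80 (30-300);
        # g4 = 2600 (>=300); g2 excluded (final RPKM 0)
        assert first.loc["3-30", "n_genes"] == 2
        assert first.loc["3-30", "fraction_converged"] == pytest.approx(1.0)
        assert first.loc["30-300", "fraction_converged"] == pytest.approx(1.0)
        assert first.loc[">=300", "fraction_converged"] == pytest.approx(0.0)
        assert first.loc["<3", "n_genes"] == 0
        last = df[df.cumulative_reads == 200]
        assert np.allclose(last.fraction_converged.dropna(), 1.0)

    def test_tolerance_boundary_95_percent_counts(self):
        # a prefix at 95.1% of the final value is converged at 5% tolerance
        counts = np.array([[951.0], [1049.0]])
        df = saturation_from_counts(counts, [1000, 1000], [1e6])
        assert df.dropna().fraction_converged.iloc[0] == 1.0
        counts = np.array([[940.0], [1060.0]])
        df = saturation_from_counts(counts, [1000, 1000], [1e6])
        assert df.dropna().fraction_converged.iloc[0] == 0.0

    def test_requires_two_increments(self):
        with pytest.raises(ValueError):
            saturation_from_counts(np.array([[1, 2]]), [10], [100, 100])
        with pytest.raises(ValueError):
            saturation_analysis([[]], [])

    def test_final_increment_always_converged(self, small_study):
        alns = small_study.alignments[0]
        bounds = np.linspace(0, len(alns), 4).astype(int)
        incs = [alns[bounds[i]:bounds[i + 1]] for i in range(3)]
        df = saturation_analysis(incs, small_study.annotated,
                                 small_study.sej_gene_of)
        last = df[df.cumulative_reads == df.cumulative_reads.max()]
        assert np.allclose(last.fraction_converged.dropna(), 1.0)


class TestFoldChangeRecovery:
    def test_planted_ratios_recovered(self, errorfree_study):
        """Planted fold changes are recovered within 10% by the RPKM ratio
        for genes with >= 500 expected reads in both conditions."""
        s = errorfree_study
        expr = expression_table(s.alignments, s.models, s.sej_gene_of)
        tr = s.expression.set_index("gene_id")
        w = {c: tr[f"abundance_{c}"] * tr.length for c in (0, 1)}
        n_tx = {c: (s.truth[c].origin == "transcript").sum() for c in (0, 1)}
        exp_reads = {c: w[c] / w[c].sum() * n_tx[c] for c in (0, 1)}
        checked = 0
        for g, row in tr.iterrows():
            if row.ratio == 1.0 or min(exp_reads[0][g], exp_reads[1][g]) < 500:
                continue
            est = expr.loc[g, "RPKM_1"] / expr.loc[g, "RPKM_0"]
            assert est == pytest.approx(row.ratio, rel=0.10), g
            checked += 1
        assert checked >= 3
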