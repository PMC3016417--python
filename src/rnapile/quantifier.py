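"""Read counting, RPKM, coverage tracks, and sequencing-saturation analysis.

RPKM (reads per kilobase of exon model per million mapped reads) is
``10^9 * C / (N * L)`` where C is the read count assigned to a gene, L its
summed exon length, and N the library size — here the number of uniquely
mapped reads (genome-unique + bridged) in the sample.
"""

from __future__ import annotations

import logging
import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotation_model import GeneModel
from .read_mapper import AlignmentClass, ReadAlignment

logger = logging.getLogger(__name__)

__all__ = [
    "rpkm",
    "alignment_blocks",
    "library_size",
    "count_reads_per_gene",
    "expression_table",
    "coverage_track",
    "write_bedgraph",
    "cumulative_coverage",
    "saturation_from_counts",
    "saturation_analysis",
    "SATURATION_CLASS_BOUNDS",
]

SATURATION_CLASS_BOUNDS = (3.0, 30.0, 300.0)
DEFAULT_MIN_OVERLAP = 18  # half of a 36-bp read must lie on exon sequence


def rpkm(C, L, N):
    """10^9 * C / (N * L); vectorised over any of the arguments."""
    C = np.asarray(C, dtype=float)
    L = np.asarray(L, dtype=float)
    N = np.asarray(N, dtype=float)
    if (N < 1).any():
        raise ValueError("library size N must be >= 1")
    if (L < 1).any():
        raise ValueError("exon model length L must be >= 1")
    out = 1e9 * C / (N * L)
    return float(out) if out.ndim == 0 else out


def alignment_blocks(aln: ReadAlignment) -> tuple[tuple[int, int], ...]:
    """Genomic interval(s) covered by a uniquely mapped read."""
    h = aln.best
    if h is None:
        return ()
    if h.blocks:
        return h.blocks
    return ((h.start, h.start + h.span),)


def library_size(alignments: Iterable[ReadAlignment]) -> int:
    """N: uniquely mapped reads (genome + bridged), the normalisation basis."""
    return sum(1 for a in alignments
               if a.category in (AlignmentClass.UNIQUE_GENOME,
                                 AlignmentClass.UNIQUE_BRIDGED))


def _exon_trees(models: list[GeneModel]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for m in models:
        tree = trees.setdefault(m.chrom, IntervalTree())
        for s, e in m.exons:
            tree[s:e] = m.gene_id
    return trees


def count_reads_per_gene(alignments: list[ReadAlignment],
                         models: list[GeneModel],
                         sej_gene_of: dict[str, str] | None = None,
                         min_overlap: int = DEFAULT_MIN_OVERLAP,
                         ) -> tuple[pd.Series, int]:
    """Assign uniquely mapped reads to genes; returns (counts, n_ambiguous).

    A genome-unique read is assigned to a gene when its alignment overlaps
    that gene's exons by at least ``min_overlap`` bases in total; a bridged
    read is assigned to its junction's transcript's gene (via
    ``sej_gene_of``, junction_id -> gene_id).  Reads qualifying for two or
    more genes are discarded from counting and tallied as ambiguous.
    MULTIPLE and UNMAPPED reads are never counted.
    """
    trees = _exon_trees(models)
    known_chroms = {m.chrom for m in models}
    counts = {m.gene_id: 0 for m in models}
    ambiguous = 0
    for a in alignments:
        if a.category is AlignmentClass.UNIQUE_BRIDGED and sej_gene_of:
            gene = sej_gene_of.get(a.best.target)
            if gene in counts:
                counts[gene] += 1
                continue
        if a.category not in (AlignmentClass.UNIQUE_GENOME,
                              AlignmentClass.UNIQUE_BRIDGED):
            continue
        h = a.best
        if h.chrom not in known_chroms and h.chrom not in trees:
            raise ValueError(f"alignment on unknown chromosome {h.chrom}")
        overlap: dict[str, int] = {}
        tree = trees.get(h.chrom)
        if tree is None:
            continue
        for bs, be in alignment_blocks(a):
            for iv in tree.overlap(bs, be):
                ol = min(be, iv.end) - max(bs, iv.begin)
                if ol > 0:
                    overlap[iv.data] = overlap.get(iv.data, 0) + ol
        qualifying = [g for g, ol in overlap.items() if ol >= min_overlap]
        if len(qualifying) == 1:
            counts[qualifying[0]] += 1
        elif len(qualifying) > 1:
            ambiguous += 1
    order = [m.gene_id for m in models]
    return pd.Series(counts, name="count").reindex(order), ambiguous


def expression_table(alignments_by_condition: Sequence[list[ReadAlignment]],
                     models: list[GeneModel],
                     sej_gene_of: dict[str, str] | None = None,
                     min_overlap: int = DEFAULT_MIN_OVERLAP) -> pd.DataFrame:
    """Per-gene counts and RPKM for each condition (columns C_i, RPKM_i, N_i)."""
    data = {"gene_id": [m.gene_id for m in models],
            "length": [m.exon_model_length for m in models]}
    df = pd.DataFrame(data).set_index("gene_id")
    for i, alignments in enumerate(alignments_by_condition):
        counts, ambiguous = count_reads_per_gene(
            alignments, models, sej_gene_of, min_overlap)
        if ambiguous:
            logger.info("condition %d: %d ambiguous multi-gene reads discarded",
                        i, ambiguous)
        N = library_size(alignments)
        df[f"C_{i}"] = counts.values
        df[f"N_{i}"] = N
        df[f"RPKM_{i}"] = rpkm(counts.values, df["length"].values, max(N, 1))
        if N == 0:
            df[f"RPKM_{i}"] = 0.0
    return df


def coverage_track(alignments: list[ReadAlignment],
                   chrom_lengths: dict[str, int],
                   bin_size: int = 100,
                   N: int | None = None) -> dict[str, np.ndarray]:
    """Reads overlapping each bin, per million mapped reads.

    Bridged reads contribute to the bins of both their genomic blocks and
    never to the intronic bins between them.
    """
    if bin_size <= 0:
        raise ValueError("bin size must be positive")
    if N is None:
        N = library_size(alignments)
    tracks = {c: np.zeros(-(-length // bin_size))
              for c, length in chrom_lengths.items()}
    for a in alignments:
        if a.category not in (AlignmentClass.UNIQUE_GENOME,
                              AlignmentClass.UNIQUE_BRIDGED):
            continue
        h = a.best
        track = tracks.get(h.chrom)
        if track is None:
            continue
        for bs, be in alignment_blocks(a):
            track[bs // bin_size: (be - 1) // bin_size + 1] += 1
    scale = 1e6 / max(N, 1)
    return {c: t * scale for c, t in tracks.items()}


def write_bedgraph(track: dict[str, np.ndarray], bin_size: int,
                   chrom_lengths: dict[str, int], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track):
            values = track[chrom]
            for i, v in enumerate(values):
                if v == 0:
                    continue
                end = min((i + 1) * bin_size, chrom_lengths[chrom])
                fh.write(f"{chrom}\t{i * bin_size}\t{end}\t{v:.6g}\n")


def cumulative_coverage(increments: Sequence[list[ReadAlignment]],
                        targets: list[tuple[str, int, int]],
                        chrom_lengths: dict[str, int]) -> list[float]:
    """Fraction of target bases covered by >= 1 uniquely mapped read after
    each cumulative increment of reads.  Monotone non-decreasing by
    construction (coverage only accumulates)."""
    total = sum(e - s for _, s, e in targets)
    if total == 0:
        raise ValueError("empty target region")
    covered = {c: np.zeros(length, dtype=bool)
               for c, length in chrom_lengths.items()}
    fractions = []
    for alignments in increments:
        for a in alignments:
            if a.category not in (AlignmentClass.UNIQUE_GENOME,
                                  AlignmentClass.UNIQUE_BRIDGED):
                continue
            mask = covered.get(a.best.chrom)
            if mask is None:
                continue
            for bs, be in alignment_blocks(a):
                mask[bs:be] = True
        hit = sum(int(covered[c][s:e].sum()) for c, s, e in targets
                  if c in covered)
        fractions.append(hit / total)
    return fractions


def saturation_from_counts(counts: np.ndarray,
                           increment_sizes: Sequence[int],
                           lengths: Sequence[int],
                           tolerance: float = 0.05,
                           class_bounds: Sequence[float] = SATURATION_CLASS_BOUNDS,
                           ) -> pd.DataFrame:
    """Convergence of prefix RPKM toward the full-data RPKM.

    ``counts`` is a (k increments x g genes) matrix of per-increment assigned
    read counts and ``increment_sizes`` the per-increment uniquely mapped
    totals.  Genes are stratified by their *final* RPKM into
    (<b0, [b0,b1), [b1,b2), >=b2); at each cumulative prefix the fraction of
    each stratum whose prefix RPKM lies within ``tolerance`` of the final
    value is reported.  Genes with final RPKM 0 are excluded.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2:
        raise ValueError("need a (k >= 2 increments) x genes count matrix")
    sizes = np.asarray(increment_sizes, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    cum_counts = counts.cumsum(axis=0)
    cum_N = sizes.cumsum()
    final = rpkm(cum_counts[-1], lengths, cum_N[-1])
    keep = final > 0
    b = list(class_bounds)
    edges = [0.0] + b + [np.inf]
    labels = [f"<{b[0]:g}"] + \
        [f"{lo:g}-{hi:g}" for lo, hi in zip(b[:-1], b[1:])] + [f">={b[-1]:g}"]
    strata = np.digitize(final, b)  # 0..len(b), left-closed classes
    rows = []
    for k in range(counts.shape[0]):
        prefix = rpkm(cum_counts[k], lengths, max(cum_N[k], 1))
        within = np.abs(prefix - final) <= tolerance * final
        for s, label in enumerate(labels):
            sel = keep & (strata == s)
            n = int(sel.sum())
            rows.append({
                "cumulative_reads": int(cum_N[k]),
                "expression_class": label,
                "class_low": edges[s],
                "n_genes": n,
                "fraction_converged": float(within[sel].mean()) if n else np.nan,
            })
    return pd.DataFrame(rows)


def saturation_analysis(increments: Sequence[list[ReadAlignment]],
                        models: list[GeneModel],
                        sej_gene_of: dict[str, str] | None = None,
                        tolerance: float = 0.05,
                        class_bounds: Sequence[float] = SATURATION_CLASS_BOUNDS,
                        min_overlap: int = DEFAULT_MIN_OVERLAP) -> pd.DataFrame:
    """Saturation analysis from disjoint read increments in a fixed order."""
    if len(increments) < 2:
        raise ValueError("need at least 2 increments")
    count_rows, sizes = [], []
    for alignments in increments:
        counts, _ = count_reads_per_gene(alignments, models, sej_gene_of,
                                         min_overlap)
        count_rows.append(counts.values)
        sizes.append(library_size(alignments))
    lengths = [m.exon_model_length for m in models]
    return saturation_from_counts(np.vstack(count_rows), sizes, lengths,
                                  tolerance, class_bounds)
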