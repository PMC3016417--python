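"""Transcript discovery from the pile-up of uniquely mapped reads.

The procedure is deliberately transparent: maximal coverage islands become
exon blocks, islands are joined across introns by observed junction-bridging
reads, fragments failing the RPKM >= 2 / length >= 100 bp retention filters
are dropped, and survivors are classified against the annotation at locus
granularity.  It is not an isoform-resolving assembler.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotation_model import GeneModel
from .quantifier import (DEFAULT_MIN_OVERLAP, alignment_blocks, library_size,
                         rpkm)
from .read_mapper import AlignmentClass, ReadAlignment

logger = logging.getLogger(__name__)

__all__ = [
    "TranscriptFragment",
    "depth_arrays",
    "call_islands",
    "join_islands",
    "fragment_expression",
    "filter_fragments",
    "classify_vs_annotation",
    "discover_fragments",
    "write_fragments_gff3",
    "write_fragments_bed12",
]

MIN_RPKM = 2.0
MIN_LENGTH = 100


@dataclass
class TranscriptFragment:
    """A pile-up-derived transcript model (ordered, non-overlapping blocks)."""

    fragment_id: str
    chrom: str
    blocks: list[tuple[int, int]]
    category: str = ""             # "annotated-locus" | "unannotated"
    junction_ids: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.blocks)

    @property
    def extent(self) -> tuple[int, int]:
        return self.blocks[0][0], self.blocks[-1][1]


def depth_arrays(alignments: list[ReadAlignment],
                 chrom_lengths: dict[str, int]) -> dict[str, np.ndarray]:
    """Per-base depth from uniquely mapped reads (bridged reads add depth to
    both blocks, none to the intron between)."""
    depth = {c: np.zeros(n, dtype=np.int32) for c, n in chrom_lengths.items()}
    for a in alignments:
        if a.category not in (AlignmentClass.UNIQUE_GENOME,
                              AlignmentClass.UNIQUE_BRIDGED):
            continue
        arr = depth.get(a.best.chrom)
        if arr is None:
            continue
        for bs, be in alignment_blocks(a):
            arr[bs:be] += 1
    return depth


def call_islands(depth: dict[str, np.ndarray],
                 min_depth: int = 1) -> list[tuple[str, int, int]]:
    """Maximal runs of positions with depth >= min_depth, per chromosome."""
    islands = []
    for chrom in sorted(depth):
        mask = depth[chrom] >= min_depth
        if not mask.any():
            continue
        padded = np.concatenate([[False], mask, [False]])
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        for s, e in zip(edges[::2], edges[1::2]):
            islands.append((chrom, int(s), int(e)))
    return islands


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def join_islands(islands: list[tuple[str, int, int]],
                 alignments: list[ReadAlignment],
                 min_junction_reads: int = 1) -> list[TranscriptFragment]:
    """Connect islands into multi-block fragments using bridged reads.

    Two islands are joined when at least ``min_junction_reads`` bridged reads
    have one genomic block overlapping each; joining is transitive (connected
    components).  Bridged reads whose blocks overlap no island are ignored.
    """
    trees: dict[str, IntervalTree] = {}
    for i, (chrom, s, e) in enumerate(islands):
        trees.setdefault(chrom, IntervalTree())[s:e] = i
    uf = _UnionFind(len(islands))
    pair_support: dict[tuple[int, int], int] = {}
    pair_junctions: dict[tuple[int, int], set] = {}
    for a in alignments:
        if a.category is not AlignmentClass.UNIQUE_BRIDGED:
            continue
        h = a.best
        tree = trees.get(h.chrom)
        if tree is None or len(h.blocks) != 2:
            continue
        hits = []
        for bs, be in h.blocks:
            ids = {iv.data for iv in tree.overlap(bs, be)}
            hits.append(ids)
        if not hits[0] or not hits[1]:
            logger.debug("bridged read %s overlaps no island; ignored", a.read_id)
            continue
        for i in hits[0]:
            for j in hits[1]:
                if i == j:
                    continue
                key = (min(i, j), max(i, j))
                pair_support[key] = pair_support.get(key, 0) + 1
                pair_junctions.setdefault(key, set()).add(h.target)
    joined_junctions: dict[int, set] = {}
    for key, support in pair_support.items():
        if support >= min_junction_reads:
            uf.union(*key)
    for key in pair_support:
        if pair_support[key] >= min_junction_reads:
            root = uf.find(key[0])
            joined_junctions.setdefault(root, set()).update(pair_junctions[key])
    components: dict[int, list[int]] = {}
    for i in range(len(islands)):
        components.setdefault(uf.find(i), []).append(i)
    fragments = []
    for n, root in enumerate(sorted(components)):
        members = sorted(components[root], key=lambda i: islands[i][1])
        chrom = islands[members[0]][0]
        blocks = [(islands[i][1], islands[i][2]) for i in members]
        fragments.append(TranscriptFragment(
            fragment_id=f"frag_{n:05d}", chrom=chrom, blocks=blocks,
            junction_ids=sorted(joined_junctions.get(root, ()))))
    return fragments


def fragment_expression(fragments: list[TranscriptFragment],
                        alignments_by_condition,
                        min_overlap: int = DEFAULT_MIN_OVERLAP) -> pd.DataFrame:
    """Counts and RPKM per fragment per condition.

    Same assignment rule as for genes, with the fragment's blocks as its exon
    model: a unique read counts for a fragment when its alignment blocks
    overlap the fragment's blocks by >= min_overlap bases in total; reads
    qualifying for several fragments are discarded.  Also reports pooled
    (all-conditions) RPKM, the retention statistic.
    """
    trees: dict[str, IntervalTree] = {}
    for i, f in enumerate(fragments):
        tree = trees.setdefault(f.chrom, IntervalTree())
        for s, e in f.blocks:
            tree[s:e] = i
    k = len(alignments_by_condition)
    counts = np.zeros((k, len(fragments)), dtype=int)
    Ns = []
    for ci, alignments in enumerate(alignments_by_condition):
        Ns.append(library_size(alignments))
        for a in alignments:
            if a.category not in (AlignmentClass.UNIQUE_GENOME,
                                  AlignmentClass.UNIQUE_BRIDGED):
                continue
            tree = trees.get(a.best.chrom)
            if tree is None:
                continue
            overlap: dict[int, int] = {}
            for bs, be in alignment_blocks(a):
                for iv in tree.overlap(bs, be):
                    ol = min(be, iv.end) - max(bs, iv.begin)
                    if ol > 0:
                        overlap[iv.data] = overlap.get(iv.data, 0) + ol
            qualifying = [i for i, ol in overlap.items() if ol >= min_overlap]
            if len(qualifying) == 1:
                counts[ci, qualifying[0]] += 1
    lengths = np.array([f.length for f in fragments], dtype=float)
    df = pd.DataFrame({"fragment_id": [f.fragment_id for f in fragments],
                       "length": lengths.astype(int)}).set_index("fragment_id")
    for ci in range(k):
        df[f"C_{ci}"] = counts[ci]
        df[f"N_{ci}"] = Ns[ci]
        df[f"RPKM_{ci}"] = rpkm(counts[ci], lengths, max(Ns[ci], 1))
    pooled_N = max(sum(Ns), 1)
    df["RPKM_pooled"] = rpkm(counts.sum(axis=0), lengths, pooled_N)
    return df


def filter_fragments(fragments: list[TranscriptFragment],
                     expression: pd.DataFrame,
                     min_rpkm: float = MIN_RPKM,
                     min_length: int = MIN_LENGTH,
                     rpkm_column: str = "RPKM_pooled",
                     ) -> tuple[list[TranscriptFragment], pd.DataFrame]:
    """Retain fragments with RPKM >= min_rpkm and length >= min_length
    (both thresholds inclusive)."""
    keep_ids = []
    kept = []
    for f in fragments:
        if f.length >= min_length and \
                expression.loc[f.fragment_id, rpkm_column] >= min_rpkm:
            kept.append(f)
            keep_ids.append(f.fragment_id)
    return kept, expression.loc[keep_ids]


def classify_vs_annotation(fragments: list[TranscriptFragment],
                           models: list[GeneModel]) -> None:
    """Set each fragment's category in place.

    annotated-locus iff any block overlaps any annotated gene's locus extent
    (first to last exon, introns included, strand-agnostic) by >= 1 bp; else
    unannotated.
    """
    trees: dict[str, IntervalTree] = {}
    for m in models:
        lo, hi = m.extent
        trees.setdefault(m.chrom, IntervalTree())[lo:hi] = m.gene_id
    for f in fragments:
        tree = trees.get(f.chrom)
        hit = tree is not None and any(tree.overlap(s, e) for s, e in f.blocks)
        f.category = "annotated-locus" if hit else "unannotated"


def discover_fragments(alignments_by_condition,
                       models: list[GeneModel],
                       chrom_lengths: dict[str, int],
                       min_depth: int = 1,
                       min_junction_reads: int = 1,
                       min_rpkm: float = MIN_RPKM,
                       min_length: int = MIN_LENGTH,
                       ) -> tuple[list[TranscriptFragment], pd.DataFrame]:
    """End-to-end discovery: pile-up -> islands -> joining -> filters ->
    annotation classification.  Pools reads of all conditions for the
    pile-up; expression is reported per condition."""
    pooled = [a for alignments in alignments_by_condition for a in alignments]
    depth = depth_arrays(pooled, chrom_lengths)
    islands = call_islands(depth, min_depth)
    fragments = join_islands(islands, pooled, min_junction_reads)
    expr = fragment_expression(fragments, alignments_by_condition)
    fragments, expr = filter_fragments(fragments, expr, min_rpkm, min_length)
    classify_vs_annotation(fragments, models)
    return fragments, expr


def write_fragments_gff3(fragments: list[TranscriptFragment],
                         expression: pd.DataFrame,
                         path: str | os.PathLike) -> None:
    lines = ["##gff-version 3"]
    for f in fragments:
        lo, hi = f.extent
        row = expression.loc[f.fragment_id]
        attrs = (f"ID={f.fragment_id};category={f.category};"
                 f"RPKM_0={row['RPKM_0']:.6g};RPKM_1={row['RPKM_1']:.6g}")
        lines.append("\t".join([f.chrom, "rnapile", "transcript_fragment",
                                str(lo + 1), str(hi), ".", ".", ".", attrs]))
        for i, (s, e) in enumerate(f.blocks, 1):
            lines.append("\t".join([
                f.chrom, "rnapile", "exon", str(s + 1), str(e), ".", ".", ".",
                f"ID={f.fragment_id}.block{i};Parent={f.fragment_id}"]))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_fragments_bed12(fragments: list[TranscriptFragment],
                          path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for f in fragments:
            lo, hi = f.extent
            sizes = ",".join(str(e - s) for s, e in f.blocks) + ","
            starts = ",".join(str(s - lo) for s, e in f.blocks) + ","
            fh.write("\t".join(map(str, [
                f.chrom, lo, hi, f.fragment_id, 0, ".", lo, hi, "0",
                len(f.blocks), sizes, starts])) + "\n")
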