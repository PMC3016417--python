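"""Seed-and-extend alignment of 36-bp reads to genome + SEJ library.

Alignment contract: up to 2 mismatches, or a single contiguous indel of up
to 3 bp (mismatches and indels never combine in one alignment).  Both strands
of the genome and of every SEJ sequence are searched.  Alignments are ranked
by stratum ``(mismatches, indel length)``, lexicographically; within the best
stratum a genomic hit takes precedence over an SEJ hit, because an SEJ hit
that does not cross the junction is redundant with the genome.  An SEJ hit
counts as "bridged" only when the read overlaps the junction point by at
least one base on each side; bridged hits are projected back to two genomic
blocks through the SEJ record's flank intervals.

Indel alignments are searched on the genome only; SEJ hits are mismatch-only
(an indel across a junction record has no unambiguous two-block projection,
and junction+indel reads are vanishingly rare at realistic error rates).

The index uses 12-mer exact seeds in three partitions (0-12, 12-24, 24-36):
by pigeonhole, any <=2-mismatch alignment of a 36-bp read leaves at least one
partition exact.  For one indel with otherwise exact matching, the read
splits into two exact segments, one of which anchors either the first or the
last 12-mer, so those two seeds are additionally queried in gapped mode.
Correctness, not speed, is the contract: the exhaustive scorer in the test
suite is the arbiter.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .annotation_model import SEJRecord
from .util import (SEPARATOR_CODE, common_prefix_len, common_suffix_len,
                   encode, revcomp)

__all__ = [
    "AlignmentClass",
    "Hit",
    "ReadAlignment",
    "MappingStats",
    "ReferenceIndex",
    "align_read",
    "align_reads",
    "mapping_stats",
    "classify_unmapped",
    "write_sam",
    "write_alignment_tsv",
    "write_mapping_stats_tsv",
]


class AlignmentClass(str, Enum):
    UNIQUE_GENOME = "UNIQUE_GENOME"
    UNIQUE_BRIDGED = "UNIQUE_BRIDGED"
    MULTIPLE = "MULTIPLE"
    UNMAPPED = "UNMAPPED"


@dataclass(frozen=True)
class Hit:
    """One candidate placement of a read.

    ``start`` is 0-based on the forward strand of the target (chromosome or
    SEJ record); ``span`` is the number of target bases consumed (read length
    +d for a deletion in the read, -d for an insertion).  For SEJ hits,
    ``blocks`` holds the two projected genomic intervals and ``chrom`` the
    genomic chromosome.
    """

    kind: str                    # "genome" | "sej"
    target: str                  # chromosome name or junction_id
    chrom: str
    start: int
    strand: str
    mismatches: int
    indel_len: int
    span: int
    blocks: tuple[tuple[int, int], ...] = ()

    @property
    def stratum(self) -> tuple[int, int]:
        return (self.mismatches, self.indel_len)


@dataclass
class ReadAlignment:
    read_id: str
    category: AlignmentClass
    hits: list[Hit] = field(default_factory=list)

    @property
    def best(self) -> Hit | None:
        return self.hits[0] if self.hits else None


class ReferenceIndex:
    """12-mer seed index over genome chromosomes plus the SEJ library."""

    SEED = 12

    def __init__(self, genome: dict[str, str], sej_records: list[SEJRecord],
                 max_mismatch: int = 2, max_indel: int = 3,
                 min_bridge_overlap: int = 1):
        if not genome:
            raise ValueError("empty genome index")
        self.genome = genome
        self.sej_by_id = {r.junction_id: r for r in sej_records}
        self.max_mismatch = max_mismatch
        self.max_indel = max_indel
        self.min_bridge_overlap = min_bridge_overlap

        # concatenate all targets with >=35-byte separators so neither seeds
        # nor alignments can cross a target boundary
        sep = np.full(35, SEPARATOR_CODE, dtype=np.uint8)
        parts, self._targets, self._starts = [], [], []
        pos = 0
        for name in sorted(genome):
            arr = encode(genome[name])
            parts.extend([arr, sep])
            self._targets.append(("genome", name, len(arr)))
            self._starts.append(pos)
            pos += len(arr) + len(sep)
        for rec in sej_records:
            arr = encode(rec.sequence)
            parts.extend([arr, sep])
            self._targets.append(("sej", rec.junction_id, len(arr)))
            self._starts.append(pos)
            pos += len(arr) + len(sep)
        self._seq = np.concatenate(parts) if parts else sep
        self._starts = np.asarray(self._starts)
        self._build_seed_index()

    def _build_seed_index(self) -> None:
        k = self.SEED
        seq = self._seq.astype(np.uint32)
        n = len(seq) - k + 1
        if n <= 0:
            self._sorted_keys = np.empty(0, dtype=np.uint32)
            self._sorted_pos = np.empty(0, dtype=np.int64)
            return
        keys = np.zeros(n, dtype=np.uint32)
        valid = np.ones(n, dtype=bool)
        for j in range(k):
            w = seq[j:j + n]
            keys = (keys << 2) | (w & 3)
            valid &= w < 4
        pos = np.flatnonzero(valid)
        keys = keys[pos]
        order = np.argsort(keys, kind="stable")
        self._sorted_keys = keys[order]
        self._sorted_pos = pos[order]

    def _seed_positions(self, codes: np.ndarray) -> np.ndarray:
        if (codes > 3).any():
            return np.empty(0, dtype=np.int64)
        key = np.uint32(0)
        for c in codes:
            key = np.uint32((int(key) << 2) | int(c))
        lo = np.searchsorted(self._sorted_keys, key, side="left")
        hi = np.searchsorted(self._sorted_keys, key, side="right")
        return self._sorted_pos[lo:hi]

    def _locate(self, pos: int) -> tuple[int, int]:
        """Map a concatenated-space offset to (target index, local offset)."""
        i = int(np.searchsorted(self._starts, pos, side="right")) - 1
        return i, pos - int(self._starts[i])

    # ------------------------------------------------------------- alignment

    def _mismatch_hits(self, codes: np.ndarray, strand: str) -> list[tuple]:
        """All ungapped placements with <= max_mismatch mismatches."""
        L = len(codes)
        k = self.SEED
        cands: set[int] = set()
        for part in range(0, L - k + 1, k):
            for p in self._seed_positions(codes[part:part + k]):
                cands.add(int(p) - part)
        out = []
        for s in cands:
            if s < 0 or s + L > len(self._seq):
                continue
            mm = int(np.count_nonzero(self._seq[s:s + L] != codes))
            if mm <= self.max_mismatch:
                out.append((s, strand, mm, 0, L))
        return out

    def _indel_hits(self, codes: np.ndarray, strand: str) -> list[tuple]:
        """Placements with one 1..max_indel bp gap and no mismatches."""
        L = len(codes)
        k = self.SEED
        anchors: set[int] = set()
        for p in self._seed_positions(codes[:k]):           # start-anchored
            anchors.add(int(p))
        for p in self._seed_positions(codes[L - k:]):       # end-anchored
            end = int(p) + k
            for d in range(1, self.max_indel + 1):
                anchors.add(end - L - d)   # deletion in read: span L+d
                anchors.add(end - L + d)   # insertion in read: span L-d
        out = []
        seen: set[tuple] = set()
        for s in anchors:
            if s < 0:
                continue
            lcp = common_prefix_len(codes, self._seq[s:s + L])
            if lcp == 0:
                continue
            for d in range(1, self.max_indel + 1):
                # deletion in read: prefix p at s, suffix at s+p+d; span L+d;
                # feasible iff some split p in [1, L-1] has p <= lcp and
                # L-p <= lcs, i.e. max(1, L-lcs) <= min(L-1, lcp)
                if s + L + d <= len(self._seq):
                    lcs = common_suffix_len(codes, self._seq[s + d:s + L + d])
                    if max(1, L - lcs) <= min(L - 1, lcp):
                        key = (s, strand, d, L + d)
                        if key not in seen:
                            seen.add(key)
                            out.append((s, strand, 0, d, L + d))
                # insertion in read: span L-d, split p in [1, L-d-1]
                if L - d >= 2 and s + L - d <= len(self._seq):
                    lcs = common_suffix_len(codes[d:], self._seq[s:s + L - d])
                    if max(1, L - d - lcs) <= min(L - d - 1, lcp):
                        key = (s, strand, -d, L - d)
                        if key not in seen:
                            seen.add(key)
                            out.append((s, strand, 0, d, L - d))
        return out

    def align(self, read_id: str, seq: str) -> ReadAlignment:
        """Align one read; see the module docstring for the contract."""
        L = len(seq)
        if L < 20:
            raise ValueError("reads shorter than 20 bp are rejected upstream")
        fwd = encode(seq)
        rev = encode(revcomp(seq))
        raw: list[tuple] = []
        for strand, codes in (("+", fwd), ("-", rev)):
            raw.extend(self._mismatch_hits(codes, strand))
        best_mm = min((h[2] for h in raw), default=None)
        if best_mm is None or best_mm > 0:
            # an indel alignment (stratum (0, d)) could still win
            for strand, codes in (("+", fwd), ("-", rev)):
                raw.extend(self._indel_hits(codes, strand))
        hits = []
        for s, strand, mm, indel, span in raw:
            ti, local = self._locate(s)
            kind, name, tlen = self._targets[ti]
            if local + span > tlen:
                continue
            if kind == "sej" and indel > 0:
                continue  # SEJ hits are mismatch-only by contract
            hits.append(self._make_hit(kind, name, local, strand, mm, indel, span))
        hits = [h for h in hits if h is not None]
        if not hits:
            return ReadAlignment(read_id, AlignmentClass.UNMAPPED)
        best = min(h.stratum for h in hits)
        top = [h for h in hits if h.stratum == best]
        genome_top = [h for h in top if h.kind == "genome"]
        if genome_top:
            chosen = sorted(genome_top, key=lambda h: (h.chrom, h.start, h.strand))
            cat = (AlignmentClass.UNIQUE_GENOME if len(chosen) == 1
                   else AlignmentClass.MULTIPLE)
            return ReadAlignment(read_id, cat, chosen)
        # bridged hits: dedupe junctions that project to identical blocks
        by_blocks: dict[tuple, Hit] = {}
        for h in sorted(top, key=lambda h: (h.target, h.start, h.strand)):
            by_blocks.setdefault((h.chrom, h.blocks, h.strand), h)
        chosen = list(by_blocks.values())
        cat = (AlignmentClass.UNIQUE_BRIDGED if len(chosen) == 1
               else AlignmentClass.MULTIPLE)
        return ReadAlignment(read_id, cat, chosen)

    def _make_hit(self, kind, name, local, strand, mm, indel, span):
        if kind == "genome":
            return Hit(kind, name, name, local, strand, mm, indel, span)
        rec = self.sej_by_id[name]
        j = rec.offset
        left_olap = j - local
        right_olap = local + span - j
        if left_olap < self.min_bridge_overlap or right_olap < self.min_bridge_overlap:
            return None  # does not cross the junction: redundant with genome
        blocks = ((rec.left[1] - left_olap, rec.left[1]),
                  (rec.right[0], rec.right[0] + right_olap))
        return Hit(kind, name, rec.chrom, local, strand, mm, indel, span, blocks)


def align_read(read_id: str, seq: str, index: ReferenceIndex) -> ReadAlignment:
    return index.align(read_id, seq)


def align_reads(reads: list[tuple[str, str]],
                index: ReferenceIndex) -> list[ReadAlignment]:
    return [index.align(rid, seq) for rid, seq in reads]


# ------------------------------------------------------------------ summaries

@dataclass
class MappingStats:
    """Four-way read classification counts with one-decimal percentages."""

    total: int
    unique_genome: int
    unique_bridged: int
    multiple: int
    unmapped: int

    @property
    def unique_total(self) -> int:
        return self.unique_genome + self.unique_bridged

    def pct(self, count: int) -> float:
        return 0.0 if self.total == 0 else round(100.0 * count / self.total, 1)

    def as_dict(self) -> dict[str, float | int]:
        return {
            "total": self.total,
            "unique_total": self.unique_total,
            "unique_total_pct": self.pct(self.unique_total),
            "unique_genome": self.unique_genome,
            "unique_genome_pct": self.pct(self.unique_genome),
            "unique_bridged": self.unique_bridged,
            "unique_bridged_pct": self.pct(self.unique_bridged),
            "multiple": self.multiple,
            "multiple_pct": self.pct(self.multiple),
            "unmapped": self.unmapped,
            "unmapped_pct": self.pct(self.unmapped),
        }


def mapping_stats(alignments: list[ReadAlignment] | None = None,
                  counts: dict[str, int] | None = None,
                  total: int | None = None) -> MappingStats:
    """Tabulate the four-way classification.

    Either pass alignments, or pass pre-tabulated ``counts`` with keys
    unique_genome / unique_bridged / multiple / unmapped (useful for checking
    published count tables).  ``total`` overrides the summed total for
    published tables whose filtered-read total exceeds the tabulated classes;
    for alignment input the partition is exact by construction.
    """
    if counts is None:
        seen = set()
        counts = {c.value: 0 for c in AlignmentClass}
        for a in alignments or []:
            if a.read_id in seen:
                raise ValueError(f"duplicate read id {a.read_id}")
            seen.add(a.read_id)
            counts[a.category.value] += 1
        counts = {
            "unique_genome": counts["UNIQUE_GENOME"],
            "unique_bridged": counts["UNIQUE_BRIDGED"],
            "multiple": counts["MULTIPLE"],
            "unmapped": counts["UNMAPPED"],
        }
    if total is None:
        total = sum(counts.values())
    return MappingStats(total=total, **counts)


def classify_unmapped(reads: list[tuple[str, str]],
                      adapter_refs: dict[str, str],
                      rrna_refs: dict[str, str],
                      foreign_refs: dict[str, str],
                      min_identity: float = 0.90) -> dict[str, str]:
    """Assign unmapped reads to contaminant categories.

    A read matches a reference when an ungapped alignment over the *full*
    read reaches ``min_identity`` on either strand.  Categories are assigned
    in priority order adapter -> foreign organism -> rRNA; everything else is
    "other".  Empty reference sets simply never match.
    """
    if not reads:
        return {}
    L = len(reads[0][1])
    ref_sets = [("adapter", adapter_refs), ("foreign", foreign_refs),
                ("rrna", rrna_refs)]
    # every full-read placement in every reference, as one window matrix per
    # category, so each read is screened with a handful of vector ops
    windows = {}
    for cat, refs in ref_sets:
        mats = []
        for s in refs.values():
            arr = encode(s)
            n = len(arr) - L + 1
            if n > 0:
                mats.append(np.lib.stride_tricks.sliding_window_view(arr, L))
        windows[cat] = np.vstack(mats) if mats else None
    out = {}
    for rid, seq in reads:
        if len(seq) != L:
            raise ValueError("classify_unmapped expects equal-length reads")
        need = int(np.ceil(min_identity * L))
        fwd, rev = encode(seq), encode(revcomp(seq))
        category = "other"
        for cat, _ in ref_sets:
            w = windows[cat]
            if w is None:
                continue
            best = max(int((w == fwd).sum(axis=1).max()),
                       int((w == rev).sum(axis=1).max()))
            if best >= need:
                category = cat
                break
        out[rid] = category
    return out


# ------------------------------------------------------------------- writers

def write_sam(alignments: list[ReadAlignment], reads: dict[str, str],
              chrom_lengths: dict[str, int], path: str | os.PathLike) -> None:
    """Emit SAM; bridged alignments use an N CIGAR operation across the intron."""
    import pysam

    names = sorted(chrom_lengths)
    header = {"HD": {"VN": "1.6", "SO": "unknown"},
              "SQ": [{"SN": n, "LN": chrom_lengths[n]} for n in names]}
    tid = {n: i for i, n in enumerate(names)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for aln in alignments:
            seg = pysam.AlignedSegment()
            seg.query_name = aln.read_id
            seq = reads.get(aln.read_id, "")
            h = aln.best
            if aln.category in (AlignmentClass.UNMAPPED, AlignmentClass.MULTIPLE) \
                    or h is None:
                seg.is_unmapped = True
                seg.query_sequence = seq or None
                out.write(seg)
                continue
            L = len(seq)
            seg.reference_id = tid[h.chrom]
            seg.is_reverse = h.strand == "-"
            seg.query_sequence = seq if h.strand == "+" else revcomp(seq)
            seg.mapping_quality = 255
            if aln.category is AlignmentClass.UNIQUE_BRIDGED:
                (l0, l1), (r0, r1) = h.blocks
                seg.reference_start = l0
                seg.cigarstring = f"{l1 - l0}M{r0 - l1}N{r1 - r0}M"
                seg.set_tag("XJ", h.target)
            else:
                seg.reference_start = h.start
                if h.indel_len == 0:
                    seg.cigarstring = f"{L}M"
                elif h.span > L:   # deletion in read
                    d = h.span - L
                    p = min(L - 1, max(1, L // 2))
                    seg.cigarstring = f"{p}M{d}D{L - p}M"
                else:              # insertion in read
                    d = L - h.span
                    p = min(h.span - 1, max(1, h.span // 2))
                    seg.cigarstring = f"{p}M{d}I{L - p - d}M"
                seg.set_tag("NM", h.mismatches + h.indel_len)
            out.write(seg)


def write_alignment_tsv(alignments: list[ReadAlignment],
                        path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tclass\tchrom\tstart\tstrand\tmismatches\t"
                 "indel_len\tblocks\tjunction_id\n")
        for a in alignments:
            h = a.best
            if h is None:
                fh.write(f"{a.read_id}\t{a.category.value}\t.\t.\t.\t.\t.\t.\t.\n")
                continue
            blocks = (",".join(f"{s}-{e}" for s, e in h.blocks)
                      if h.blocks else f"{h.start}-{h.start + h.span}")
            jid = h.target if h.kind == "sej" else "."
            fh.write(f"{a.read_id}\t{a.category.value}\t{h.chrom}\t{h.start}\t"
                     f"{h.strand}\t{h.mismatches}\t{h.indel_len}\t{blocks}\t{jid}\n")


def write_mapping_stats_tsv(stats_by_sample: dict[str, MappingStats],
                            path: str | os.PathLike) -> None:
    cols = ["total", "unique_total", "unique_total_pct", "unique_genome",
            "unique_genome_pct", "unique_bridged", "unique_bridged_pct",
            "multiple", "multiple_pct", "unmapped", "unmapped_pct"]
    with open(path, "w") as fh:
        fh.write("sample\t" + "\t".join(cols) + "\n")
        for sample, st in stats_by_sample.items():
            d = st.as_dict()
            fh.write(sample + "\t" + "\t".join(str(d[c]) for c in cols) + "\n")
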