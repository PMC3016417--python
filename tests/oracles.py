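"""Independent oracles used by the test suite.

Everything here is deliberately written from the definitions, without seeds,
indexes or shortcuts, so it can arbitrate the production implementations:
an exhaustive aligner that scores every offset on both strands, a direct
2x2 likelihood-ratio statistic, a hand-rolled BH step-up, a six-frame ORF
enumerator, and a tiny local-alignment DP.
"""

from __future__ import annotations

import math

import numpy as np

from rnapile.util import encode, revcomp

L_DEFAULT = 36


def _mismatch_matrix(genome_codes: np.ndarray, read_codes: np.ndarray) -> np.ndarray:
    """M[j, off] = 1 iff genome[off + j] != read[j], for every valid offset."""
    L = len(read_codes)
    n = len(genome_codes) - L + 1
    if n <= 0:
        return np.zeros((L, 0), dtype=np.int32)
    M = np.empty((L, n), dtype=np.int32)
    for j in range(L):
        M[j] = genome_codes[j:j + n] != read_codes[j]
    return M


def exhaustive_ungapped(genome_codes: np.ndarray, read_codes: np.ndarray,
                        max_mm: int) -> list[tuple[int, int]]:
    """All (offset, mismatches) with mismatches <= max_mm."""
    M = _mismatch_matrix(genome_codes, read_codes)
    if M.shape[1] == 0:
        return []
    mm = M.sum(axis=0)
    return [(int(o), int(mm[o])) for o in np.flatnonzero(mm <= max_mm)]


def _segment_matches(genome_codes, read_codes, off, r_lo, r_hi, g_start):
    """Exact match of read[r_lo:r_hi] at genome position g_start (scalar)."""
    if g_start < 0 or g_start + (r_hi - r_lo) > len(genome_codes):
        return False
    return bool((genome_codes[g_start:g_start + (r_hi - r_lo)]
                 == read_codes[r_lo:r_hi]).all())


def exhaustive_gapped(genome_codes: np.ndarray, read_codes: np.ndarray,
                      max_indel: int) -> list[tuple[int, int, int]]:
    """All (offset, indel_len, span) placements with one 1..max_indel bp gap
    and zero mismatches, checked at every offset and every split point.

    The check is the definition itself — prefix read[:p] exact at off and
    suffix exact after the gap — evaluated for all (off, p) via cumulative
    mismatch sums; a small scalar fallback covers chromosome-edge offsets
    the matrix cannot represent.
    """
    L = len(read_codes)
    G = len(genome_codes)
    out = []
    M = _mismatch_matrix(genome_codes, read_codes)
    n = M.shape[1]          # offsets with a full ungapped window
    if n <= 0:
        return out
    pm = np.zeros((L + 1, n), dtype=np.int32)   # pm[p, off] = mm of read[:p]
    np.cumsum(M, axis=0, out=pm[1:])
    for d in range(1, max_indel + 1):
        # deletion in read (genome consumes L + d): prefix at off, suffix at
        # off + p + d, i.e. read[p:] aligned at offset off + d of the matrix
        if n - d > 0:
            A = pm[1:L, 0:n - d] == 0
            B = (pm[L, d:n][None, :] - pm[1:L, d:n]) == 0
            for off in np.flatnonzero((A & B).any(axis=0)):
                out.append((int(off), d, L + d))
        # insertion in read (genome consumes L - d): suffix read[p+d:]
        # aligned at matrix offset off - d
        if L - d >= 2:
            if n - d > 0:
                A = pm[1:L - d, d:n] == 0
                B = (pm[L, 0:n - d][None, :] - pm[1 + d:L, 0:n - d]) == 0
                for off in np.flatnonzero((A & B).any(axis=0)):
                    out.append((int(off) + d, d, L - d))
            # edge offsets outside the matrix: off < d or off >= n
            edge = list(range(0, min(d, G))) + \
                list(range(max(n, d), min(G - (L - d), n + d) + 1))
            for off in edge:
                if off < 0 or off + L - d > G:
                    continue
                for p in range(1, L - d):
                    if _segment_matches(genome_codes, read_codes, off, 0, p, off) \
                            and _segment_matches(genome_codes, read_codes, off,
                                                 p + d, L, off + p):
                        out.append((off, d, L - d))
                        break
    return out


def brute_force_align(seq: str, genome: dict[str, str], sej_records,
                      max_mm: int = 2, max_indel: int = 3,
                      min_bridge: int = 1):
    """Exhaustively classify one read against genome + SEJ library.

    Returns (category, frozenset of hit keys).  Hit keys are
    ('genome', chrom, start, strand, mm, indel, span) or
    ('sej', chrom, blocks, strand, mm) after junction-crossing filtering,
    block projection and block-level deduplication — the same contract the
    production mapper implements, derived here from the definitions.
    """
    genome_hits = []
    sej_hits = []
    for strand, oriented in (("+", seq), ("-", revcomp(seq))):
        codes = encode(oriented)
        L = len(codes)
        for chrom in sorted(genome):
            g = encode(genome[chrom])
            for off, mm in exhaustive_ungapped(g, codes, max_mm):
                genome_hits.append((chrom, off, strand, mm, 0, L))
            for off, d, span in exhaustive_gapped(g, codes, max_indel):
                genome_hits.append((chrom, off, strand, 0, d, span))
        for rec in sej_records:
            g = encode(rec.sequence)
            for off, mm in exhaustive_ungapped(g, codes, max_mm):
                j = rec.offset
                left = j - off
                right = off + L - j
                if left < min_bridge or right < min_bridge:
                    continue
                blocks = ((rec.left[1] - left, rec.left[1]),
                          (rec.right[0], rec.right[0] + right))
                sej_hits.append((rec.chrom, blocks, strand, mm))
    strata = [ (mm, ind) for (_, _, _, mm, ind, _) in genome_hits ] + \
             [ (mm, 0) for (_, _, _, mm) in sej_hits ]
    if not strata:
        return "UNMAPPED", frozenset()
    best = min(strata)
    g_top = [h for h in genome_hits if (h[3], h[4]) == best]
    if g_top:
        keys = frozenset(("genome",) + h for h in g_top)
        return ("UNIQUE_GENOME" if len(g_top) == 1 else "MULTIPLE"), keys
    s_top = {}
    for chrom, blocks, strand, mm in sej_hits:
        if (mm, 0) == best:
            s_top[(chrom, blocks, strand)] = mm
    keys = frozenset(("sej", c, b, s, mm) for (c, b, s), mm in s_top.items())
    return ("UNIQUE_BRIDGED" if len(s_top) == 1 else "MULTIPLE"), keys


def alignment_keys(alignment) -> frozenset:
    """Hit keys of a production ReadAlignment in the oracle's vocabulary."""
    keys = set()
    for h in alignment.hits:
        if h.kind == "genome":
            keys.add(("genome", h.chrom, h.start, h.strand, h.mismatches,
                      h.indel_len, h.span))
        else:
            keys.add(("sej", h.chrom, h.blocks, h.strand, h.mismatches))
    return frozenset(keys)


# ------------------------------------------------------------- statistics

def lrt_2x2(c0: int, c1: int, n0: int, n1: int) -> float:
    """Likelihood-ratio statistic for a 2x2 gene-vs-rest x condition table,
    computed cell by cell from observed and margin-expected counts."""
    table = [[c0, c1], [n0 - c0, n1 - c1]]
    total = n0 + n1
    g = 0.0
    for i in range(2):
        for j in range(2):
            o = table[i][j]
            if o == 0:
                continue
            e = (table[i][0] + table[i][1]) * (table[0][j] + table[1][j]) / total
            g += o * math.log(o / e)
    return 2.0 * g


def bh_stepup(pvalues, alpha: float):
    """Manual Benjamini-Hochberg: returns (q, reject) in input order."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        q_sorted[rank - 1] = running
    q = np.empty(m)
    q[order] = q_sorted
    k = 0
    for rank in range(1, m + 1):
        if p[order[rank - 1]] <= rank * alpha / m:
            k = rank
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    return q, reject


# ----------------------------------------------------------------- ORFs

STOPS = {"TAA", "TAG", "TGA"}


def orf_enumerate(seq: str) -> list[tuple[int, int, int]]:
    """Every ATG..stop ORF in all six frames as (aa_len, frame, start_codon_pos);
    ORFs may not span codons containing non-ACGT bases."""
    out = []
    rc = revcomp(seq)
    for frame in range(1, 7):
        s = (seq if frame <= 3 else rc).upper()
        off = (frame - 1) % 3
        codons = [s[off + 3 * i: off + 3 * i + 3]
                  for i in range((len(s) - off) // 3)]
        for i, c in enumerate(codons):
            if c != "ATG":
                continue
            for j in range(i + 1, len(codons)):
                cj = codons[j]
                if any(b not in "ACGT" for b in cj):
                    break
                if cj in STOPS:
                    out.append((j - i, frame, i))
                    break
    return out


def brute_longest_orf(seq: str) -> tuple[int, int]:
    """(aa_len, frame) of the longest ORF; frame ties to the smaller number."""
    orfs = orf_enumerate(seq)
    if not orfs:
        return 0, 0
    best = max(orfs, key=lambda o: (o[0], -o[1], -o[2]))
    return best[0], best[1]


def local_align_dp(a: str, b: str, match: int = 1, mismatch: int = -1,
                   gap: int = -2) -> int:
    """Smith-Waterman best local score with linear gap penalty."""
    m, n = len(a), len(b)
    prev = [0] * (n + 1)
    best = 0
    for i in range(1, m + 1):
        cur = [0] * (n + 1)
        for j in range(1, n + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            cur[j] = max(0, prev[j - 1] + s, prev[j] + gap, cur[j - 1] + gap)
            best = max(best, cur[j])
        prev = cur
    return best
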