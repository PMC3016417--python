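"""ORF content of unannotated transcript fragments.

Fragments are split three ways, mirroring how novel transcripts are triaged
against a protein database: (1) a translated-similarity hit to a supplied
protein set; (2) no hit but a longest ORF of >= 20 amino acids; (3) neither.
The translated search is a transparent local-alignment criterion (match +1,
mismatch -1, gap -2; identity and aligned-length thresholds) against a
user-supplied protein FASTA; hit tables computed by an external
translated-similarity search can also be imported via :func:`read_hits_tsv`
and used for the same categorisation.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Seq import Seq

from .util import revcomp

__all__ = [
    "ORFResult",
    "TranslatedHit",
    "longest_orf",
    "translated_search",
    "categorize",
    "orf_report",
    "read_hits_tsv",
]

STOP_CODONS = {"TAA", "TAG", "TGA"}
START_CODON = "ATG"
CATEGORIES = ("similarity-hit", "orf-ge-20-no-hit", "no-orf-or-lt-20")


@dataclass(frozen=True)
class ORFResult:
    """Longest ORF over all six frames.

    ``aa_length`` excludes the stop codon; ``frame`` is 1-3 for the forward
    strand offsets 0-2 and 4-6 for the reverse strand (0 when no ORF exists).
    ``nt_start``/``nt_end`` delimit the ORF including its stop codon, in the
    input sequence's forward coordinates.
    """

    aa_length: int
    frame: int
    nt_start: int
    nt_end: int
    protein: str


_EMPTY_ORF = ORFResult(0, 0, -1, -1, "")


def _scan_frame(seq: str, offset: int) -> tuple[int, int, int] | None:
    """Best (aa_len, start_codon_index, stop_codon_index) in one frame.

    An ORF requires both an ATG and an in-frame stop; codons containing
    non-ACGT characters are untranslatable barriers an ORF cannot span.
    Ties prefer the leftmost start.
    """
    best = None
    start = None   # codon index of the earliest ATG since the last stop/barrier
    n_codons = (len(seq) - offset) // 3
    for ci in range(n_codons):
        codon = seq[offset + 3 * ci: offset + 3 * ci + 3]
        if any(b not in "ACGT" for b in codon):
            start = None
            continue
        if codon in STOP_CODONS:
            if start is not None:
                aa = ci - start
                if aa > 0 and (best is None or aa > best[0]):
                    best = (aa, start, ci)
            start = None
        elif codon == START_CODON and start is None:
            start = ci
    return best


def longest_orf(sequence: str) -> ORFResult:
    """Scan all six reading frames for the longest ATG-to-stop ORF.

    Ties are broken by frame number (1-6), then by leftmost start within the
    scanned orientation of that frame.
    """
    if len(sequence) < 3:
        raise ValueError("sequence must be at least one codon long")
    seq = sequence.upper()
    rc = revcomp(seq)
    best = _EMPTY_ORF
    for frame in range(1, 7):
        s = seq if frame <= 3 else rc
        offset = (frame - 1) % 3
        found = _scan_frame(s, offset)
        if found is None:
            continue
        aa, start_ci, stop_ci = found
        if aa <= best.aa_length:
            continue
        lo = offset + 3 * start_ci
        hi = offset + 3 * (stop_ci + 1)
        if frame <= 3:
            nt_start, nt_end = lo, hi
        else:
            nt_start, nt_end = len(seq) - hi, len(seq) - lo
        protein = str(Seq(s[lo:hi - 3]).translate())
        best = ORFResult(aa, frame, nt_start, nt_end, protein)
    return best


@dataclass(frozen=True)
class TranslatedHit:
    subject: str
    description: str
    identity: float
    aln_len: int
    score: float
    frame: int


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    return aligner


def _six_frame_translations(seq: str) -> list[tuple[int, str]]:
    out = []
    rc = revcomp(seq.upper())
    for frame in range(1, 7):
        s = seq.upper() if frame <= 3 else rc
        offset = (frame - 1) % 3
        trimmed = s[offset: offset + 3 * ((len(s) - offset) // 3)]
        if trimmed:
            out.append((frame, str(Seq(trimmed).translate())))
    return out


def translated_search(sequence: str,
                      proteins: list[tuple[str, str, str]],
                      min_identity: float = 0.40,
                      min_aln_aa: int = 30) -> TranslatedHit | None:
    """Best local alignment of any six-frame translation against a protein set.

    A hit requires identity >= ``min_identity`` over >= ``min_aln_aa``
    aligned residue pairs; the best hit is chosen by alignment score.  An
    empty protein set yields no hit (never an error).
    """
    if not proteins:
        return None
    aligner = _make_aligner()
    best: TranslatedHit | None = None
    for frame, translation in _six_frame_translations(sequence):
        if not translation:
            continue
        for pid, desc, prot in proteins:
            if not prot:
                continue
            alignments = aligner.align(translation, prot)
            if len(alignments) == 0:
                continue
            aln = alignments[0]
            pairs = matches = 0
            for (qs, qe), (ts, te) in zip(*aln.aligned):
                pairs += qe - qs
                matches += sum(a == b for a, b in
                               zip(translation[qs:qe], prot[ts:te]))
            if pairs < min_aln_aa:
                continue
            identity = matches / pairs
            if identity < min_identity:
                continue
            cand = TranslatedHit(pid, desc, identity, pairs,
                                 float(aln.score), frame)
            if best is None or cand.score > best.score:
                best = cand
    return best


def categorize(fragment_ids: list[str],
               hits: dict[str, TranslatedHit | None],
               orfs: dict[str, ORFResult],
               min_orf_aa: int = 20) -> tuple[pd.DataFrame, dict[str, int]]:
    """Three-way ORF categorisation of unannotated fragments.

    Precedence: similarity hit > ORF >= min_orf_aa (inclusive) > rest.  The
    returned counts partition ``fragment_ids`` exactly.
    """
    rows = []
    counts = dict.fromkeys(CATEGORIES, 0)
    for fid in fragment_ids:
        if fid not in hits or fid not in orfs:
            raise ValueError(f"fragment {fid} missing from hits/orfs input")
        hit = hits[fid]
        orf = orfs[fid]
        if hit is not None:
            cat = "similarity-hit"
        elif orf.aa_length >= min_orf_aa:
            cat = "orf-ge-20-no-hit"
        else:
            cat = "no-orf-or-lt-20"
        counts[cat] += 1
        rows.append({
            "fragment_id": fid,
            "aa_length": orf.aa_length,
            "frame": orf.frame,
            "category": cat,
            "description": hit.description if hit else "",
            "subject": hit.subject if hit else "",
            "identity": hit.identity if hit else np.nan,
        })
    df = pd.DataFrame(rows, columns=["fragment_id", "aa_length", "frame",
                                     "category", "description", "subject",
                                     "identity"])
    return df.set_index("fragment_id"), counts


def orf_report(categories: pd.DataFrame,
               fragment_expression: pd.DataFrame,
               path: str | os.PathLike | None = None) -> pd.DataFrame:
    """Per-fragment report: nt length, per-condition RPKM, ratio, ORF length,
    category, description."""
    from .diffexpr import expression_ratio

    df = categories.join(fragment_expression[["length", "RPKM_0", "RPKM_1"]])
    df = df.rename(columns={"length": "nt_length"})
    df["ratio"] = [expression_ratio(a, b)
                   for a, b in zip(df["RPKM_0"], df["RPKM_1"])]
    cols = ["nt_length", "RPKM_0", "RPKM_1", "ratio", "aa_length",
            "category", "description"]
    df = df[cols]
    if path is not None:
        out = df.reset_index()
        out["ratio"] = out["ratio"].map(
            lambda r: "-" if r is None or pd.isna(r) else f"{r:.1f}")
        out["RPKM_0"] = out["RPKM_0"].map(lambda v: f"{v:.6g}")
        out["RPKM_1"] = out["RPKM_1"].map(lambda v: f"{v:.6g}")
        out.to_csv(path, sep="\t", index=False)
    return df


def read_hits_tsv(path: str | os.PathLike) -> dict[str, TranslatedHit]:
    """Import externally computed translated-similarity hits
    (fragment_id, subject, identity, aln_len, description)."""
    df = pd.read_csv(path, sep="\t")
    hits = {}
    for row in df.itertuples(index=False):
        hits[row.fragment_id] = TranslatedHit(
            subject=row.subject, description=row.description,
            identity=float(row.identity), aln_len=int(row.aln_len),
            score=np.nan, frame=0)
    return hits
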