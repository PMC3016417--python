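"""Synthetic mRNA-Seq study generator.

Emulates a two-condition short-read transcriptome experiment (an unstressed
baseline versus an acute-stress time point) on a toy multi-chromosome genome:
multi-exon gene models with a hidden "unannotated" subset, planted expression
fold changes, uniform-start 36-bp reads with substitution/indel errors, and an
adapter / rRNA / foreign-organism / random contaminant fraction.  Every read
carries a TruthRecord so downstream stages can be tested against ground truth
without any external data.

The defaults below *are* the study conditions used throughout the test suite
and the acceptance script; see docs/methods.md for the rationale behind each
value.
"""

from __future__ import annotations

import logging
import math
import os
from collections import namedtuple
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _refs
from .annotation_model import GeneModel
from .util import canonical_kmer, kmer_census, revcomp

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "ConfigurationError",
    "PlacementError",
    "generate_genome",
    "generate_gene_models",
    "generate_expression",
    "simulate_reads",
    "chastity_filter",
    "simulate_intensities",
    "make_protein_reference",
    "write_fastq",
    "write_fasta",
    "write_protein_fasta",
    "write_contaminant_refs",
]

# Length of the duplicated segment planted in the genome so that the
# "Multiple" (repetitive) read class is exercised.
REPEAT_SEGMENT_LENGTH = 300

ChastityResult = namedtuple("ChastityResult", "passed reason chastity")


class ConfigurationError(ValueError):
    pass


class PlacementError(RuntimeError):
    pass


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    ``contaminant_fractions`` are fractions of the *total* emitted reads; the
    defaults put ~11.7% of reads into non-transcript classes, split between
    adapter, foreign-organism, rRNA and unalignable random sequence.
    ``fold_change_spec`` entries are ``(selector, ratio)`` where the selector
    is either a fraction of genes or an explicit list of gene ids and the
    ratio is condition-1 / condition-0 abundance.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length: int = 50_000
    n_genes: int = 50
    fraction_hidden: float = 0.16
    exon_count_range: tuple[int, int] = (2, 5)
    exon_length_range: tuple[int, int] = (120, 300)
    intron_length_range: tuple[int, int] = (60, 200)
    read_length: int = 36
    n_reads_per_condition: int = 60_000
    mismatch_rate: float = 0.004
    indel_rate: float = 0.001
    contaminant_fractions: dict[str, float] = field(default_factory=lambda: {
        "adapter": 0.012870,
        "foreign": 0.009594,
        "rrna": 0.008073,
        "random": 0.086463,
    })
    fold_change_spec: list[tuple[object, float]] = field(default_factory=lambda: [
        (0.06, 4.0),
        (0.08, 0.25),
    ])
    abundance_sigma: float = 0.7

    def __post_init__(self) -> None:
        for name in ("exon_count_range", "exon_length_range", "intron_length_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ConfigurationError(f"{name} must satisfy 0 < min <= max")
        if self.read_length < 1:
            raise ConfigurationError("read_length must be >= 1")
        fracs = list(self.contaminant_fractions.values())
        if any(not 0 <= f <= 1 for f in fracs) or sum(fracs) >= 1:
            raise ConfigurationError(
                "contaminant fractions must each lie in [0, 1] and sum to < 1")
        if not 0 <= self.fraction_hidden <= 1:
            raise ConfigurationError("fraction_hidden must lie in [0, 1]")
        if self.n_chromosomes < 1 or self.chromosome_length < 1:
            raise ConfigurationError("need at least one chromosome of positive length")

    def rng(self, stream: int) -> np.random.Generator:
        """An independent, reproducible RNG stream keyed off the config seed."""
        return np.random.default_rng([self.seed, stream])


# RNG stream ids; reads get 100 + condition.
_STREAM_GENOME, _STREAM_MODELS, _STREAM_EXPR, _STREAM_PROT = 0, 1, 2, 3


def generate_genome(config: SimulationConfig) -> dict[str, str]:
    """Random genome with one planted duplicated segment.

    The duplication (two exact copies of a 300-bp segment, placed on the
    first and last chromosomes) guarantees exact-duplicate 36-mers so the
    repetitive ("Multiple") read class can occur.
    """
    rng = config.rng(_STREAM_GENOME)
    n, L = config.n_chromosomes, config.chromosome_length
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    chroms = {
        f"chr{i + 1}": bases[rng.integers(0, 4, L)].tobytes().decode("ascii")
        for i in range(n)
    }
    if L >= 4 * REPEAT_SEGMENT_LENGTH:
        src_chrom, dst_chrom = "chr1", f"chr{n}"
        src = L // 4
        dst = (3 * L) // 4
        segment = chroms[src_chrom][src:src + REPEAT_SEGMENT_LENGTH]
        s = chroms[dst_chrom]
        chroms[dst_chrom] = s[:dst] + segment + s[dst + REPEAT_SEGMENT_LENGTH:]
    return chroms


def generate_gene_models(
        genome: dict[str, str],
        config: SimulationConfig) -> tuple[list[GeneModel], list[GeneModel]]:
    """Place non-overlapping multi-exon genes; return (annotated, hidden).

    floor(n_genes * fraction_hidden) genes are flagged hidden: they are real
    transcription units for the simulator but are withheld from the emitted
    GFF3, forming the ground truth for unannotated-transcript discovery.
    """
    if not genome:
        raise ValueError("empty genome")
    rng = config.rng(_STREAM_MODELS)
    chrom_names = sorted(genome)
    models: list[GeneModel] = []
    chrom_iter = iter(chrom_names)
    chrom = next(chrom_iter)
    cursor = int(rng.integers(80, 200))
    while len(models) < config.n_genes:
        k = int(rng.integers(config.exon_count_range[0], config.exon_count_range[1] + 1))
        exon_lens = rng.integers(config.exon_length_range[0],
                                 config.exon_length_range[1] + 1, k)
        intron_lens = rng.integers(config.intron_length_range[0],
                                   config.intron_length_range[1] + 1, max(k - 1, 0))
        span = int(exon_lens.sum() + intron_lens.sum())
        if cursor + span > len(genome[chrom]):
            try:
                chrom = next(chrom_iter)
            except StopIteration:
                raise PlacementError(
                    f"genome too small to place {config.n_genes} genes "
                    f"(placed {len(models)})") from None
            cursor = int(rng.integers(80, 200))
            continue
        exons, pos = [], cursor
        for i in range(k):
            exons.append((pos, pos + int(exon_lens[i])))
            pos += int(exon_lens[i])
            if i < k - 1:
                pos += int(intron_lens[i])
        gid = f"g{len(models):03d}"
        models.append(GeneModel(
            gene_id=gid, transcript_id=f"{gid}.1", chrom=chrom,
            strand="+" if rng.random() < 0.5 else "-", exons=exons))
        cursor = pos + int(rng.integers(80, 300))
    n_hidden = math.floor(config.n_genes * config.fraction_hidden)
    hidden_idx = set(rng.choice(config.n_genes, size=n_hidden, replace=False).tolist())
    annotated, hidden = [], []
    for i, m in enumerate(models):
        if i in hidden_idx:
            m.hidden = True
            hidden.append(m)
        else:
            annotated.append(m)
    return annotated, hidden


def generate_expression(models: list[GeneModel],
                        config: SimulationConfig) -> pd.DataFrame:
    """Two-condition abundance truth with planted, pool-conserving fold changes.

    Baseline abundances are log-normal.  Because a sequencing library samples
    a fixed number of reads, only relative concentrations are observable:
    if planted regulation changed the total transcript mass appreciably,
    every unchanged gene would appear spuriously regulated.  Stress responses
    of the kind emulated here are roughly balanced between induction and
    repression, so the generator plants them that way: up-regulated genes are
    drawn from the middle of the abundance distribution (measurable without
    dominating the pool) and down-regulated genes are then chosen, among the
    most abundant remaining genes, so that the mass they release best offsets
    the mass the up-regulated genes gain.  Explicit gene-id selectors in
    ``fold_change_spec`` bypass this balancing.
    """
    rng = config.rng(_STREAM_EXPR)
    n = len(models)
    abundance = np.exp(rng.normal(np.log(10.0), config.abundance_sigma, n))
    lengths = np.array([m.exon_model_length for m in models], dtype=float)
    w = abundance * lengths            # expected read mass per transcript
    ratio = np.ones(n)
    gene_ids = [m.gene_id for m in models]
    taken: set[int] = set()
    ups: list[tuple[int, float]] = []
    downs: list[tuple[int, float]] = []
    for selector, r in config.fold_change_spec:
        if isinstance(selector, (int, float)) and not isinstance(selector, bool):
            count = math.floor(n * float(selector))
            (ups if r > 1 else downs).append((count, float(r)))
        else:
            for g in selector:
                i = gene_ids.index(g)
                ratio[i] = float(r)
                taken.add(i)
    order = np.argsort(w, kind="stable")
    added_mass = 0.0
    band = [int(i) for i in order[int(0.5 * n):int(0.85 * n)] if i not in taken]
    for count, r in ups:
        chosen = rng.choice(len(band), size=min(count, len(band)),
                            replace=False)
        for i in sorted((band[int(j)] for j in chosen), reverse=True):
            ratio[i] = r
            taken.add(i)
            added_mass += w[i] * (r - 1.0)
            band.remove(i)
    for count, r in downs:
        pool = [int(i) for i in order[::-1] if int(i) not in taken]
        take = min(count, len(pool))
        if take == 0:
            continue
        release = np.array([w[i] * (1.0 - r) for i in pool])
        window = np.convolve(release, np.ones(take), mode="valid")
        best = int(np.argmin(np.abs(window - max(added_mass, 0.0))))
        for i in pool[best:best + take]:
            ratio[i] = r
            taken.add(i)
            added_mass -= w[i] * (1.0 - r)
    return pd.DataFrame({
        "gene_id": gene_ids,
        "transcript_id": [m.transcript_id for m in models],
        "length": [m.exon_model_length for m in models],
        "hidden": [m.hidden for m in models],
        "abundance_0": abundance,
        "abundance_1": abundance * ratio,
        "ratio": ratio,
    }).set_index("transcript_id")


def _apply_indel(spliced: str, start: int, rl: int,
                 rng: np.random.Generator) -> tuple[str, int, int]:
    """Introduce one contiguous 1-3 bp insertion or deletion into a read.

    Returns (read, indel_length, template_span); the template span is the
    number of transcript bases consumed (rl + d for a deletion in the read,
    rl - d for an insertion).  Falls back to an error-free read when the
    transcript end leaves no room.
    """
    d = int(rng.integers(1, 4))
    gap = int(rng.integers(1, rl - d)) if rl - d > 1 else 1
    if rng.random() < 0.5 and start + rl + d <= len(spliced):  # deletion in read
        read = spliced[start:start + gap] + spliced[start + gap + d:start + rl + d]
        return read, d, rl + d
    # insertion in read
    insert = "".join("ACGT"[int(b)] for b in rng.integers(0, 4, d))
    read = spliced[start:start + gap] + insert + spliced[start + gap:start + rl - d]
    return read, d, rl - d


def _apply_mismatches(read: str, rate: float, rng: np.random.Generator) -> tuple[str, int]:
    if rate <= 0:
        return read, 0
    hits = np.flatnonzero(rng.random(len(read)) < rate)
    if hits.size == 0:
        return read, 0
    out = list(read)
    for i in hits:
        choices = [b for b in "ACGT" if b != out[i]]
        out[i] = choices[int(rng.integers(0, 3))]
    return "".join(out), int(hits.size)


def simulate_reads(genome: dict[str, str],
                   models: list[GeneModel],
                   expression: pd.DataFrame,
                   config: SimulationConfig,
                   condition: int,
                   census: dict[str, int] | None = None,
                   ) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Draw 36-bp reads for one condition; returns (reads, truth table).

    Expected read count per transcript is proportional to abundance x exon
    model length; start positions are uniform along the spliced transcript
    (simple chemical-fragmentation model).  Contaminant reads are appended
    per ``contaminant_fractions``.  Every read gets exactly one truth row.
    """
    rl = config.read_length
    rng = config.rng(100 + condition)
    if census is None:
        census = kmer_census(genome, rl)
    abund_col = f"abundance_{condition}"
    usable, weights = [], []
    for m in models:
        if m.exon_model_length < rl:
            logger.warning("transcript %s shorter than read length; excluded",
                           m.transcript_id)
            continue
        a = float(expression.loc[m.transcript_id, abund_col])
        if a < 0:
            raise ValueError(f"negative abundance for {m.transcript_id}")
        usable.append(m)
        weights.append(a * m.exon_model_length)
    weights = np.asarray(weights, dtype=float)

    n_total = config.n_reads_per_condition
    cont_counts = {cls: math.floor(n_total * frac)
                   for cls, frac in config.contaminant_fractions.items()}
    n_tx = n_total - sum(cont_counts.values())
    if weights.sum() <= 0:
        n_tx = 0
        tx_counts = np.zeros(len(usable), dtype=int)
    else:
        tx_counts = rng.multinomial(n_tx, weights / weights.sum())

    reads: list[tuple[str, str]] = []
    truth_rows: list[dict] = []
    serial = 0

    def emit(seq, origin, tid, offset, strand, true_class, n_mm, indel, contig):
        nonlocal serial
        rid = f"c{condition}_{serial:06d}"
        serial += 1
        reads.append((rid, seq))
        truth_rows.append(dict(
            read_id=rid, origin=origin, transcript_id=tid, offset=offset,
            strand=strand, true_class=true_class, n_mismatches=n_mm,
            indel_len=indel, contiguous_match=contig))

    for m, count in zip(usable, tx_counts):
        if count == 0:
            continue
        spliced = m.spliced_sequence(genome)
        bounds = m.exon_boundaries()
        starts = rng.integers(0, m.exon_model_length - rl + 1, int(count))
        for start in starts:
            start = int(start)
            indel = 0
            span = rl
            if config.indel_rate > 0 and rng.random() < config.indel_rate:
                clean, indel, span = _apply_indel(spliced, start, rl, rng)
                if len(clean) != rl:  # no room for an indel here
                    clean, indel, span = spliced[start:start + rl], 0, rl
            else:
                clean = spliced[start:start + rl]
            crossing = any(start < b < start + span for b in bounds)
            if crossing:
                true_class = "junction-spanning"
                contig = indel == 0 and census.get(canonical_kmer(clean), 0) >= 1
            else:
                window = spliced[start:start + rl]
                true_class = ("repeat"
                              if census.get(canonical_kmer(window), 0) >= 2
                              else "genome-unique")
                contig = True
            strand = "+" if rng.random() < 0.5 else "-"
            oriented = clean if strand == "+" else revcomp(clean)
            seq, n_mm = _apply_mismatches(oriented, config.mismatch_rate, rng)
            emit(seq, "transcript", m.transcript_id, start, strand,
                 true_class, n_mm, indel, contig)

    cont_sources = {
        "adapter": _refs.ADAPTER,
        "rrna": _refs.RRNA,
        "foreign": _refs.FOREIGN,
    }
    for cls in ("adapter", "rrna", "foreign", "random"):
        for _ in range(cont_counts.get(cls, 0)):
            if cls == "random":
                seq = "".join("ACGT"[int(b)] for b in rng.integers(0, 4, rl))
                n_mm, strand, off = 0, "+", -1
            else:
                ref = cont_sources[cls]
                off = 0 if cls == "adapter" else int(rng.integers(0, len(ref) - rl + 1))
                window = ref[off:off + rl]
                strand = "+" if cls == "adapter" or rng.random() < 0.5 else "-"
                oriented = window if strand == "+" else revcomp(window)
                seq, n_mm = _apply_mismatches(oriented, config.mismatch_rate, rng)
            emit(seq, cls, "", off, strand, "contaminant", n_mm, 0, False)

    truth = pd.DataFrame(truth_rows, columns=[
        "read_id", "origin", "transcript_id", "offset", "strand", "true_class",
        "n_mismatches", "indel_len", "contiguous_match"])
    return reads, truth


def chastity_filter(intensities, threshold: float = 0.6) -> ChastityResult:
    """Per-cycle purity filter on raw four-channel intensities.

    chastity = (highest channel) / (highest + second highest); a read passes
    only if every cycle's chastity is at or above ``threshold``.  A cycle with
    all four channels at zero is uncallable and fails outright.
    """
    arr = np.asarray(intensities, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 4:
        raise ValueError("intensities must have shape (n_cycles, 4)")
    if (arr < 0).any():
        raise ValueError("intensities must be non-negative")
    top2 = -np.partition(-arr, 1, axis=1)[:, :2]
    denom = top2.sum(axis=1)
    if (denom == 0).any():
        return ChastityResult(False, "uncallable", None)
    chastity = top2[:, 0] / denom
    passed = bool((chastity >= threshold).all())
    return ChastityResult(passed, None if passed else "low-chastity", chastity)


def simulate_intensities(seq: str, rng: np.random.Generator,
                         noise: float = 0.2) -> np.ndarray:
    """Toy four-channel intensities for a called sequence (tests only)."""
    order = "ACGT"
    arr = rng.uniform(0, noise, size=(len(seq), 4))
    for i, b in enumerate(seq):
        if b in order:
            arr[i, order.index(b)] += 1.0
    return arr


def make_protein_reference(genome: dict[str, str],
                           models: list[GeneModel],
                           config: SimulationConfig,
                           include_fraction: float = 0.5,
                           n_decoys: int = 4,
                           min_aa: int = 30) -> list[tuple[str, str, str]]:
    """Small protein set for translated-similarity categorization.

    Takes the longest-ORF translations of a deterministic subset of the
    *hidden* genes (so some discovered unannotated fragments will have
    translated-similarity hits, as real novel transcripts would against a
    curated protein database) plus a few random decoy proteins.  Returns
    ``(protein_id, description, aa_sequence)`` triples.
    """
    from .orf_annot import longest_orf

    rng = config.rng(_STREAM_PROT)
    hidden = sorted((m for m in models if m.hidden), key=lambda m: m.transcript_id)
    n_take = math.ceil(len(hidden) * include_fraction)
    proteins: list[tuple[str, str, str]] = []
    for m in hidden[:n_take]:
        orf = longest_orf(m.spliced_sequence(genome))
        if orf.aa_length >= min_aa:
            proteins.append((f"prot_{m.transcript_id}",
                             f"translation of hidden locus {m.gene_id}",
                             orf.protein))
    aa = "ACDEFGHIKLMNPQRSTVWY"
    for i in range(n_decoys):
        seq = "".join(aa[int(j)] for j in rng.integers(0, len(aa), 120))
        proteins.append((f"decoy_{i}", "synthetic decoy protein", seq))
    return proteins


# ---------------------------------------------------------------- file output

def write_fastq(reads: list[tuple[str, str]], path: str | os.PathLike) -> None:
    """Sanger/Phred+33 FASTQ with a flat quality profile (see Non-goals)."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path: str | os.PathLike) -> list[tuple[str, str]]:
    from Bio import SeqIO
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


def write_fasta(seqs: dict[str, str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), 70):
                fh.write(s[i:i + 70] + "\n")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    from Bio import SeqIO
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_protein_fasta(proteins: list[tuple[str, str, str]],
                        path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for pid, desc, seq in proteins:
            fh.write(f">{pid} {desc}\n{seq}\n")


def write_contaminant_refs(out_dir: str | os.PathLike) -> dict[str, str]:
    """Write the packaged adapter/rRNA/foreign references; returns the paths."""
    paths = {}
    for name, seq in (("adapter", _refs.ADAPTER), ("rrna", _refs.RRNA),
                      ("foreign", _refs.FOREIGN)):
        p = os.path.join(out_dir, f"{name}.fa")
        write_fasta({name: seq}, p)
        paths[name] = p
    return paths
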