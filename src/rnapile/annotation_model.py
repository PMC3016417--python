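"""Gene models, GFF3 round-trip IO, and the spliced-exon-junction (SEJ) library.

An SEJ record concatenates up to ``flank`` (default 40) bases from the 3' end
of an upstream exon with up to ``flank`` bases from the 5' start of the next
exon of the same transcript.  Short reads that span a splice junction cannot
be placed on the genome contiguously, but they match the SEJ sequence; a hit
that crosses the junction offset is evidence for the junction and can be
projected back onto the genome as a two-block split alignment.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import gffutils

__all__ = [
    "GeneModel",
    "SEJRecord",
    "ValidationError",
    "read_gff3",
    "write_gff3",
    "build_sej",
    "write_sej_fasta",
    "read_sej_fasta",
]


class ValidationError(ValueError):
    """Raised for malformed annotations or inconsistent gene models."""


@dataclass
class GeneModel:
    """A transcript with ordered exons on one chromosome.

    ``exons`` are 0-based half-open genomic intervals, sorted and
    non-overlapping.  ``hidden`` marks simulated genes that are withheld from
    the emitted annotation (ground truth for discovery benchmarks).
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    hidden: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValidationError(f"{self.transcript_id}: bad strand {self.strand!r}")
        if not self.exons:
            raise ValidationError(f"{self.transcript_id}: no exons")
        prev_end = None
        for start, end in self.exons:
            if end <= start or start < 0:
                raise ValidationError(
                    f"{self.transcript_id}: invalid exon interval [{start}, {end})")
            if prev_end is not None and start < prev_end:
                raise ValidationError(
                    f"{self.transcript_id}: exons overlap or are unsorted")
            prev_end = end

    @property
    def exon_model_length(self) -> int:
        """L of the RPKM formula: summed exon length in bp."""
        return sum(e - s for s, e in self.exons)

    @property
    def extent(self) -> tuple[int, int]:
        """Locus extent from first exon start to last exon end (introns included)."""
        return self.exons[0][0], self.exons[-1][1]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def spliced_sequence(self, genome: dict[str, str]) -> str:
        chrom_seq = genome[self.chrom]
        return "".join(chrom_seq[s:e] for s, e in self.exons)

    def exon_boundaries(self) -> list[int]:
        """Transcript-coordinate offsets of internal exon-exon boundaries."""
        bounds, pos = [], 0
        for s, e in self.exons[:-1]:
            pos += e - s
            bounds.append(pos)
        return bounds

    def validate_against_genome(self, genome: dict[str, str]) -> None:
        if self.chrom not in genome:
            raise ValidationError(f"{self.transcript_id}: unknown chromosome {self.chrom}")
        n = len(genome[self.chrom])
        for s, e in self.exons:
            if e > n:
                raise ValidationError(
                    f"{self.transcript_id}: exon [{s}, {e}) outside {self.chrom} [0, {n})")


@dataclass
class SEJRecord:
    """One exon-exon junction sequence with the genomic provenance of each half."""

    junction_id: str
    transcript_id: str            # first transcript contributing the junction
    upstream_exon_index: int
    chrom: str
    sequence: str
    left: tuple[int, int]         # genomic interval of the upstream flank
    right: tuple[int, int]        # genomic interval of the downstream flank
    offset: int                   # position in `sequence` where the halves meet
    transcript_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.transcript_ids:
            self.transcript_ids = [self.transcript_id]
        lw = self.left[1] - self.left[0]
        rw = self.right[1] - self.right[0]
        if len(self.sequence) != lw + rw or self.offset != lw:
            raise ValidationError(f"{self.junction_id}: flank geometry inconsistent")
        if self.left[1] >= self.right[0]:
            raise ValidationError(f"{self.junction_id}: halves are genomically adjacent")


def write_gff3(models: list[GeneModel], path: str | os.PathLike) -> None:
    """Emit gene/mRNA/exon features; 0-based half-open converts to 1-based inclusive."""
    lines = ["##gff-version 3"]
    for m in sorted(models, key=lambda m: (m.chrom, m.extent[0], m.gene_id)):
        lo, hi = m.extent
        attrs = f"ID={m.gene_id}"
        lines.append("\t".join(
            [m.chrom, "rnapile", "gene", str(lo + 1), str(hi), ".", m.strand, ".", attrs]))
        lines.append("\t".join(
            [m.chrom, "rnapile", "mRNA", str(lo + 1), str(hi), ".", m.strand, ".",
             f"ID={m.transcript_id};Parent={m.gene_id}"]))
        for i, (s, e) in enumerate(m.exons, 1):
            lines.append("\t".join(
                [m.chrom, "rnapile", "exon", str(s + 1), str(e), ".", m.strand, ".",
                 f"ID={m.transcript_id}.exon{i};Parent={m.transcript_id}"]))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_gff3(path: str | os.PathLike,
              genome: dict[str, str] | None = None) -> list[GeneModel]:
    """Load gene models from GFF3 (gene/mRNA/exon features).

    Round-trips with :func:`write_gff3` up to feature ordering.  When a genome
    is supplied, exon bounds are checked against chromosome lengths.
    """
    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)
    models = []
    for mrna in db.features_of_type("mRNA"):
        parents = list(db.parents(mrna, featuretype="gene"))
        gene_id = parents[0].id if parents else mrna.id
        exons = []
        for ex in db.children(mrna, featuretype="exon"):
            if ex.end < ex.start:
                raise ValidationError(f"{mrna.id}: exon end < start in GFF3")
            exons.append((ex.start - 1, ex.end))  # to 0-based half-open
        exons.sort()
        model = GeneModel(gene_id=gene_id, transcript_id=mrna.id,
                          chrom=mrna.seqid, strand=mrna.strand, exons=exons)
        if genome is not None:
            model.validate_against_genome(genome)
        models.append(model)
    models.sort(key=lambda m: (m.chrom, m.extent[0], m.gene_id))
    return models


def build_sej(models: list[GeneModel], genome: dict[str, str],
              flank: int = 40) -> list[SEJRecord]:
    """Build the SEJ library: one record per adjacent exon pair per transcript.

    Flanks are truncated to the exon when an exon is shorter than ``flank``;
    they never extend into the intron.  Junctions shared by several
    transcripts (same flank intervals on the same chromosome) are
    deduplicated, keeping all transcript back-references.  Output order is
    deterministic: records appear in (transcript_id, exon index) order of
    their first occurrence.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    records: list[SEJRecord] = []
    seen: dict[tuple, SEJRecord] = {}
    for m in sorted(models, key=lambda m: m.transcript_id):
        m.validate_against_genome(genome)
        chrom_seq = genome[m.chrom]
        for i in range(m.n_exons - 1):
            (us, ue), (ds, de) = m.exons[i], m.exons[i + 1]
            left = (max(us, ue - flank), ue)
            right = (ds, min(de, ds + flank))
            key = (m.chrom, left, right)
            if key in seen:
                seen[key].transcript_ids.append(m.transcript_id)
                continue
            seq = chrom_seq[left[0]:left[1]] + chrom_seq[right[0]:right[1]]
            rec = SEJRecord(
                junction_id=f"sej_{len(records):05d}",
                transcript_id=m.transcript_id,
                upstream_exon_index=i,
                chrom=m.chrom,
                sequence=seq,
                left=left,
                right=right,
                offset=left[1] - left[0],
            )
            seen[key] = rec
            records.append(rec)
    return records


def write_sej_fasta(records: list[SEJRecord], path: str | os.PathLike) -> None:
    """SEJ FASTA with a tab-safe header encoding provenance:

    ``>sej_00000 transcripts=t1,t2 chrom=chr1 left=60-100 right=200-240 offset=40 exon=0``
    """
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f">{r.junction_id} transcripts={','.join(r.transcript_ids)} "
                f"chrom={r.chrom} left={r.left[0]}-{r.left[1]} "
                f"right={r.right[0]}-{r.right[1]} offset={r.offset} "
                f"exon={r.upstream_exon_index}\n{r.sequence}\n")


def read_sej_fasta(path: str | os.PathLike) -> list[SEJRecord]:
    from Bio import SeqIO

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = dict(kv.split("=", 1) for kv in rec.description.split()[1:])
        left = tuple(int(x) for x in fields["left"].split("-"))
        right = tuple(int(x) for x in fields["right"].split("-"))
        tids = fields["transcripts"].split(",")
        records.append(SEJRecord(
            junction_id=rec.id,
            transcript_id=tids[0],
            upstream_exon_index=int(fields["exon"]),
            chrom=fields["chrom"],
            sequence=str(rec.seq),
            left=(left[0], left[1]),
            right=(right[0], right[1]),
            offset=int(fields["offset"]),
            transcript_ids=tids,
        ))
    return records
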