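"""Genomes, genes, operons and upstream regions.

This module is the coordinate substrate of the pipeline.  Conventions:

* internal coordinates are 0-based half-open intervals on the forward strand;
* GFF3 on disk is 1-based inclusive; BED on disk is 0-based half-open;
* conversion happens only at the I/O boundary.

An *operon* is a maximal run of consecutive, co-directional genes whose
intergenic gaps do not exceed ``max_gap_bp`` (default 200 bp).  The *upstream
region* of an operon is the intergenic segment immediately 5' of its lead
gene, truncated at ``max_len`` (default 350 bp) or at the boundary of the
neighbouring gene, whichever is shorter.  Upstream sequences are oriented so
that position 0 is farthest from the start codon; minus-strand regions are
reverse complemented.  Divergently transcribed operons may share intergenic
DNA, so their upstream regions may overlap each other (but never a gene body).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from gffutils.feature import feature_from_line

from .dnautil import revcomp
from .errors import CoordinateError, FormatError, ParameterError

DEFAULT_UPSTREAM_LEN = 350
DEFAULT_OPERON_GAP = 200


@dataclass
class Gene:
    """A protein-coding gene on a replicon.

    ``start``/``end`` form a 0-based half-open interval on the forward
    strand regardless of the gene's own strand.
    """

    locus_tag: str
    start: int
    end: int
    strand: str
    protein: Optional[str] = None
    product: str = ""
    tf_family: Optional[str] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"unknown strand {self.strand!r} for {self.locus_tag}")
        if not self.start < self.end:
            raise CoordinateError(
                f"gene {self.locus_tag}: start {self.start} must be < end {self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class Genome:
    """A single annotated replicon with its genes sorted by start."""

    genome_id: str
    sequence: str
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genes = sorted(self.genes, key=lambda g: (g.start, g.end))
        seen: set[str] = set()
        for g in self.genes:
            if g.locus_tag in seen:
                raise FormatError(f"duplicate locus_tag {g.locus_tag} in {self.genome_id}")
            seen.add(g.locus_tag)
            if g.end > len(self.sequence):
                raise CoordinateError(
                    f"gene {g.locus_tag} ends at {g.end}, beyond sequence "
                    f"length {len(self.sequence)} of {self.genome_id}"
                )

    def gene(self, locus_tag: str) -> Gene:
        for g in self.genes:
            if g.locus_tag == locus_tag:
                return g
        raise KeyError(locus_tag)

    @property
    def proteins(self) -> dict[str, str]:
        """locus_tag -> amino-acid sequence, for genes carrying a translation."""
        return {g.locus_tag: g.protein for g in self.genes if g.protein}


@dataclass
class Operon:
    """A maximal run of co-directional, closely spaced genes."""

    operon_id: str
    member_genes: list[str]
    strand: str
    lead_gene: str
    start: int = 0
    end: int = 0


@dataclass
class UpstreamRegion:
    """Promoter-proximal sequence window 5' of an operon's lead gene.

    ``sequence`` is oriented so position 0 lies farthest from the start
    codon; for minus-strand operons it is the reverse complement of the
    genomic slice ``[start, end)``.
    """

    operon_id: str
    genome_id: str
    sequence: str
    start: int
    end: int
    strand: str
    max_len: int = DEFAULT_UPSTREAM_LEN

    @property
    def is_empty(self) -> bool:
        return len(self.sequence) == 0

    def genomic_interval(self, offset: int, length: int) -> tuple[int, int]:
        """Map a window at `offset` in region orientation to genome coordinates."""
        if self.strand == "+":
            return self.start + offset, self.start + offset + length
        return self.end - offset - length, self.end - offset


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_genome(
    fasta_path: str | Path,
    gff3_path: str | Path,
    protein_fasta: str | Path | None = None,
) -> Genome:
    """Read one replicon from a genome FASTA plus GFF3 annotation.

    GFF3 ``gene``/``CDS`` features must carry a ``locus_tag`` attribute;
    1-based inclusive coordinates are converted to internal 0-based
    half-open ones.  Protein translations come from the ``translation``
    attribute or, if given, from ``protein_fasta`` keyed by locus_tag.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise FormatError(f"expected one FASTA record in {fasta_path}, found {len(records)}")
    rec = records[0]
    sequence = str(rec.seq).upper()

    proteins: dict[str, str] = {}
    if protein_fasta is not None:
        proteins = {r.id: str(r.seq) for r in SeqIO.parse(str(protein_fasta), "fasta")}

    genes: list[Gene] = []
    seen: set[str] = set()
    with open(gff3_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            feat = feature_from_line(line)
            if feat.featuretype not in ("gene", "CDS"):
                continue
            tags = feat.attributes.get("locus_tag")
            if not tags:
                raise FormatError(f"feature without locus_tag in {gff3_path}: {line}")
            locus = tags[0]
            if locus in seen:
                # gene + CDS pairs for the same locus are allowed; true
                # duplicates of the same feature type are not
                continue
            seen.add(locus)
            if feat.strand not in ("+", "-"):
                raise FormatError(f"unknown strand {feat.strand!r} for {locus}")
            start, end = feat.start - 1, feat.end  # GFF3 1-based incl -> half-open
            if start < 0 or end > len(sequence):
                raise CoordinateError(
                    f"{locus}: interval ({start},{end}) outside sequence of length {len(sequence)}"
                )
            product = (feat.attributes.get("product") or [""])[0]
            tf_family = (feat.attributes.get("tf_family") or [None])[0]
            translation = (feat.attributes.get("translation") or [None])[0]
            genes.append(
                Gene(
                    locus_tag=locus,
                    start=start,
                    end=end,
                    strand=feat.strand,
                    protein=proteins.get(locus, translation),
                    product=product,
                    tf_family=tf_family,
                )
            )
    return Genome(genome_id=rec.id, sequence=sequence, genes=genes)


def write_genome(
    genome: Genome,
    fasta_path: str | Path,
    gff3_path: str | Path,
    protein_fasta: str | Path | None = None,
) -> None:
    """Write a Genome back to FASTA + GFF3 (inverse of :func:`read_genome`)."""
    SeqIO.write(
        [SeqRecord(Seq(genome.sequence), id=genome.genome_id, description="")],
        str(fasta_path),
        "fasta",
    )
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.genome_id} 1 {len(genome.sequence)}\n")
        for g in genome.genes:
            attrs = [f"ID={g.locus_tag}", f"locus_tag={g.locus_tag}"]
            if g.product:
                attrs.append(f"product={g.product}")
            if g.tf_family:
                attrs.append(f"tf_family={g.tf_family}")
            fh.write(
                "\t".join(
                    [
                        genome.genome_id,
                        "regulonkit",
                        "gene",
                        str(g.start + 1),
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )
    if protein_fasta is not None:
        recs = [
            SeqRecord(Seq(g.protein), id=g.locus_tag, description="")
            for g in genome.genes
            if g.protein
        ]
        SeqIO.write(recs, str(protein_fasta), "fasta")


# ---------------------------------------------------------------------------
# Operons and upstream regions
# ---------------------------------------------------------------------------

def call_operons(genome: Genome, max_gap_bp: int = DEFAULT_OPERON_GAP) -> list[Operon]:
    """Group consecutive co-directional genes with gaps <= max_gap_bp.

    Every gene ends up in exactly one operon; the lead gene is the 5'-most
    member in transcription order (first for '+', last for '-').
    """
    if max_gap_bp < 0:
        raise ParameterError(f"max_gap_bp must be >= 0, got {max_gap_bp}")
    operons: list[Operon] = []
    run: list[Gene] = []

    def _flush() -> None:
        if not run:
            return
        strand = run[0].strand
        lead = run[0] if strand == "+" else run[-1]
        operons.append(
            Operon(
                operon_id=f"opn_{lead.locus_tag}",
                member_genes=[g.locus_tag for g in run],
                strand=strand,
                lead_gene=lead.locus_tag,
                start=run[0].start,
                end=run[-1].end,
            )
        )
        run.clear()

    for gene in genome.genes:
        if run and (gene.strand != run[-1].strand or gene.start - run[-1].end > max_gap_bp):
            _flush()
        run.append(gene)
    _flush()
    return operons


def extract_upstream(
    genome: Genome,
    operon: Operon,
    max_len: int = DEFAULT_UPSTREAM_LEN,
) -> UpstreamRegion:
    """Intergenic segment immediately 5' of the operon's lead gene.

    Truncated at ``max_len`` or at the neighbouring gene boundary, whichever
    is shorter; never overlaps an annotated gene body.  A lead gene at the
    contig edge with zero intergenic space yields an empty region (callers
    exclude those from training sets).
    """
    lead = genome.gene(operon.lead_gene)
    if operon.strand == "+":
        anchor = lead.start
        neighbor_end = max((g.end for g in genome.genes if g.end <= anchor and g is not lead), default=0)
        start = max(neighbor_end, anchor - max_len)
        end = anchor
        seq = genome.sequence[start:end]
    else:
        anchor = lead.end
        neighbor_start = min(
            (g.start for g in genome.genes if g.start >= anchor and g is not lead),
            default=len(genome.sequence),
        )
        start = anchor
        end = min(neighbor_start, anchor + max_len)
        seq = revcomp(genome.sequence[start:end])
    return UpstreamRegion(
        operon_id=operon.operon_id,
        genome_id=genome.genome_id,
        sequence=seq,
        start=start,
        end=end,
        strand=operon.strand,
        max_len=max_len,
    )


def upstream_regions(
    genome: Genome,
    operons: Iterable[Operon] | None = None,
    max_len: int = DEFAULT_UPSTREAM_LEN,
    per_gene: bool = False,
    max_gap_bp: int = DEFAULT_OPERON_GAP,
) -> list[UpstreamRegion]:
    """Upstream regions of all operons (or of every gene with ``per_gene``).

    Empty regions are dropped.  ``per_gene=True`` treats each gene as its own
    single-gene operon.
    """
    if per_gene:
        operons = [
            Operon(
                operon_id=f"opn_{g.locus_tag}",
                member_genes=[g.locus_tag],
                strand=g.strand,
                lead_gene=g.locus_tag,
                start=g.start,
                end=g.end,
            )
            for g in genome.genes
        ]
    elif operons is None:
        operons = call_operons(genome, max_gap_bp=max_gap_bp)
    regions = [extract_upstream(genome, op, max_len=max_len) for op in operons]
    return [r for r in regions if not r.is_empty]
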