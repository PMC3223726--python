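"""Seeded multi-genome pangenome simulator with ground truth.

The simulator emulates the structure of a bacterial pangenome analysed by
comparative regulon reconstruction: a set of genomes sharing *core* gene
families (present everywhere), *variable* families (a subset of genomes)
and *strain-specific* families (one genome each).  Orthologous proteins are
derived from a random family ancestor by i.i.d. substitutions (no indels,
so Smith-Waterman identity stays analytically predictable), intergenic DNA
is i.i.d. uniform over ACGT (so log-odds-vs-uniform PWM weights are exactly
calibrated), and a palindromic consensus motif is implanted upstream of the
designated target families with bounded per-site mutational noise.  Decoy
sites carry the *same* consensus but appear in only the designated genomes,
so only the cross-genome consistency filter -- not the score -- can remove
them.  A block-structured expression matrix (shared latent profile per
block plus independent noise) emulates condition-wise co-expression of
regulon members.

Everything is a pure function of the configuration, including its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import genome_model
from .dnautil import BASES, revcomp
from .errors import ConfigError, ParameterError, PlacementError
from .genome_model import Gene, Genome, Operon, UpstreamRegion

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
# Robinson-Robinson-style background frequencies; drawing ancestors from a
# realistic composition keeps chance Smith-Waterman alignments between
# unrelated proteins as rare as they are in real proteomes (uniform
# composition over-weights rare high-scoring residues such as W and C).
AA_BACKGROUND = np.array(
    [0.074, 0.052, 0.045, 0.054, 0.025, 0.034, 0.054, 0.074, 0.026, 0.068,
     0.099, 0.058, 0.025, 0.047, 0.039, 0.057, 0.051, 0.013, 0.032, 0.073]
)
AA_BACKGROUND = AA_BACKGROUND / AA_BACKGROUND.sum()
DEFAULT_CONSENSUS = "TTGACAATATATTGTCAA"  # 18 bp, equal to its own reverse complement


@dataclass
class ExprBlock:
    """One co-expression block over whole ortholog families."""

    family_ids: list[str]
    corr_target: float = 0.8
    noise_sd: Optional[float] = None  # default: sqrt(1/r - 1), hits corr_target


@dataclass
class SimConfig:
    """Study conditions of the synthetic pangenome.

    Defaults describe the benchmark the package is validated on: 16 genomes,
    an 18-bp palindromic consensus implanted upstream of 12 core target
    families with at most 2 point mutations per site, decoy sites confined
    to a single genome, 5% protein divergence, and a two-block expression
    design at within-block correlation 0.8 over 50 conditions.
    """

    n_genomes: int = 16
    n_core_families: int = 20
    n_variable_families: int = 6
    n_specific_per_genome: int = 2
    gene_len_bp: tuple[int, int] = (300, 45)       # mean, sd; rounded to codons
    intergenic_len_bp: tuple[int, int] = (280, 30)  # mean, sd; clamped >= 230
    min_intergenic_bp: int = 230
    motif_len: int = 18
    motif_consensus: str = DEFAULT_CONSENSUS
    site_mutations_max: int = 2
    n_target_families: int = 12
    target_family_ids: Optional[list[str]] = None
    target_presence: Optional[dict[str, list[str]]] = None  # family -> genome_ids
    decoy_site_spec: tuple[int, int] = (3, 1)       # (count, genomes per decoy)
    protein_divergence: float = 0.05
    tf_family_label: str = "SimTF"
    minus_strand_fraction: float = 0.0
    gc_content: float = 0.5                          # 0.5 = uniform background
    expr_blocks: Optional[list[ExprBlock]] = None
    expr_n_conditions: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genomes < 3:
            raise ConfigError("n_genomes must be >= 3 (consistency filter needs two 'other' genomes)")
        if self.motif_len % 2 != 0:
            raise ConfigError("motif_len must be even")
        if len(self.motif_consensus) != self.motif_len:
            raise ConfigError("motif_consensus length must equal motif_len")
        if self.motif_consensus != revcomp(self.motif_consensus):
            raise ConfigError("motif_consensus must equal its own reverse complement")
        if self.n_target_families > self.n_core_families - 1:
            raise ConfigError("target families must fit among core families (one is reserved for the TF)")
        if self.min_intergenic_bp < self.motif_len:
            raise ConfigError("intergenic spacing must accommodate the motif")

    # family id helpers -----------------------------------------------------
    def genome_ids(self) -> list[str]:
        return [f"G{i + 1:02d}" for i in range(self.n_genomes)]

    def core_ids(self) -> list[str]:
        return [f"FC{i + 1:03d}" for i in range(self.n_core_families)]

    def variable_ids(self) -> list[str]:
        return [f"FV{i + 1:03d}" for i in range(self.n_variable_families)]

    def tf_family_id(self) -> str:
        # last core family hosts the simulated transcription factor
        return self.core_ids()[-1]

    def resolved_targets(self) -> list[str]:
        if self.target_family_ids is not None:
            return list(self.target_family_ids)
        return self.core_ids()[: self.n_target_families]

    def default_expr_blocks(self) -> list[ExprBlock]:
        targets = self.resolved_targets()
        half = len(targets) // 2
        return [
            ExprBlock(family_ids=targets[:half]),
            ExprBlock(family_ids=targets[half:]),
        ]


@dataclass
class TrueSite:
    genome_id: str
    start: int
    end: int
    strand: str
    family_id: str
    operon_id: str
    sequence: str
    n_mutations: int
    is_decoy: bool = False


@dataclass
class PangenomeTruth:
    """Ground truth emitted alongside the simulated genomes."""

    true_ortho_partition: dict[str, dict[str, list[str]]]  # family -> genome -> loci
    true_sites: list[TrueSite] = field(default_factory=list)
    true_motif_counts: Optional[np.ndarray] = None
    true_expr_blocks: dict[str, int] = field(default_factory=dict)  # locus -> block
    target_families: list[str] = field(default_factory=list)
    tf_family: str = ""

    def family_of(self, genome_id: str, locus_tag: str) -> Optional[str]:
        for fam, members in self.true_ortho_partition.items():
            if locus_tag in members.get(genome_id, []):
                return fam
        return None

    def sites_of(self, is_decoy: bool) -> list[TrueSite]:
        return [s for s in self.true_sites if s.is_decoy == is_decoy]


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list(BASES))[rng.choice(4, size=n, p=p)])


def _mutate_protein(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    for i in np.nonzero(rng.random(len(seq)) < rate)[0]:
        choices = [a for a in AMINO_ACIDS if a != out[i]]
        out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def generate_pangenome(config: SimConfig) -> tuple[list[Genome], PangenomeTruth]:
    """Simulate genomes with known orthology (no sites implanted yet).

    Families are laid out in a fixed canonical order; each family contributes
    one gene per genome in which it is present, separated by intergenic DNA
    wide enough that every gene forms its own operon under the default
    operon gap.
    """
    rng = np.random.default_rng(config.seed)
    genome_ids = config.genome_ids()

    # family -> present genomes
    presence: dict[str, list[str]] = {}
    for fam in config.core_ids():
        presence[fam] = list(genome_ids)
    for fam in config.variable_ids():
        k = int(rng.integers(2, config.n_genomes))  # in [2, n-1]
        chosen = sorted(rng.choice(len(genome_ids), size=k, replace=False))
        presence[fam] = [genome_ids[i] for i in chosen]
    specific: dict[str, list[str]] = {}
    for gi, gid in enumerate(genome_ids):
        for j in range(config.n_specific_per_genome):
            fam = f"FS{gi + 1:02d}{j + 1:02d}"
            presence[fam] = [gid]

    # ancestors
    mean_len, sd_len = config.gene_len_bp
    ancestors: dict[str, str] = {}
    for fam in presence:
        aa_len = max(80, int(round(rng.normal(mean_len, sd_len) / 3)))
        ancestors[fam] = "".join(
            AMINO_ACIDS[i] for i in rng.choice(20, size=aa_len, p=AA_BACKGROUND)
        )

    tf_fam = config.tf_family_id()
    family_order = sorted(presence)  # canonical layout order
    partition: dict[str, dict[str, list[str]]] = {f: {} for f in presence}

    ig_mean, ig_sd = config.intergenic_len_bp
    genomes: list[Genome] = []
    for gid in genome_ids:
        parts: list[str] = []
        genes: list[Gene] = []
        pos = 0
        counter = 0
        lead_gap = max(config.min_intergenic_bp, int(round(rng.normal(ig_mean, ig_sd))))
        parts.append(_random_dna(rng, lead_gap, config.gc_content))
        pos += lead_gap
        for fam in family_order:
            if gid not in presence[fam]:
                continue
            counter += 1
            locus = f"{gid}_{counter:04d}"
            protein = _mutate_protein(rng, ancestors[fam], config.protein_divergence)
            dna = _random_dna(rng, 3 * len(protein), config.gc_content)
            strand = "-" if rng.random() < config.minus_strand_fraction else "+"
            genes.append(
                Gene(
                    locus_tag=locus,
                    start=pos,
                    end=pos + len(dna),
                    strand=strand,
                    protein=protein,
                    product=f"family {fam} protein",
                    tf_family=config.tf_family_label if fam == tf_fam else None,
                )
            )
            partition[fam].setdefault(gid, []).append(locus)
            parts.append(dna)
            pos += len(dna)
            gap = max(config.min_intergenic_bp, int(round(rng.normal(ig_mean, ig_sd))))
            parts.append(_random_dna(rng, gap, config.gc_content))
            pos += gap
        genomes.append(Genome(genome_id=gid, sequence="".join(parts), genes=genes))

    truth = PangenomeTruth(
        true_ortho_partition=partition,
        target_families=config.resolved_targets(),
        tf_family=tf_fam,
    )
    return genomes, truth


def implant_regulon(
    genomes: Sequence[Genome],
    truth: PangenomeTruth,
    config: SimConfig,
) -> tuple[list[Genome], PangenomeTruth]:
    """Write motif instances into target upstream regions; record ground truth.

    One instance per target operon per designated genome, at a seeded random
    offset, with a seeded number (<= site_mutations_max) of point mutations.
    Decoy instances go into the upstream regions of non-target core families
    in only the designated number of genomes.
    """
    rng = np.random.default_rng(config.seed + 1)
    L = config.motif_len
    consensus = config.motif_consensus
    presence = truth.true_ortho_partition
    targets = config.resolved_targets()
    for fam in targets:
        if fam not in presence:
            raise ConfigError(f"target family {fam} not in the pangenome")
    target_presence = config.target_presence or {
        fam: sorted(presence[fam]) for fam in targets
    }

    # decoy families: core, not targets, not the TF
    decoy_count, decoy_genomes = config.decoy_site_spec
    decoy_pool = [
        f for f in config.core_ids() if f not in targets and f != truth.tf_family
    ]
    if decoy_count > len(decoy_pool):
        raise ConfigError("not enough non-target core families for the requested decoys")
    decoy_fams = decoy_pool[:decoy_count]

    seqs = {g.genome_id: list(g.sequence) for g in genomes}
    new_truth_sites: list[TrueSite] = []
    site_seqs: list[str] = []

    def _implant(genome: Genome, fam: str, is_decoy: bool) -> None:
        locus = presence[fam][genome.genome_id][0]
        gene = genome.gene(locus)
        operon = Operon(
            operon_id=f"opn_{locus}",
            member_genes=[locus],
            strand=gene.strand,
            lead_gene=locus,
            start=gene.start,
            end=gene.end,
        )
        region = genome_model.extract_upstream(genome, operon)
        if len(region.sequence) < L:
            raise PlacementError(
                f"upstream region of {operon.operon_id} in {genome.genome_id} "
                f"is shorter than the motif ({len(region.sequence)} < {L})"
            )
        offset = int(rng.integers(0, len(region.sequence) - L + 1))
        n_mut = int(rng.integers(0, config.site_mutations_max + 1))
        site = list(consensus)
        for j in rng.choice(L, size=n_mut, replace=False):
            site[j] = rng.choice([b for b in BASES if b != site[j]])
        site_str = "".join(site)
        gstart, gend = region.genomic_interval(offset, L)
        genomic_site = site_str if region.strand == "+" else revcomp(site_str)
        seqs[genome.genome_id][gstart:gend] = list(genomic_site)
        new_truth_sites.append(
            TrueSite(
                genome_id=genome.genome_id,
                start=gstart,
                end=gend,
                strand=region.strand,
                family_id=fam,
                operon_id=operon.operon_id,
                sequence=site_str,
                n_mutations=n_mut,
                is_decoy=is_decoy,
            )
        )
        if not is_decoy:
            site_seqs.append(site_str)

    by_id = {g.genome_id: g for g in genomes}
    for fam in targets:
        for gid in target_presence[fam]:
            if gid in presence[fam]:
                _implant(by_id[gid], fam, is_decoy=False)
    for i, fam in enumerate(decoy_fams):
        # rotate the host genome so decoys do not pile up in one genome
        hosts = sorted(presence[fam])
        chosen = [hosts[(i * decoy_genomes + k) % len(hosts)] for k in range(decoy_genomes)]
        for gid in chosen:
            _implant(by_id[gid], fam, is_decoy=True)

    new_genomes = [
        Genome(
            genome_id=g.genome_id,
            sequence="".join(seqs[g.genome_id]),
            genes=[Gene(**{**vars(gene)}) for gene in g.genes],
        )
        for g in genomes
    ]
    from .motif_discovery import WeightMatrix

    counts = WeightMatrix.from_sequences(site_seqs).counts if site_seqs else None
    truth_out = PangenomeTruth(
        true_ortho_partition=truth.true_ortho_partition,
        true_sites=list(truth.true_sites) + new_truth_sites,
        true_motif_counts=counts,
        true_expr_blocks=dict(truth.true_expr_blocks),
        target_families=truth.target_families,
        tf_family=truth.tf_family,
    )
    return new_genomes, truth_out


def simulate(config: SimConfig) -> tuple[list[Genome], PangenomeTruth]:
    """generate_pangenome followed by implant_regulon."""
    genomes, truth = generate_pangenome(config)
    return implant_regulon(genomes, truth, config)


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def generate_expression(
    truth: PangenomeTruth,
    config: SimConfig,
    genome_id: Optional[str] = None,
) -> pd.DataFrame:
    """Block-structured expression matrix (genes x conditions).

    Rows are the model genome's genes of the block families.  Each block is
    a shared standard-normal latent condition profile plus independent
    Gaussian noise; with noise standard deviation sqrt(1/r - 1) the expected
    within-block Pearson correlation is r and the expected between-block
    correlation is 0.  Updates ``truth.true_expr_blocks``.
    """
    if config.expr_n_conditions < 3:
        raise ParameterError("need >= 3 conditions for meaningful correlations")
    blocks = config.expr_blocks or config.default_expr_blocks()
    rng = np.random.default_rng(config.seed + 2)
    if genome_id is None:
        genome_id = sorted(
            {g for members in truth.true_ortho_partition.values() for g in members}
        )[0]

    rows: list[np.ndarray] = []
    index: list[str] = []
    truth.true_expr_blocks.clear()
    n_cond = config.expr_n_conditions
    for bi, block in enumerate(blocks):
        if not (0 < block.corr_target <= 1):
            raise ParameterError("within-block correlation target must lie in (0, 1]")
        sd = (
            block.noise_sd
            if block.noise_sd is not None
            else float(np.sqrt(1.0 / block.corr_target - 1.0))
        )
        latent = rng.standard_normal(n_cond)
        for fam in block.family_ids:
            members = truth.true_ortho_partition.get(fam)
            if not members:
                raise ConfigError(f"expression block references unknown family {fam}")
            if genome_id not in members:
                continue
            locus = members[genome_id][0]
            rows.append(latent + sd * rng.standard_normal(n_cond))
            index.append(locus)
            truth.true_expr_blocks[locus] = bi
    return pd.DataFrame(
        np.array(rows), index=index, columns=[f"cond_{j + 1:03d}" for j in range(n_cond)]
    )


# ---------------------------------------------------------------------------
# On-disk emission (same formats genome_model reads)
# ---------------------------------------------------------------------------

def write_pangenome(
    genomes: Sequence[Genome],
    truth: PangenomeTruth,
    outdir: str | Path,
    config: Optional[SimConfig] = None,
) -> None:
    """Emit FASTA/GFF3/protein-FASTA per genome plus truth tables (TSV/BED)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for g in genomes:
        genome_model.write_genome(
            g,
            outdir / f"{g.genome_id}.fna",
            outdir / f"{g.genome_id}.gff3",
            outdir / f"{g.genome_id}.faa",
        )
    rows = [
        {"family_id": fam, "genome_id": gid, "locus_tag": locus}
        for fam, members in sorted(truth.true_ortho_partition.items())
        for gid, loci in sorted(members.items())
        for locus in loci
    ]
    pd.DataFrame(rows).to_csv(outdir / "true_orthologs.tsv", sep="\t", index=False)
    with open(outdir / "true_sites.bed", "w") as fh:
        for s in truth.true_sites:
            kind = "decoy" if s.is_decoy else "site"
            fh.write(
                f"{s.genome_id}\t{s.start}\t{s.end}\t{kind}\t{s.n_mutations}\t"
                f"{s.strand}\t{s.family_id}\n"
            )
    if config is not None:
        payload = asdict(config)
        payload["expr_blocks"] = (
            [asdict(b) for b in config.expr_blocks] if config.expr_blocks else None
        )
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)
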