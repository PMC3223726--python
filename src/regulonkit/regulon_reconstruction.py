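"""Cross-genome regulon assembly.

A *regulon* is the set of operons directly co-regulated by one transcription
factor.  Two reconstruction workflows are provided:

* **propagation** of a known regulon from a model genome: find orthologs of
  the TF, project the known targets through orthology, re-derive the motif
  from the orthologous upstream regions, scan every genome encoding the TF
  at the training-minimum threshold, and keep candidates that pass the
  cross-genome consistency check.  If new members are admitted the procedure
  is repeated once from the ortholog-projection step with the enlarged
  training set.
* **ab initio** inference for a training set of putatively co-regulated
  operons (pathway- or gene-cluster-derived): discover a motif on their
  pooled upstream regions, scan, filter, and attribute a TF afterwards from
  genomic context (positional clustering, autoregulation, phylogenetic
  pattern).

The consistency check retains a candidate operon only when orthologs of its
lead gene in at least ``min_other_genomes`` other genomes (default 2) also
carry a candidate site above the threshold, or when the candidate is
explicitly flagged as functionally linked to established members.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from . import genome_model
from .errors import ConsistencyError, DiscoveryError, InputError
from .genome_model import Genome, Operon, UpstreamRegion
from .motif_discovery import (
    MotifComparison,
    WeightMatrix,
    compare_motifs,
    discover_motif,
)
from .orthology import OrthoGroup
from .site_scan import SiteHit, scan_regions, training_threshold

SITE_CONSERVED = "site_conserved"
FUNCTIONALLY_LINKED = "functionally_linked"


@dataclass
class RegulonMember:
    """One operon belonging to a regulon in one genome."""

    genome_id: str
    operon_id: str
    hits: list[SiteHit] = field(default_factory=list)
    evidence: str = SITE_CONSERVED

    @property
    def best_score(self) -> float:
        return max((h.score for h in self.hits), default=float("-inf"))


@dataclass
class Regulon:
    """A reconstructed cross-genome regulon."""

    tf_group: Optional[str]
    motif: Optional[WeightMatrix]
    members: dict[str, list[RegulonMember]] = field(default_factory=dict)
    provenance: str = "ab_initio"  # or "propagated"
    threshold: float = float("nan")
    motif_comparison: Optional[MotifComparison] = None
    confident: bool = True
    notes: list[str] = field(default_factory=list)

    @property
    def tf_less(self) -> bool:
        return self.tf_group is None

    def member_set(self) -> set[tuple[str, str]]:
        return {
            (genome, m.operon_id) for genome, mm in self.members.items() for m in mm
        }

    def presence_pattern(self, genome_ids: Sequence[str]) -> tuple[bool, ...]:
        return tuple(bool(self.members.get(g)) for g in genome_ids)

    def to_json(self) -> str:
        payload = {
            "tf_group": self.tf_group,
            "provenance": self.provenance,
            "threshold": self.threshold,
            "consensus": self.motif.consensus if self.motif else None,
            "info_content_bits": self.motif.info_content_bits if self.motif else None,
            "confident": self.confident,
            "members": {
                genome: [
                    {
                        "operon_id": m.operon_id,
                        "evidence": m.evidence,
                        "sites": [
                            {
                                "start": h.start,
                                "end": h.end,
                                "strand": h.strand,
                                "score": round(h.score, 4),
                                "sequence": h.sequence,
                            }
                            for h in m.hits
                        ],
                    }
                    for m in mm
                ]
                for genome, mm in sorted(self.members.items())
            },
        }
        return json.dumps(payload)


# ---------------------------------------------------------------------------
# Genome context shared by the workflows
# ---------------------------------------------------------------------------

@dataclass
class ReconstructionParams:
    """Tunable knobs of the reconstruction workflows."""

    motif_len: Optional[int] = None          # default: length of the seed sites
    max_mismatch_pairs: Optional[int] = None  # default ceil(L/4)
    max_ignored: Optional[int] = 0            # propagation trusts its training set
    max_iter: int = 50
    symmetric: bool = True
    min_other_genomes: int = 2
    max_gap_bp: int = genome_model.DEFAULT_OPERON_GAP
    upstream_len: int = genome_model.DEFAULT_UPSTREAM_LEN
    max_repeats: int = 1                      # re-runs from the projection step
    # mean column IC below this -> "no confident regulon" flag; profiles
    # overfit to signal-free regions plateau near 0.5 bits/column while
    # recovered palindromic signal stays above ~1 bit/column
    min_ic_per_column_bits: float = 0.8
    max_seeds: Optional[int] = 500


class GenomeContext:
    """Precomputed operons, upstream regions and lead-gene indices."""

    def __init__(self, genomes: Sequence[Genome], params: ReconstructionParams):
        self.genomes = {g.genome_id: g for g in genomes}
        self.params = params
        self.operons: dict[str, list[Operon]] = {}
        self.regions: dict[str, list[UpstreamRegion]] = {}
        self.region_by_operon: dict[tuple[str, str], UpstreamRegion] = {}
        self.operon_by_id: dict[tuple[str, str], Operon] = {}
        self.operon_of_gene: dict[tuple[str, str], Operon] = {}
        for g in genomes:
            ops = genome_model.call_operons(g, max_gap_bp=params.max_gap_bp)
            self.operons[g.genome_id] = ops
            regs = genome_model.upstream_regions(g, ops, max_len=params.upstream_len)
            self.regions[g.genome_id] = regs
            for r in regs:
                self.region_by_operon[(g.genome_id, r.operon_id)] = r
            for op in ops:
                self.operon_by_id[(g.genome_id, op.operon_id)] = op
                for locus in op.member_genes:
                    self.operon_of_gene[(g.genome_id, locus)] = op


def _group_index(groups: Iterable[OrthoGroup]) -> dict[tuple[str, str], str]:
    index: dict[tuple[str, str], str] = {}
    for grp in groups:
        for genome, locus in grp.loci():
            index[(genome, locus)] = grp.group_id
    return index


# ---------------------------------------------------------------------------
# Consistency filter
# ---------------------------------------------------------------------------

def consistency_filter(
    candidates: Mapping[str, Sequence[SiteHit]],
    context: GenomeContext,
    groups: Sequence[OrthoGroup],
    min_other_genomes: int = 2,
    functional_links: Optional[set[tuple[str, str]]] = None,
) -> dict[str, list[RegulonMember]]:
    """Retain candidates whose lead-gene orthologs carry sites elsewhere.

    ``candidates`` maps genome_id to site hits with ``target_operon`` set.  A
    candidate operon in genome g survives iff orthologs of its lead gene in
    at least ``min_other_genomes`` genomes other than g also have a candidate
    hit, or iff (genome_id, operon_id) is in ``functional_links`` (explicit,
    user-supplied pathway knowledge); such members are marked accordingly.
    The filter never adds members.
    """
    functional_links = functional_links or set()
    ortho_of = _group_index(groups)

    # candidate operons per genome, with their hits
    per_operon: dict[tuple[str, str], list[SiteHit]] = {}
    for genome_id, hits in candidates.items():
        for hit in hits:
            if hit.target_operon is None:
                continue
            per_operon.setdefault((genome_id, hit.target_operon), []).append(hit)

    # genomes in which each ortholog group has a candidate
    group_hit_genomes: dict[str, set[str]] = {}
    group_of_candidate: dict[tuple[str, str], str] = {}
    for genome_id, operon_id in per_operon:
        operon = context.operon_by_id.get((genome_id, operon_id))
        if operon is None:
            raise ConsistencyError(f"unknown operon {operon_id} in {genome_id}")
        group = ortho_of.get((genome_id, operon.lead_gene))
        if group is None:
            raise ConsistencyError(
                f"lead gene {operon.lead_gene} of {operon_id} has no ortholog group"
            )
        group_of_candidate[(genome_id, operon_id)] = group
        group_hit_genomes.setdefault(group, set()).add(genome_id)

    retained: dict[str, list[RegulonMember]] = {}
    for (genome_id, operon_id), hits in sorted(per_operon.items()):
        group = group_of_candidate[(genome_id, operon_id)]
        n_other = len(group_hit_genomes[group] - {genome_id})
        if n_other >= min_other_genomes:
            evidence = SITE_CONSERVED
        elif (genome_id, operon_id) in functional_links:
            evidence = FUNCTIONALLY_LINKED
        else:
            continue
        retained.setdefault(genome_id, []).append(
            RegulonMember(
                genome_id=genome_id,
                operon_id=operon_id,
                hits=sorted(hits, key=lambda h: h.start),
                evidence=evidence,
            )
        )
    return retained


# ---------------------------------------------------------------------------
# Propagation of a known regulon
# ---------------------------------------------------------------------------

@dataclass
class SeedRegulon:
    """A known regulon in a model genome: TF, targets, and known sites."""

    tf_name: str
    model_genome: str
    tf_locus: Optional[str]
    target_loci: list[str]
    known_sites: list[str] = field(default_factory=list)


@dataclass
class PropagationReport:
    """Outcome bookkeeping for a propagation run."""

    tf_name: str
    skipped: bool = False
    reason: str = ""
    iterations: int = 0


def _project_targets(
    seed_loci: Sequence[str],
    model_genome: str,
    groups: Sequence[OrthoGroup],
    context: GenomeContext,
    restrict_genomes: Optional[set[str]] = None,
) -> dict[tuple[str, str], UpstreamRegion]:
    """Orthologous target operons (and upstreams) of the seed's target genes."""
    ortho_of = _group_index(groups)
    by_id = {g.group_id: g for g in groups}
    projected: dict[tuple[str, str], UpstreamRegion] = {}
    for locus in seed_loci:
        group_id = ortho_of.get((model_genome, locus))
        if group_id is None:
            continue
        for genome_id, member_locus in by_id[group_id].loci():
            if restrict_genomes is not None and genome_id not in restrict_genomes:
                continue
            operon = context.operon_of_gene.get((genome_id, member_locus))
            if operon is None:
                continue
            region = context.region_by_operon.get((genome_id, operon.operon_id))
            if region is not None and not region.is_empty:
                projected[(genome_id, operon.operon_id)] = region
    return projected


def propagate_regulon(
    seed: SeedRegulon,
    genomes: Sequence[Genome],
    groups: Sequence[OrthoGroup],
    params: Optional[ReconstructionParams] = None,
    functional_links: Optional[set[tuple[str, str]]] = None,
) -> tuple[Optional[Regulon], PropagationReport]:
    """Propagate a known regulon across a genome set.

    Steps: (i) locate the orthologous TF group; (ii) take the seed's known
    targets and sites; (iii) project targets through orthology and extract
    upstream regions; (iv) re-derive the motif from those regions and compare
    it with the seed motif; (v) scan every genome encoding the TF at the
    training-minimum threshold, then apply the consistency check.  When the
    member repertoire grows beyond the projected seed targets, steps iii-v
    run once more with the enlarged training set.
    """
    params = params or ReconstructionParams()
    report = PropagationReport(tf_name=seed.tf_name)
    context = GenomeContext(genomes, params)
    ortho_of = _group_index(groups)
    by_id = {g.group_id: g for g in groups}

    # (i) the TF's ortholog group and the genomes that encode it
    tf_group_id: Optional[str] = None
    if seed.tf_locus is not None:
        tf_group_id = ortho_of.get((seed.model_genome, seed.tf_locus))
    if tf_group_id is None:
        report.skipped = True
        report.reason = f"TF {seed.tf_name} has no ortholog group in the genome set"
        return None, report
    tf_genomes = set(by_id[tf_group_id].members)

    # (ii) seed motif from the known sites, when provided
    L = params.motif_len or (len(seed.known_sites[0]) if seed.known_sites else None)
    if L is None:
        raise InputError("motif length unknown: provide params.motif_len or known_sites")
    seed_motif = (
        WeightMatrix.from_sequences(seed.known_sites) if seed.known_sites else None
    )

    # (iii) project the seed targets through orthology
    training: dict[tuple[str, str], UpstreamRegion] = _project_targets(
        seed.target_loci, seed.model_genome, groups, context, restrict_genomes=tf_genomes
    )
    if len(training) < 3:
        report.skipped = True
        report.reason = "fewer than 3 orthologous target upstream regions available"
        return None, report

    regulon: Optional[Regulon] = None
    projected_set = set(training)
    for iteration in range(1 + params.max_repeats):
        report.iterations = iteration + 1
        # (iv) motif re-derivation on the training upstreams
        try:
            motif = discover_motif(
                [(f"{g}:{op}", r.sequence) for (g, op), r in sorted(training.items())],
                motif_len=L,
                max_mismatched_pairs=params.max_mismatch_pairs,
                max_ignored=params.max_ignored,
                max_iter=params.max_iter,
                symmetric=params.symmetric,
                max_seeds=params.max_seeds,
            )
        except DiscoveryError as exc:
            raise DiscoveryError(f"motif discovery failed for TF {seed.tf_name}: {exc}")
        threshold = training_threshold(motif)

        # (v) scan genomes encoding the TF, upstream regions only
        candidates: dict[str, list[SiteHit]] = {}
        for genome_id in sorted(tf_genomes):
            if genome_id not in context.regions:
                continue
            candidates[genome_id] = scan_regions(
                context.regions[genome_id], motif, threshold
            )
        members = consistency_filter(
            candidates,
            context,
            groups,
            min_other_genomes=params.min_other_genomes,
            functional_links=functional_links,
        )
        regulon = Regulon(
            tf_group=tf_group_id,
            motif=motif,
            members=members,
            provenance="propagated",
            threshold=threshold,
            motif_comparison=(
                compare_motifs(motif, seed_motif) if seed_motif is not None else None
            ),
        )
        member_set = regulon.member_set()
        if member_set <= projected_set or iteration >= params.max_repeats:
            break
        # repertoire grew: enlarge the training set and repeat from (iii)
        for genome_id, operon_id in sorted(member_set - projected_set):
            region = context.region_by_operon.get((genome_id, operon_id))
            if region is not None and not region.is_empty:
                training[(genome_id, operon_id)] = region
        projected_set = set(training)
    return regulon, report


# ---------------------------------------------------------------------------
# Ab initio inference
# ---------------------------------------------------------------------------

def infer_novel_regulon(
    training_operons: Sequence[tuple[str, str]],
    genomes: Sequence[Genome],
    groups: Sequence[OrthoGroup],
    motif_len: int,
    params: Optional[ReconstructionParams] = None,
    functional_links: Optional[set[tuple[str, str]]] = None,
) -> Regulon:
    """Infer a regulon from a training set of putatively co-regulated operons.

    ``training_operons`` is a list of (genome_id, operon_id).  A motif is
    discovered on their pooled upstream regions, every genome is scanned at
    the training-minimum threshold, and the consistency check prunes the
    candidates.  TF attribution is left to :func:`attribute_tf`.  When the
    discovered motif is weak (mean column information content below
    ``params.min_ic_per_column_bits``) the regulon is flagged not confident.
    """
    params = params or ReconstructionParams(max_ignored=None)  # ab initio default d = n//5
    context = GenomeContext(genomes, params)
    regions = []
    for genome_id, operon_id in training_operons:
        region = context.region_by_operon.get((genome_id, operon_id))
        if region is not None and not region.is_empty:
            regions.append((f"{genome_id}:{operon_id}", region.sequence))
    if len(regions) < 3:
        raise InputError("need >= 3 training operons with non-empty upstream regions")
    motif = discover_motif(
        sorted(regions),
        motif_len=motif_len,
        max_mismatched_pairs=params.max_mismatch_pairs,
        max_ignored=params.max_ignored,
        max_iter=params.max_iter,
        symmetric=params.symmetric,
        max_seeds=params.max_seeds,
    )
    threshold = training_threshold(motif)
    candidates = {
        genome_id: scan_regions(context.regions[genome_id], motif, threshold)
        for genome_id in sorted(context.genomes)
    }
    members = consistency_filter(
        candidates,
        context,
        groups,
        min_other_genomes=params.min_other_genomes,
        functional_links=functional_links,
    )
    confident = (
        motif.info_content_bits / motif.length >= params.min_ic_per_column_bits
    )
    regulon = Regulon(
        tf_group=None,
        motif=motif,
        members=members,
        provenance="ab_initio",
        threshold=threshold,
        confident=confident,
    )
    if not confident:
        regulon.notes.append(
            f"low-information motif ({motif.info_content_bits:.2f} bits over "
            f"{motif.length} columns); no confident regulon"
        )
    return regulon


# ---------------------------------------------------------------------------
# TF attribution
# ---------------------------------------------------------------------------

@dataclass
class TFAttribution:
    group_id: str
    evidences: list[str]  # subset of {positional, autoregulation, phylo_pattern}


def attribute_tf(
    regulon: Regulon,
    genomes: Sequence[Genome],
    groups: Sequence[OrthoGroup],
    params: Optional[ReconstructionParams] = None,
) -> list[TFAttribution]:
    """Score TF-labelled ortholog groups on three context evidences.

    (i) *positional*: a TF gene lies inside or within two genes of a member
    operon in some genome; (ii) *autoregulation*: the TF's own upstream
    region carries a site above the regulon threshold; (iii) *phylo_pattern*:
    the TF group's genome-presence pattern equals the regulon's.  Groups
    tying for the most evidences are all returned (no tie-breaking by
    design); an empty list is a valid outcome for TF-less regulons.
    """
    params = params or ReconstructionParams()
    context = GenomeContext(genomes, params)
    genome_ids = sorted(context.genomes)

    # TF-labelled loci per ortholog group
    tf_loci: dict[str, list[tuple[str, str]]] = {}
    labelled = {
        (g.genome_id, gene.locus_tag)
        for g in genomes
        for gene in g.genes
        if gene.tf_family
    }
    for grp in groups:
        mine = [loc for loc in grp.loci() if loc in labelled]
        if mine:
            tf_loci[grp.group_id] = mine
    if not tf_loci:
        return []

    member_set = regulon.member_set()
    member_gene_pos: dict[str, list[int]] = {}
    gene_rank: dict[tuple[str, str], int] = {}
    for genome_id, genome in context.genomes.items():
        for i, gene in enumerate(genome.genes):
            gene_rank[(genome_id, gene.locus_tag)] = i
    for genome_id, operon_id in member_set:
        operon = context.operon_by_id.get((genome_id, operon_id))
        if operon:
            member_gene_pos.setdefault(genome_id, []).extend(
                gene_rank[(genome_id, l)] for l in operon.member_genes
            )

    regulon_pattern = regulon.presence_pattern(genome_ids)
    attributions: list[TFAttribution] = []
    for group_id, loci in sorted(tf_loci.items()):
        evidences: list[str] = []
        # (i) positional clustering: TF within <= 2 genes of a member operon
        positional = any(
            any(
                abs(gene_rank[(genome_id, locus)] - pos) <= 2
                for pos in member_gene_pos.get(genome_id, [])
            )
            for genome_id, locus in loci
        )
        if positional:
            evidences.append("positional")
        # (ii) autoregulation: a site in the TF's own upstream region
        if regulon.motif is not None and not pd.isna(regulon.threshold):
            auto = False
            for genome_id, locus in loci:
                operon = context.operon_of_gene.get((genome_id, locus))
                if operon is None:
                    continue
                region = context.region_by_operon.get((genome_id, operon.operon_id))
                if region is None or region.is_empty:
                    continue
                hits = scan_regions([region], regulon.motif, regulon.threshold)
                if hits:
                    auto = True
                    break
            if auto:
                evidences.append("autoregulation")
        # (iii) phylogenetic pattern match
        grp_members = next(g for g in groups if g.group_id == group_id).members
        tf_pattern = tuple(g in grp_members for g in genome_ids)
        if tf_pattern == regulon_pattern:
            evidences.append("phylo_pattern")
        if evidences:
            attributions.append(TFAttribution(group_id=group_id, evidences=evidences))
    if not attributions:
        return []
    best = max(len(a.evidences) for a in attributions)
    return [a for a in attributions if len(a.evidences) == best]


# ---------------------------------------------------------------------------
# Conservation matrix
# ---------------------------------------------------------------------------

def conservation_matrix(
    regulons: Mapping[str, Regulon],
    genome_ids: Sequence[str],
) -> pd.DataFrame:
    """Regulon x genome presence matrix ('+' / '-') with marginals.

    A cell is '+' iff the regulon has at least one member operon in that
    genome.  Row sums appear in an ``n_genomes`` column, column sums in an
    ``n_regulons`` row.
    """
    data = {
        name: ["+" if reg.members.get(g) else "-" for g in genome_ids]
        for name, reg in sorted(regulons.items())
    }
    df = pd.DataFrame(data, index=list(genome_ids)).T
    df["n_genomes"] = (df == "+").sum(axis=1)
    totals = (df.drop(columns="n_genomes") == "+").sum(axis=0)
    totals["n_genomes"] = df["n_genomes"].sum()
    df.loc["n_regulons"] = totals
    return df


def regulons_to_table(regulons: Mapping[str, Regulon]) -> pd.DataFrame:
    """Flatten regulons to a tidy TSV-ready table of member sites."""
    rows = []
    for name, reg in sorted(regulons.items()):
        for genome_id, members in sorted(reg.members.items()):
            for m in members:
                for h in m.hits:
                    rows.append(
                        {
                            "regulon": name,
                            "tf_group": reg.tf_group or "",
                            "genome_id": genome_id,
                            "operon_id": m.operon_id,
                            "evidence": m.evidence,
                            "site_start": h.start,
                            "site_end": h.end,
                            "strand": h.strand,
                            "score": round(h.score, 4),
                            "sequence": h.sequence,
                        }
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "regulon", "tf_group", "genome_id", "operon_id", "evidence",
            "site_start", "site_end", "strand", "score", "sequence",
        ],
    )
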