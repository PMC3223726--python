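"""Smith-Waterman bidirectional-best-hit orthology and conservation classes.

Orthologs between genomes are reciprocal best local-alignment hits
(Smith-Waterman, BLOSUM62, affine gaps open 11 / extend 1) whose identity --
matches divided by aligned columns, gap columns included in the denominator
-- reaches a configurable threshold (default 30%).  Cross-genome orthologous
groups are connected components of the BBH graph; a group is *core* when it
spans every genome, *strain-specific* when it spans exactly one, and
*variable* otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import math

import networkx as nx
from skbio.alignment import pair_align
from skbio.sequence import Protein

from .errors import ConsistencyError, InputError
from .genome_model import Genome

DEFAULT_MIN_IDENTITY = 0.30
DEFAULT_MIN_COVERAGE = 0.50  # aligned columns / length of the shorter protein
DEFAULT_MAX_EVALUE = 1e-5
DEFAULT_SUB_MATRIX = "BLOSUM62"
DEFAULT_GAP_COST = (11.0, 1.0)  # affine: open + extend per residue

# Karlin-Altschul parameters for gapped BLOSUM62 with open 11 / extend 1
# (the values BLASTP reports for this scoring scheme); used to screen
# reciprocal best hits for statistical significance, E = K*m*n*exp(-lambda*S)
GAPPED_LAMBDA = 0.267
GAPPED_K = 0.041

CORE = "core"
VARIABLE = "variable"
STRAIN_SPECIFIC = "strain_specific"


@dataclass(frozen=True)
class BBHPair:
    """A reciprocal best Smith-Waterman hit between two genomes."""

    genome_a: str
    genome_b: str
    locus_a: str
    locus_b: str
    identity: float
    score: float


@dataclass
class OrthoGroup:
    """A cross-genome orthologous group of proteins."""

    group_id: str
    members: dict[str, list[str]]  # genome_id -> locus_tags
    conservation_class: str = ""

    @property
    def n_genomes(self) -> int:
        return len(self.members)

    def loci(self) -> list[tuple[str, str]]:
        return [(g, l) for g, ll in self.members.items() for l in ll]


def _as_protein(seq: str, label: str) -> Protein:
    if not seq:
        raise InputError(f"empty protein sequence for {label}")
    try:
        return Protein(seq.upper())
    except ValueError as exc:
        raise InputError(f"invalid residue in {label}: {exc}") from exc


def sw_identity(
    protein_a: str,
    protein_b: str,
    sub_matrix: str = DEFAULT_SUB_MATRIX,
    gap_cost: tuple[float, float] = DEFAULT_GAP_COST,
) -> tuple[float, float]:
    """Local alignment score and identity of two amino-acid sequences.

    Identity is matches / aligned columns with gap columns counted in the
    denominator.  Sequences with no positively scoring local alignment
    (score 0, empty alignment) report identity 0.
    """
    score, identity, _ = _sw_align(
        _as_protein(protein_a, "protein_a"),
        _as_protein(protein_b, "protein_b"),
        sub_matrix,
        gap_cost,
    )
    return score, identity


def _sw_align(
    pa: Protein, pb: Protein, sub_matrix: str, gap_cost
) -> tuple[float, float, float]:
    """(score, identity, coverage); coverage = columns / shorter protein."""
    score, paths, _ = pair_align(
        pa, pb, mode="local", sub_score=sub_matrix, gap_cost=gap_cost, max_paths=1
    )
    if not paths or score <= 0:
        return float(score), 0.0, 0.0
    aln_a, aln_b = paths[0].to_aligned((pa, pb))
    columns = len(aln_a)
    matches = sum(1 for x, y in zip(aln_a, aln_b) if x == y and x != "-")
    identity = matches / columns if columns else 0.0
    coverage = columns / min(len(pa), len(pb))
    return float(score), identity, coverage


def _sw_score(pa: Protein, pb: Protein, sub_matrix: str, gap_cost) -> float:
    score, _, _ = pair_align(
        pa, pb, mode="local", sub_score=sub_matrix, gap_cost=gap_cost, max_paths=0
    )
    return float(score)


def bbh_orthologs(
    genome_a_proteins: Mapping[str, str],
    genome_b_proteins: Mapping[str, str],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    genome_a: str = "A",
    genome_b: str = "B",
    sub_matrix: str = DEFAULT_SUB_MATRIX,
    gap_cost: tuple[float, float] = DEFAULT_GAP_COST,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    max_evalue: float = DEFAULT_MAX_EVALUE,
) -> list[BBHPair]:
    """Reciprocal best-hit pairs between two proteomes.

    A pair (a, b) is emitted iff b is a's highest-scoring hit in B, a is b's
    highest-scoring hit in A (score ties broken by lexicographic locus_tag),
    and the alignment identity reaches ``min_identity``.  Two further guards
    reject chance pairings of proteins that have no true counterpart in the
    partner genome (best-hit selection maximizes over many alignments, so
    such pairs carry inflated short alignments): the local alignment must
    span at least ``min_coverage`` of the shorter protein, and its
    Karlin-Altschul expect value K*m*n*exp(-lambda*S) must not exceed
    ``max_evalue``.
    """
    if not genome_a_proteins or not genome_b_proteins:
        raise InputError("both proteomes must be non-empty")
    loci_a = sorted(genome_a_proteins)  # lexicographic order makes ties deterministic
    loci_b = sorted(genome_b_proteins)
    pa = {l: _as_protein(genome_a_proteins[l], l) for l in loci_a}
    pb = {l: _as_protein(genome_b_proteins[l], l) for l in loci_b}

    best_in_b: dict[str, tuple[float, str]] = {}
    best_in_a: dict[str, tuple[float, str]] = {}
    scores: dict[tuple[str, str], float] = {}
    for la in loci_a:
        for lb in loci_b:
            s = _sw_score(pa[la], pb[lb], sub_matrix, gap_cost)
            scores[(la, lb)] = s
            if la not in best_in_b or s > best_in_b[la][0]:
                best_in_b[la] = (s, lb)
            if lb not in best_in_a or s > best_in_a[lb][0]:
                best_in_a[lb] = (s, la)

    pairs: list[BBHPair] = []
    for la, (s, lb) in best_in_b.items():
        if s <= 0 or best_in_a[lb][1] != la:
            continue
        score, identity, coverage = _sw_align(pa[la], pb[lb], sub_matrix, gap_cost)
        evalue = GAPPED_K * len(pa[la]) * len(pb[lb]) * math.exp(-GAPPED_LAMBDA * score)
        if identity >= min_identity and coverage >= min_coverage and evalue <= max_evalue:
            pairs.append(
                BBHPair(
                    genome_a=genome_a,
                    genome_b=genome_b,
                    locus_a=la,
                    locus_b=lb,
                    identity=identity,
                    score=score,
                )
            )
    return pairs


def all_pairwise_bbh(
    proteomes: Mapping[str, Mapping[str, str]],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    **kw,
) -> list[BBHPair]:
    """BBH pairs over every unordered pair of genomes."""
    ids = sorted(proteomes)
    pairs: list[BBHPair] = []
    for i, ga in enumerate(ids):
        for gb in ids[i + 1 :]:
            pairs.extend(
                bbh_orthologs(
                    proteomes[ga],
                    proteomes[gb],
                    min_identity=min_identity,
                    genome_a=ga,
                    genome_b=gb,
                    **kw,
                )
            )
    return pairs


def cluster_ortholog_groups(
    pairs: Iterable[BBHPair],
    proteomes: Mapping[str, Mapping[str, str]],
    model_genome: Optional[str] = None,
) -> list[OrthoGroup]:
    """Connected components of the BBH graph; unmatched proteins become singletons.

    Groups are named by a representative locus_tag: the lexicographically
    smallest member from the model genome when present there, otherwise the
    smallest member overall.
    """
    known = {(g, l) for g, prot in proteomes.items() for l in prot}
    graph: nx.Graph = nx.Graph()
    graph.add_nodes_from(known)
    for p in pairs:
        a, b = (p.genome_a, p.locus_a), (p.genome_b, p.locus_b)
        if a not in known or b not in known:
            raise ConsistencyError(f"BBH pair references unknown locus: {p}")
        graph.add_edge(a, b)

    n_genomes = len(proteomes)
    groups: list[OrthoGroup] = []
    for component in nx.connected_components(graph):
        members: dict[str, list[str]] = {}
        for g, l in sorted(component):
            members.setdefault(g, []).append(l)
        if model_genome and model_genome in members:
            rep = members[model_genome][0]
        else:
            rep = min(l for _, l in component)
        groups.append(
            OrthoGroup(
                group_id=f"OG_{rep}",
                members=members,
                conservation_class=_conservation_class(len(members), n_genomes),
            )
        )
    groups.sort(key=lambda g: g.group_id)
    return groups


def _conservation_class(span: int, n_genomes: int) -> str:
    if span == n_genomes:
        return CORE
    if span == 1:
        return STRAIN_SPECIFIC
    return VARIABLE


@dataclass
class ConservationSummary:
    """Counts and integer percentages of groups per conservation class."""

    counts: dict[str, int]
    percentages: dict[str, int]
    total: int


def classify_conservation(
    groups: Sequence[OrthoGroup],
    n_genomes: int,
    genome_ids: Optional[set[str]] = None,
) -> ConservationSummary:
    """Classify groups as core / variable / strain-specific and summarize.

    Percentages are class_count / total_groups rounded to the nearest
    integer percent.
    """
    counts = {CORE: 0, VARIABLE: 0, STRAIN_SPECIFIC: 0}
    for grp in groups:
        if genome_ids is not None and not set(grp.members) <= genome_ids:
            unknown = set(grp.members) - genome_ids
            raise ConsistencyError(f"group {grp.group_id} cites unknown genomes {unknown}")
        cls = _conservation_class(grp.n_genomes, n_genomes)
        grp.conservation_class = cls
        counts[cls] += 1
    total = len(groups)
    percentages = {
        cls: (round(100 * c / total) if total else 0) for cls, c in counts.items()
    }
    return ConservationSummary(counts=counts, percentages=percentages, total=total)


def groups_table(groups: Sequence[OrthoGroup]):
    """Flatten groups to a tidy DataFrame (group_id, genome_id, locus_tag, class)."""
    import pandas as pd

    rows = [
        {
            "group_id": g.group_id,
            "genome_id": genome,
            "locus_tag": locus,
            "conservation_class": g.conservation_class,
        }
        for g in groups
        for genome, locus in g.loci()
    ]
    return pd.DataFrame(rows, columns=["group_id", "genome_id", "locus_tag", "conservation_class"])


def compute_ortholog_groups(
    genomes: Sequence[Genome],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    model_genome: Optional[str] = None,
    **kw,
) -> list[OrthoGroup]:
    """End-to-end: proteomes -> all pairwise BBH -> connected components."""
    proteomes = {g.genome_id: g.proteins for g in genomes}
    pairs = all_pairwise_bbh(proteomes, min_identity=min_identity, **kw)
    return cluster_ortholog_groups(
        pairs, proteomes, model_genome=model_genome or sorted(proteomes)[0]
    )
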