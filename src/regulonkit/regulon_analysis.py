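"""Comparative analytics over reconstructed regulons.

Covers the repertoire summary of TF protein families, regulon overlap
degrees and regulatory cascades, and expression-correlation subregulon
splitting (single-linkage components of the gene graph with edges where
Pearson r reaches a threshold).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ParameterError
from .genome_model import Genome
from .regulon_reconstruction import Regulon, TFAttribution


# ---------------------------------------------------------------------------
# TF repertoire
# ---------------------------------------------------------------------------

def repertoire_summary(genomes: Sequence[Genome]) -> pd.DataFrame:
    """Count TF-family-labelled genes per (family, genome).

    Returns a families x genomes table with a ``total`` row per genome and a
    ``multi_member_fraction`` row: the fraction of a genome's TFs belonging
    to families with at least two members in that genome.
    """
    genome_ids = [g.genome_id for g in genomes]
    counts: dict[str, dict[str, int]] = {}
    for g in genomes:
        for gene in g.genes:
            if gene.tf_family:
                counts.setdefault(gene.tf_family, {}).setdefault(g.genome_id, 0)
                counts[gene.tf_family][g.genome_id] += 1
    families = sorted(counts)
    df = pd.DataFrame(
        [[counts[f].get(g, 0) for g in genome_ids] for f in families],
        index=families,
        columns=genome_ids,
        dtype=float,
    )
    totals = df.sum(axis=0)
    multi = df.where(df >= 2, 0.0).sum(axis=0)
    df.loc["total"] = totals
    with np.errstate(invalid="ignore", divide="ignore"):
        df.loc["multi_member_fraction"] = np.where(totals > 0, multi / totals, 0.0)
    return df


# ---------------------------------------------------------------------------
# Overlap and cascades
# ---------------------------------------------------------------------------

@dataclass
class OverlapReport:
    """Which regulons control each operon, and how that degree distributes."""

    controllers: dict[tuple[str, str], list[str]]  # (genome, operon) -> regulons
    degree_histogram: dict[int, int]
    cascades: list[tuple[str, str]]  # (regulator regulon, target TF regulon)


def regulon_overlap(
    regulons: Mapping[str, Regulon],
    tf_operon_of_regulon: Optional[Mapping[str, set[tuple[str, str]]]] = None,
) -> OverlapReport:
    """Per-operon controller lists, the overlap-degree histogram, and cascades.

    ``tf_operon_of_regulon`` maps regulon name -> set of (genome_id,
    operon_id) holding that regulon's attributed TF gene; when given, a
    cascade (R, R') is reported whenever a member operon of R is the operon
    encoding the TF of another regulon R' in the same genome.
    """
    controllers: dict[tuple[str, str], list[str]] = {}
    for name, reg in sorted(regulons.items()):
        for genome_id, members in reg.members.items():
            for m in members:
                controllers.setdefault((genome_id, m.operon_id), []).append(name)
    histogram: dict[int, int] = {}
    for regs in controllers.values():
        histogram[len(regs)] = histogram.get(len(regs), 0) + 1

    cascades: list[tuple[str, str]] = []
    if tf_operon_of_regulon:
        for name, reg in sorted(regulons.items()):
            member_set = reg.member_set()
            for other, tf_operons in sorted(tf_operon_of_regulon.items()):
                if other != name and member_set & set(tf_operons):
                    cascades.append((name, other))
    return OverlapReport(
        controllers=controllers,
        degree_histogram=dict(sorted(histogram.items())),
        cascades=sorted(set(cascades)),
    )


# ---------------------------------------------------------------------------
# Expression correlation and subregulons
# ---------------------------------------------------------------------------

def pearson_matrix(expression: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation of gene expression profiles.

    Rows of ``expression`` are genes, columns are conditions.  Genes with a
    constant profile have undefined correlation; they are excluded with a
    warning rather than propagating NaN.  The result is exactly symmetric
    with a unit diagonal.
    """
    if expression.shape[1] < 3:
        raise ParameterError("need >= 3 conditions for Pearson correlation")
    values = expression.to_numpy(dtype=float)
    sd = values.std(axis=1)
    constant = sd == 0
    if constant.any():
        dropped = list(expression.index[constant])
        warnings.warn(f"excluding constant-profile genes: {dropped}", stacklevel=2)
    keep = expression.index[~constant]
    corr = np.atleast_2d(np.corrcoef(values[~constant]))
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=keep, columns=keep)


@dataclass
class SubregulonPartition:
    """Gene clusters with distinct co-expression patterns."""

    labels: dict[str, int]
    correlation: pd.DataFrame
    r_threshold: float

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.values()))

    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for gene, lab in sorted(self.labels.items()):
            out.setdefault(lab, []).append(gene)
        return out


def split_subregulons(
    correlation: pd.DataFrame,
    r_threshold: float = 0.5,
) -> SubregulonPartition:
    """Single-linkage components of the graph with edges where r >= threshold.

    Cluster labels are assigned in order of each component's alphabetically
    first gene, so the partition is deterministic.
    """
    if not -1.0 < r_threshold < 1.0:
        raise ParameterError("r_threshold must lie in (-1, 1)")
    genes = list(correlation.index)
    graph = nx.Graph()
    graph.add_nodes_from(genes)
    mat = correlation.to_numpy()
    n = len(genes)
    for i in range(n):
        for j in range(i + 1, n):
            if mat[i, j] >= r_threshold:
                graph.add_edge(genes[i], genes[j])
    components = sorted(nx.connected_components(graph), key=lambda c: min(c))
    labels = {gene: k for k, comp in enumerate(components) for gene in comp}
    return SubregulonPartition(
        labels=labels, correlation=correlation, r_threshold=r_threshold
    )
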