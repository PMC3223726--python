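"""Self-contained validation benchmarks over the built-in simulator.

Each function runs one complete, seeded experiment on synthetic data and
returns plain numbers: conservation-class arithmetic on a published-style
clustering summary, motif-consensus recovery, scan equivalence against an
exhaustive sliding-window oracle, training-threshold self-consistency,
consistency-filter discrimination, orthology partition recovery,
end-to-end regulon propagation, and expression subregulon recovery.
These are the quantitative claims the test suite asserts; the routines are
deliberately ordinary library client code.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import genome_model
from .dnautil import BASES, revcomp
from .motif_discovery import WeightMatrix, discover_motif, score_site
from .orthology import OrthoGroup, classify_conservation, compute_ortholog_groups
from .regulon_reconstruction import (
    GenomeContext,
    ReconstructionParams,
    SeedRegulon,
    consistency_filter,
    propagate_regulon,
)
from .regulon_analysis import pearson_matrix, split_subregulons
from .site_scan import scan_genome, scan_regions, training_threshold
from .synthetic_data import PangenomeTruth, SimConfig, generate_expression, simulate


# ---------------------------------------------------------------------------
# Published-style clustering arithmetic
# ---------------------------------------------------------------------------

def conservation_summary_from_counts(
    n_core: int, n_variable: int, n_specific: int, n_genomes: int
):
    """Run classify_conservation on a partition with the given class sizes.

    Groups are materialized with genuine genome spans (all genomes / a
    rotating subset of 2..n-1 genomes / a single genome) so the classifier
    derives every class from the span rule rather than from labels.
    """
    gids = [f"g{i}" for i in range(n_genomes)]
    groups: list[OrthoGroup] = []

    def _group(idx: int, span: list[str]) -> OrthoGroup:
        return OrthoGroup(
            group_id=f"OG{idx:04d}",
            members={g: [f"{g}_l{idx}"] for g in span},
        )

    idx = 0
    for _ in range(n_core):
        groups.append(_group(idx, gids))
        idx += 1
    for i in range(n_variable):
        k = 2 + i % (n_genomes - 2)  # spans cycle over 2..n-1
        groups.append(_group(idx, gids[:k]))
        idx += 1
    for i in range(n_specific):
        groups.append(_group(idx, [gids[i % n_genomes]]))
        idx += 1
    return classify_conservation(groups, n_genomes)


# ---------------------------------------------------------------------------
# Simulator helpers
# ---------------------------------------------------------------------------

def _model_target_regions(genomes, truth: PangenomeTruth, genome_id=None):
    """Upstream regions of the implanted target operons in one genome."""
    gid = genome_id or genomes[0].genome_id
    genome = next(g for g in genomes if g.genome_id == gid)
    operons = genome_model.call_operons(genome)
    regions = genome_model.upstream_regions(genome, operons)
    wanted = {
        s.operon_id for s in truth.true_sites if s.genome_id == gid and not s.is_decoy
    }
    return [r for r in regions if r.operon_id in wanted]


def truth_groups(truth: PangenomeTruth) -> list[OrthoGroup]:
    """OrthoGroups taken directly from the simulator's true partition."""
    return [
        OrthoGroup(group_id=f"OG_{fam}", members={g: list(ll) for g, ll in mem.items()})
        for fam, mem in sorted(truth.true_ortho_partition.items())
    ]


def truth_motif(truth: PangenomeTruth) -> WeightMatrix:
    """PWM of all implanted (non-decoy) site sequences."""
    sites = [s.sequence for s in truth.sites_of(is_decoy=False)]
    return WeightMatrix.from_sequences(sites)


# ---------------------------------------------------------------------------
# Motif recovery
# ---------------------------------------------------------------------------

def motif_recovery_trial(seed: int, config: SimConfig | None = None) -> bool:
    """Did discovery recover the consensus at every informative column?

    Discovery runs at default weak-palindrome and region-dropping settings
    on the model genome's implanted target upstream regions; recovery is
    judged at the columns where the *true* site alignment carries at least
    1 bit of information.
    """
    config = config or SimConfig(seed=seed)
    genomes, truth = simulate(config)
    regions = _model_target_regions(genomes, truth)
    found = discover_motif(regions, motif_len=config.motif_len)
    true_wm = truth_motif(truth)
    informative = np.nonzero(true_wm.column_ic_bits >= 1.0)[0]
    return all(
        found.consensus[j] == config.motif_consensus[j] for j in informative
    )


# ---------------------------------------------------------------------------
# Scan vs exhaustive oracle
# ---------------------------------------------------------------------------

def _exhaustive_scan(sequence: str, matrix: WeightMatrix, threshold: float):
    """Plain-loop both-strand sliding-window scan (the independent oracle)."""
    L = matrix.length
    out = []
    for i in range(len(sequence) - L + 1):
        window = sequence[i : i + L]
        if "N" in window:
            continue
        s = score_site(matrix.weights, window)
        if s >= threshold:
            out.append((i, "+", s))
        if not matrix.is_palindromic:
            s = score_site(matrix.weights, revcomp(window))
            if s >= threshold:
                out.append((i, "-", s))
    return sorted(out)


def scan_oracle_trial(seed: int, genome_len: int = 50_000) -> tuple[int, int]:
    """(number of oracle hits, number of disagreements with scan_genome).

    An asymmetric PWM trained on seeded near-consensus sites scans a random
    genome with a handful of implanted instances; agreement must be exact in
    coordinates, strands and scores.
    """
    rng = np.random.default_rng(seed)
    consensus = "TTGACACCGGTGTTAAAC"  # deliberately non-palindromic
    sites = []
    for _ in range(8):
        site = list(consensus)
        for j in rng.choice(len(site), size=2, replace=False):
            site[j] = str(rng.choice([b for b in BASES if b != site[j]]))
        sites.append("".join(site))
    matrix = WeightMatrix.from_sequences(sites)
    seq = "".join(np.array(list(BASES))[rng.integers(0, 4, genome_len)])
    for k in range(5):  # implant on both strands
        pos = int(rng.integers(0, genome_len - len(consensus)))
        ins = consensus if k % 2 == 0 else revcomp(consensus)
        seq = seq[:pos] + ins + seq[pos + len(consensus):]
    # well below the training minimum, so plenty of background windows pass
    # and the equivalence check covers more than the implanted sites
    threshold = training_threshold(matrix, sites) - 20.0
    genome = genome_model.Genome(genome_id="oracle", sequence=seq, genes=[])
    fast = sorted(
        (h.start, h.strand, h.score) for h in scan_genome(genome, matrix, threshold)
    )
    slow = _exhaustive_scan(seq, matrix, threshold)
    mismatches = len(set(map(_rounded, fast)) ^ set(map(_rounded, slow)))
    return len(slow), mismatches


def _rounded(hit: tuple[int, str, float]) -> tuple[int, str, float]:
    return (hit[0], hit[1], round(hit[2], 9))


# ---------------------------------------------------------------------------
# Threshold self-consistency
# ---------------------------------------------------------------------------

def threshold_selfconsistency_trial(
    seed: int, config: SimConfig | None = None
) -> tuple[int, int]:
    """(training windows, training windows re-detected at the threshold)."""
    config = config or SimConfig(
        n_genomes=6,
        n_core_families=10,
        n_variable_families=2,
        n_specific_per_genome=1,
        n_target_families=5,
        seed=seed,
    )
    genomes, truth = simulate(config)
    regions = _model_target_regions(genomes, truth)
    motif = discover_motif(regions, motif_len=config.motif_len)
    threshold = training_threshold(motif)
    hits = scan_regions(regions, motif, threshold)
    found = {(h.target_operon, h.sequence) for h in hits}
    redetected = sum(
        1
        for w in motif.member_windows
        if (w.region_id, w.sequence) in found or (w.region_id, revcomp(w.sequence)) in found
    )
    return len(motif.member_windows), redetected


# ---------------------------------------------------------------------------
# Consistency-filter discrimination
# ---------------------------------------------------------------------------

@dataclass
class FilterTrialResult:
    decoys_total: int
    decoys_removed: int
    true_total: int
    true_retained: int


def consistency_filter_trial(seed: int, config: SimConfig | None = None) -> FilterTrialResult:
    """Scan every genome with the true-site PWM, then apply the filter.

    Decoy sites live in exactly one genome and must all be removed; true
    members are implanted in every genome and must all be retained
    (min_other_genomes=2).  Orthology is taken from the simulator truth so
    the trial isolates the filter itself.
    """
    config = config or SimConfig(seed=seed)
    genomes, truth = simulate(config)
    matrix = truth_motif(truth)
    threshold = min(score_site(matrix.weights, s.sequence) for s in truth.true_sites)
    params = ReconstructionParams()
    context = GenomeContext(genomes, params)
    candidates = {
        g.genome_id: scan_regions(context.regions[g.genome_id], matrix, threshold)
        for g in genomes
    }
    retained = consistency_filter(
        candidates, context, truth_groups(truth), min_other_genomes=2
    )
    retained_set = {
        (genome, m.operon_id) for genome, mm in retained.items() for m in mm
    }
    decoys = {(s.genome_id, s.operon_id) for s in truth.sites_of(is_decoy=True)}
    true_members = {(s.genome_id, s.operon_id) for s in truth.sites_of(is_decoy=False)}
    return FilterTrialResult(
        decoys_total=len(decoys),
        decoys_removed=len(decoys - retained_set),
        true_total=len(true_members),
        true_retained=len(true_members & retained_set),
    )


# ---------------------------------------------------------------------------
# Orthology recovery
# ---------------------------------------------------------------------------

def orthology_recovery_trial(seed: int, divergence: float = 0.10) -> float:
    """Adjusted Rand index between recovered and true ortholog partitions."""
    from sklearn.metrics import adjusted_rand_score

    config = SimConfig(seed=seed, protein_divergence=divergence)
    genomes, truth = simulate(config)
    groups = compute_ortholog_groups(genomes)
    fam_of = {
        (g, l): fam
        for fam, mem in truth.true_ortho_partition.items()
        for g, ll in mem.items()
        for l in ll
    }
    grp_of = {loc: grp.group_id for grp in groups for loc in grp.loci()}
    loci = sorted(fam_of)
    return float(
        adjusted_rand_score([fam_of[x] for x in loci], [grp_of[x] for x in loci])
    )


# ---------------------------------------------------------------------------
# End-to-end propagation
# ---------------------------------------------------------------------------

def propagation_trial(
    seed: int, config: SimConfig | None = None
) -> tuple[float, float]:
    """(member precision, member recall) of propagation against truth."""
    config = config or SimConfig(seed=seed)
    genomes, truth = simulate(config)
    groups = compute_ortholog_groups(genomes)
    model = genomes[0].genome_id
    tf_locus = truth.true_ortho_partition[truth.tf_family][model][0]
    target_loci = [
        truth.true_ortho_partition[fam][model][0] for fam in truth.target_families
    ]
    known_sites = [
        s.sequence
        for s in truth.sites_of(is_decoy=False)
        if s.genome_id == model
    ]
    seed_reg = SeedRegulon(
        tf_name="SimTF",
        model_genome=model,
        tf_locus=tf_locus,
        target_loci=target_loci,
        known_sites=known_sites,
    )
    regulon, report = propagate_regulon(seed_reg, genomes, groups)
    if regulon is None:
        return 0.0, 0.0
    got = regulon.member_set()
    true_members = {(s.genome_id, s.operon_id) for s in truth.sites_of(is_decoy=False)}
    tp = len(got & true_members)
    precision = tp / len(got) if got else 0.0
    recall = tp / len(true_members) if true_members else 0.0
    return precision, recall


# ---------------------------------------------------------------------------
# Subregulon recovery
# ---------------------------------------------------------------------------

def subregulon_recovery_trial(seed: int, config: SimConfig | None = None) -> bool:
    """Does correlation clustering recover the two expression blocks?"""
    config = config or SimConfig(seed=seed)
    _, truth = simulate(config)
    expr = generate_expression(truth, config)
    corr = pearson_matrix(expr)
    part = split_subregulons(corr, r_threshold=0.5)
    true_blocks = truth.true_expr_blocks
    if part.n_clusters != len(set(true_blocks.values())):
        return False
    # partitions must agree up to label names
    mapping: dict[int, int] = {}
    for gene, lab in part.labels.items():
        true_lab = true_blocks[gene]
        if mapping.setdefault(lab, true_lab) != true_lab:
            return False
    return len(set(mapping.values())) == len(mapping)
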