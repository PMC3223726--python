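"""Consistency filtering, propagation, ab initio inference, TF attribution."""

import numpy as np
import pytest

from regulonkit.genome_model import Gene, Genome
from regulonkit.motif_discovery import WeightMatrix
from regulonkit.orthology import OrthoGroup
from regulonkit.regulon_reconstruction import (
    GenomeContext,
    ReconstructionParams,
    Regulon,
    RegulonMember,
    SeedRegulon,
    attribute_tf,
    consistency_filter,
    conservation_matrix,
    infer_novel_regulon,
    propagate_regulon,
)
from regulonkit.site_scan import SiteHit
from regulonkit.validation import (
    consistency_filter_trial,
    propagation_trial,
    truth_groups,
)


def _hit(genome, operon, score=10.0):
    return SiteHit(
        genome_id=genome,
        start=0,
        end=10,
        strand="+",
        sequence="TTGATATCAA",
        score=score,
        target_operon=operon,
    )


class TestConsistencyFilter:
    @pytest.fixture()
    def context(self, small_pangenome):
        genomes, _ = small_pangenome
        return GenomeContext(genomes, ReconstructionParams())

    @pytest.fixture()
    def groups(self, small_pangenome):
        _, truth = small_pangenome
        return truth_groups(truth)

    def _candidates_for_family(self, truth, fam, genomes_subset):
        """Candidate hits for one family's operon in a chosen genome subset."""
        out = {}
        for gid in genomes_subset:
            locus = truth.true_ortho_partition[fam][gid][0]
            out.setdefault(gid, []).append(_hit(gid, f"opn_{locus}"))
        return out

    def test_two_other_genomes_suffice(self, small_pangenome, context, groups):
        _, truth = small_pangenome
        fam = truth.target_families[0]
        candidates = self._candidates_for_family(truth, fam, ["G01", "G02", "G03"])
        retained = consistency_filter(candidates, context, groups, min_other_genomes=2)
        assert sorted(retained) == ["G01", "G02", "G03"]

    def test_one_other_genome_is_not_enough(self, small_pangenome, context, groups):
        _, truth = small_pangenome
        fam = truth.target_families[0]
        candidates = self._candidates_for_family(truth, fam, ["G01", "G02"])
        assert consistency_filter(candidates, context, groups) == {}

    def test_functional_link_rescues_candidate(self, small_pangenome, context, groups):
        _, truth = small_pangenome
        fam = truth.target_families[0]
        locus = truth.true_ortho_partition[fam]["G01"][0]
        candidates = self._candidates_for_family(truth, fam, ["G01"])
        retained = consistency_filter(
            candidates,
            context,
            groups,
            functional_links={("G01", f"opn_{locus}")},
        )
        assert retained["G01"][0].evidence == "functionally_linked"

    def test_filter_never_adds_members(self, small_pangenome, context, groups):
        _, truth = small_pangenome
        fam = truth.target_families[1]
        candidates = self._candidates_for_family(
            truth, fam, ["G01", "G02", "G03", "G04"]
        )
        retained = consistency_filter(candidates, context, groups)
        inputs = {
            (g, h.target_operon) for g, hh in candidates.items() for h in hh
        }
        outputs = {(g, m.operon_id) for g, mm in retained.items() for m in mm}
        assert outputs <= inputs

    def test_monotone_in_min_other_genomes(self, small_pangenome, context, groups):
        _, truth = small_pangenome
        fam = truth.target_families[2]
        candidates = self._candidates_for_family(truth, fam, ["G01", "G02", "G03"])
        loose = consistency_filter(candidates, context, groups, min_other_genomes=2)
        strict = consistency_filter(candidates, context, groups, min_other_genomes=3)
        assert {
            (g, m.operon_id) for g, mm in strict.items() for m in mm
        } <= {(g, m.operon_id) for g, mm in loose.items() for m in mm}

    def test_decoys_removed_and_true_members_kept(self, small_config):
        result = consistency_filter_trial(7, config=small_config)
        assert result.decoys_total > 0
        assert result.decoys_removed == result.decoys_total
        assert result.true_retained == result.true_total


class TestPropagation:
    def test_recovers_implanted_regulon_exactly(self, small_config):
        precision, recall = propagation_trial(7, config=small_config)
        assert precision == 1.0
        assert recall == 1.0

    def test_seed_without_tf_ortholog_is_skipped(self, small_pangenome, small_groups):
        genomes, _ = small_pangenome
        seed = SeedRegulon(
            tf_name="ghost",
            model_genome="G01",
            tf_locus="G01_9999",
            target_loci=[],
            known_sites=[],
        )
        regulon, report = propagate_regulon(seed, genomes, small_groups)
        assert regulon is None
        assert report.skipped
        assert "ghost" in report.reason

    def test_unmutated_implant_yields_conserved_motif(self):
        from regulonkit.synthetic_data import SimConfig
        from regulonkit.validation import propagation_trial as _trial
        from regulonkit import orthology
        from regulonkit.synthetic_data import simulate
        from regulonkit.validation import truth_motif

        config = SimConfig(
            n_genomes=5,
            n_core_families=10,
            n_variable_families=0,
            n_specific_per_genome=0,
            n_target_families=5,
            decoy_site_spec=(2, 1),
            site_mutations_max=0,
            seed=19,
        )
        genomes, truth = simulate(config)
        groups = orthology.compute_ortholog_groups(genomes)
        model = genomes[0].genome_id
        seed = SeedRegulon(
            tf_name="SimTF",
            model_genome=model,
            tf_locus=truth.true_ortho_partition[truth.tf_family][model][0],
            target_loci=[
                truth.true_ortho_partition[f][model][0] for f in truth.target_families
            ],
            known_sites=[
                s.sequence for s in truth.sites_of(is_decoy=False) if s.genome_id == model
            ],
        )
        regulon, _ = propagate_regulon(seed, genomes, groups)
        assert regulon.motif_comparison.consensus_mismatches == 0
        assert regulon.motif_comparison.divergence_class == "conserved"


class TestInferNovel:
    def test_training_family_recovered_from_pooled_upstreams(
        self, small_pangenome
    ):
        genomes, truth = small_pangenome
        training = sorted(
            {(s.genome_id, s.operon_id) for s in truth.sites_of(is_decoy=False)}
        )
        regulon = infer_novel_regulon(
            training, genomes, truth_groups(truth), motif_len=18,
            params=ReconstructionParams(max_ignored=0),
        )
        assert regulon.provenance == "ab_initio"
        assert regulon.confident
        true_members = {(s.genome_id, s.operon_id) for s in truth.sites_of(is_decoy=False)}
        assert regulon.member_set() == true_members
        # self-detection: all site-bearing training operons stay members
        assert len(regulon.member_set()) >= len(training)

    def test_unrelated_training_operons_flagged_not_confident(self, small_pangenome):
        genomes, truth = small_pangenome
        target_ops = {s.operon_id for s in truth.true_sites}
        unrelated = []
        for genome in genomes:
            from regulonkit.genome_model import call_operons

            for op in call_operons(genome):
                if op.operon_id not in target_ops:
                    unrelated.append((genome.genome_id, op.operon_id))
        regulon = infer_novel_regulon(
            unrelated[:12], genomes, truth_groups(truth), motif_len=18
        )
        assert not regulon.confident
        assert regulon.notes


def _attribution_fixture():
    """Three genomes; a target gene and an adjacent TF gene with an
    autoregulatory site in the TF's own upstream region."""
    consensus = "TTGATATCAA"
    genomes = []
    rng = np.random.default_rng(31)
    for gid in ("A", "B", "C"):
        seq = list("".join("ACGT"[i] for i in rng.integers(0, 4, 2400)))
        seq[940:950] = list(consensus)    # site upstream of target [1000, 1300)
        seq[1640:1650] = list(consensus)  # site upstream of tf gene [1700, 2000)
        genomes.append(
            Genome(
                gid,
                "".join(seq),
                [
                    Gene(f"{gid}_t", 1000, 1300, "+", protein="M" + "K" * 40),
                    Gene(f"{gid}_tf", 1700, 2000, "+", protein="M" + "R" * 40, tf_family="SimTF"),
                ],
            )
        )
    groups = [
        OrthoGroup("OG_t", {g.genome_id: [f"{g.genome_id}_t"] for g in genomes}),
        OrthoGroup("OG_tf", {g.genome_id: [f"{g.genome_id}_tf"] for g in genomes}),
    ]
    motif = WeightMatrix.from_sequences([consensus] * 4)
    members = {
        g.genome_id: [RegulonMember(g.genome_id, f"opn_{g.genome_id}_t")]
        for g in genomes
    }
    regulon = Regulon(
        tf_group=None,
        motif=motif,
        members=members,
        threshold=motif.max_score() - 1e-6,
    )
    return genomes, groups, regulon


class TestAttributeTF:
    def test_adjacent_autoregulated_tf_wins(self):
        genomes, groups, regulon = _attribution_fixture()
        (attribution,) = attribute_tf(regulon, genomes, groups)
        assert attribution.group_id == "OG_tf"
        assert {"positional", "autoregulation"} <= set(attribution.evidences)

    def test_no_tf_labels_gives_empty_attribution(self):
        genomes, groups, regulon = _attribution_fixture()
        stripped = [
            Genome(
                g.genome_id,
                g.sequence,
                [
                    Gene(x.locus_tag, x.start, x.end, x.strand, protein=x.protein)
                    for x in g.genes
                ],
            )
            for g in genomes
        ]
        assert attribute_tf(regulon, stripped, groups) == []

    def test_tied_tf_candidates_all_reported(self):
        genomes, groups, regulon = _attribution_fixture()
        # strip autoregulatory evidence by raising the threshold out of reach
        regulon.threshold = regulon.motif.max_score() + 100
        # add a second, distant TF whose presence pattern also matches
        richer = []
        for g in genomes:
            genes = list(g.genes) + [
                Gene(f"{g.genome_id}_tf2", 100, 400, "+", protein="M" + "W" * 40, tf_family="Other")
            ]
            richer.append(Genome(g.genome_id, g.sequence, genes))
        groups2 = groups + [
            OrthoGroup("OG_tf2", {g.genome_id: [f"{g.genome_id}_tf2"] for g in richer})
        ]
        attributions = attribute_tf(regulon, richer, groups2)
        assert {a.group_id for a in attributions} == {"OG_tf", "OG_tf2"}


class TestConservationMatrix:
    def _regulon(self, present):
        return Regulon(
            tf_group="tf",
            motif=None,
            members={g: [RegulonMember(g, f"opn_{g}")] for g in present},
        )

    def test_full_presence_row(self):
        gids = [f"G{i}" for i in range(4)]
        df = conservation_matrix({"RegA": self._regulon(gids)}, gids)
        assert list(df.loc["RegA", gids]) == ["+"] * 4
        assert df.loc["RegA", "n_genomes"] == 4

    def test_partial_presence_row_sum(self):
        gids = [f"G{i}" for i in range(6)]
        df = conservation_matrix({"RegA": self._regulon(gids[:5])}, gids)
        assert df.loc["RegA", "n_genomes"] == 5
        assert df.loc["RegA", gids[5]] == "-"

    def test_empty_regulon_set(self):
        df = conservation_matrix({}, ["G0", "G1"])
        assert len(df.index.drop("n_regulons", errors="ignore")) <= 1
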