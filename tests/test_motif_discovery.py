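"""PWM arithmetic, weak palindromes, and the iterative discovery procedure."""

import itertools
import math

import numpy as np
import pytest

from regulonkit.dnautil import BASES, revcomp
from regulonkit.errors import DiscoveryError, InputError, ParameterError
from regulonkit.motif_discovery import (
    WeightMatrix,
    compare_motifs,
    count_mismatched_pairs,
    discover_motif,
    find_weak_palindromes,
    information_content,
    positional_weights,
    score_site,
    symmetrize,
)

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def counts_matrix(cols: list[dict]) -> np.ndarray:
    """4 x L counts from per-column {base: count} dicts."""
    out = np.zeros((4, len(cols)))
    for j, col in enumerate(cols):
        for base, n in col.items():
            out[BASES.index(base), j] = n
    return out


class TestWeakPalindromes:
    def test_perfect_palindrome_has_zero_mismatched_pairs(self):
        assert count_mismatched_pairs("AAGTACTT") == 0

    def test_single_terminal_mismatch_counted(self):
        # pair (0,7): A vs complement(A)=T mismatches; other 3 pairs match
        assert count_mismatched_pairs("AAGTACTA") == 1

    @pytest.mark.parametrize("m,expected", [(0, 0), (1, 1)])
    def test_selection_respects_tolerance(self, m, expected):
        windows = find_weak_palindromes("AAGTACTA", 8, m)
        assert len(windows) == expected

    def test_window_enumeration_matches_brute_force(self):
        rng = np.random.default_rng(5)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
        L, m = 8, 2
        brute = 0
        for i in range(len(seq) - L + 1):
            w = seq[i : i + L]
            mism = sum(
                1 for j in range(L // 2) if w[j] != COMP[w[L - 1 - j]]
            )
            if mism <= m:
                brute += 1
        assert len(find_weak_palindromes(seq, L, m)) == brute

    def test_windows_with_n_are_skipped(self):
        windows = find_weak_palindromes("AAGTACTTN" + "AAGTACTT", 8, 4)
        assert all("N" not in w.sequence for w in windows)

    def test_short_region_gives_empty_list(self):
        assert find_weak_palindromes("ACGT", 8, 2) == []

    def test_odd_length_rejected(self):
        with pytest.raises(ParameterError):
            find_weak_palindromes("ACGTACGTA", 7, 1)


class TestWeights:
    def test_uniform_column_has_zero_weights(self):
        counts = counts_matrix([{"A": 1, "C": 1, "G": 1, "T": 1}])
        assert np.allclose(positional_weights(counts, 4), 0.0)

    def test_two_site_pure_column(self):
        counts = counts_matrix([{"A": 2}])
        w = positional_weights(counts, 2)
        assert w[0, 0] == pytest.approx(math.log2(2.5), abs=1e-6)

    def test_absent_base_weight(self):
        counts = counts_matrix([{"A": 2, "C": 1, "G": 1}])
        w = positional_weights(counts, 4)
        assert w[BASES.index("T"), 0] == pytest.approx(math.log2((0.5 / 6) / 0.25), abs=1e-6)
        assert w[BASES.index("T"), 0] == pytest.approx(-1.585, abs=1e-3)

    def test_inconsistent_column_sums_rejected(self):
        counts = counts_matrix([{"A": 2}, {"A": 3}])
        with pytest.raises(InputError):
            positional_weights(counts, 2)


class TestScore:
    def test_additivity_on_toy_matrix(self):
        weights = np.array(
            [
                [1.0, -0.5],
                [-1.0, -0.5],
                [-1.0, -0.5],
                [-1.0, 0.5],
            ]
        )
        assert score_site(weights, "AT") == pytest.approx(1.5)

    def test_consensus_maximizes_score_exhaustively(self):
        rng = np.random.default_rng(9)
        raw = rng.integers(0, 10, size=(4, 6)).astype(float)
        counts = raw * 12 / raw.sum(axis=0, keepdims=True)
        wm = WeightMatrix(counts=counts, n_sites=12)
        best = score_site(wm.weights, wm.consensus)
        for combo in itertools.product(BASES, repeat=6):
            assert score_site(wm.weights, "".join(combo)) <= best + 1e-9

    def test_matches_per_position_lookup_on_random_windows(self):
        rng = np.random.default_rng(3)
        counts = counts_matrix(
            [{b: int(n) for b, n in zip(BASES, row)} for row in
             rng.multinomial(20, [0.25] * 4, size=8)]
        )
        wm = WeightMatrix(counts=counts, n_sites=20)
        for _ in range(100):
            window = "".join("ACGT"[i] for i in rng.integers(0, 4, 8))
            manual = sum(
                wm.weights[BASES.index(b), j] for j, b in enumerate(window)
            )
            assert score_site(wm.weights, window) == pytest.approx(manual)

    def test_length_mismatch_rejected(self):
        wm = WeightMatrix(counts=counts_matrix([{"A": 2}, {"C": 2}]), n_sites=2)
        with pytest.raises(InputError):
            score_site(wm.weights, "ACG")


class TestInformationContent:
    def test_uniform_matrix_has_zero_bits(self):
        counts = counts_matrix([{"A": 2, "C": 2, "G": 2, "T": 2}] * 3)
        assert information_content(counts, 8) == pytest.approx(0.0)

    def test_pure_column_approaches_two_bits(self):
        n = 10**6
        counts = counts_matrix([{"A": n}])
        assert information_content(counts, n) == pytest.approx(2.0, abs=1e-3)

    def test_four_site_pure_column_closed_form(self):
        counts = counts_matrix([{"A": 4}])
        expected = 0.75 * math.log2(3) + 3 * (1 / 12) * math.log2(1 / 3)
        assert information_content(counts, 4) == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(0.7925, abs=1e-4)

    def test_ic_equals_frequency_weighted_weight_sum(self):
        rng = np.random.default_rng(17)
        counts = counts_matrix(
            [{b: int(n) for b, n in zip(BASES, row)} for row in
             rng.multinomial(30, [0.25] * 4, size=5)]
        )
        wm = WeightMatrix(counts=counts, n_sites=30)
        freqs = (counts + 0.5) / 32
        assert wm.info_content_bits == pytest.approx(float((freqs * wm.weights).sum()))


class TestSymmetrize:
    def test_symmetric_input_is_fixed_point(self):
        sites = ["TTGATATCAA", "TTGATATCAA", "TAGATATCTA"]
        wm = WeightMatrix.from_sequences(sites)
        sym = symmetrize(wm)
        assert np.allclose(sym.counts, 2 * wm.counts)
        assert sym.consensus == wm.consensus

    def test_scores_become_strand_symmetric(self):
        rng = np.random.default_rng(21)
        sites = ["".join("ACGT"[i] for i in rng.integers(0, 4, 8)) for _ in range(6)]
        sym = symmetrize(WeightMatrix.from_sequences(sites))
        for _ in range(50):
            w = "".join("ACGT"[i] for i in rng.integers(0, 4, 8))
            assert score_site(sym.weights, w) == pytest.approx(
                score_site(sym.weights, revcomp(w)), abs=1e-9
            )

    def test_mirrored_cells_add_up(self):
        counts = counts_matrix([{"A": 4}, {"G": 4}])
        sym = symmetrize(WeightMatrix(counts=counts, n_sites=4))
        a, c, g, t = (BASES.index(b) for b in "ACGT")
        assert sym.counts[a, 0] == 4 and sym.counts[t, 1] == 4
        assert sym.counts[c, 0] == 4 and sym.counts[g, 1] == 4

    def test_odd_length_rejected(self):
        counts = counts_matrix([{"A": 2}, {"C": 2}, {"G": 2}])
        with pytest.raises(ParameterError):
            symmetrize(WeightMatrix(counts=counts, n_sites=2))


CONSENSUS10 = "TTGATATCAA"  # palindromic


def regions_with_implant(rng, n_regions, implant_in=None, length=60):
    regions = []
    offsets = {}
    implant_in = set(range(n_regions)) if implant_in is None else set(implant_in)
    for i in range(n_regions):
        seq = "".join("ACGT"[b] for b in rng.integers(0, 4, length))
        if i in implant_in:
            off = int(rng.integers(0, length - 10))
            seq = seq[:off] + CONSENSUS10 + seq[off + 10 :]
            offsets[f"r{i}"] = off
        regions.append((f"r{i}", seq))
    return regions, offsets


class TestDiscover:
    def test_recovers_exact_implanted_consensus(self):
        rng = np.random.default_rng(11)
        regions, offsets = regions_with_implant(rng, 10)
        wm = discover_motif(regions, motif_len=10, max_ignored=0)
        assert wm.consensus == CONSENSUS10
        assert wm.converged
        assert {(w.region_id, w.offset) for w in wm.member_windows} == set(
            offsets.items()
        )

    def test_background_only_has_lower_information_content(self):
        rng = np.random.default_rng(11)
        implanted, _ = regions_with_implant(rng, 10)
        rng2 = np.random.default_rng(11)
        background = [
            (f"r{i}", "".join("ACGT"[b] for b in rng2.integers(0, 4, 60)))
            for i in range(10)
        ]
        ic_implanted = discover_motif(implanted, motif_len=10, max_ignored=0).info_content_bits
        ic_background = discover_motif(background, motif_len=10, max_ignored=0).info_content_bits
        assert ic_background < ic_implanted

    def test_signal_free_regions_are_the_ones_dropped(self):
        rng = np.random.default_rng(23)
        regions, _ = regions_with_implant(rng, 12, implant_in=range(10))
        wm = discover_motif(regions, motif_len=10, max_ignored=2)
        kept = {w.region_id for w in wm.member_windows}
        assert kept == {f"r{i}" for i in range(10)}

    def test_too_few_regions_rejected(self):
        with pytest.raises(DiscoveryError):
            discover_motif([("r0", "ACGTACGTACGT")], motif_len=10)


class TestCompareMotifs:
    def strong_motif(self, consensus, n=20):
        counts = counts_matrix([{b: n} for b in consensus])
        return WeightMatrix(counts=counts, n_sites=n)

    def test_self_comparison_is_conserved(self):
        wm = self.strong_motif("TTGATATCAA")
        cmp = compare_motifs(wm, wm)
        assert cmp.consensus_mismatches == 0
        assert cmp.divergence_class == "conserved"

    def test_three_conserved_mismatches_is_moderate(self):
        a = self.strong_motif("TTGATATCAA")
        b = self.strong_motif("ATGCTATCAC")  # differs at positions 0, 3, 9
        cmp = compare_motifs(a, b)
        assert cmp.consensus_mismatches == 3
        assert cmp.divergence_class == "moderate"

    def test_low_ic_columns_do_not_count(self):
        strong = counts_matrix([{"T": 20}, {"A": 5, "C": 5, "G": 5, "T": 5}, {"A": 20}])
        a = WeightMatrix(counts=strong, n_sites=20)
        other = counts_matrix([{"T": 20}, {"G": 20}, {"A": 20}])
        b = WeightMatrix(counts=other, n_sites=20)
        cmp = compare_motifs(a, b)
        assert 1 not in cmp.conserved_positions
        assert cmp.consensus_mismatches == 0
        assert cmp.divergence_class == "conserved"

    @pytest.mark.parametrize(
        "mismatches,klass",
        [(0, "conserved"), (1, "slight"), (2, "slight"), (3, "moderate"), (4, "moderate"), (5, "different")],
    )
    def test_divergence_bins(self, mismatches, klass):
        from regulonkit.motif_discovery import MotifComparison

        assert MotifComparison.classify(mismatches) == klass
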