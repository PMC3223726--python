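"""Iterative palindrome-seeded PWM discovery.

The recognition model is a position weight matrix (PWM) over A/C/G/T.  With
observed counts ``c(b, j)`` over ``N`` aligned sites, pseudocounted
frequencies and weights are

    f(b, j) = (c(b, j) + 0.5) / (N + 2)
    w(b, j) = log2( f(b, j) / 0.25 )

i.e. log-odds against a uniform background (the simulator's background is
uniform by design, so these weights are exactly calibrated).  A candidate
site's score is the sum of the positional nucleotide weights of its bases,
and a profile's information content is

    IC = sum_j sum_b f(b, j) * log2( f(b, j) / 0.25 )   [bits]

Discovery proceeds from *weak palindromes*: length-L windows in which at
most ``m`` of the L/2 complementary position pairs (i, L-1-i) mismatch.
Each weak palindrome seeds a profile (the seed plus its nearest neighbour
per region by Hamming distance), which is then refined by a fixed-point
iteration: score every weak palindrome, keep the best window per region,
drop the ``d`` lowest-scoring regions, rebuild the profile; stop when a
previously seen selection recurs.  Among converged profiles the one with
the largest information content is the recognition rule (ties broken by
lexicographically smallest consensus).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .dnautil import BASES, COMP_CODE, decode, encode, revcomp, sliding_windows
from .errors import DiscoveryError, InputError, ParameterError

UNIFORM_BG = 0.25
PSEUDOCOUNT = 0.5


# ---------------------------------------------------------------------------
# Weight matrix
# ---------------------------------------------------------------------------

def positional_weights(counts: np.ndarray, n_sites: int) -> np.ndarray:
    """Log-odds weights (base 2, uniform background) from a 4 x L count matrix."""
    counts = np.asarray(counts, dtype=float)
    if counts.shape[0] != 4 or np.any(counts < 0):
        raise InputError("counts must be a non-negative 4 x L matrix")
    if n_sites <= 0 or not np.allclose(counts.sum(axis=0), n_sites):
        raise InputError("every column of counts must sum to n_sites > 0")
    freqs = (counts + PSEUDOCOUNT) / (n_sites + 4 * PSEUDOCOUNT)
    return np.log2(freqs / UNIFORM_BG)


def information_content(counts: np.ndarray, n_sites: int) -> float:
    """Information content in bits of a pseudocounted count matrix."""
    counts = np.asarray(counts, dtype=float)
    if n_sites <= 0 or not np.allclose(counts.sum(axis=0), n_sites):
        raise InputError("every column of counts must sum to n_sites > 0")
    freqs = (counts + PSEUDOCOUNT) / (n_sites + 4 * PSEUDOCOUNT)
    return float(np.sum(freqs * np.log2(freqs / UNIFORM_BG)))


@dataclass
class PalindromeWindow:
    """One candidate window inside a training region."""

    region_id: str
    offset: int
    sequence: str
    mismatched_pairs: int


@dataclass
class WeightMatrix:
    """PWM counts + log-odds weights + information content."""

    counts: np.ndarray
    n_sites: int
    member_windows: list[PalindromeWindow] = field(default_factory=list)
    converged: bool = True

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.weights = positional_weights(self.counts, self.n_sites)
        self.info_content_bits = information_content(self.counts, self.n_sites)

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        # argmax takes the lowest index on ties -> alphabetical (A<C<G<T)
        return "".join(BASES[i] for i in np.argmax(self.weights, axis=0))

    @property
    def column_ic_bits(self) -> np.ndarray:
        freqs = (self.counts + PSEUDOCOUNT) / (self.n_sites + 4 * PSEUDOCOUNT)
        return np.sum(freqs * np.log2(freqs / UNIFORM_BG), axis=0)

    @property
    def is_palindromic(self) -> bool:
        return bool(np.allclose(self.counts, self.counts[::-1, ::-1]))

    def max_score(self) -> float:
        return float(self.weights.max(axis=0).sum())

    @classmethod
    def from_sequences(cls, sequences: Sequence[str], **kw) -> "WeightMatrix":
        """Build a PWM from equal-length ungapped site sequences."""
        if not sequences:
            raise InputError("cannot build a weight matrix from zero sites")
        mat = np.stack([encode(s) for s in sequences])
        if mat.shape[1] == 0 or np.any(mat == 4):
            raise InputError("sites must be non-empty and N-free")
        counts = np.stack([(mat == b).sum(axis=0) for b in range(4)])
        return cls(counts=counts, n_sites=len(sequences), **kw)


def score_site(weights: np.ndarray, window: str) -> float:
    """Sum of positional nucleotide weights over one length-L window."""
    codes = encode(window)
    if codes.shape[0] != weights.shape[1]:
        raise InputError(
            f"window length {codes.shape[0]} != matrix length {weights.shape[1]}"
        )
    if np.any(codes == 4):
        raise InputError("window contains a non-ACGT base")
    return float(weights[codes, np.arange(weights.shape[1])].sum())


def score_windows(weights: np.ndarray, windows: np.ndarray) -> np.ndarray:
    """Vectorized :func:`score_site` over encoded windows (n x L, codes 0-3)."""
    return weights[windows, np.arange(weights.shape[1])].sum(axis=1)


def symmetrize(matrix: WeightMatrix) -> WeightMatrix:
    """Palindromic averaging: add the reverse-complement-mirrored counts.

    After symmetrization a window and its reverse complement score equally,
    so a palindromic profile can be scanned on one strand only.
    """
    counts = np.asarray(matrix.counts)
    if counts.shape[1] % 2 != 0:
        raise ParameterError("symmetrize requires an even motif length")
    sym = counts + counts[::-1, ::-1]
    return WeightMatrix(
        counts=sym,
        n_sites=2 * matrix.n_sites,
        member_windows=list(matrix.member_windows),
        converged=matrix.converged,
    )


def _symmetrize_counts(counts: np.ndarray) -> np.ndarray:
    return counts + counts[::-1, ::-1]


# ---------------------------------------------------------------------------
# Weak palindromes
# ---------------------------------------------------------------------------

def count_mismatched_pairs(sequence: str) -> int:
    """Number of complementary pairs (i, L-1-i), i < L/2, that mismatch."""
    codes = encode(sequence)
    L = codes.shape[0]
    if L % 2 != 0:
        raise ParameterError("palindrome windows must have even length")
    half = codes[: L // 2]
    other = COMP_CODE[codes[L // 2:][::-1]]
    return int(np.sum(half != other))


def find_weak_palindromes(
    region,
    motif_len: int,
    max_mismatched_pairs: int,
    region_id: Optional[str] = None,
) -> list[PalindromeWindow]:
    """All forward-strand windows with <= m mismatched complementary pairs.

    ``region`` is an :class:`~regulonkit.genome_model.UpstreamRegion` or a
    plain string.  Windows containing N are skipped.  Palindromic windows
    are strand-symmetric, so forward enumeration suffices.  A region shorter
    than the motif yields an empty list.
    """
    if motif_len % 2 != 0:
        raise ParameterError(f"motif_len must be even, got {motif_len}")
    if not 0 <= max_mismatched_pairs <= motif_len // 2:
        raise ParameterError("max_mismatched_pairs must lie in [0, L/2]")
    seq = region if isinstance(region, str) else region.sequence
    if region_id is None:
        region_id = "region" if isinstance(region, str) else region.operon_id
    codes = encode(seq)
    wins = sliding_windows(codes, motif_len)
    if wins.shape[0] == 0:
        return []
    clean = ~np.any(wins == 4, axis=1)
    half = wins[:, : motif_len // 2]
    mirror = COMP_CODE[wins[:, motif_len // 2:][:, ::-1]]
    mism = np.sum(half != mirror, axis=1)
    keep = clean & (mism <= max_mismatched_pairs)
    return [
        PalindromeWindow(
            region_id=region_id,
            offset=int(i),
            sequence=seq[i : i + motif_len].upper(),
            mismatched_pairs=int(mism[i]),
        )
        for i in np.nonzero(keep)[0]
    ]


# ---------------------------------------------------------------------------
# Motif comparison
# ---------------------------------------------------------------------------

@dataclass
class MotifComparison:
    """Divergence of one motif from another at informative columns."""

    conserved_positions: list[int]
    consensus_mismatches: int
    divergence_class: str

    @staticmethod
    def classify(mismatches: int) -> str:
        if mismatches == 0:
            return "conserved"
        if mismatches <= 2:
            return "slight"
        if mismatches <= 4:
            return "moderate"
        return "different"


def compare_motifs(
    motif_a: WeightMatrix,
    motif_b: WeightMatrix,
    ic_threshold_bits: float = 1.0,
) -> MotifComparison:
    """Count consensus mismatches at motif_a's conserved (high-IC) columns.

    Unequal lengths are aligned by the best ungapped offset of the consensi
    (maximal matches over the overlap).  Divergence classes follow the bins
    0 / 1-2 / 3-4 / >=5 mismatches.
    """
    if motif_a.n_sites == 0 and motif_b.n_sites == 0:
        raise InputError("cannot compare two empty motifs")
    cons_a, cons_b = motif_a.consensus, motif_b.consensus
    col_ic = motif_a.column_ic_bits
    offset_b = 0
    if len(cons_a) != len(cons_b):
        best = (-1, 0)
        span = range(-(len(cons_b) - 1), len(cons_a))
        for off in span:
            matches = sum(
                1
                for j in range(len(cons_a))
                if 0 <= j - off < len(cons_b) and cons_a[j] == cons_b[j - off]
            )
            if matches > best[0]:
                best = (matches, off)
        offset_b = best[1]
    conserved = [int(j) for j in np.nonzero(col_ic >= ic_threshold_bits)[0]]
    mismatches = sum(
        1
        for j in conserved
        if not (0 <= j - offset_b < len(cons_b)) or cons_a[j] != cons_b[j - offset_b]
    )
    return MotifComparison(
        conserved_positions=conserved,
        consensus_mismatches=mismatches,
        divergence_class=MotifComparison.classify(mismatches),
    )


# ---------------------------------------------------------------------------
# Iterative discovery
# ---------------------------------------------------------------------------

def default_max_mismatched_pairs(motif_len: int) -> int:
    return math.ceil(motif_len / 4)


def discover_motif(
    regions: Iterable,
    motif_len: int,
    max_mismatched_pairs: Optional[int] = None,
    max_ignored: Optional[int] = None,
    max_iter: int = 50,
    symmetric: bool = True,
    max_seeds: Optional[int] = 500,
) -> WeightMatrix:
    """Run the iterative palindrome procedure over training regions.

    Parameters
    ----------
    regions:
        Upstream regions (or (region_id, sequence) pairs / plain strings).
    motif_len:
        Even motif width L (no automatic width search).
    max_mismatched_pairs:
        Weak-palindrome tolerance m; default ceil(L/4).
    max_ignored:
        Number d of lowest-scoring regions dropped each iteration, housing
        the "allow a few sequences to be ignored" behaviour; default n // 5.
    symmetric:
        Symmetrize profiles during iteration and in the result (palindromic
        runs); the returned matrix then scores both strands identically.
    max_seeds:
        Cap on the number of seed palindromes tried; candidates are ordered
        by palindromicity (fewest mismatched pairs first, then region order
        and offset) so the strongest palindromes always seed and the search
        stays deterministic and tractable on large pooled training sets.

    Returns the converged profile with the largest information content
    (ties -> lexicographically smallest consensus).  If an individual seed
    fails to converge within ``max_iter`` its last profile competes with
    ``converged=False``.
    """
    if max_mismatched_pairs is None:
        max_mismatched_pairs = default_max_mismatched_pairs(motif_len)

    windows: list[PalindromeWindow] = []
    region_ids: list[str] = []
    for item in regions:
        if isinstance(item, tuple):
            rid, seq = item
        elif isinstance(item, str):
            rid, seq = f"region_{len(region_ids)}", item
        else:
            rid, seq = item.operon_id, item.sequence
        region_ids.append(rid)
        windows.extend(
            find_weak_palindromes(seq, motif_len, max_mismatched_pairs, region_id=rid)
        )

    regions_with_windows = {w.region_id for w in windows}
    if len(regions_with_windows) < 3:
        raise DiscoveryError(
            f"need weak palindromes in >= 3 regions, found {len(regions_with_windows)}"
        )
    n_regions = len(regions_with_windows)
    if max_ignored is None:
        max_ignored = n_regions // 5
    if not 0 <= max_ignored <= n_regions - 3:
        max_ignored = max(0, min(max_ignored, n_regions - 3))

    # stable region indexing in input order; windows arrive region-by-region,
    # so win_region is non-decreasing and reduceat segments the score vector
    ordered_regions = [r for r in region_ids if r in regions_with_windows]
    region_index = {r: i for i, r in enumerate(ordered_regions)}
    win_region = np.array([region_index[w.region_id] for w in windows])
    order = np.argsort(win_region, kind="stable")
    windows = [windows[i] for i in order]
    win_region = win_region[order]
    enc = np.stack([encode(w.sequence) for w in windows])
    n_win = enc.shape[0]
    region_starts = np.searchsorted(win_region, np.arange(n_regions))
    region_members = [np.nonzero(win_region == i)[0] for i in range(n_regions)]
    win_arange = np.arange(n_win)

    def _profile_from(sel: np.ndarray) -> tuple[np.ndarray, int]:
        sub = enc[sel]
        counts = np.stack([(sub == b).sum(axis=0) for b in range(4)])
        n = sub.shape[0]
        if symmetric:
            return _symmetrize_counts(counts), 2 * n
        return counts, n

    def _select(weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Best window per region (first occurrence wins ties) and its score."""
        scores = score_windows(weights, enc)
        best_score = np.maximum.reduceat(scores, region_starts)
        is_best = scores == best_score[win_region]
        best_idx = np.minimum.reduceat(np.where(is_best, win_arange, n_win), region_starts)
        return best_idx, best_score

    def _iterate(initial_sel: np.ndarray) -> tuple[frozenset, bool]:
        """Fixed-point iteration from an initial window selection.

        Any selection ever visited is remembered with the attractor it led
        to, so later seeds stop the moment they enter known territory.
        """
        trajectory: list[frozenset] = []
        seen: set[frozenset] = set()
        sel_key = frozenset(int(i) for i in initial_sel)
        sel = initial_sel
        converged = False
        for _ in range(max_iter):
            if sel_key in memo_path:
                final_key, converged = memo_path[sel_key]
                break
            if sel_key in seen:
                final_key, converged = sel_key, True
                break
            trajectory.append(sel_key)
            seen.add(sel_key)
            counts, n = _profile_from(sel)
            weights = positional_weights(counts, n)
            best_idx, best_score = _select(weights)
            if max_ignored > 0:
                keep = np.sort(np.argsort(best_score, kind="stable")[max_ignored:])
            else:
                keep = np.arange(n_regions)
            sel = best_idx[keep]
            new_key = frozenset(int(i) for i in sel)
            if new_key == sel_key:
                final_key, converged = sel_key, True
                break
            sel_key = new_key
        else:
            final_key = sel_key
        for key in trajectory:
            memo_path[key] = (final_key, converged)
        return final_key, converged

    # candidate seeds: strongest palindromes first (fewest mismatched pairs,
    # then region order and offset), optionally capped; deterministic
    mism = np.array([w.mismatched_pairs for w in windows])
    seed_indices = np.argsort(mism, kind="stable")
    if max_seeds is not None and n_win > max_seeds:
        seed_indices = seed_indices[:max_seeds]

    memo_path: dict[frozenset, tuple[frozenset, bool]] = {}
    memo_final: dict[frozenset, tuple[float, str, np.ndarray, int, bool]] = {}
    best_key: Optional[frozenset] = None

    for s in seed_indices:
        # initial selection: the seed plus its nearest weak palindrome
        # (Hamming distance, ties -> region order then offset) in every
        # other region
        dists = np.sum(enc != enc[s], axis=1)
        best_dist = np.minimum.reduceat(dists, region_starts)
        is_near = dists == best_dist[win_region]
        init = np.minimum.reduceat(np.where(is_near, win_arange, n_win), region_starts)
        init[win_region[s]] = s
        final_key, converged = _iterate(init)
        if final_key not in memo_final:
            sel = np.array(sorted(final_key))
            counts, n = _profile_from(sel)
            ic = information_content(counts, n)
            consensus = decode(np.argmax(positional_weights(counts, n), axis=0))
            memo_final[final_key] = (ic, consensus, counts, n, converged)
        ic, consensus, _, _, _ = memo_final[final_key]
        if best_key is None or (ic, _neg_lex(consensus)) > (
            memo_final[best_key][0],
            _neg_lex(memo_final[best_key][1]),
        ):
            best_key = final_key

    assert best_key is not None
    ic, consensus, counts, n, converged = memo_final[best_key]
    members = [windows[i] for i in sorted(best_key)]
    return WeightMatrix(
        counts=counts, n_sites=n, member_windows=members, converged=converged
    )


class _neg_lex(str):
    """Ordering helper: larger is lexicographically *smaller* consensus."""

    def __lt__(self, other) -> bool:  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other) -> bool:  # type: ignore[override]
        return str.__lt__(self, other)
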