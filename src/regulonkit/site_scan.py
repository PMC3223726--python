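"""PWM scanning of genomes and upstream regions.

The scan threshold follows the training-set-minimum rule: the threshold is
the lowest score observed among the training windows, compared with ``>=``,
so every training site is re-detected by construction.  For palindromic
(symmetric) profiles a window and its reverse complement score identically
and are reported once, on the forward strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .dnautil import encode, revcomp, sliding_windows
from .errors import InputError
from .genome_model import Genome, Operon, UpstreamRegion
from .motif_discovery import PalindromeWindow, WeightMatrix, score_windows


@dataclass
class SiteHit:
    """One scored candidate binding site."""

    genome_id: str
    start: int
    end: int
    strand: str
    sequence: str
    score: float
    target_operon: Optional[str] = None
    location: str = "unassigned"  # upstream / intergenic / intragenic
    in_training_set: bool = False

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def training_threshold(matrix: WeightMatrix, training_windows: Optional[Sequence] = None) -> float:
    """Lowest score observed in the training set.

    ``training_windows`` defaults to the matrix's own member windows; items
    may be :class:`PalindromeWindow` or plain strings.
    """
    if training_windows is None:
        training_windows = matrix.member_windows
    seqs = [
        w.sequence if isinstance(w, PalindromeWindow) else str(w)
        for w in training_windows
    ]
    if not seqs:
        raise InputError("training set is empty")
    enc = np.stack([encode(s) for s in seqs])
    if np.any(enc == 4):
        raise InputError("training windows must be N-free")
    return float(score_windows(matrix.weights, enc).min())


def _scan_codes(
    codes: np.ndarray, matrix: WeightMatrix, threshold: float, both_strands: bool
) -> list[tuple[int, str, float]]:
    """(offset, strand, score) of every passing window in an encoded sequence."""
    L = matrix.length
    wins = sliding_windows(codes, L)
    if wins.shape[0] == 0:
        return []
    clean = ~np.any(wins == 4, axis=1)
    safe = np.where(wins == 4, 0, wins)
    fwd = score_windows(matrix.weights, safe)
    hits: list[tuple[int, str, float]] = []
    passing = clean & (fwd >= threshold)
    for i in np.nonzero(passing)[0]:
        hits.append((int(i), "+", float(fwd[i])))
    if both_strands and not matrix.is_palindromic:
        # score the reverse complement of each window with the same matrix
        rc_weights = matrix.weights[::-1, ::-1]
        rev = score_windows(rc_weights, safe)
        passing = clean & (rev >= threshold)
        for i in np.nonzero(passing)[0]:
            hits.append((int(i), "-", float(rev[i])))
    return hits


def scan_genome(
    genome: Genome,
    matrix: WeightMatrix,
    threshold: float,
    both_strands: bool = True,
) -> list[SiteHit]:
    """Report every genomic window scoring >= threshold, sorted by position."""
    if not np.isfinite(threshold):
        raise InputError("scan threshold must be finite")
    codes = encode(genome.sequence)
    hits = []
    for off, strand, score in _scan_codes(codes, matrix, threshold, both_strands):
        seq = genome.sequence[off : off + matrix.length]
        hits.append(
            SiteHit(
                genome_id=genome.genome_id,
                start=off,
                end=off + matrix.length,
                strand=strand,
                sequence=seq if strand == "+" else revcomp(seq),
                score=score,
            )
        )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def scan_regions(
    regions: Iterable[UpstreamRegion],
    matrix: WeightMatrix,
    threshold: float,
    both_strands: bool = True,
) -> list[SiteHit]:
    """Scan upstream regions; hit coordinates are mapped back to the genome.

    The target operon of each hit is the operon whose upstream region it was
    found in.  Hits are sorted by (genome, position).
    """
    if not np.isfinite(threshold):
        raise InputError("scan threshold must be finite")
    hits: list[SiteHit] = []
    for region in regions:
        if region.is_empty:
            continue
        codes = encode(region.sequence)
        for off, strand, score in _scan_codes(codes, matrix, threshold, both_strands):
            gstart, gend = region.genomic_interval(off, matrix.length)
            hit_strand = strand if region.strand == "+" else ("-" if strand == "+" else "+")
            hits.append(
                SiteHit(
                    genome_id=region.genome_id,
                    start=gstart,
                    end=gend,
                    strand=hit_strand if not matrix.is_palindromic else "+",
                    sequence=region.sequence[off : off + matrix.length],
                    score=score,
                    target_operon=region.operon_id,
                    location="upstream",
                )
            )
    hits.sort(key=lambda h: (h.genome_id, h.start, h.target_operon or ""))
    return hits


def assign_targets(
    hits: Iterable[SiteHit],
    operons: Sequence[Operon],
    regions: Sequence[UpstreamRegion],
    upstream_only: bool = True,
) -> list[SiteHit]:
    """Assign genome-wide hits to the operons whose upstream regions hold them.

    A hit fully inside an upstream region is attributed to that operon; a hit
    inside a divergent intergenic region shared by two operons yields one
    record per operon.  Outside any upstream region a hit is dropped in
    upstream-only mode, otherwise flagged intergenic or intragenic.
    """
    from dataclasses import replace

    region_by_genome: dict[str, list[UpstreamRegion]] = {}
    for r in regions:
        region_by_genome.setdefault(r.genome_id, []).append(r)

    out: list[SiteHit] = []
    for hit in hits:
        containers = [
            r
            for r in region_by_genome.get(hit.genome_id, [])
            if r.start <= hit.start and hit.end <= r.end
        ]
        if containers:
            for r in containers:
                out.append(replace(hit, target_operon=r.operon_id, location="upstream"))
        elif not upstream_only:
            intragenic = any(
                op.start <= hit.start < op.end or op.start < hit.end <= op.end
                for op in operons
            )
            out.append(
                replace(
                    hit,
                    target_operon=None,
                    location="intragenic" if intragenic else "intergenic",
                )
            )
    out.sort(key=lambda h: (h.genome_id, h.start, h.target_operon or ""))
    return out


def hits_to_bed(hits: Iterable[SiteHit]) -> str:
    """Render hits as BED6 plus target-operon and sequence columns."""
    lines = []
    for h in hits:
        name = h.target_operon or "."
        lines.append(
            "\t".join(
                [
                    h.genome_id,
                    str(h.start),
                    str(h.end),
                    name,
                    f"{h.score:.4f}",
                    h.strand,
                    h.sequence,
                ]
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")
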