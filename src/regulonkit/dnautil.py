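"""Small DNA helpers shared by the motif and simulator modules.

The alphabet is A/C/G/T with N allowed in genomic sequence; every window-level
operation (palindrome detection, PWM scoring) skips windows containing N.
Encoding maps A,C,G,T -> 0,1,2,3 and N (or anything else) -> 4.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

# byte -> code lookup; 4 marks "not a concrete base"
_ENC = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i

# code -> complementary code (A<->T, C<->G); N stays N
COMP_CODE = np.array([3, 2, 1, 0, 4], dtype=np.int8)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-preserving)."""
    return seq.translate(_TRANS)[::-1]


_TRANS = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as int8 codes (A=0, C=1, G=2, T=3, other=4)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode` for concrete bases."""
    return "".join("ACGTN"[c] for c in codes)


def sliding_windows(codes: np.ndarray, length: int) -> np.ndarray:
    """View of all length-`length` windows of an encoded sequence.

    Returns an array of shape (n_windows, length); empty if the sequence is
    shorter than `length`.
    """
    if codes.shape[0] < length:
        return np.empty((0, length), dtype=codes.dtype)
    return np.lib.stride_tricks.sliding_window_view(codes, length)
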