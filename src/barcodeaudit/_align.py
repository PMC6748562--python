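"""Low-level overlap (end-gap free) alignment kernel.

Sequences are encoded as 4-bit IUPAC presence masks so that an ambiguity
code matches another code exactly when their base sets intersect.  The
kernel fills a semi-global dynamic-programming matrix (match +1,
mismatch -1, linear gap -2, terminal gaps free on both sequences) while
propagating, along the locally chosen optimal move, the number of matched
columns and the total number of aligned columns.  Terminal-gap columns are
never counted.  Ties between moves are broken diagonal > up > left so the
reported (matches, columns) pair is deterministic.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["encode", "overlap_align", "AlphabetError"]


class AlphabetError(ValueError):
    """A sequence contains a character outside the IUPAC nucleotide codes."""


_BITS = {
    "A": 0b0001,
    "C": 0b0010,
    "G": 0b0100,
    "T": 0b1000,
    "R": 0b0101,  # A/G
    "Y": 0b1010,  # C/T
    "S": 0b0110,  # G/C
    "W": 0b1001,  # A/T
    "K": 0b1100,  # G/T
    "M": 0b0011,  # A/C
    "B": 0b1110,  # C/G/T
    "D": 0b1101,  # A/G/T
    "H": 0b1011,  # A/C/T
    "V": 0b0111,  # A/C/G
    "N": 0b1111,
}

_MASK_TABLE = np.zeros(256, dtype=np.uint8)
for _ch, _bits in _BITS.items():
    _MASK_TABLE[ord(_ch)] = _bits
    _MASK_TABLE[ord(_ch.lower())] = _bits

IUPAC_CHARS = frozenset(_BITS) | frozenset(c.lower() for c in _BITS)


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as IUPAC bitmasks, dropping gap characters.

    Raises :class:`AlphabetError` on any character that is neither an
    IUPAC nucleotide code nor a gap (``-``).
    """
    raw = np.frombuffer(seq.replace("-", "").encode("ascii", "replace"), dtype=np.uint8)
    masks = _MASK_TABLE[raw]
    if masks.size and (masks == 0).any():
        bad = sorted({seq[i] for i in range(len(seq)) if seq[i] != "-" and seq[i] not in IUPAC_CHARS})
        raise AlphabetError(f"non-IUPAC characters in sequence: {bad!r}")
    if masks.size == 0:
        raise AlphabetError("empty sequence (no non-gap characters)")
    return masks


@njit(cache=True)
def overlap_align(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int]:  # pragma: no cover - numba
    """Return (matches, aligned_columns, score) of the best overlap alignment."""
    la = a.size
    lb = b.size
    h_prev = np.zeros(lb + 1, dtype=np.int64)
    m_prev = np.zeros(lb + 1, dtype=np.int64)
    c_prev = np.zeros(lb + 1, dtype=np.int64)
    h_cur = np.zeros(lb + 1, dtype=np.int64)
    m_cur = np.zeros(lb + 1, dtype=np.int64)
    c_cur = np.zeros(lb + 1, dtype=np.int64)
    best_h = np.int64(0)
    best_m = np.int64(0)
    best_c = np.int64(0)
    for i in range(1, la + 1):
        ai = a[i - 1]
        h_cur[0] = 0
        m_cur[0] = 0
        c_cur[0] = 0
        for j in range(1, lb + 1):
            is_match = 1 if (ai & b[j - 1]) != 0 else 0
            diag = h_prev[j - 1] + (1 if is_match else -1)
            up = h_prev[j] - 2
            left = h_cur[j - 1] - 2
            if diag >= up and diag >= left:
                h_cur[j] = diag
                m_cur[j] = m_prev[j - 1] + is_match
                c_cur[j] = c_prev[j - 1] + 1
            elif up >= left:
                h_cur[j] = up
                m_cur[j] = m_prev[j]
                c_cur[j] = c_prev[j] + 1
            else:
                h_cur[j] = left
                m_cur[j] = m_cur[j - 1]
                c_cur[j] = c_cur[j - 1] + 1
        # candidate alignment end on the last column (free trailing gap in b)
        if h_cur[lb] > best_h:
            best_h = h_cur[lb]
            best_m = m_cur[lb]
            best_c = c_cur[lb]
        h_prev, h_cur = h_cur, h_prev
        m_prev, m_cur = m_cur, m_prev
        c_prev, c_cur = c_cur, c_prev
    # candidate ends on the last row (free trailing gap in a)
    for j in range(lb + 1):
        if h_prev[j] > best_h:
            best_h = h_prev[j]
            best_m = m_prev[j]
            best_c = c_prev[j]
    return int(best_m), int(best_c), int(best_h)
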