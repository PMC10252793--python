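"""Position-incidence descriptors and the 2-D sequence matrix.

A validated protein sequence ``Z1...Zn`` is converted deterministically into:

* a square **sequence matrix** — residues coded 1..20 laid out row-major into
  an m×m grid with m = ceil(sqrt(n)), zero-padded at the tail;
* the **position-relative incidence matrix** (PRIM) — a 20×20 matrix whose
  entry (a, b) accumulates the 1-based positions of residue ``b`` relative to
  the first occurrence of residue ``a``;
* the **accumulative absolute position incidence vector** (AAPIV) — per
  residue, the sum of its 1-based occurrence positions;
* the **frequency distribution vector** (FDV) — per-residue occurrence
  counts;

plus reversed-order variants of PRIM and AAPIV computed on the reversed
sequence, which capture positional bias from the C-terminal end.

All encoders are pure functions of the sequence string.  Positions are
1-based here; matrix indices in the moments module are 0-based.
"""

from __future__ import annotations

import math

import numpy as np

from .seqio import ALPHABET, ALPHABET_SET, ProteinRecord

#: Fixed residue → integer code, A=1 .. Y=20 (alphabetical).  Serialized with
#: any trained model via the feature version tag.
RESIDUE_INDEX = {aa: i + 1 for i, aa in enumerate(ALPHABET)}

_N_RESIDUES = len(ALPHABET)


def _sequence_of(rec) -> str:
    seq = rec.sequence if isinstance(rec, ProteinRecord) else str(rec)
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - ALPHABET_SET
    if bad:
        raise ValueError(f"nonstandard letters in sequence: {sorted(bad)}")
    return seq


def encode_residues(rec) -> np.ndarray:
    """Integer codes (1..20) of a sequence, in order."""
    seq = _sequence_of(rec)
    return np.array([RESIDUE_INDEX[c] for c in seq], dtype=np.int64)


def build_sequence_matrix(rec) -> np.ndarray:
    """Row-major m×m embedding of the coded sequence, m = ceil(sqrt(n)).

    The first n cells (row-major) hold the residue codes; the remaining
    m²−n cells are 0 (padding, distinct from every residue code).
    """
    codes = encode_residues(rec)
    n = codes.size
    m = math.isqrt(n)
    if m * m < n:
        m += 1
    out = np.zeros(m * m, dtype=np.int64)
    out[:n] = codes
    return out.reshape(m, m)


def compute_fdv(rec) -> np.ndarray:
    """Frequency distribution vector: occurrence count per residue (length 20)."""
    codes = encode_residues(rec)
    return np.bincount(codes - 1, minlength=_N_RESIDUES).astype(np.int64)


def compute_aapiv(rec) -> np.ndarray:
    """Accumulative absolute position incidence vector.

    Entry ``a`` is the sum of the 1-based positions at which residue ``a``
    occurs (0 for absent residues).  Its total is always n(n+1)/2.
    """
    codes = encode_residues(rec)
    positions = np.arange(1, codes.size + 1, dtype=np.int64)
    return np.bincount(codes - 1, weights=positions, minlength=_N_RESIDUES).astype(
        np.int64
    )


def compute_raapiv(rec) -> np.ndarray:
    """AAPIV of the reversed sequence."""
    return compute_aapiv(_sequence_of(rec)[::-1])


def compute_prim(rec) -> np.ndarray:
    """Position-relative incidence matrix (20×20).

    PRIM[a, b] = Σ over every position p where residue b occurs of
    (p − firstpos(a)), for every residue a present in the sequence; rows for
    absent residues are all zero.  Entries may be negative (occurrences of b
    upstream of a's first occurrence contribute negatively).

    Closed form used here: PRIM[a, b] = AAPIV[b] − FDV[b] · firstpos(a).
    """
    seq = _sequence_of(rec)
    codes = np.array([RESIDUE_INDEX[c] for c in seq], dtype=np.int64)
    aapiv = compute_aapiv(seq)
    fdv = compute_fdv(seq)
    prim = np.zeros((_N_RESIDUES, _N_RESIDUES), dtype=np.int64)
    for a in range(_N_RESIDUES):
        occ = np.nonzero(codes == a + 1)[0]
        if occ.size == 0:
            continue
        first = int(occ[0]) + 1  # 1-based
        prim[a, :] = aapiv - fdv * first
    return prim


def compute_rprim(rec) -> np.ndarray:
    """PRIM of the reversed sequence (20×20)."""
    return compute_prim(_sequence_of(rec)[::-1])
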