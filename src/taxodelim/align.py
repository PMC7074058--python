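"""Local alignment primitives shared by the ANIb and POCP searches.

The core is a single affine-gap Smith–Waterman kernel (numba-compiled) that
works on integer-encoded sequences and an arbitrary substitution matrix, so
the same code path scores nucleotide fragments (match/mismatch matrix) and
proteins (BLOSUM62).  The kernel supports an optional diagonal band, which
the seeded heuristic uses to align a query against a small subject window
around a k-mer seed; with the band disabled it is an exhaustive quadratic
DP over the full rectangle.

Gap convention: the first gapped column of a run costs ``gap_first`` and
every further column ``gap_extend`` (both positive penalties here), i.e.
a gap of length L scores ``-(gap_first + (L-1)*gap_extend)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "encode_dna",
    "encode_protein",
    "revcomp",
    "nt_substitution_matrix",
    "blosum62_matrix",
    "LocalHit",
    "smith_waterman",
    "KmerIndex",
]

# ---------------------------------------------------------------------------
# encodings

_DNA_CODE = np.full(256, 4, dtype=np.uint8)  # 4 = unknown/ambiguous
for i, b in enumerate("ACGT"):
    _DNA_CODE[ord(b)] = i
    _DNA_CODE[ord(b.lower())] = i

_PROT_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
_PROT_CODE = np.full(256, _PROT_ALPHABET.index("X"), dtype=np.uint8)
for i, a in enumerate(_PROT_ALPHABET):
    _PROT_CODE[ord(a)] = i
    _PROT_CODE[ord(a.lower())] = i

_RC = str.maketrans("ACGTacgtRYKMBVDHrykmbvdh", "TGCAtgcaYRMKVBHDyrmkvbhd")


def encode_dna(seq: str) -> np.ndarray:
    """A,C,G,T -> 0..3; anything else -> 4 (never matches)."""
    return _DNA_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def encode_protein(seq: str) -> np.ndarray:
    return _PROT_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def nt_substitution_matrix(match: float = 1.0, mismatch: float = -3.0) -> np.ndarray:
    """5x5 nucleotide scoring matrix; code 4 (ambiguous) always mismatches."""
    m = np.full((5, 5), mismatch, dtype=np.float64)
    for i in range(4):
        m[i, i] = match
    return m


_BLOSUM62 = None


def blosum62_matrix() -> np.ndarray:
    """BLOSUM62 as a dense array over the 24-letter protein alphabet."""
    global _BLOSUM62
    if _BLOSUM62 is None:
        from Bio.Align import substitution_matrices

        bl = substitution_matrices.load("BLOSUM62")
        n = len(_PROT_ALPHABET)
        m = np.zeros((n, n), dtype=np.float64)
        for i, a in enumerate(_PROT_ALPHABET):
            for j, b in enumerate(_PROT_ALPHABET):
                m[i, j] = bl[a][b]
        _BLOSUM62 = m
    return _BLOSUM62


# ---------------------------------------------------------------------------
# Smith-Waterman kernel


@njit(cache=True)
def _sw_kernel(q, s, smat, gap_first, gap_extend, lo, hi):  # pragma: no cover
    """Banded affine local alignment with traceback statistics.

    Cells (i, j) with j - i outside [lo, hi] are skipped; passing
    lo = -len(q), hi = len(s) disables the band (full DP).
    Returns (score, q_start, q_end, s_start, s_end, matches, columns).
    Coordinates are 0-based half-open on the un-gapped sequences; ``columns``
    counts all alignment columns including gap columns.
    """
    m = q.shape[0]
    n = s.shape[0]
    NEG = -1e18
    H = np.zeros((m + 1, n + 1))
    E = np.full((m + 1, n + 1), NEG)
    F = np.full((m + 1, n + 1), NEG)
    # pointers: pH 0=stop 1=diag 2=from E 3=from F; pE/pF 1 = opened from H
    pH = np.zeros((m + 1, n + 1), dtype=np.uint8)
    pE = np.zeros((m + 1, n + 1), dtype=np.uint8)
    pF = np.zeros((m + 1, n + 1), dtype=np.uint8)
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        j0 = i + lo
        if j0 < 1:
            j0 = 1
        j1 = i + hi
        if j1 > n:
            j1 = n
        for j in range(j0, j1 + 1):
            eo = H[i, j - 1] - gap_first
            ee = E[i, j - 1] - gap_extend
            if eo >= ee:
                E[i, j] = eo
                pE[i, j] = 1
            else:
                E[i, j] = ee
                pE[i, j] = 0
            fo = H[i - 1, j] - gap_first
            fe = F[i - 1, j] - gap_extend
            if fo >= fe:
                F[i, j] = fo
                pF[i, j] = 1
            else:
                F[i, j] = fe
                pF[i, j] = 0
            d = H[i - 1, j - 1] + smat[q[i - 1], s[j - 1]]
            h = 0.0
            p = 0
            if d > h:
                h = d
                p = 1
            if E[i, j] > h:
                h = E[i, j]
                p = 2
            if F[i, j] > h:
                h = F[i, j]
                p = 3
            H[i, j] = h
            pH[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    # traceback
    matches = 0
    columns = 0
    i = bi
    j = bj
    state = 0  # 0 = H, 1 = E, 2 = F
    while True:
        if state == 0:
            p = pH[i, j]
            if p == 0:
                break
            if p == 1:
                if q[i - 1] == s[j - 1] and q[i - 1] < smat.shape[0]:
                    matches += 1
                columns += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            op = pE[i, j]
            columns += 1
            j -= 1
            if op == 1:
                state = 0
        else:
            op = pF[i, j]
            columns += 1
            i -= 1
            if op == 1:
                state = 0
    return best, i, bi, j, bj, matches, columns


@dataclass(frozen=True)
class LocalHit:
    """Best local alignment of a query against a subject (one strand)."""

    score: float
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    matches: int
    columns: int

    @property
    def identity(self) -> float:
        """Identities / alignment columns (gap columns included)."""
        return self.matches / self.columns if self.columns else 0.0

    @property
    def q_span(self) -> int:
        return self.q_end - self.q_start


def smith_waterman(
    q: np.ndarray,
    s: np.ndarray,
    smat: np.ndarray,
    gap_first: float,
    gap_extend: float,
    band: tuple[int, int] | None = None,
) -> LocalHit:
    """Affine-gap local alignment of encoded sequences.

    ``band=(lo, hi)`` restricts cells to lo <= j - i <= hi (both 0-based,
    measured on the DP matrix diagonals); ``None`` runs the full DP.
    """
    if band is None:
        lo, hi = -int(q.shape[0]), int(s.shape[0])
    else:
        lo, hi = int(band[0]), int(band[1])
    score, qs, qe, ss, se, matches, cols = _sw_kernel(
        q, s, smat, float(gap_first), float(gap_extend), lo, hi
    )
    return LocalHit(float(score), int(qs), int(qe), int(ss), int(se), int(matches), int(cols))


# ---------------------------------------------------------------------------
# exact k-mer seeding


class KmerIndex:
    """Exact k-mer index of one subject sequence (one strand).

    Maps every k-mer (as bytes) to its start offsets.  K-mers containing
    non-ACGT characters are skipped for nucleotide data; protein callers
    index the raw bytes directly.
    """

    def __init__(self, seq: str, k: int, nucleotide: bool = True) -> None:
        self.k = int(k)
        self.n = len(seq)
        data = seq.upper().encode("ascii")
        index: dict[bytes, list[int]] = {}
        valid = frozenset(b"ACGT")
        for i in range(len(data) - self.k + 1):
            kmer = data[i : i + self.k]
            if nucleotide and not valid.issuperset(kmer):
                continue
            index.setdefault(kmer, []).append(i)
        self._index = index

    def seed_diagonals(self, query: str, max_candidates: int) -> list[int]:
        """Diagonals (subject_offset - query_offset) ranked by seed count.

        Ties rank by smaller diagonal so candidate order is deterministic.
        """
        data = query.upper().encode("ascii")
        counts: dict[int, int] = {}
        k = self.k
        idx = self._index
        for qpos in range(len(data) - k + 1):
            hits = idx.get(data[qpos : qpos + k])
            if hits:
                for spos in hits:
                    diag = spos - qpos
                    counts[diag] = counts.get(diag, 0) + 1
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        return [d for d, _ in ranked[:max_candidates]]
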