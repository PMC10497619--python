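"""Smith-Waterman local alignment kernel with affine gaps (numba-accelerated).

The kernel aligns an encoded read against an encoded reference and returns
the best local alignment together with traceback-derived statistics:
mismatches, gap columns (total inserted + deleted bases, BLAST tabular
"gaps" semantics) and the reference span covered by the alignment.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# base encoding: A=0 C=1 G=2 T=3, anything else = 4 (never matches)
_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as int8 codes for the alignment kernel."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@njit(cache=True)
def sw_align(q, r, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    """Affine-gap local alignment of query ``q`` against reference ``r``.

    Penalties are non-negative magnitudes; a gap of length L costs
    ``gap_open + L * gap_extend`` (BLAST-style existence + per-base cost).

    Returns ``(score, mismatches, gap_cols, q_start, q_end, r_start, r_end)``
    with half-open coordinates on both sequences. A score of 0 means no
    positive-scoring local alignment exists.
    """
    m = q.shape[0]
    n = r.shape[0]
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    E = np.full((m + 1, n + 1), -10**6, dtype=np.int32)  # gap in query (read consumes ref)
    F = np.full((m + 1, n + 1), -10**6, dtype=np.int32)  # gap in reference
    # pointers: 0 stop, 1 diag, 2 from E (horizontal), 3 from F (vertical)
    PH = np.zeros((m + 1, n + 1), dtype=np.uint8)
    PE = np.zeros((m + 1, n + 1), dtype=np.uint8)  # 1 = opened here, 0 = extended
    PF = np.zeros((m + 1, n + 1), dtype=np.uint8)

    best = np.int32(0)
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        qi = q[i - 1]
        for j in range(1, n + 1):
            s = match if qi == r[j - 1] and qi != 4 else -mismatch
            e_open = H[i, j - 1] - gap_open - gap_extend
            e_ext = E[i, j - 1] - gap_extend
            if e_open >= e_ext:
                E[i, j] = e_open
                PE[i, j] = 1
            else:
                E[i, j] = e_ext
                PE[i, j] = 0
            f_open = H[i - 1, j] - gap_open - gap_extend
            f_ext = F[i - 1, j] - gap_extend
            if f_open >= f_ext:
                F[i, j] = f_open
                PF[i, j] = 1
            else:
                F[i, j] = f_ext
                PF[i, j] = 0
            diag = H[i - 1, j - 1] + s
            h = diag
            p = 1
            if E[i, j] > h:
                h = E[i, j]
                p = 2
            if F[i, j] > h:
                h = F[i, j]
                p = 3
            if h <= 0:
                h = 0
                p = 0
            H[i, j] = h
            PH[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j

    # traceback
    mismatches = 0
    gap_cols = 0
    i = bi
    j = bj
    state = 0  # 0 = H, 1 = E, 2 = F
    while i > 0 and j > 0:
        if state == 0:
            p = PH[i, j]
            if p == 0:
                break
            if p == 1:
                if q[i - 1] != r[j - 1] or q[i - 1] == 4:
                    mismatches += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            gap_cols += 1
            opened = PE[i, j] == 1
            j -= 1
            if opened:
                state = 0
        else:
            gap_cols += 1
            opened = PF[i, j] == 1
            i -= 1
            if opened:
                state = 0
    return best, mismatches, gap_cols, i, bi, j, bj
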