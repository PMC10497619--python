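"""Independent brute-force oracles used by the test suite.

Deliberately simple, pure-Python reimplementations of the quantities the
package computes by faster or more structured means. They share tie-break
conventions with the production code (documented per function) but no code.
"""

from __future__ import annotations


def sw_oracle(query: str, ref: str, match: int, mismatch: int, gap_open: int, gap_extend: int):
    """Brute-force affine-gap Smith-Waterman with traceback.

    A gap of length L costs gap_open + L * gap_extend. Tie preference at
    equal score: diagonal, then gap-in-query (horizontal), then
    gap-in-reference (vertical); gap opening preferred over extension.
    The best cell is the first maximum in row-major order.
    Returns (score, mismatches, gap_columns, ref_start, ref_end).
    """
    m, n = len(query), len(ref)
    NEG = float("-inf")
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    ph = [[0] * (n + 1) for _ in range(m + 1)]
    pe = [[0] * (n + 1) for _ in range(m + 1)]
    pf = [[0] * (n + 1) for _ in range(m + 1)]
    best, bi, bj = 0.0, 0, 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = match if query[i - 1] == ref[j - 1] else -mismatch
            open_e = H[i][j - 1] - gap_open - gap_extend
            ext_e = E[i][j - 1] - gap_extend
            E[i][j], pe[i][j] = (open_e, 1) if open_e >= ext_e else (ext_e, 0)
            open_f = H[i - 1][j] - gap_open - gap_extend
            ext_f = F[i - 1][j] - gap_extend
            F[i][j], pf[i][j] = (open_f, 1) if open_f >= ext_f else (ext_f, 0)
            cands = [
                (H[i - 1][j - 1] + s, 1),
                (E[i][j], 2),
                (F[i][j], 3),
            ]
            h, p = cands[0]
            for val, tag in cands[1:]:
                if val > h:
                    h, p = val, tag
            if h <= 0:
                h, p = 0.0, 0
            H[i][j], ph[i][j] = h, p
            if h > best:
                best, bi, bj = h, i, j
    mismatches = gap_cols = 0
    i, j, state = bi, bj, 0
    while i > 0 and j > 0:
        if state == 0:
            p = ph[i][j]
            if p == 0:
                break
            if p == 1:
                if query[i - 1] != ref[j - 1]:
                    mismatches += 1
                i, j = i - 1, j - 1
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            gap_cols += 1
            opened = pe[i][j] == 1
            j -= 1
            if opened:
                state = 0
        else:
            gap_cols += 1
            opened = pf[i][j] == 1
            i -= 1
            if opened:
                state = 0
    return int(best), mismatches, gap_cols, j, bj


def min_boundary_distance(start: int, end: int, boundaries) -> float:
    """Smallest gap between a half-open interval and any boundary point."""
    best = float("inf")
    for p in boundaries:
        if p < start:
            d = start - p
        elif p > end:
            d = p - end
        else:
            d = 0
        best = min(best, d)
    return best


def scan_motif(sequence: str, pattern: str, iupac: dict) -> int:
    """Position-by-position degenerate motif scan (overlapping)."""
    count = 0
    for i in range(len(sequence) - len(pattern) + 1):
        if all(sequence[i + j] in iupac[c] for j, c in enumerate(pattern)):
            count += 1
    return count


def window_trim_oracle(quals, min_phred: float, window: int = 4) -> int:
    """Position-by-position scan of the trailing-window quality rule."""
    for j in range(len(quals)):
        w = quals[max(0, j - window + 1) : j + 1]
        if sum(w) / len(w) <= min_phred:
            return j
    return len(quals)


def welch_t_p_value(a, b) -> float:
    """Two-tailed Welch t-test p-value from first principles.

    Uses the t survival function via the regularized incomplete beta
    function computed by continued fraction — no scipy.
    """
    import math

    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    if se2 == 0:
        return 1.0 if ma == mb else float("nan")
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    x = df / (df + t * t)
    return _reg_inc_beta(df / 2.0, 0.5, x)


def _reg_inc_beta(a: float, b: float, x: float) -> float:
    import math

    if x <= 0:
        return 0.0
    if x >= 1:
        return 1.0
    if x > (a + 1) / (a + b + 2):
        return 1.0 - _reg_inc_beta(b, a, 1 - x)
    lbeta = math.lgamma(a) + math.lgamma(b) - math.lgamma(a + b)
    front = math.exp(math.log(x) * a + math.log(1 - x) * b - lbeta) / a
    # Lentz continued fraction
    f, c, d = 1.0, 1.0, 0.0
    for i in range(200):
        m = i // 2
        if i == 0:
            num = 1.0
        elif i % 2 == 0:
            num = m * (b - m) * x / ((a + 2 * m - 1) * (a + 2 * m))
        else:
            num = -(a + m) * (a + b + m) * x / ((a + 2 * m) * (a + 2 * m + 1))
        d = 1.0 + num * d
        if abs(d) < 1e-30:
            d = 1e-30
        d = 1.0 / d
        c = 1.0 + num / c
        if abs(c) < 1e-30:
            c = 1e-30
        f *= c * d
        if abs(1.0 - c * d) < 1e-12:
            break
    p = front * (f - 1.0)
    return min(max(p, 0.0), 1.0)
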