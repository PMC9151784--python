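"""Reference quadratic-space affine Smith-Waterman with traceback.

Independent oracle for te.local_identity: full Gotoh matrices, numba-jitted
so 2 kb pairs stay fast. Gap scoring matches the convention where a gap of
length L costs open + (L-1)*extend (first gapped residue pays the open
penalty). Returns (score, matches, columns, span_a, span_b).
"""

import numpy as np
from numba import njit

MATCH, MISMATCH, OPEN, EXT = 1.0, -1.0, -5.0, -1.0

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


@njit(cache=True)
def _gotoh(a, b):  # uint8 arrays
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), -1e18)  # gap in a (horizontal)
    F = np.full((n + 1, m + 1), -1e18)  # gap in b (vertical)
    best = 0.0
    bi = bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] + OPEN, E[i, j - 1] + EXT)
            F[i, j] = max(H[i - 1, j] + OPEN, F[i - 1, j] + EXT)
            s = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            h = H[i - 1, j - 1] + s
            if E[i, j] > h:
                h = E[i, j]
            if F[i, j] > h:
                h = F[i, j]
            if h < 0.0:
                h = 0.0
            H[i, j] = h
            if h > best:
                best, bi, bj = h, i, j
    # traceback from (bi, bj) in H until a zero cell
    i, j = bi, bj
    matches = 0
    columns = 0
    state = 0  # 0=H, 1=E, 2=F
    ei, ej = i, j
    while i > 0 and j > 0:
        if state == 0:
            if H[i, j] == 0.0:
                break
            s = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            if H[i, j] == H[i - 1, j - 1] + s:
                if a[i - 1] == b[j - 1]:
                    matches += 1
                columns += 1
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            columns += 1
            if E[i, j] == H[i, j - 1] + OPEN:
                state = 0
            j -= 1
        else:
            columns += 1
            if F[i, j] == H[i - 1, j] + OPEN:
                state = 0
            i -= 1
    return best, matches, columns, ei - i, ej - j


def sw_identity(seq_a: str, seq_b: str, both_strands: bool = True):
    """(identity, short_coverage, score) per the reference alignment."""
    def run(sa, sb):
        a = np.frombuffer(sa.encode(), dtype=np.uint8)
        b = np.frombuffer(sb.encode(), dtype=np.uint8)
        return _gotoh(a, b)

    score, matches, columns, span_a, span_b = run(seq_a, seq_b)
    if both_strands:
        alt = run(seq_a, revcomp(seq_b))
        if alt[0] > score:
            score, matches, columns, span_a, span_b = alt
    if score <= 0 or columns == 0:
        return 0.0, 0.0, 0.0
    identity = matches / columns
    short = min(len(seq_a), len(seq_b))
    cov = (span_a if len(seq_a) <= len(seq_b) else span_b) / short
    return identity, cov, float(score)
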