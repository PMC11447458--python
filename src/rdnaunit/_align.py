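"""Global alignment kernel used by pairwise identity.

Needleman-Wunsch with match +1, mismatch -1, linear gap -2. Among all
optimal-score alignments the kernel maximizes the number of matched
columns, then minimizes the total column count — a deterministic,
symmetric tie-break, so identity is well defined without exposing an
arbitrary traceback.
"""

from __future__ import annotations

import numpy as np
from numba import njit

MATCH = 1
MISMATCH = -1
GAP = -2


@njit(cache=True)
def _nw_kernel(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int]:  # pragma: no cover
    n, m = len(a), len(b)
    score = np.empty((n + 1, m + 1), dtype=np.int32)
    matches = np.empty((n + 1, m + 1), dtype=np.int32)
    cols = np.empty((n + 1, m + 1), dtype=np.int32)
    score[0, 0] = 0
    matches[0, 0] = 0
    cols[0, 0] = 0
    for j in range(1, m + 1):
        score[0, j] = GAP * j
        matches[0, j] = 0
        cols[0, j] = j
    for i in range(1, n + 1):
        score[i, 0] = GAP * i
        matches[i, 0] = 0
        cols[i, 0] = i
        for j in range(1, m + 1):
            is_match = a[i - 1] == b[j - 1]
            d_s = score[i - 1, j - 1] + (MATCH if is_match else MISMATCH)
            d_m = matches[i - 1, j - 1] + (1 if is_match else 0)
            d_c = cols[i - 1, j - 1] + 1
            u_s = score[i - 1, j] + GAP
            u_m = matches[i - 1, j]
            u_c = cols[i - 1, j] + 1
            l_s = score[i, j - 1] + GAP
            l_m = matches[i, j - 1]
            l_c = cols[i, j - 1] + 1
            # lexicographic max over (score, matches, -cols)
            bs, bm, bc = d_s, d_m, d_c
            if (u_s > bs) or (u_s == bs and (u_m > bm or (u_m == bm and u_c < bc))):
                bs, bm, bc = u_s, u_m, u_c
            if (l_s > bs) or (l_s == bs and (l_m > bm or (l_m == bm and l_c < bc))):
                bs, bm, bc = l_s, l_m, l_c
            score[i, j] = bs
            matches[i, j] = bm
            cols[i, j] = bc
    return int(score[n, m]), int(matches[n, m]), int(cols[n, m])


def global_alignment_stats(a: str, b: str) -> tuple[int, int, int]:
    """(score, matched columns, total columns) of the canonical global
    alignment of *a* and *b* under +1/-1/-2 scoring."""
    ac = np.frombuffer(a.encode(), dtype=np.uint8)
    bc = np.frombuffer(b.encode(), dtype=np.uint8)
    return _nw_kernel(ac, bc)
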