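"""Independent brute-force oracles used by the test suite.

Each function re-computes, by direct enumeration in plain Python, a
quantity that the package computes by a faster route. They deliberately
share no code with the implementation.
"""

from __future__ import annotations

GAP = -2


def brute_cpg_islands(seq: str, min_len: int = 201, min_gc: float = 0.5, min_oe: float = 0.6):
    """Greedy leftmost-longest maximal qualifying CpG stretches.

    Enumerates every candidate end for every candidate start with
    incrementally maintained counts.
    """
    seq = seq.upper()
    n = len(seq)
    out = []
    a = 0
    while a <= n - min_len:
        n_g = seq[a : a + min_len - 1].count("G")
        n_c = seq[a : a + min_len - 1].count("C")
        n_cg = sum(1 for i in range(a, a + min_len - 2) if seq[i : i + 2] == "CG")
        best_b = None
        for b in range(a + min_len, n + 1):
            ch = seq[b - 1]
            if ch == "G":
                n_g += 1
            elif ch == "C":
                n_c += 1
            if b - 2 >= a and seq[b - 2 : b] == "CG":
                n_cg += 1
            L = b - a
            gc_ok = (n_g + n_c) > min_gc * L
            oe_ok = n_c > 0 and n_g > 0 and n_cg * L > min_oe * n_c * n_g
            if gc_ok and oe_ok:
                best_b = b
        if best_b is None:
            a += 1
        else:
            out.append((a, best_b))
            a = best_b
    return out


def _primitive(motif: str) -> bool:
    p = len(motif)
    for d in range(1, p):
        if p % d == 0 and motif == motif[:d] * (p // d):
            return False
    return True


def brute_microsatellites(seq: str, min_unit: int = 2, max_unit: int = 6, min_copies: int = 3):
    """All maximal perfect tandem repeats as (start, motif, copies) triples."""
    seq = seq.upper()
    n = len(seq)
    out = set()
    for p in range(min_unit, max_unit + 1):
        for s in range(0, n - p * min_copies + 1):
            motif = seq[s : s + p]
            if "N" in motif or not _primitive(motif):
                continue
            if s >= p and seq[s - p : s] == motif:
                continue  # extendable left by a whole copy: not maximal
            c = 0
            while seq[s + c * p : s + (c + 1) * p] == motif:
                c += 1
            if c >= min_copies:
                out.add((s, motif, c))
    return out


def brute_identity(a: str, b: str) -> float:
    """Full-matrix global alignment DP (match +1 / mismatch -1 / gap -2),
    maximizing (score, matches, -columns) lexicographically."""
    a, b = a.upper(), b.upper()
    n, m = len(a), len(b)
    prev = [(GAP * j, 0, -j) for j in range(m + 1)]
    for i in range(1, n + 1):
        cur = [(GAP * i, 0, -i)] + [None] * m
        ai = a[i - 1]
        for j in range(1, m + 1):
            match = ai == b[j - 1]
            ds, dm, dc = prev[j - 1]
            d = (ds + (1 if match else -1), dm + (1 if match else 0), dc - 1)
            us, um, uc = prev[j]
            u = (us + GAP, um, uc - 1)
            ls, lm, lc = cur[j - 1]
            l = (ls + GAP, lm, lc - 1)
            cur[j] = max(d, u, l)
        prev = cur
    _, matches, negcols = prev[m]
    return round(100.0 * matches / (-negcols), 1)


def naive_motif_count(seq: str, motif: str) -> int:
    """Position-by-position overlapping occurrence count."""
    return sum(1 for i in range(len(seq) - len(motif) + 1) if seq[i : i + len(motif)] == motif)


def brute_tss(depth, frac: float = 0.1, sustain: int = 50):
    """Dumb scan for the first position with a sustained onset."""
    top = sorted(depth)[-max(1, len(depth) // 10):]
    mid = len(top) // 2
    plateau = top[mid] if len(top) % 2 == 1 else (top[mid - 1] + top[mid]) / 2
    thr = frac * plateau
    for p in range(0, len(depth) - sustain + 1):
        if all(depth[p + i] >= thr for i in range(sustain)):
            return p
    return None
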