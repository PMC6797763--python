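"""Independent brute-force oracles used to validate the implementation.

Each oracle recomputes a quantity from its mathematical definition by
exhaustive enumeration, sharing no code with the implementation under test.
"""
from __future__ import annotations

import math
from fractions import Fraction


# ---- density clustering ------------------------------------------------


def paraclu_oracle(signal, min_value=20, max_length=200, fold=5.0):
    """Exhaustive candidate-cluster enumeration.

    A run of consecutive sites S is a candidate iff maxD(S) exceeds the
    maximal maxD of every strict superset run, where maxD is the minimum
    prefix/suffix removal density.  Retention and flattening follow the
    same rules as the operation under test, recomputed independently.
    Returns sorted (start, end, total) triples.
    """
    items = sorted((p, v) for p, v in signal.items() if v > 0)
    if not items:
        return []
    pos = [p for p, _ in items]
    val = [float(v) for _, v in items]
    n = len(items)
    csum = [0.0]
    for v in val:
        csum.append(csum[-1] + v)

    def maxD(a, b):
        if a == b:
            return math.inf
        best = math.inf
        for k in range(a + 1, b + 1):
            best = min(best, (csum[k] - csum[a]) / (pos[k] - pos[a]))
            best = min(best, (csum[b + 1] - csum[k]) / (pos[b] - pos[k - 1]))
        return best

    maxd = {}
    for a in range(n):
        for b in range(a, n):
            maxd[(a, b)] = maxD(a, b)
    # M(a,b) = max maxD over all strict supersets, by decreasing span
    M = {}
    spans = sorted(maxd, key=lambda ab: ab[0] - ab[1])
    for a, b in spans:
        best = 0.0
        if a > 0:
            best = max(best, maxd[(a - 1, b)], M[(a - 1, b)])
        if b < n - 1:
            best = max(best, maxd[(a, b + 1)], M[(a, b + 1)])
        M[(a, b)] = best
    cands = []
    for (a, b), md in maxd.items():
        mind = M[(a, b)]
        if md <= mind:
            continue
        total = csum[b + 1] - csum[a]
        length = pos[b] - pos[a] + 1
        if total < min_value or length > max_length:
            continue
        if mind > 0 and math.isfinite(md) and md / mind < fold:
            continue
        cands.append((a, b, total))
    cands.sort(key=lambda t: (-(pos[t[1]] - pos[t[0]]), t[0]))
    kept = []
    for c in cands:
        if any(not (c[1] < k[0] or k[1] < c[0]) for k in kept):
            continue
        kept.append(c)
    return sorted((pos[a], pos[b] + 1, total) for a, b, total in kept)


# ---- branching-process null -------------------------------------------


def _polymul(f: dict[int, Fraction], g: dict[int, Fraction]) -> dict[int, Fraction]:
    out: dict[int, Fraction] = {}
    for i, ci in f.items():
        for j, cj in g.items():
            out[i + j] = out.get(i + j, Fraction(0)) + ci * cj
    return out


def branching_pmf_exact(p: Fraction, K: int) -> dict[int, Fraction]:
    """Leaf-count distribution of the depth-K Galton-Watson tree with
    offspring {1, 2}, via the generating-function recursion
    g_{k+1}(x) = (1-p) g_k(x) + p g_k(x)^2, g_0(x) = x (exact rationals)."""
    g: dict[int, Fraction] = {1: Fraction(1)}
    for _ in range(K):
        sq = _polymul(g, g)
        nxt = {n: (1 - p) * c for n, c in g.items()}
        for n, c in sq.items():
            nxt[n] = nxt.get(n, Fraction(0)) + p * c
        g = nxt
    return g


# ---- ORF / uORF scanners ----------------------------------------------

_STOPS = ("TAA", "TAG", "TGA")


def all_orfs_bruteforce(seq: str) -> list[tuple[int, int]]:
    """Every ATG -> first in-frame stop pair (end includes the stop)."""
    s = seq.upper().replace("U", "T")
    out = []
    for i in range(len(s) - 2):
        if s[i : i + 3] != "ATG":
            continue
        for j in range(i + 3, len(s) - 2, 3):
            if s[j : j + 3] in _STOPS:
                out.append((i, j + 3))
                break
    return out


def longest_orf_bruteforce(seq: str):
    orfs = all_orfs_bruteforce(seq)
    if not orfs:
        return None
    return min(orfs, key=lambda o: (-(o[1] - o[0]), o[0]))


def uorfs_bruteforce(seq: str, min_aa: int = 2) -> list[tuple[int, int]]:
    return [(a, b) for a, b in all_orfs_bruteforce(seq) if (b - a) // 3 - 1 >= min_aa]


# ---- RG4 ---------------------------------------------------------------


def rg4_bruteforce(seq: str, min_tract: int = 4, min_loop: int = 2):
    """Enumerate all equal-tract-length quadruplex placements; canonicalise
    to the minimal span per (tract length, start); resolve overlaps by
    longest tract, then leftmost, then shortest."""
    s = seq.upper().replace("U", "T")
    n = len(s)
    is_g = [c == "G" for c in s]

    def tract_at(i, t):
        return i + t <= n and all(is_g[i : i + t])

    cands = {}
    max_t = 0
    run = 0
    for g in is_g:
        run = run + 1 if g else 0
        max_t = max(max_t, run)
    for t in range(min_tract, max_t + 1):
        starts = [i for i in range(n) if tract_at(i, t)]
        for s1 in starts:
            best_end = None
            for s2 in starts:
                if s2 < s1 + t + min_loop:
                    continue
                for s3 in starts:
                    if s3 < s2 + t + min_loop:
                        continue
                    for s4 in starts:
                        if s4 < s3 + t + min_loop:
                            continue
                        end = s4 + t
                        if best_end is None or end < best_end:
                            best_end = end
            if best_end is not None:
                cands[(t, s1)] = best_end
    flat = sorted(
        ((t, a, e) for (t, a), e in cands.items()),
        key=lambda c: (-c[0], c[1], c[2] - c[1]),
    )
    kept = []
    for t, a, e in flat:
        if any(a < ke and ka < e for _, ka, ke in kept):
            continue
        kept.append((t, a, e))
    return sorted((a, e, t) for t, a, e in kept)


# ---- U-rich ------------------------------------------------------------


def urich_bruteforce(seq: str, window: int = 10, min_frac: float = 0.8, min_len: int = 6):
    """Naive re-derivation of the U-rich definition: qualifying clipped
    windows, merged, trimmed to U boundaries, length-filtered."""
    s = seq.upper().replace("T", "U")
    n = len(s)
    if n == 0:
        return []
    w = min(window, n)
    qual = [
        (i, i + w)
        for i in range(n - w + 1)
        if s[i : i + w].count("U") / w >= min_frac
    ]
    merged = []
    for a, b in qual:
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    out = []
    for a, b in merged:
        while a < b and s[a] != "U":
            a += 1
        while b > a and s[b - 1] != "U":
            b -= 1
        if b - a >= min_len:
            out.append((a, b))
    return out
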