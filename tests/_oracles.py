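"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (exhaustive enumeration, exact integer
arithmetic) and shares no code path with the package implementation.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from functools import lru_cache
from math import comb

# --- genetic code, written out independently of the package tables ---------

_BASES = "TCAG"
_AMINO = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
CODE = {
    a + b + c: _AMINO[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}
STOPS = {c for c, aa in CODE.items() if aa == "*"}


def oracle_site_counts(codon: str) -> float:
    """Synonymous sites of one codon: per position, synonymous single-nt
    changes / 3 (stop targets are not synonymous)."""
    s = Fraction(0)
    for pos in range(3):
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if alt not in STOPS and CODE[alt] == CODE[codon]:
                s += Fraction(1, 3)
    return s


def oracle_pathway_counts(ca: str, cb: str):
    """(Sd, Nd) for one codon pair: enumerate every ordering of the differing
    positions, drop orderings passing through stops, average the synonymous /
    nonsynonymous step counts as exact fractions."""
    diffs = [p for p in range(3) if ca[p] != cb[p]]
    if not diffs:
        return Fraction(0), Fraction(0)
    path_counts = []
    for order in itertools.permutations(diffs):
        cur = ca
        syn = non = 0
        ok = True
        for p in order:
            nxt = cur[:p] + cb[p] + cur[p + 1 :]
            if nxt in STOPS:
                ok = False
                break
            if CODE[nxt] == CODE[cur]:
                syn += 1
            else:
                non += 1
            cur = nxt
        if ok:
            path_counts.append((syn, non))
    if not path_counts:
        # positionwise fallback, averaged over both source contexts
        sd = Fraction(0)
        nd = Fraction(0)
        for p in diffs:
            syn_frac = Fraction(0)
            for src, dst in ((ca, cb[p]), (cb, ca[p])):
                alt = src[:p] + dst + src[p + 1 :]
                if alt not in STOPS and CODE[alt] == CODE[src]:
                    syn_frac += Fraction(1, 2)
            sd += syn_frac
            nd += 1 - syn_frac
        return sd, nd
    n = len(path_counts)
    sd = sum(Fraction(s) for s, _ in path_counts) / n
    nd = sum(Fraction(x) for _, x in path_counts) / n
    return sd, nd


def oracle_ng86_counts(cols):
    """Exact-fraction NG86 counts over a list of codon-pair columns."""
    S = sum((oracle_site_counts(a) + oracle_site_counts(b)) / 2 for a, b in cols)
    Sd = sum(oracle_pathway_counts(a, b)[0] for a, b in cols)
    Nd = sum(oracle_pathway_counts(a, b)[1] for a, b in cols)
    N = 3 * len(cols) - S
    return S, N, Sd, Nd


# --- Fisher exact, exact integer arithmetic --------------------------------

def oracle_fisher(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher exact P as an exact rational.

    All tables with the observed margins whose hypergeometric numerator is
    <= the observed one contribute (equal numerators = exact ties included).
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if min(r1, r2, c1, b + d) == 0:
        return Fraction(1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    num_obs = comb(r1, a) * comb(r2, c1 - a)
    total = sum(
        num for k in range(lo, hi + 1)
        if (num := comb(r1, k) * comb(r2, c1 - k)) <= num_obs
    )
    return Fraction(total, comb(n, c1))


# --- exhaustive alignment oracles ------------------------------------------

def _gap_cost(length: int, open_: int, extend: int) -> int:
    return open_ + length * extend


def enumerate_global_alignments(a: str, b: str):
    """Yield every global alignment as a list of column pairs, where a column
    is (x, y) with x/y a residue or '-' (never both gaps)."""
    @lru_cache(maxsize=None)
    def rec(i: int, j: int):
        if i == len(a) and j == len(b):
            return [()]
        outs = []
        if i < len(a) and j < len(b):
            outs += [((a[i], b[j]),) + rest for rest in rec(i + 1, j + 1)]
        if i < len(a):
            outs += [((a[i], "-"),) + rest for rest in rec(i + 1, j)]
        if j < len(b):
            outs += [(("-", b[j]),) + rest for rest in rec(i, j + 1)]
        return outs

    return rec(0, 0)


def score_alignment(columns, score_fn, gap_open: int, gap_extend: int) -> float:
    """Affine-gap score of one alignment (gap run of k costs open + k*extend)."""
    total = 0.0
    run_a = run_b = 0
    for x, y in columns:
        if x == "-":
            run_a += 1
            if run_b:
                total -= _gap_cost(run_b, gap_open, gap_extend)
                run_b = 0
        elif y == "-":
            run_b += 1
            if run_a:
                total -= _gap_cost(run_a, gap_open, gap_extend)
                run_a = 0
        else:
            if run_a:
                total -= _gap_cost(run_a, gap_open, gap_extend)
                run_a = 0
            if run_b:
                total -= _gap_cost(run_b, gap_open, gap_extend)
                run_b = 0
            total += score_fn(x, y)
    if run_a:
        total -= _gap_cost(run_a, gap_open, gap_extend)
    if run_b:
        total -= _gap_cost(run_b, gap_open, gap_extend)
    return total


def oracle_global_score(a: str, b: str, score_fn, gap_open: int = 11, gap_extend: int = 1) -> float:
    """Optimal global score by full enumeration (use only for tiny inputs)."""
    return max(
        score_alignment(cols, score_fn, gap_open, gap_extend)
        for cols in enumerate_global_alignments(a, b)
    )


def oracle_local_score(a: str, b: str, score_fn, gap_open: int = 11, gap_extend: int = 1) -> float:
    """Optimal local score: best global score over all substring pairs,
    floored at 0 (empty alignment)."""
    best = 0.0
    for i1 in range(len(a)):
        for i2 in range(i1 + 1, len(a) + 1):
            for j1 in range(len(b)):
                for j2 in range(j1 + 1, len(b) + 1):
                    s = oracle_global_score(a[i1:i2], b[j1:j2], score_fn, gap_open, gap_extend)
                    best = max(best, s)
    return best


# --- fast independent DP (Gotoh), itself validated against enumeration -----

def gotoh_global(a: str, b: str, score_fn, gap_open: int = 11, gap_extend: int = 1) -> float:
    """Affine-gap global alignment score (Gotoh three-state DP, end gaps
    penalized; a gap of length k costs open + k*extend; adjacent gaps in
    opposite sequences are allowed, matching the enumeration oracle)."""
    neg = float("-inf")
    la, lb = len(a), len(b)
    go = gap_open + gap_extend  # cost of opening (first gap character)
    M = [[neg] * (lb + 1) for _ in range(la + 1)]
    X = [[neg] * (lb + 1) for _ in range(la + 1)]  # column (a_i, '-')
    Y = [[neg] * (lb + 1) for _ in range(la + 1)]  # column ('-', b_j)
    M[0][0] = 0.0
    for i in range(1, la + 1):
        X[i][0] = -(gap_open + i * gap_extend)
    for j in range(1, lb + 1):
        Y[0][j] = -(gap_open + j * gap_extend)
    for i in range(la + 1):
        for j in range(lb + 1):
            if i > 0 and j > 0:
                M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + score_fn(
                    a[i - 1], b[j - 1]
                )
            if i > 0 and j > 0:
                X[i][j] = max(M[i - 1][j] - go, X[i - 1][j] - gap_extend, Y[i - 1][j] - go)
                Y[i][j] = max(M[i][j - 1] - go, Y[i][j - 1] - gap_extend, X[i][j - 1] - go)
    return max(M[la][lb], X[la][lb], Y[la][lb])


def gotoh_local(a: str, b: str, score_fn, gap_open: int = 11, gap_extend: int = 1) -> float:
    """Affine-gap Smith-Waterman score (floor 0; best cell over match state)."""
    la, lb = len(a), len(b)
    neg = float("-inf")
    go = gap_open + gap_extend
    best = 0.0
    M = [[0.0] * (lb + 1) for _ in range(la + 1)]
    X = [[neg] * (lb + 1) for _ in range(la + 1)]
    Y = [[neg] * (lb + 1) for _ in range(la + 1)]
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            X[i][j] = max(M[i - 1][j] - go, X[i - 1][j] - gap_extend, Y[i - 1][j] - go)
            Y[i][j] = max(M[i][j - 1] - go, Y[i][j - 1] - gap_extend, X[i][j - 1] - go)
            diag = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            M[i][j] = max(0.0, diag + score_fn(a[i - 1], b[j - 1]))
            best = max(best, M[i][j])
    return best
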