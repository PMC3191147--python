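"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations, structurally unrelated to the package
code paths they check.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def naive_find(seq: str, motif: str) -> list[int]:
    return [i for i in range(len(seq) - len(motif) + 1)
            if seq[i:i + len(motif)] == motif]


def brute_force_digest(seq: str) -> tuple[list[tuple], list[tuple]]:
    """Enumerate every (MluI, nearest-NlaIII) fragment pair directly.

    Returns (fragments, tags); fragments are (start, end, side) and tags are
    (fragment start, end, side, tag sequence, strand), the tag being the 17
    bases interior to the CATG read toward the MluI end.
    """
    mlu = naive_find(seq, "ACGCGT")
    nla = naive_find(seq, "CATG")
    fragments = []
    tags = []
    for k, m in enumerate(mlu):
        prev_m = mlu[k - 1] if k > 0 else None
        next_m = mlu[k + 1] if k + 1 < len(mlu) else None
        lefts = [n for n in nla if n < m]
        rights = [n for n in nla if n > m]

        if prev_m is not None and not any(prev_m < n < m for n in nla):
            fragments.append((prev_m, m + 6, "mlu_mlu"))
        elif lefts:
            n = max(lefts)
            fragments.append((n, m + 6, "left"))
            if m - (n + 4) >= 17:
                t = seq[n + 4 : n + 21]
                if "N" not in t:
                    tags.append((n, m + 6, "left", t, "+"))

        if next_m is not None and not any(m < n < next_m for n in nla):
            continue  # shared fragment recorded when visiting next_m
        if rights:
            n = min(rights)
            fragments.append((m, n + 4, "right"))
            if n - (m + 6) >= 17:
                t = rc(seq[n - 17 : n])
                if "N" not in t:
                    tags.append((m, n + 4, "right", t, "-"))
    return fragments, tags


def exact_binom_two_sided(x1: int, x2: int, n1: int, n2: int) -> Fraction:
    """Doubled inclusive binomial tail as an exact fraction.

    x1 | x1+x2=T ~ Binomial(T, n1/(n1+n2)); p = min(1, 2 min(tails)).
    """
    T = x1 + x2
    if T == 0:
        return Fraction(1)
    pi = Fraction(n1, n1 + n2)
    pmf = [comb(T, k) * pi**k * (1 - pi) ** (T - k) for k in range(T + 1)]
    lower = sum(pmf[: x1 + 1])
    upper = sum(pmf[x1:])
    return min(Fraction(1), 2 * min(lower, upper))


def naive_cgi_scan(seq: str, window: int = 501) -> list[tuple[int, int]]:
    """Direct window scan + merge + re-test; O(L * W), small inputs only."""

    def stats(s: str) -> tuple[float, float]:
        n_c = s.count("C")
        n_g = s.count("G")
        n_cpg = sum(1 for i in range(len(s) - 1) if s[i : i + 2] == "CG")
        gc = (n_c + n_g) / len(s)
        oe = n_cpg * len(s) / (n_c * n_g) if n_c and n_g else 0.0
        return gc, oe

    passing = []
    for i in range(len(seq) - window + 1):
        w = seq[i : i + window]
        if "N" in w:
            continue
        gc, oe = stats(w)
        if gc > 0.5 and oe > 0.6:
            passing.append(i)
    regions = []
    for i in passing:
        if regions and i <= regions[-1][1]:
            regions[-1] = (regions[-1][0], max(regions[-1][1], i + window))
        else:
            regions.append((i, i + window))
    out = []
    for a, b in regions:
        gc, oe = stats(seq[a:b])
        if b - a > 500 and gc > 0.5 and oe > 0.6:
            out.append((a, b))
    return out


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def brute_force_map(read: str, tag_seqs: list[tuple[str, bool]]) -> tuple[str, int, int]:
    """All-pairs Hamming scan over (sequence, unique) virtual tags.

    Returns (tier, mismatches, n_best_candidates) under the mapper's
    semantics: both read orientations searched, exact single hit on a
    unique tag is high, any other <=1-mismatch placement low.
    """
    if "N" in read:
        return ("unmapped", 0, 0)
    best = 2
    candidates: list[tuple[int, bool]] = []
    for orient in (read, rc(read)):
        for idx, (t, uniq) in enumerate(tag_seqs):
            d = hamming(orient, t)
            if d < best:
                best = d
                candidates = [(idx, uniq)]
            elif d == best and d < 2:
                if (idx, uniq) not in candidates:
                    candidates.append((idx, uniq))
    if best >= 2 or not candidates:
        return ("unmapped", 0, 0)
    if best == 0 and len(candidates) == 1 and candidates[0][1]:
        return ("high", 0, 1)
    return ("low", best, len(candidates))
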