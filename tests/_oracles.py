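"""Independent reference implementations used as test oracles.

Everything here is deliberately written from first principles (plain loops,
no shared code with the package) so that agreement with the package is a
genuine dual-route check.
"""

from __future__ import annotations

import math

_RC = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def smith_waterman_score(q: str, s: str, match=1, mismatch=-1, gap_open=2, gap_extend=1) -> int:
    """Full affine-gap Smith-Waterman best local score (Gotoh, plain loops)."""
    m, n = len(q), len(s)
    NEG = -(10**9)
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best = 0
    open_cost = gap_open + gap_extend
    for i in range(1, m + 1):
        qi = q[i - 1]
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] - open_cost, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - open_cost, F[i - 1][j] - gap_extend)
            sub = match if (qi == s[j - 1] and qi in "ACGT") else mismatch
            H[i][j] = max(0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


def smith_waterman_score_both_strands(q: str, s: str, **kw) -> int:
    return max(smith_waterman_score(q, s, **kw), smith_waterman_score(revcomp(q), s, **kw))


# unified duplex parameter table transcribed independently: (stack, dH, dS)
_NN_ROWS = [
    ("AA", -7.9, -22.2), ("AT", -7.2, -20.4), ("TA", -7.2, -21.3),
    ("CA", -8.5, -22.7), ("GT", -8.4, -22.4), ("CT", -7.8, -21.0),
    ("GA", -8.2, -22.2), ("CG", -10.6, -27.2), ("GC", -9.8, -24.4),
    ("GG", -8.0, -19.9),
]


def _stack_params(pair: str):
    for stack, dh, ds in _NN_ROWS:
        if pair == stack:
            return dh, ds
        # a stack read on the complementary strand has the same parameters
        if pair == revcomp(stack):
            return dh, ds
    raise KeyError(pair)


def nn_melting_temperature(seq: str, na_mM: float = 50.0, oligo_nM: float = 500.0) -> float:
    """Nearest-neighbor Tm recomputed by table lookup, independent code path."""
    dh, ds = 0.0, 0.0
    for terminal in (seq[0], seq[-1]):
        if terminal in "GC":
            dh += 0.1
            ds += -2.8
        else:
            dh += 2.3
            ds += 4.1
    for i in range(len(seq) - 1):
        h, s = _stack_params(seq[i : i + 2])
        dh += h
        ds += s
    selfcomp = seq == revcomp(seq)
    if selfcomp:
        ds += -1.4
    ct = oligo_nM * 1e-9 / (1.0 if selfcomp else 4.0)
    tm_kelvin = 1000.0 * dh / (ds + 1.987 * math.log(ct))
    return tm_kelvin - 273.15 + 16.6 * math.log10(na_mM / 1000.0)


def bh_step_up(pvalues):
    """Textbook Benjamini-Hochberg step-up, written longhand."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running_min = float("inf")
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        value = pvalues[idx] * m / rank_from_top
        running_min = min(running_min, value, 1.0)
        adjusted[idx] = running_min
    return adjusted


def tally_rates(chroms, calls):
    """Per-chromosome miss/het/hom rates by direct symbol counting."""
    out = {}
    for chrom, call in zip(chroms, calls):
        d = out.setdefault(chrom, {"NoCall": 0, "AB": 0, "hom": 0, "n": 0})
        d["n"] += 1
        if call == "NoCall":
            d["NoCall"] += 1
        elif call == "AB":
            d["AB"] += 1
        else:
            d["hom"] += 1
    return {
        c: (d["NoCall"] / d["n"], d["AB"] / d["n"], d["hom"] / d["n"], d["n"])
        for c, d in out.items()
    }


def tally_shared(chroms, calls_a, calls_b):
    """Per-chromosome shared fraction over co-called loci, by explicit loop."""
    co = {}
    same = {}
    for chrom, a, b in zip(chroms, calls_a, calls_b):
        if a != "NoCall" and b != "NoCall":
            co[chrom] = co.get(chrom, 0) + 1
            if a == b:
                same[chrom] = same.get(chrom, 0) + 1
    return {c: same.get(c, 0) / n for c, n in co.items()}
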