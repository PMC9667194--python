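"""Local sequence alignment engine.

Affine-gap Smith-Waterman (Gotoh) with two execution paths:

* an exact full dynamic program, used whenever the DP matrix is small
  (``len(q) * len(s) <= EXACT_CELLS``), and
* a k-mer seeded, banded dynamic program for transcript-versus-chromosome
  problems, where exact seeds define candidate diagonals and the DP is run in
  a band around each seeded diagonal cluster.

Scoring defaults: match +1, mismatch -1, gap open -2, gap extend -1 (a gap of
length L costs 2 + L).  N never matches anything and scores as a mismatch.
Identity is matches / aligned columns, gap columns counting as non-matches;
query coverage is the aligned query span over the query length.  Both strands
of the query are searched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from ._seq import encode, revcomp_codes

#: problems with at most this many DP cells are solved exactly (no seeding)
EXACT_CELLS = 1_000_000

MATCH = 1
MISMATCH = -1
GAP_OPEN = 2  # penalty, charged once per gap
GAP_EXTEND = 1  # penalty per gapped column

_NEG = -(10**9)


@dataclass(frozen=True)
class LocalAlignment:
    """Best local alignment of a query against a subject.

    Coordinates are 1-based inclusive; ``strand`` is '+' when the query
    aligned as given and '-' when its reverse complement did.  A score of 0
    means no positive-scoring local alignment exists (no hit): identity and
    coverage are then 0 and the coordinates are 0.
    """

    score: int
    matches: int
    mismatches: int
    gaps: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str

    @property
    def aligned_columns(self) -> int:
        return self.matches + self.mismatches + self.gaps

    @property
    def identity(self) -> float:
        cols = self.aligned_columns
        return 100.0 * self.matches / cols if cols else 0.0

    def query_coverage(self, query_length: int) -> float:
        if self.score <= 0:
            return 0.0
        return 100.0 * (self.q_end - self.q_start + 1) / query_length


NO_HIT = LocalAlignment(0, 0, 0, 0, 0, 0, 0, 0, "+")


@njit(cache=False)
def _sw_banded(q, s, dlo, dhi, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    """Banded affine-gap Smith-Waterman with traceback.

    Cells (i, j), 1-based, restricted to the diagonal band dlo <= j-i <= dhi.
    Returns (score, matches, mismatches, gaps, q_start, q_end, s_start, s_end).
    """
    m = q.shape[0]
    n = s.shape[0]
    W = dhi - dlo + 1
    open_cost = gap_open + gap_extend

    H = np.full((m + 1, W + 2), _NEG, np.int32)
    E = np.full((m + 1, W + 2), _NEG, np.int32)
    F = np.full((m + 1, W + 2), _NEG, np.int32)
    PH = np.zeros((m + 1, W + 2), np.uint8)  # 0 stop, 1 diag, 2 from E, 3 from F
    PE = np.zeros((m + 1, W + 2), np.uint8)  # 1 = gap extension
    PF = np.zeros((m + 1, W + 2), np.uint8)

    # empty-alignment boundary: row 0 and column j=0 score 0 inside the band
    for c in range(1, W + 1):
        j = dlo + c - 1
        if 0 <= j <= n:
            H[0, c] = 0

    best = 0
    bi = 0
    bc = 0
    for i in range(1, m + 1):
        c0 = 1 - i - dlo  # band cell corresponding to j = 0
        if 0 <= c0 <= W + 1:
            H[i, c0] = 0
        jlo = i + dlo
        if jlo < 1:
            jlo = 1
        jhi = i + dhi
        if jhi > n:
            jhi = n
        qi = q[i - 1]
        for j in range(jlo, jhi + 1):
            c = j - i - dlo + 1
            # gap in query (consume subject char j)
            e_open = H[i, c - 1] - open_cost
            e_ext = E[i, c - 1] - gap_extend
            if e_ext > e_open:
                E[i, c] = e_ext
                PE[i, c] = 1
            else:
                E[i, c] = e_open
                PE[i, c] = 0
            # gap in subject (consume query char i)
            f_open = H[i - 1, c + 1] - open_cost
            f_ext = F[i - 1, c + 1] - gap_extend
            if f_ext > f_open:
                F[i, c] = f_ext
                PF[i, c] = 1
            else:
                F[i, c] = f_open
                PF[i, c] = 0
            sj = s[j - 1]
            if qi == sj and qi < 4:
                sub = match
            else:
                sub = mismatch
            h = 0
            p = 0
            diag = H[i - 1, c] + sub
            if diag > h:
                h = diag
                p = 1
            if E[i, c] > h:
                h = E[i, c]
                p = 2
            if F[i, c] > h:
                h = F[i, c]
                p = 3
            H[i, c] = h
            PH[i, c] = p
            if h > best:
                best = h
                bi = i
                bc = c
    if best <= 0:
        return 0, 0, 0, 0, 0, 0, 0, 0

    # traceback
    matches = 0
    mismatches = 0
    gaps = 0
    i = bi
    c = bc
    q_end = bi
    s_end = bi + dlo + bc - 1
    while True:
        p = PH[i, c]
        if p == 0:
            break
        if p == 1:
            j = i + dlo + c - 1
            if q[i - 1] == s[j - 1] and q[i - 1] < 4:
                matches += 1
            else:
                mismatches += 1
            i -= 1
        elif p == 2:
            while True:
                gaps += 1
                ext = PE[i, c]
                c -= 1
                if ext == 0:
                    break
        else:
            while True:
                gaps += 1
                ext = PF[i, c]
                i -= 1
                c += 1
                if ext == 0:
                    break
    q_start = i + 1
    s_start = i + dlo + c - 1 + 1
    return best, matches, mismatches, gaps, q_start, q_end, s_start, s_end


def _run_banded(qc: np.ndarray, sc: np.ndarray, dlo: int, dhi: int, scoring) -> tuple:
    m, n = qc.shape[0], sc.shape[0]
    dlo = max(dlo, 1 - m)
    dhi = min(dhi, n - 1)
    if dlo > dhi:
        return (0, 0, 0, 0, 0, 0, 0, 0)
    return _sw_banded(qc, sc, dlo, dhi, *scoring)


class KmerIndex:
    """Sorted k-mer index of a subject sequence for exact-seed lookup."""

    def __init__(self, codes: np.ndarray, k: int):
        self.k = k
        self.n = codes.shape[0]
        if self.n < k:
            self.values = np.empty(0, dtype=np.uint64)
            self.positions = np.empty(0, dtype=np.int64)
            return
        win = np.lib.stride_tricks.sliding_window_view(codes, k)
        valid = (win < 4).all(axis=1)
        powers = (4 ** np.arange(k - 1, -1, -1)).astype(np.uint64)
        vals = win.astype(np.uint64) @ powers
        pos = np.nonzero(valid)[0].astype(np.int64)
        vals = vals[valid]
        order = np.argsort(vals, kind="stable")
        self.values = vals[order]
        self.positions = pos[order]

    def matches(self, query_codes: np.ndarray, max_pairs: int = 100_000):
        """Return (query_pos, subject_pos) arrays of exact k-mer matches."""
        k = self.k
        mq = query_codes.shape[0]
        if mq < k or self.values.size == 0:
            return np.empty(0, np.int64), np.empty(0, np.int64)
        win = np.lib.stride_tricks.sliding_window_view(query_codes, k)
        valid = (win < 4).all(axis=1)
        powers = (4 ** np.arange(k - 1, -1, -1)).astype(np.uint64)
        qvals = win.astype(np.uint64) @ powers
        qpos_all = np.nonzero(valid)[0]
        qvals = qvals[valid]
        lo = np.searchsorted(self.values, qvals, side="left")
        hi = np.searchsorted(self.values, qvals, side="right")
        counts = hi - lo
        hits = counts > 0
        total = int(counts.sum())
        qp_list = []
        sp_list = []
        budget = max_pairs
        for qp, l, h in zip(qpos_all[hits], lo[hits], hi[hits]):
            c = int(h - l)
            if c > budget:
                c = budget
            sp_list.append(self.positions[l : l + c])
            qp_list.append(np.full(c, qp, dtype=np.int64))
            budget -= c
            if budget <= 0:
                break
        if not qp_list:
            return np.empty(0, np.int64), np.empty(0, np.int64)
        del total
        return np.concatenate(qp_list), np.concatenate(sp_list)


def _seed_clusters(qpos: np.ndarray, spos: np.ndarray, merge_gap: int = 16):
    """Group seed diagonals into clusters: list of (count, dmin, dmax, dmode)."""
    diags = np.sort(spos - qpos)
    breaks = np.nonzero(np.diff(diags) > merge_gap)[0] + 1
    clusters = []
    for chunk in np.split(diags, breaks):
        vals, cnts = np.unique(chunk, return_counts=True)
        dmode = int(vals[int(np.argmax(cnts))])
        clusters.append((int(chunk.size), int(chunk[0]), int(chunk[-1]), dmode))
    clusters.sort(key=lambda t: (-t[0], t[1]))
    return clusters


def _best_over_strands(qc: np.ndarray, sc: np.ndarray, scoring, min_seed: int,
                       index_cache=None, pad: int = 12, max_band: int = 128,
                       max_clusters: int = 8):
    m, n = qc.shape[0], sc.shape[0]
    exact = m * n <= EXACT_CELLS
    if not exact:
        if index_cache is None:
            index_cache = KmerIndex(sc, min_seed)
        index = index_cache
    best = None
    for strand, q in (("+", qc), ("-", revcomp_codes(qc))):
        if exact:
            res = _run_banded(q, sc, 1 - m, n - 1, scoring)
            cand = [(res, strand)]
        else:
            qpos, spos = index.matches(q)
            cand = []
            if qpos.size:
                for count, dmin, dmax, dmode in _seed_clusters(qpos, spos)[:max_clusters]:
                    dlo, dhi = dmin - pad, dmax + pad
                    if dhi - dlo + 1 > max_band:
                        half = max_band // 2
                        dlo, dhi = dmode - half, dmode + half
                    cand.append((_run_banded(q, sc, dlo, dhi, scoring), strand))
        for res, st in cand:
            if best is None or res[0] > best[0][0]:
                best = (res, st)
    if best is None or best[0][0] <= 0:
        return NO_HIT
    (score, ma, mi, ga, qs, qe, ss, se), strand = best
    return LocalAlignment(score, ma, mi, ga, qs, qe, ss, se, strand)


def align_local(query: str, subject: str, min_seed: int = 11,
                match: int = MATCH, mismatch: int = MISMATCH,
                gap_open: int = GAP_OPEN, gap_extend: int = GAP_EXTEND,
                index: "KmerIndex | None" = None) -> LocalAlignment:
    """Best local alignment of ``query`` (either strand) against ``subject``.

    Small problems are solved with the exact full dynamic program; larger
    ones with exact-k-mer seeding and banded DP around seeded diagonals.
    ``index`` may pass a pre-built :class:`KmerIndex` of the subject.
    """
    if not query or not subject:
        raise ValueError("empty sequence")
    if len(query) < min_seed:
        raise ValueError(f"query shorter than min_seed={min_seed}")
    qc = encode(query.upper())
    sc = encode(subject.upper())
    scoring = (match, mismatch, gap_open, gap_extend)
    return _best_over_strands(qc, sc, scoring, min_seed, index_cache=index)
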