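"""Primer design, in-silico PCR specificity screening, marker classification.

Primer pairs are enumerated exhaustively under the classic STS-marker
constraints (length 18-27 bp, Tm 57-63 degC, GC 40-60%, product 200-700 bp,
pair delta-Tm <= 3 degC), ranked by distance from the Tm midrange and then by
product-size centrality.  Melting temperatures use the unified
nearest-neighbor duplex parameter set (SantaLucia 1998, PNAS 95:1460;
Allawi & SantaLucia 1997, Biochemistry 36:10581) with the Schildkraut-Lifson
monovalent-salt correction, at 50 mM Na+ and 500 nM oligo by default.

In-silico PCR reports amplicons between convergent primer binding sites with
at most ``max_mismatch`` mismatches and a perfect 3'-terminal clamp; marker
classification maps the band pattern over a validation panel onto
donor-specific / transferable / non-specific / failed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional

import numpy as np

from ._seq import encode, revcomp, validate_sequence

# unified nearest-neighbor duplex parameters, 5'->3' stacks:
# dH in kcal/mol, dS in cal/(mol K)
NN_UNIFIED: Dict[str, tuple[float, float]] = {
    "AA": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7),
    "GT": (-8.4, -22.4),
    "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
    # complementary stacks (read on the other strand)
    "TT": (-7.9, -22.2),
    "TG": (-8.5, -22.7),
    "AC": (-8.4, -22.4),
    "AG": (-7.8, -21.0),
    "TC": (-8.2, -22.2),
    "CC": (-8.0, -19.9),
}
#: duplex initiation with a terminal G.C / A.T pair
NN_INIT = {"G": (0.1, -2.8), "C": (0.1, -2.8), "A": (2.3, 4.1), "T": (2.3, 4.1)}
#: entropy correction for self-complementary duplexes
SYM_DS = -1.4

R_GAS = 1.987  # cal / (mol K)


@dataclass(frozen=True)
class PrimerConstraints:
    """Per-primer and per-pair design constraints (all bounds inclusive)."""

    length_min: int = 18
    length_max: int = 27
    tm_min: float = 57.0
    tm_max: float = 63.0
    gc_min: float = 40.0
    gc_max: float = 60.0
    product_min: int = 200
    product_max: int = 700
    max_tm_diff: float = 3.0

    def __post_init__(self) -> None:
        for lo, hi, name in (
            (self.length_min, self.length_max, "length"),
            (self.tm_min, self.tm_max, "tm"),
            (self.gc_min, self.gc_max, "gc"),
            (self.product_min, self.product_max, "product"),
        ):
            if lo > hi:
                raise ValueError(f"{name}: min exceeds max")


@dataclass(frozen=True)
class PrimerPair:
    """A designed primer pair on a template.

    The reverse primer is given 5'->3' as synthesised (reverse complement of
    the template window).  Template coordinates are 1-based inclusive;
    ``product_size`` spans the forward 5' end to the reverse 5' end.
    """

    marker_id: str
    forward: str
    reverse: str
    tm_forward: float
    tm_reverse: float
    gc_forward: float
    gc_reverse: float
    product_size: int
    template_id: str
    fwd_start: int  # 1-based position of the forward primer 5' end
    rev_end: int  # 1-based position of the reverse primer 5' end on the template


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product on a panel genome."""

    genome: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str  # strand carrying the forward-primer site
    mismatch_forward: int
    mismatch_reverse: int

    @property
    def size(self) -> int:
        return self.end - self.start + 1


MARKER_CLASSES = ("donor_specific", "transferable", "non_specific", "failed")


@dataclass(frozen=True)
class MarkerClass:
    marker_id: str
    pattern: Dict[str, bool]
    marker_class: str


# ---------------------------------------------------------------------------
# thermodynamics

def gc_content(sequence: str) -> float:
    """GC percentage of an unambiguous sequence."""
    seq = sequence.upper()
    if not seq:
        raise ValueError("empty sequence")
    if set(seq) - set("ACGT"):
        raise ValueError("ambiguous base in sequence; GC content requires A/C/G/T")
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


def melting_temperature(
    sequence: str, na_mM: float = 50.0, oligo_nM: float = 500.0
) -> float:
    """Nearest-neighbor duplex melting temperature in degrees Celsius.

    Tm = 1000*dH / (dS + R ln(CT/x)) - 273.15 + 16.6 log10([Na+]), with
    x = 4 for non-self-complementary duplexes (1 for self-complementary,
    which also receive the symmetry entropy term).
    """
    seq = sequence.upper()
    if set(seq) - set("ACGT"):
        raise ValueError("ambiguous base in primer sequence")
    if not 8 <= len(seq) <= 40:
        raise ValueError("Tm model is calibrated for lengths 8..40")
    dh, ds = 0.0, 0.0
    for base in (seq[0], seq[-1]):
        h, s = NN_INIT[base]
        dh += h
        ds += s
    for i in range(len(seq) - 1):
        h, s = NN_UNIFIED[seq[i : i + 2]]
        dh += h
        ds += s
    selfcomp = seq == revcomp(seq)
    x = 1.0 if selfcomp else 4.0
    if selfcomp:
        ds += SYM_DS
    ct = oligo_nM * 1e-9
    tm = 1000.0 * dh / (ds + R_GAS * math.log(ct / x)) - 273.15
    return tm + 16.6 * math.log10(na_mM / 1000.0)


def _window_thermo(seq: str, length: int, na_mM: float, oligo_nM: float):
    """Vectorised Tm and GC for every window of ``length`` along ``seq``.

    Uses the same parameter table as :func:`melting_temperature`; windows
    containing non-ACGT symbols come back as NaN.  Self-complementary
    windows are vanishingly rare in design practice and are recomputed
    exactly by the scalar audit; the vectorised path assumes x = 4.
    """
    codes = encode(seq)
    n = len(seq)
    if n < length:
        return np.empty(0), np.empty(0)
    stack_dh = np.zeros(n - 1)
    stack_ds = np.zeros(n - 1)
    valid = codes < 4
    for i in range(n - 1):
        if valid[i] and valid[i + 1]:
            h, s = NN_UNIFIED[seq[i : i + 2]]
            stack_dh[i] = h
            stack_ds[i] = s
        else:
            stack_dh[i] = np.nan
    cdh = np.concatenate([[0.0], np.cumsum(stack_dh)])
    cds = np.concatenate([[0.0], np.cumsum(stack_ds)])
    starts = np.arange(n - length + 1)
    dh = cdh[starts + length - 1] - cdh[starts]
    ds = cds[starts + length - 1] - cds[starts]
    init_h = np.array([NN_INIT.get(b, (np.nan, np.nan))[0] for b in "ACGT"] + [np.nan])
    init_s = np.array([NN_INIT.get(b, (np.nan, np.nan))[1] for b in "ACGT"] + [np.nan])
    first = codes[starts]
    last = codes[starts + length - 1]
    dh = dh + init_h[first] + init_h[last]
    ds = ds + init_s[first] + init_s[last]
    ct = oligo_nM * 1e-9
    with np.errstate(invalid="ignore"):
        tm = 1000.0 * dh / (ds + R_GAS * math.log(ct / 4.0)) - 273.15
        tm = tm + 16.6 * math.log10(na_mM / 1000.0)
    is_gc = ((codes == 1) | (codes == 2)).astype(float)
    cgc = np.concatenate([[0.0], np.cumsum(is_gc)])
    gc = 100.0 * (cgc[starts + length] - cgc[starts]) / length
    gc[np.isnan(dh)] = np.nan
    tm[np.isnan(dh)] = np.nan
    return tm, gc


# ---------------------------------------------------------------------------
# design

def audit_primer_pair(pair: PrimerPair, constraints: PrimerConstraints = PrimerConstraints(),
                      na_mM: float = 50.0, oligo_nM: float = 500.0) -> bool:
    """Independently recheck every constraint from the primer sequences alone."""
    checks = []
    for primer in (pair.forward, pair.reverse):
        checks.append(constraints.length_min <= len(primer) <= constraints.length_max)
        tm = melting_temperature(primer, na_mM=na_mM, oligo_nM=oligo_nM)
        checks.append(constraints.tm_min <= tm <= constraints.tm_max)
        gc = gc_content(primer)
        checks.append(constraints.gc_min <= gc <= constraints.gc_max)
    checks.append(constraints.product_min <= pair.product_size <= constraints.product_max)
    tm_f = melting_temperature(pair.forward, na_mM=na_mM, oligo_nM=oligo_nM)
    tm_r = melting_temperature(pair.reverse, na_mM=na_mM, oligo_nM=oligo_nM)
    checks.append(abs(tm_f - tm_r) <= constraints.max_tm_diff)
    checks.append(pair.product_size == pair.rev_end - pair.fwd_start + 1)
    return all(checks)


def design_primers(
    template: str,
    constraints: PrimerConstraints = PrimerConstraints(),
    max_pairs: int = 5,
    template_id: str = "template",
    na_mM: float = 50.0,
    oligo_nM: float = 500.0,
) -> List[PrimerPair]:
    """Enumerate and rank primer pairs on a template.

    All windows on both strands satisfying the per-primer constraints are
    paired under the product-size and delta-Tm constraints, ranked by
    sum |Tm - Tm midrange| then |product - product midrange|, and the top
    ``max_pairs`` returned in deterministic order.  A template shorter than
    the minimum product size yields an empty list.
    """
    template = validate_sequence(template)
    n = len(template)
    if n < constraints.product_min:
        return []
    tm_mid = 0.5 * (constraints.tm_min + constraints.tm_max)
    prod_mid = 0.5 * (constraints.product_min + constraints.product_max)

    # valid windows per length: a window serves as forward primer (its own
    # sequence) or reverse primer (reverse complement); the duplex Tm and GC
    # are identical in both roles.
    starts_list, lens_list, tms_list = [], [], []
    for length in range(constraints.length_min, constraints.length_max + 1):
        tm, gc = _window_thermo(template, length, na_mM, oligo_nM)
        if tm.size == 0:
            continue
        ok = (
            (tm >= constraints.tm_min)
            & (tm <= constraints.tm_max)
            & (gc >= constraints.gc_min)
            & (gc <= constraints.gc_max)
        )
        idx = np.nonzero(ok)[0]
        starts_list.append(idx)
        lens_list.append(np.full(idx.size, length))
        tms_list.append(tm[idx])
    if not starts_list:
        return []
    w_start = np.concatenate(starts_list)  # 0-based window start
    w_len = np.concatenate(lens_list)
    w_tm = np.concatenate(tms_list)
    w_end = w_start + w_len - 1

    # pair forward windows with reverse windows; product spans fwd_start..rev_end
    order = np.lexsort((w_len, w_start))
    w_start, w_len, w_tm, w_end = (a[order] for a in (w_start, w_len, w_tm, w_end))
    best: List[tuple] = []
    nf = w_start.size
    chunk = 512
    for lo in range(0, nf, chunk):
        hi = min(lo + chunk, nf)
        fs = w_start[lo:hi, None]
        ftm = w_tm[lo:hi, None]
        product = w_end[None, :] - fs + 1
        ok = (
            (product >= constraints.product_min)
            & (product <= constraints.product_max)
            & (np.abs(w_tm[None, :] - ftm) <= constraints.max_tm_diff)
        )
        fi, ri = np.nonzero(ok)
        if fi.size == 0:
            continue
        fi_g = fi + lo
        score1 = np.abs(w_tm[fi_g] - tm_mid) + np.abs(w_tm[ri] - tm_mid)
        score2 = np.abs(product[fi, ri] - prod_mid)
        for k in range(fi.size):
            key = (
                float(score1[k]),
                float(score2[k]),
                int(w_start[fi_g[k]]),
                int(w_end[ri[k]]),
                int(w_len[fi_g[k]]),
                int(w_len[ri[k]]),
            )
            # keep extra candidates: the vectorised Tm assumes x=4, so the
            # rare self-complementary window is re-audited with the exact
            # scalar model below and may be discarded
            keep = 4 * max_pairs
            if len(best) < keep:
                best.append(key)
                best.sort()
            elif key < best[-1]:
                best[-1] = key
                best.sort()
    pairs: List[PrimerPair] = []
    for _, _, fstart, rend, flen, rlen in best:
        if len(pairs) >= max_pairs:
            break
        fwd = template[fstart : fstart + flen]
        rev_window = template[rend - rlen + 1 : rend + 1]
        rev = revcomp(rev_window)
        rank = len(pairs) + 1
        candidate = PrimerPair(
                marker_id=f"{template_id}_p{rank}",
                forward=fwd,
                reverse=rev,
                tm_forward=melting_temperature(fwd, na_mM=na_mM, oligo_nM=oligo_nM),
                tm_reverse=melting_temperature(rev, na_mM=na_mM, oligo_nM=oligo_nM),
                gc_forward=gc_content(fwd),
                gc_reverse=gc_content(rev),
                product_size=rend - fstart + 1,
                template_id=template_id,
                fwd_start=fstart + 1,
                rev_end=rend + 1,
            )
        if audit_primer_pair(candidate, constraints, na_mM=na_mM, oligo_nM=oligo_nM):
            pairs.append(candidate)
    return pairs


# ---------------------------------------------------------------------------
# in-silico PCR

def _binding_sites(primer_codes: np.ndarray, chrom_codes: np.ndarray,
                   max_mismatch: int, clamp: int, three_prime_last: bool):
    """Start positions (0-based) and mismatch counts of primer binding sites.

    ``three_prime_last=True``: the primer's 3' end maps to the window's last
    base (right-extending site on this strand); False: the window holds the
    reverse complement of the primer, 3' end at the window's first base.
    The clamp region must match exactly; candidate sites are pre-filtered on
    the clamp before full mismatch counting.
    """
    L = primer_codes.size
    n = chrom_codes.size
    if n < L:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    win = np.lib.stride_tricks.sliding_window_view(chrom_codes, L)
    if three_prime_last:
        clamp_codes = primer_codes[L - clamp :]
        clamp_win = win[:, L - clamp :]
    else:
        clamp_codes = primer_codes[:clamp]
        clamp_win = win[:, :clamp]
    cand = np.nonzero((clamp_win == clamp_codes).all(axis=1))[0]
    if cand.size == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    mism = (win[cand] != primer_codes).sum(axis=1)
    ok = mism <= max_mismatch
    return cand[ok].astype(np.int64), mism[ok].astype(np.int64)


def in_silico_pcr(
    pair: PrimerPair,
    genome: Mapping[str, str],
    genome_name: str = "",
    max_mismatch: int = 2,
    three_prime_clamp: int = 5,
    max_amplicon: int = 2000,
) -> List[Amplicon]:
    """Predict amplicons of a primer pair on one genome collection.

    A site tolerates at most ``max_mismatch`` mismatches with a perfect
    3'-terminal clamp.  Amplicons arise between a plus-strand (right
    extending) site of one primer and a downstream minus-strand (left
    extending) site of the other, within ``max_amplicon``; both primer
    orientations are considered, and the reported strand is the one carrying
    the forward primer's extending site.
    """
    f_codes = encode(pair.forward)
    r_codes = encode(pair.reverse)
    amplicons: List[Amplicon] = []
    for chrom, seq in genome.items():
        codes = encode(seq)
        sites = {}
        for name, pc in (("F", f_codes), ("R", r_codes)):
            # plus: primer sequence matches the + strand, extends rightward
            plus_pos, plus_mm = _binding_sites(
                pc, codes, max_mismatch, three_prime_clamp, three_prime_last=True
            )
            # minus: reverse complement of primer matches the + strand,
            # primer binds + strand and extends leftward
            rc = np.where(pc < 4, 3 - pc, 4).astype(np.uint8)[::-1]
            minus_pos, minus_mm = _binding_sites(
                rc, codes, max_mismatch, three_prime_clamp, three_prime_last=False
            )
            sites[name] = {
                "+": (plus_pos, plus_mm, pc.size),
                "-": (minus_pos, minus_mm, pc.size),
            }
        for left, right, strand in (("F", "R", "+"), ("R", "F", "-")):
            lpos, lmm, llen = sites[left]["+"]
            rpos, rmm, rlen = sites[right]["-"]
            for a, ma in zip(lpos, lmm):
                for b, mb in zip(rpos, rmm):
                    start = int(a)
                    end = int(b) + rlen - 1
                    size = end - start + 1
                    if b >= a and llen + rlen <= size <= max_amplicon:
                        mmf = int(ma) if left == "F" else int(mb)
                        mmr = int(mb) if left == "F" else int(ma)
                        amplicons.append(
                            Amplicon(
                                genome=genome_name,
                                chrom=chrom,
                                start=start + 1,
                                end=end + 1,
                                strand=strand,
                                mismatch_forward=mmf,
                                mismatch_reverse=mmr,
                            )
                        )
    amplicons.sort(key=lambda a: (a.chrom, a.start, a.end, a.strand))
    return amplicons


# ---------------------------------------------------------------------------
# classification

PANEL_ROLES = ("recipient", "donor", "donor_derived", "relative")


def classify_marker(
    marker_id: str,
    pattern: Mapping[str, bool],
    roles: Mapping[str, str],
) -> MarkerClass:
    """Classify a marker from its band pattern over the validation panel.

    donor_specific: bands only in the donor and donor-derived lines;
    non_specific: any band in a recipient cultivar; transferable: bands also
    in other relatives but not in the recipient; failed: no band anywhere.
    Every panel member must appear in the pattern.
    """
    missing = set(roles) - set(pattern)
    if missing:
        raise ValueError(f"pattern lacks panel members {sorted(missing)}")
    unknown_roles = set(roles.values()) - set(PANEL_ROLES)
    if unknown_roles:
        raise ValueError(f"unknown panel roles {sorted(unknown_roles)}")
    banded_roles = {roles[m] for m in roles if pattern[m]}
    if not banded_roles:
        cls = "failed"
    elif "recipient" in banded_roles:
        cls = "non_specific"
    elif "relative" in banded_roles:
        cls = "transferable"
    else:
        cls = "donor_specific"
    return MarkerClass(marker_id=marker_id, pattern={m: bool(pattern[m]) for m in roles}, marker_class=cls)
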