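"""Per-chromosome SNP-array statistics and substitution-chromosome calling.

A disomic alien substitution leaves a characteristic array signature: on the
replaced wheat chromosome the line's probes no longer see their intended
target, so the missing-call and heterozygous-call rates jump, while the
residual calls track the alien donor rather than the wheat parent.  The
caller quantifies this as a robust z-score on (miss + het) per chromosome
and requires the anomalous chromosome to also maximise allele sharing with
the donor before reporting a confident call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

CALLS = ("AA", "BB", "AB", "NoCall")

#: chromosomes with fewer informative loci are excluded from the z-score
#: reference distribution (variance control on small simulated maps)
MIN_INFORMATIVE_LOCI = 10


@dataclass
class GenotypeMatrix:
    """Locus x sample genotype calls plus the locus map.

    ``loci``: DataFrame indexed by locus_id with columns chrom, pos_bp
    (positions 1-based inclusive).  ``calls``: DataFrame indexed by locus_id,
    one column per sample, values in {AA, BB, AB, NoCall}.  ``qc``: optional
    per-sample metrics (dqc, call_rate as a percentage).
    """

    loci: pd.DataFrame
    calls: pd.DataFrame
    qc: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if not self.loci.index.equals(self.calls.index):
            raise ValueError("loci and calls must share the same locus index")
        bad = set(np.unique(self.calls.to_numpy())) - set(CALLS)
        if bad:
            raise ValueError(f"illegal genotype symbols {sorted(bad)}; allowed: {CALLS}")
        if (self.loci["pos_bp"] < 0).any():
            raise ValueError("positions must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.calls.columns)


@dataclass
class SubstitutionCall:
    """Outcome of the substituted-chromosome call.

    ``evidence`` holds the per-chromosome robust z-scores of (miss + het);
    ``donor_sharing_rank`` is the 1-based rank of the called chromosome by
    shared-allele fraction with the donor (1 = maximum).  ``confident`` is
    true only when the anomaly z exceeds the threshold and the same
    chromosome maximises donor sharing.
    """

    substituted_chromosome: Optional[str]
    evidence: pd.Series
    donor_sharing_rank: Optional[int]
    confident: bool


def qc_filter(
    matrix: GenotypeMatrix, dqc_min: float = 0.82, cr_min: float = 90.0
) -> GenotypeMatrix:
    """Drop samples failing the dish-QC / call-rate thresholds (inclusive >=).

    When the matrix carries no QC metrics the filter is a no-op (identity
    transform).  Removing every sample is an error.
    """
    if matrix.qc is None:
        return matrix
    qc = matrix.qc
    keep = [
        s
        for s in matrix.samples
        if qc.loc[s, "dqc"] >= dqc_min and qc.loc[s, "call_rate"] >= cr_min
    ]
    if not keep:
        raise ValueError("QC filter removed every sample")
    return GenotypeMatrix(loci=matrix.loci, calls=matrix.calls[keep], qc=qc.loc[keep])


def chromosome_snp_summary(matrix: GenotypeMatrix, sample: str) -> pd.DataFrame:
    """Per-chromosome miss / het / hom call rates for one sample.

    miss = NoCall fraction, het = AB fraction, hom = AA+BB fraction, each
    over that chromosome's loci, so the three rates sum to 1.  Chromosomes
    present in the locus map with zero loci would be undefined; they cannot
    arise from a groupby, but zero-locus chromosomes passed explicitly in
    the map are reported as NaN rows by reindexing.
    """
    if sample not in matrix.calls.columns:
        raise KeyError(f"unknown sample {sample!r}")
    calls = matrix.calls[sample]
    chrom = matrix.loci["chrom"]
    df = pd.DataFrame({"chrom": chrom, "call": calls})
    grouped = df.groupby("chrom", sort=True)["call"]
    n_loci = grouped.size()
    miss = grouped.apply(lambda c: (c == "NoCall").mean())
    het = grouped.apply(lambda c: (c == "AB").mean())
    out = pd.DataFrame(
        {
            "miss_rate": miss,
            "het_rate": het,
            "hom_rate": 1.0 - miss - het,
            "n_loci": n_loci,
        }
    )
    out.index.name = "chrom"
    return out


def shared_locus_fraction(
    matrix: GenotypeMatrix, sample_a: str, sample_b: str
) -> pd.Series:
    """Per-chromosome fraction of co-called loci with identical calls.

    Denominator: loci where both samples have a non-NoCall call.  A
    chromosome with zero co-called loci is reported as NaN (undefined).
    """
    for s in (sample_a, sample_b):
        if s not in matrix.calls.columns:
            raise KeyError(f"unknown sample {s!r}")
    a = matrix.calls[sample_a]
    b = matrix.calls[sample_b]
    co = (a != "NoCall") & (b != "NoCall")
    same = co & (a == b)
    df = pd.DataFrame({"chrom": matrix.loci["chrom"], "co": co, "same": same})
    g = df.groupby("chrom", sort=True).sum(numeric_only=False)
    frac = g["same"] / g["co"]
    frac.name = f"shared_{sample_a}_{sample_b}"
    return frac.astype(float)


def call_substitution(
    summary_line: pd.DataFrame,
    shared_with_donor: pd.Series,
    shared_with_parent: pd.Series,
    z_threshold: float = 3.0,
    min_loci: int = MIN_INFORMATIVE_LOCI,
) -> SubstitutionCall:
    """Call the substituted chromosome from array statistics.

    The anomaly score per chromosome is s = miss_rate + het_rate; it is
    z-scored against a robust location/scale (median and scaled MAD) over
    chromosomes with at least ``min_loci`` informative loci.  The call is
    confident only when the top chromosome exceeds ``z_threshold`` and also
    maximises the shared-allele fraction with the donor.
    """
    eligible = summary_line[summary_line["n_loci"] >= min_loci].dropna(
        subset=["miss_rate", "het_rate"]
    )
    if len(eligible) < 3:
        raise ValueError("need >= 3 chromosomes with defined rates")
    s = eligible["miss_rate"] + eligible["het_rate"]
    med = float(s.median())
    mad = float((s - med).abs().median())
    scale = 1.4826 * mad
    if scale == 0.0:
        if s.nunique() == 1:
            return SubstitutionCall(
                substituted_chromosome=None,
                evidence=pd.Series(0.0, index=s.index),
                donor_sharing_rank=None,
                confident=False,
            )
        # degenerate MAD with unequal scores: fall back to the standard deviation
        scale = float(s.std(ddof=0))
    z = (s - med) / scale
    cand = str(z.idxmax())
    sharing = shared_with_donor.reindex(z.index).dropna()
    rank = None
    if cand in sharing.index:
        rank = int((sharing > sharing[cand]).sum()) + 1
    confident = bool(z[cand] > z_threshold and rank == 1)
    return SubstitutionCall(
        substituted_chromosome=cand,
        evidence=z,
        donor_sharing_rank=rank,
        confident=confident,
    )
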