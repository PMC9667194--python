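"""Capture-probe depth normalisation and chromosome presence/absence calling.

In genotyping-by-target-sequencing, per-probe depth reads out chromosome
dosage: probes targeting a chromosome that is absent from the sample collapse
to an off-target residual, while probes for an introgressed alien chromosome
become enriched.  Depths are normalised to the median depth over wheat-probe
targets, each chromosome's median normalised depth is thresholded into
present / absent / ambiguous, and the (missing wheat, enriched alien) pair
is reported when the two group labels agree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from ._seq import parse_chrom
from .config import DONOR_TAG


@dataclass
class ProbeDepthTable:
    """Per-probe sequencing depths for one sample.

    ``table`` columns: probe_id, target_chrom, depth (non-negative).
    Chromosome labels must parse as group + genome tag; alien targets carry
    the donor tag (default "Ns").
    """

    table: pd.DataFrame
    sample: str
    alien_tag: str = DONOR_TAG

    def __post_init__(self) -> None:
        required = {"probe_id", "target_chrom", "depth"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"probe table lacks columns {sorted(missing)}")
        if (self.table["depth"] < 0).any():
            raise ValueError("depths must be non-negative")
        for chrom in self.table["target_chrom"].unique():
            parse_chrom(chrom)  # reject unparsable labels at load

    def is_alien(self, chrom: str) -> bool:
        return parse_chrom(chrom)[1] == self.alien_tag


@dataclass
class EnrichmentCall:
    """Per-chromosome presence statuses and the inferred substitution pair.

    ``pair`` is (missing wheat chromosome, enriched alien chromosome) when
    exactly one wheat chromosome is absent, at least one alien chromosome is
    present, and their homoeologous-group numbers match; otherwise None.
    """

    status: pd.Series  # chrom -> {"present", "absent", "ambiguous"}
    median_norm_depth: pd.Series
    pair: Optional[tuple[str, str]]
    normalization_factor: float


def normalize_depth(pdt: ProbeDepthTable) -> tuple[ProbeDepthTable, float]:
    """Divide depths by the median positive depth over wheat-chromosome probes.

    Returns the normalised table and the normalisation factor.  All-zero
    depth tables are an error (nothing was sequenced).
    """
    t = pdt.table
    if len(t) == 0:
        raise ValueError("empty probe table")
    wheat = t[~t["target_chrom"].map(pdt.is_alien)]
    positive = wheat.loc[wheat["depth"] > 0, "depth"]
    if positive.empty:
        raise ValueError("all wheat-probe depths are zero; cannot normalise")
    factor = float(positive.median())
    out = t.copy()
    out["depth"] = out["depth"] / factor
    return ProbeDepthTable(table=out, sample=pdt.sample, alien_tag=pdt.alien_tag), factor


def chromosome_presence(
    pdt: ProbeDepthTable,
    absent_max: float = 0.1,
    present_min: float = 0.5,
    normalized: bool = False,
) -> EnrichmentCall:
    """Call per-chromosome presence from (normalised) probe depths.

    Median normalised depth m per chromosome: absent if m < absent_max,
    present if m > present_min, ambiguous otherwise.  Chromosomes with zero
    probes are ambiguous (with a warning).  ``normalized=False`` runs
    :func:`normalize_depth` first.
    """
    factor = 1.0
    if not normalized:
        pdt, factor = normalize_depth(pdt)
    med = pdt.table.groupby("target_chrom", sort=False)["depth"].median()
    med = med.reindex(sorted(med.index, key=parse_chrom))
    empty = med.isna()
    if empty.any():
        warnings.warn(
            f"chromosomes without probes treated as ambiguous: {list(med.index[empty])}"
        )
    status = pd.Series("ambiguous", index=med.index, dtype=object)
    status[med < absent_max] = "absent"
    status[med > present_min] = "present"
    wheat_absent = [c for c in status.index if status[c] == "absent" and not pdt.is_alien(c)]
    alien_present = [c for c in status.index if status[c] == "present" and pdt.is_alien(c)]
    pair = None
    if len(wheat_absent) == 1 and alien_present:
        missing = wheat_absent[0]
        group = parse_chrom(missing)[0]
        matching = [c for c in alien_present if parse_chrom(c)[0] == group]
        if matching:
            # several matching alien homoeologues cannot arise from one donor
            # group; break ties by depth for robustness
            enriched = max(matching, key=lambda c: (med[c], c))
            pair = (missing, enriched)
    return EnrichmentCall(
        status=status, median_norm_depth=med, pair=pair, normalization_factor=factor
    )
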