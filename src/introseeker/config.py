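"""Simulation configuration for synthetic substitution-line datasets.

The defaults describe a desk-scale hexaploid recipient (21 chromosome pairs,
subgenomes A/B/D), a diploid-like Ns-genome donor (7 chromosome pairs), and a
disomic substitution line in which one recipient pair (4D by default) is
replaced by the donor homoeologue (4Ns).  Chromosomes are simulated at 50 kb;
every downstream rule is length-free, so the small scale only affects runtime.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import yaml

from ._seq import parse_chrom

#: genome tag used for donor (alien) chromosomes, e.g. "4Ns"
DONOR_TAG = "Ns"


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic substitution-line generator.

    Rates are per-site probabilities in [0, 1]; lengths are in bp; depths in
    read counts.  A fixed ``seed`` makes every generator output byte-identical.
    """

    seed: int = 0
    n_groups: int = 7
    recipient_subgenomes: Sequence[str] = ("A", "B", "D")
    chrom_length: int = 50_000
    substituted_chrom: str = "4D"
    donor_group: int = 4
    snp_per_chrom: int = 200
    probe_per_chrom: int = 100
    n_transcripts_per_chrom: int = 20
    n_replicates: int = 3

    # sequence divergence
    #: recipient vs donor homoeologue divergence; kept above the ~50% identity
    #: local-alignment extension threshold so that donor transcripts fall below
    #: the 50%-identity criterion against the recipient reference.
    divergence_recipient_donor: float = 0.60
    divergence_within_homoeologues: float = 0.03
    #: related-species panel genomes, derived from the donor at this divergence
    related_genomes: Sequence[str] = ("H", "R", "E", "S")
    related_divergence: float = 0.25
    #: donor-proxy reference genome (criterion-III target), near-identical donor
    proxy_divergence: float = 0.02
    indel_rate: float = 0.0  # optional aligner stress knob, off by default

    # SNP array model
    array_error_rate: float = 0.01
    line_sub_nocall: float = 0.50
    line_sub_het: float = 0.17
    donor_nocall_rate: float = 0.50
    donor_background_share: float = 0.35

    # capture-depth model (negative binomial)
    depth_mean: float = 30.0
    depth_dispersion: float = 0.2
    residual_fraction: float = 0.02

    # transcript count model (negative binomial around per-transcript means)
    count_dispersion: float = 0.05
    expr_mean_low: float = 50.0
    expr_mean_high: float = 500.0
    transcript_len_min: int = 300
    transcript_len_max: int = 1500

    def __post_init__(self) -> None:
        rates = {
            "divergence_recipient_donor": self.divergence_recipient_donor,
            "divergence_within_homoeologues": self.divergence_within_homoeologues,
            "related_divergence": self.related_divergence,
            "proxy_divergence": self.proxy_divergence,
            "array_error_rate": self.array_error_rate,
            "line_sub_nocall": self.line_sub_nocall,
            "line_sub_het": self.line_sub_het,
            "donor_nocall_rate": self.donor_nocall_rate,
            "donor_background_share": self.donor_background_share,
            "residual_fraction": self.residual_fraction,
            "indel_rate": self.indel_rate,
        }
        for name, value in rates.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.line_sub_nocall + self.line_sub_het > 1.0:
            raise ValueError("line_sub_nocall + line_sub_het must not exceed 1")
        counts = {
            "n_groups": self.n_groups,
            "chrom_length": self.chrom_length,
            "snp_per_chrom": self.snp_per_chrom,
            "probe_per_chrom": self.probe_per_chrom,
            "n_transcripts_per_chrom": self.n_transcripts_per_chrom,
            "n_replicates": self.n_replicates,
            "transcript_len_min": self.transcript_len_min,
            "transcript_len_max": self.transcript_len_max,
        }
        for name, value in counts.items():
            if value < 1:
                raise ValueError(f"{name} must be >= 1, got {value}")
        if self.depth_mean <= 0 or self.depth_dispersion <= 0:
            raise ValueError("depth_mean and depth_dispersion must be positive")
        if self.count_dispersion <= 0:
            raise ValueError("count_dispersion must be positive")
        if not 0 < self.expr_mean_low <= self.expr_mean_high:
            raise ValueError("require 0 < expr_mean_low <= expr_mean_high")
        if self.transcript_len_min > self.transcript_len_max:
            raise ValueError("transcript_len_min must not exceed transcript_len_max")
        group, tag = parse_chrom(self.substituted_chrom)
        if tag not in self.recipient_subgenomes:
            raise ValueError(
                f"substituted_chrom {self.substituted_chrom!r} is not in the "
                f"recipient subgenomes {tuple(self.recipient_subgenomes)}"
            )
        if not 1 <= group <= self.n_groups:
            raise ValueError("substituted_chrom group outside 1..n_groups")
        if not 1 <= self.donor_group <= self.n_groups:
            raise ValueError("donor_group outside 1..n_groups")
        if self.snp_per_chrom > self.chrom_length or self.probe_per_chrom > self.chrom_length:
            raise ValueError("cannot place more loci/probes than chromosome sites")

    @property
    def donor_chrom(self) -> str:
        return f"{self.donor_group}{DONOR_TAG}"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["recipient_subgenomes"] = list(self.recipient_subgenomes)
        d["related_genomes"] = list(self.related_genomes)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "recipient_subgenomes" in data:
            data["recipient_subgenomes"] = tuple(data["recipient_subgenomes"])
        if "related_genomes" in data:
            data["related_genomes"] = tuple(data["related_genomes"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
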