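"""Seeded synthetic substitution-line datasets.

Generates, at desk scale, every input the downstream stages consume: a
hexaploid recipient genome (n_groups x subgenomes chromosomes, e.g. 1A..7D),
a diploid-like donor genome (1Ns..7Ns), the substitution line in which one
recipient pair is replaced by the donor homoeologue, SNP-array genotype
calls with the substitution signature (inflated missing/heterozygous calls
on the substituted chromosome), capture-probe depths (collapsed on the
missing wheat chromosome, enriched on the donor chromosome), replicated
transcript counts in which donor transcripts are silent in the parent, a
reference-genome panel for homology filtering, and simple phenotype tables.

All outputs are deterministic functions of ``SimConfig.seed``; each stage
draws from its own child stream so that changing one stage's parameters
does not perturb the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping

import json

import numpy as np
import pandas as pd

from ._seq import mutate, parse_chrom, random_seq, sorted_chroms, write_fasta
from .config import DONOR_TAG, SimConfig
from .array_caller import CALLS, GenotypeMatrix
from .capture_enrichment import ProbeDepthTable
from .alien_transcript_filter import GenomePanel, TranscriptSet

# stage identifiers for child RNG streams
_STREAMS = {"genomes": 1, "array": 2, "capture": 3, "transcripts": 4, "panel": 5, "pheno": 6}

#: panel letter of the hexaploid recipient reference
RECIPIENT_LETTER = "W"
#: panel letter of the donor-proxy reference (criterion-III target)
PROXY_LETTER = "Ns"


def _rng(config: SimConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((config.seed, _STREAMS[stage])))


def _nb_draw(rng: np.random.Generator, mean, dispersion: float, size=None) -> np.ndarray:
    """Negative-binomial draws parameterised by mean and dispersion.

    var = mean + dispersion * mean^2; mean 0 yields exact zeros.
    """
    mean = np.asarray(mean, dtype=float)
    n = 1.0 / dispersion
    out = np.zeros(np.broadcast_shapes(mean.shape if mean.shape else (1,),
                                       (size,) if isinstance(size, int) else (size or mean.shape)),
                   dtype=np.int64)
    m = np.broadcast_to(mean, out.shape)
    pos = m > 0
    if pos.any():
        p = n / (n + m[pos])
        out[pos] = rng.negative_binomial(n, p)
    return out


# ---------------------------------------------------------------------------
# genomes

def simulate_genomes(config: SimConfig) -> tuple[Dict[str, str], Dict[str, str]]:
    """Simulate recipient and donor genomes as chromosome label -> sequence.

    Each homoeologous group descends from a random group ancestor; recipient
    subgenome copies diverge from it at ``divergence_within_homoeologues``,
    and each donor chromosome is a point-mutated copy (at
    ``divergence_recipient_donor``) of the recipient chromosome carrying the
    substituted subgenome letter.
    """
    rng = _rng(config, "genomes")
    _, sub_letter = parse_chrom(config.substituted_chrom)
    recipient: Dict[str, str] = {}
    donor: Dict[str, str] = {}
    for group in range(1, config.n_groups + 1):
        ancestor = random_seq(rng, config.chrom_length)
        for letter in config.recipient_subgenomes:
            recipient[f"{group}{letter}"] = mutate(
                ancestor, config.divergence_within_homoeologues, rng
            )
        donor[f"{group}{DONOR_TAG}"] = mutate(
            recipient[f"{group}{sub_letter}"], config.divergence_recipient_donor, rng
        )
    return recipient, donor


def simulate_substitution_line(
    recipient: Mapping[str, str], donor: Mapping[str, str], config: SimConfig
) -> Dict[str, str]:
    """Replace the substituted recipient chromosome pair by the donor homoeologue."""
    if config.substituted_chrom not in recipient:
        raise KeyError(f"unknown recipient chromosome {config.substituted_chrom!r}")
    if config.donor_chrom not in donor:
        raise KeyError(f"donor has no chromosome {config.donor_chrom!r}")
    line = {k: v for k, v in recipient.items() if k != config.substituted_chrom}
    line[config.donor_chrom] = donor[config.donor_chrom]
    return dict(sorted(line.items(), key=lambda kv: parse_chrom(kv[0])))


def simulate_panel(
    recipient: Mapping[str, str], donor: Mapping[str, str], config: SimConfig
) -> GenomePanel:
    """Build the reference-genome panel used by the homology criteria.

    * ``W`` - the hexaploid recipient reference itself (criterion II target);
    * ``Ns`` - donor proxy at ``proxy_divergence`` from the donor
      (criterion III target);
    * one genome per ``related_genomes`` letter, each chromosome derived from
      the donor group-mate at ``related_divergence`` - close enough for
      full-coverage local alignment, so group homoeology is detectable;
    * diploid stand-ins for each recipient subgenome letter (A/B/D), copies
      of the corresponding recipient chromosomes.
    """
    rng = _rng(config, "panel")
    genomes: Dict[str, Dict[str, str]] = {RECIPIENT_LETTER: dict(recipient)}
    genomes[PROXY_LETTER] = {
        c: mutate(s, config.proxy_divergence, rng) for c, s in sorted(donor.items())
    }
    for letter in config.related_genomes:
        genomes[letter] = {
            f"{parse_chrom(c)[0]}{letter}": mutate(s, config.related_divergence, rng)
            for c, s in sorted(donor.items())
        }
    for letter in config.recipient_subgenomes:
        genomes[letter] = {
            c: s for c, s in recipient.items() if parse_chrom(c)[1] == letter
        }
    return GenomePanel(
        genomes=genomes, recipient=RECIPIENT_LETTER, donor_proxy=PROXY_LETTER
    )


# ---------------------------------------------------------------------------
# SNP array

def simulate_array(
    recipient: Mapping[str, str],
    donor: Mapping[str, str],
    line: Mapping[str, str],
    config: SimConfig,
) -> GenotypeMatrix:
    """Simulate SNP-array genotype calls for parent, donor and line samples.

    Parent calls are homozygous with NoCall rate ``array_error_rate``.  The
    donor is called at a reduced rate (``donor_nocall_rate``) and matches the
    parent allele at ``donor_background_share`` of loci.  On chromosomes the
    line shares with the parent its calls copy the parent's (plus errors); on
    the substituted chromosome they are drawn from the inflated
    NoCall/heterozygous mixture and the residual homozygous calls copy the
    donor genotype (the alien homoeologue is what hybridises to those probes).
    """
    rng = _rng(config, "array")
    substituted = set(recipient) - set(line)
    loci_rows: List[tuple] = []
    call_cols: Dict[str, List[str]] = {"parent": [], "donor": [], "line": []}
    for chrom in sorted_chroms(recipient):
        pos = np.sort(
            rng.choice(config.chrom_length, size=config.snp_per_chrom, replace=False)
        ) + 1  # 1-based inclusive positions
        n = config.snp_per_chrom
        parent_allele = rng.integers(0, 2, size=n)  # 0 = AA, 1 = BB
        parent_miss = rng.random(n) < config.array_error_rate
        donor_miss = rng.random(n) < config.donor_nocall_rate
        donor_matches = rng.random(n) < config.donor_background_share
        donor_allele = np.where(donor_matches, parent_allele, 1 - parent_allele)
        if chrom in substituted:
            u = rng.random(n)
            line_nocall = u < config.line_sub_nocall
            line_het = (~line_nocall) & (u < config.line_sub_nocall + config.line_sub_het)
            fallback = rng.integers(0, 2, size=n)
            line_allele = np.where(donor_miss, fallback, donor_allele)
        else:
            line_nocall = rng.random(n) < config.array_error_rate
            line_het = np.zeros(n, dtype=bool)
            line_allele = parent_allele
        hom = {0: "AA", 1: "BB"}
        for i in range(n):
            locus_id = f"AX_{chrom}_{i:04d}"
            loci_rows.append((locus_id, chrom, int(pos[i])))
            call_cols["parent"].append("NoCall" if parent_miss[i] else hom[int(parent_allele[i])])
            call_cols["donor"].append("NoCall" if donor_miss[i] else hom[int(donor_allele[i])])
            if line_nocall[i]:
                call_cols["line"].append("NoCall")
            elif line_het[i]:
                call_cols["line"].append("AB")
            else:
                call_cols["line"].append(hom[int(line_allele[i])])
    loci = pd.DataFrame(loci_rows, columns=["locus_id", "chrom", "pos_bp"]).set_index("locus_id")
    calls = pd.DataFrame(call_cols, index=loci.index)
    call_rate = (100.0 * (calls != "NoCall").mean(axis=0)).round(2)
    # the platform's CR metric reflects chip quality, not biology: the donor's
    # cross-species NoCalls are real signal, so its reported CR stays above
    # threshold (as for the alien parent genotyped in the emulated study)
    call_rate["donor"] = max(call_rate["donor"], 92.0)
    qc = pd.DataFrame(
        {"dqc": [0.99, 0.95, 0.98], "call_rate": call_rate},
        index=calls.columns,
    )
    return GenotypeMatrix(loci=loci, calls=calls, qc=qc)


# ---------------------------------------------------------------------------
# capture depths

def simulate_capture(
    line: Mapping[str, str], parent: Mapping[str, str], config: SimConfig
) -> Dict[str, ProbeDepthTable]:
    """Simulate capture-probe depths for the line and parent samples.

    Probes target every wheat chromosome (the parent's) and every alien
    chromosome 1Ns..nNs.  Depth is negative-binomial with mean ``depth_mean``
    when the target chromosome is present in the sample and
    ``depth_mean * residual_fraction`` when absent (off-target residual).
    """
    rng = _rng(config, "capture")
    targets = sorted_chroms(parent) + [f"{g}{DONOR_TAG}" for g in range(1, config.n_groups + 1)]
    tables: Dict[str, ProbeDepthTable] = {}
    for sample, genome in (("line", line), ("parent", parent)):
        rows = []
        for chrom in targets:
            mean = config.depth_mean if chrom in genome else config.depth_mean * config.residual_fraction
            depths = _nb_draw(rng, np.full(config.probe_per_chrom, mean), config.depth_dispersion)
            for i, d in enumerate(depths):
                rows.append((f"PR_{chrom}_{i:04d}", chrom, int(d)))
        tables[sample] = ProbeDepthTable(
            table=pd.DataFrame(rows, columns=["probe_id", "target_chrom", "depth"]),
            sample=sample,
        )
    return tables


# ---------------------------------------------------------------------------
# transcripts

def simulate_transcripts(
    line: Mapping[str, str], parent: Mapping[str, str], config: SimConfig
) -> TranscriptSet:
    """Sample transcripts from the line genome with replicated NB counts.

    Each line chromosome contributes ``n_transcripts_per_chrom`` transcripts
    (subsequences of length transcript_len_min..transcript_len_max).  Counts
    are negative-binomial around per-transcript means drawn log-uniformly in
    [expr_mean_low, expr_mean_high]; transcripts from donor chromosomes (the
    label's genome tag, not present in the parent) get exact zero counts in
    every parent replicate.
    """
    rng = _rng(config, "transcripts")
    sequences: Dict[str, str] = {}
    chrom_of: Dict[str, str] = {}
    donor_ids: List[str] = []
    for chrom in sorted_chroms(line):
        seq = line[chrom]
        is_donor = chrom not in parent
        for i in range(config.n_transcripts_per_chrom):
            length = int(rng.integers(config.transcript_len_min, config.transcript_len_max + 1))
            length = min(length, len(seq))
            start = int(rng.integers(0, len(seq) - length + 1))
            tid = f"tx_{chrom}_{i:03d}"
            sequences[tid] = seq[start : start + length]
            chrom_of[tid] = chrom
            if is_donor:
                donor_ids.append(tid)
    ids = list(sequences)
    n_tx = len(ids)
    log_lo, log_hi = np.log10(config.expr_mean_low), np.log10(config.expr_mean_high)
    base_mean = 10 ** rng.uniform(log_lo, log_hi, size=n_tx)
    donor_mask = np.array([tid in set(donor_ids) for tid in ids])
    cols = [f"parent_r{r + 1}" for r in range(config.n_replicates)] + [
        f"line_r{r + 1}" for r in range(config.n_replicates)
    ]
    counts = np.zeros((n_tx, len(cols)), dtype=np.int64)
    for ci, col in enumerate(cols):
        mean = base_mean.copy()
        if col.startswith("parent"):
            mean[donor_mask] = 0.0
        counts[:, ci] = _nb_draw(rng, mean, config.count_dispersion)
    counts_df = pd.DataFrame(counts, index=pd.Index(ids, name="transcript_id"), columns=cols)
    lengths = pd.Series({tid: len(s) for tid, s in sequences.items()}, name="length_bp")
    return TranscriptSet(
        sequences=sequences,
        counts=counts_df,
        lengths=lengths,
        chrom_of=pd.Series(chrom_of, name="chrom"),
        sample_groups={"parent": cols[: config.n_replicates], "line": cols[config.n_replicates :]},
        donor_ids=tuple(donor_ids),
    )


# ---------------------------------------------------------------------------
# phenotypes

def simulate_phenotypes(config: SimConfig) -> Dict[str, pd.DataFrame]:
    """Simple phenotype tables: cytology counts, rust IT grades, FHB counts."""
    rng = _rng(config, "pheno")
    mitosis_total = int(rng.integers(150, 175))
    mitosis_euploid = int(rng.binomial(mitosis_total, 0.97))
    meiosis_total = int(rng.integers(100, 130))
    meiosis_bivalent = int(rng.binomial(meiosis_total, 0.94))
    cytology = pd.DataFrame(
        {
            "stage": ["mitosis_2n42", "meiosis_21II"],
            "numerator": [mitosis_euploid, meiosis_bivalent],
            "denominator": [mitosis_total, meiosis_total],
        }
    )
    it_resistant = ["0", "0;", "1"]
    it_susceptible = ["3", "4"]
    rust = pd.DataFrame(
        {
            "sample": ["line"] * 10 + ["parent"] * 10,
            "it_grade": list(rng.choice(it_resistant, size=10, p=[0.6, 0.2, 0.2]))
            + list(rng.choice(it_susceptible, size=10, p=[0.5, 0.5])),
        }
    )
    totals = rng.integers(18, 24, size=20)
    infected = np.concatenate(
        [rng.binomial(totals[:10], 0.05), rng.binomial(totals[10:], 0.45)]
    )
    fhb = pd.DataFrame(
        {
            "sample": ["line"] * 10 + ["parent"] * 10,
            "infected_spikelets": infected.astype(int),
            "total_spikelets": totals.astype(int),
        }
    )
    return {"cytology": cytology, "stripe_rust": rust, "fhb": fhb}


# ---------------------------------------------------------------------------
# bundle

@dataclass
class Truth:
    """Ground-truth record of a synthetic dataset."""

    substituted_chrom: str
    donor_chrom: str
    donor_transcripts: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "substituted_chrom": self.substituted_chrom,
            "donor_chrom": self.donor_chrom,
            "donor_transcripts": list(self.donor_transcripts),
        }


@dataclass
class SyntheticDataset:
    config: SimConfig
    recipient: Dict[str, str]
    donor: Dict[str, str]
    line: Dict[str, str]
    genotypes: GenotypeMatrix
    probe_depths: Dict[str, ProbeDepthTable]
    transcripts: TranscriptSet
    panel: GenomePanel
    phenotypes: Dict[str, pd.DataFrame] = field(default_factory=dict)
    truth: Truth | None = None


def make_dataset(config: SimConfig, with_panel: bool = True) -> SyntheticDataset:
    """Generate the full synthetic dataset for one configuration."""
    recipient, donor = simulate_genomes(config)
    line = simulate_substitution_line(recipient, donor, config)
    genotypes = simulate_array(recipient, donor, line, config)
    depths = simulate_capture(line, recipient, config)
    transcripts = simulate_transcripts(line, recipient, config)
    panel = simulate_panel(recipient, donor, config) if with_panel else GenomePanel(
        genomes={RECIPIENT_LETTER: dict(recipient), PROXY_LETTER: dict(donor)},
        recipient=RECIPIENT_LETTER,
        donor_proxy=PROXY_LETTER,
    )
    truth = Truth(
        substituted_chrom=config.substituted_chrom,
        donor_chrom=config.donor_chrom,
        donor_transcripts=transcripts.donor_ids,
    )
    return SyntheticDataset(
        config=config,
        recipient=recipient,
        donor=donor,
        line=line,
        genotypes=genotypes,
        probe_depths=depths,
        transcripts=transcripts,
        panel=panel,
        phenotypes=simulate_phenotypes(config),
        truth=truth,
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> None:
    """Write a dataset to disk as FASTA / TSV / JSON text files."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(out / "recipient.fa", ds.recipient)
    write_fasta(out / "donor.fa", ds.donor)
    write_fasta(out / "line.fa", ds.line)
    write_fasta(out / "transcripts.fa", ds.transcripts.sequences)
    geno = ds.genotypes.loci.join(ds.genotypes.calls).reset_index()
    geno.to_csv(out / "genotypes.tsv", sep="\t", index=False)
    if ds.genotypes.qc is not None:
        ds.genotypes.qc.rename_axis("sample").reset_index().to_csv(
            out / "genotype_qc.tsv", sep="\t", index=False
        )
    for sample, pdt in ds.probe_depths.items():
        pdt.table.to_csv(out / f"depths_{sample}.tsv", sep="\t", index=False)
    counts = ds.transcripts.counts.copy()
    counts.insert(0, "length_bp", ds.transcripts.lengths)
    counts.reset_index().to_csv(out / "counts.tsv", sep="\t", index=False)
    panel_dir = out / "panel"
    panel_dir.mkdir(exist_ok=True)
    manifest = {"recipient": ds.panel.recipient, "donor_proxy": ds.panel.donor_proxy, "genomes": {}}
    for letter, genome in ds.panel.genomes.items():
        write_fasta(panel_dir / f"{letter}.fa", genome)
        manifest["genomes"][letter] = {c: parse_chrom(c)[0] for c in sorted_chroms(genome)}
    with open(panel_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    for name, df in ds.phenotypes.items():
        df.to_csv(out / f"pheno_{name}.tsv", sep="\t", index=False)
    if ds.truth is not None:
        with open(out / "truth.json", "w") as fh:
            json.dump(ds.truth.to_dict(), fh, indent=2, sort_keys=True)
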