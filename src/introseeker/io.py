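"""Readers and writers for the package's tabular interchange formats.

Genotype TSV: locus_id, chrom, pos_bp, then one call column per sample.
Probe-depth TSV: probe_id, target_chrom, depth.  Counts TSV: transcript_id,
length_bp, then one column per sample replicate.  Panel: a directory of
FASTA files plus a manifest.json naming the recipient and donor-proxy
letters.  Positions are 1-based inclusive throughout.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional

import pandas as pd

from ._seq import read_fasta
from .array_caller import GenotypeMatrix
from .capture_enrichment import ProbeDepthTable
from .alien_transcript_filter import GenomePanel, TranscriptSet


def read_genotype_tsv(path: str | Path, qc_path: Optional[str | Path] = None) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"locus_id": str, "chrom": str})
    df = df.set_index("locus_id")
    loci = df[["chrom", "pos_bp"]]
    calls = df.drop(columns=["chrom", "pos_bp"])
    qc = None
    if qc_path is not None:
        qc = pd.read_csv(qc_path, sep="\t").set_index("sample")
    return GenotypeMatrix(loci=loci, calls=calls, qc=qc)


def write_genotype_tsv(matrix: GenotypeMatrix, path: str | Path) -> None:
    matrix.loci.join(matrix.calls).reset_index().to_csv(path, sep="\t", index=False)


def read_depth_tsv(path: str | Path, sample: str = "sample") -> ProbeDepthTable:
    table = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "target_chrom": str})
    return ProbeDepthTable(table=table, sample=sample)


def read_transcript_set(fasta_path: str | Path, counts_path: str | Path) -> TranscriptSet:
    sequences = read_fasta(fasta_path)
    df = pd.read_csv(counts_path, sep="\t").set_index("transcript_id")
    lengths = df["length_bp"]
    counts = df.drop(columns=["length_bp"])
    groups: Dict[str, list] = {}
    for col in counts.columns:
        sample = col.rsplit("_r", 1)[0]
        groups.setdefault(sample, []).append(col)
    return TranscriptSet(
        sequences=sequences, counts=counts, lengths=lengths, sample_groups=groups
    )


def read_panel(panel_dir: str | Path) -> GenomePanel:
    panel_dir = Path(panel_dir)
    with open(panel_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    genomes = {
        letter: read_fasta(panel_dir / f"{letter}.fa") for letter in manifest["genomes"]
    }
    return GenomePanel(
        genomes=genomes,
        recipient=manifest["recipient"],
        donor_proxy=manifest["donor_proxy"],
    )
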