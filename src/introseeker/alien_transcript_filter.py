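"""Expression filtering and homology-based selection of alien transcripts.

Candidate transcripts for an introgressed alien chromosome are those that
are (a) expressed in the substitution line but silent in the wheat parent,
(b) assignable to the target homoeologous group through a best hit in at
least one related-species genome, (c) poorly conserved in the wheat
reference (best-hit identity < 50%), and (d) well conserved in the donor
proxy reference (> 50%).  Identity here means best local-alignment percent
identity; hits covering less than ``min_coverage`` % of the query are
treated as no-hit (identity 0), since short spurious segments carry no
homology signal.

Differential expression is a deliberate stand-in for a negative-binomial
GLM pipeline: median-of-ratios size factors, log2 fold change of normalised
means with pseudocount 1, a Welch t-test on log2(normalised count + 1), and
Benjamini-Hochberg adjustment.  Only the presence/absence rule feeds the
candidate filter; the DE table serves the chromosome-distribution summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Collection, Dict, Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._seq import encode, parse_chrom, sorted_chroms, validate_sequence
from .alignment import EXACT_CELLS, KmerIndex, LocalAlignment, NO_HIT, align_local

# thresholds of the candidate-selection criteria
FPKM_PRESENT_MIN = 1.0
LOG2FC_MIN = 1.0
PADJ_MAX = 0.05
ID_MAX_RECIPIENT = 50.0  # criterion II: identity to wheat strictly below
ID_MIN_DONOR = 50.0  # criterion III: identity to donor proxy strictly above
MIN_QUERY_COVERAGE = 30.0  # coverage floor below which a hit is treated as no-hit


@dataclass
class TranscriptSet:
    """Transcript sequences with replicated counts.

    ``counts`` is transcript x replicate-column (e.g. parent_r1..line_r3);
    ``sample_groups`` maps sample name to its replicate columns.
    ``chrom_of`` (chromosome of origin) and ``donor_ids`` are available for
    synthetic data where the truth is known.
    """

    sequences: Dict[str, str]
    counts: pd.DataFrame
    lengths: pd.Series
    chrom_of: Optional[pd.Series] = None
    sample_groups: Optional[Dict[str, list[str]]] = None
    donor_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        for tid, seq in self.sequences.items():
            if self.lengths[tid] != len(seq):
                raise ValueError(f"length mismatch for {tid}")

    @property
    def fpkm(self) -> pd.DataFrame:
        return compute_fpkm(self.counts, self.lengths)


@dataclass
class GenomePanel:
    """Labelled reference genomes for the homology criteria.

    ``genomes`` maps a genome letter to its chromosome label -> sequence
    mapping; chromosome labels carry the homoeologous group as their leading
    integer.  ``recipient`` and ``donor_proxy`` name the criterion-II and
    criterion-III targets; every other letter is a related species
    (criterion I).
    """

    genomes: Dict[str, Dict[str, str]]
    recipient: str
    donor_proxy: str
    _indexes: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        for letter in (self.recipient, self.donor_proxy):
            if letter not in self.genomes:
                raise ValueError(f"panel lacks genome {letter!r}")
        for letter, genome in self.genomes.items():
            for chrom, seq in genome.items():
                group, _ = parse_chrom(chrom)
                if not 1 <= group <= 7:
                    raise ValueError(f"{letter}:{chrom}: group must be in 1..7")
                validate_sequence(seq)

    @property
    def related(self) -> list[str]:
        return [g for g in self.genomes if g not in (self.recipient, self.donor_proxy)]

    def index_for(self, letter: str, chrom: str, k: int) -> KmerIndex:
        key = (letter, chrom, k)
        if key not in self._indexes:
            self._indexes[key] = KmerIndex(encode(self.genomes[letter][chrom]), k)
        return self._indexes[key]


@dataclass(frozen=True)
class HomologyHit:
    """Best hit of one transcript in one genome."""

    transcript_id: str
    genome: str
    chrom: Optional[str]  # None = no hit
    identity: float  # percent, over aligned columns
    aligned_columns: int
    query_coverage: float  # percent of the query length
    score: int

    @property
    def group(self) -> Optional[int]:
        return parse_chrom(self.chrom)[0] if self.chrom else None


# ---------------------------------------------------------------------------
# expression

def compute_fpkm(
    counts: pd.DataFrame,
    lengths: pd.Series,
    library_sizes: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """FPKM = count * 1e9 / (length_bp * library_size), per replicate column.

    Library sizes default to the column sums of the count matrix.
    """
    lengths = lengths.reindex(counts.index)
    if (lengths <= 0).any():
        raise ValueError("transcript lengths must be positive")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    else:
        library_sizes = library_sizes.reindex(counts.columns)
    if (library_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    return counts.mul(1e9).div(lengths, axis=0).div(library_sizes, axis=1)


def presence_absence_filter(
    fpkm: pd.DataFrame,
    line_cols: Iterable[str],
    parent_cols: Iterable[str],
    present_min: float = FPKM_PRESENT_MIN,
    mode: str = "all",
) -> pd.Index:
    """Transcripts expressed in every line replicate and in no parent replicate.

    ``mode="all"`` (default): FPKM >= present_min in ALL line replicates and
    FPKM < present_min in ALL parent replicates.  ``mode="any"`` relaxes the
    line side to at least one replicate.
    """
    line_cols, parent_cols = list(line_cols), list(parent_cols)
    for col in line_cols + parent_cols:
        if col not in fpkm.columns:
            raise KeyError(f"unknown sample column {col!r}")
    line_ok = (
        (fpkm[line_cols] >= present_min).all(axis=1)
        if mode == "all"
        else (fpkm[line_cols] >= present_min).any(axis=1)
    )
    parent_silent = (fpkm[parent_cols] < present_min).all(axis=1)
    return fpkm.index[line_ok & parent_silent]


def benjamini_hochberg(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR control)."""
    p = np.asarray(list(pvalues), dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def _size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (geometric-mean reference)."""
    arr = counts.to_numpy(dtype=float)
    allpos = (arr > 0).all(axis=1)
    if not allpos.any():
        return pd.Series(1.0, index=counts.columns)
    logref = np.log(arr[allpos]).mean(axis=1)
    ratios = np.log(arr[allpos]) - logref[:, None]
    sf = np.exp(np.median(ratios, axis=0))
    return pd.Series(sf, index=counts.columns)


def differential_expression(
    counts: pd.DataFrame,
    group_a_cols: Iterable[str],
    group_b_cols: Iterable[str],
    lengths: Optional[pd.Series] = None,
    chrom_of: Optional[pd.Series] = None,
    log2fc_min: float = LOG2FC_MIN,
    padj_max: float = PADJ_MAX,
    fpkm_min: float = FPKM_PRESENT_MIN,
) -> pd.DataFrame:
    """Two-group differential expression table (group b relative to group a).

    Columns: mean_a, mean_b (normalised means), log2fc, pvalue, padj,
    status in {up, down, unchanged} (up = higher in b), plus fpkm_a/fpkm_b
    when lengths are given and chrom when annotations are given.  Transcripts
    with all-zero counts keep NaN p-values and status "unchanged".  Status
    up/down additionally requires mean FPKM >= fpkm_min in at least one
    group when FPKM is computable.
    """
    a_cols, b_cols = list(group_a_cols), list(group_b_cols)
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("need >= 2 replicates per group")
    sf = _size_factors(counts[a_cols + b_cols])
    norm = counts[a_cols + b_cols].div(sf, axis=1)
    mean_a = norm[a_cols].mean(axis=1)
    mean_b = norm[b_cols].mean(axis=1)
    log2fc = np.log2((mean_b + 1.0) / (mean_a + 1.0))
    la = np.log2(norm[a_cols].to_numpy() + 1.0)
    lb = np.log2(norm[b_cols].to_numpy() + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, pvals = stats.ttest_ind(lb, la, axis=1, equal_var=False)
    pvals = np.asarray(pvals)
    allzero = (counts[a_cols + b_cols] == 0).all(axis=1).to_numpy()
    pvals[allzero] = np.nan
    padj = np.full_like(pvals, np.nan)
    ok = ~np.isnan(pvals)
    if ok.any():
        padj[ok] = benjamini_hochberg(pvals[ok])
    out = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": log2fc,
            "pvalue": pvals,
            "padj": padj,
        },
        index=counts.index,
    )
    expressed = pd.Series(True, index=counts.index)
    if lengths is not None:
        fpkm = compute_fpkm(counts[a_cols + b_cols], lengths)
        out["fpkm_a"] = fpkm[a_cols].mean(axis=1)
        out["fpkm_b"] = fpkm[b_cols].mean(axis=1)
        expressed = (out["fpkm_a"] >= fpkm_min) | (out["fpkm_b"] >= fpkm_min)
    sig = expressed & (out["padj"] <= padj_max) & (out["log2fc"].abs() >= log2fc_min)
    out["status"] = "unchanged"
    out.loc[sig & (out["log2fc"] > 0), "status"] = "up"
    out.loc[sig & (out["log2fc"] < 0), "status"] = "down"
    if chrom_of is not None:
        out["chrom"] = chrom_of.reindex(out.index)
    return out


def deg_chromosome_distribution(de: pd.DataFrame) -> pd.DataFrame:
    """Per-chromosome counts and fractions of up/down regulated transcripts.

    Fractions are relative to the total number of up- (resp. down-)
    regulated transcripts.  Returns an empty frame when there are no DEGs.
    """
    if "chrom" not in de.columns:
        raise ValueError("DE table lacks chromosome annotations")
    degs = de[de["status"].isin(["up", "down"])]
    if degs.empty:
        return pd.DataFrame(columns=["n_up", "n_down", "frac_up", "frac_down"])
    tab = degs.pivot_table(
        index="chrom", columns="status", aggfunc="size", fill_value=0
    )
    n_up = tab.get("up", pd.Series(0, index=tab.index)).astype(int)
    n_down = tab.get("down", pd.Series(0, index=tab.index)).astype(int)
    out = pd.DataFrame({"n_up": n_up, "n_down": n_down})
    out["frac_up"] = out["n_up"] / out["n_up"].sum() if out["n_up"].sum() else 0.0
    out["frac_down"] = out["n_down"] / out["n_down"].sum() if out["n_down"].sum() else 0.0
    out = out.reindex(sorted_chroms(out.index))
    out.index.name = "chrom"
    return out


# ---------------------------------------------------------------------------
# homology

def local_identity(
    query: str, subject: str, min_seed: int = 11, **kwargs
) -> LocalAlignment:
    """Best local alignment of query against subject (either strand).

    Thin wrapper over the alignment engine; see
    :func:`introseeker.alignment.align_local` for the scoring model.
    """
    return align_local(query, subject, min_seed=min_seed, **kwargs)


def best_hit_per_genome(
    transcript_id: str,
    sequence: str,
    panel: GenomePanel,
    min_seed: int = 11,
) -> Dict[str, HomologyHit]:
    """Best-scoring chromosome hit of one transcript in each panel genome.

    Ties are broken by higher identity, then by lexicographically smaller
    chromosome label.  A genome with no positive-scoring alignment yields a
    no-hit record (chrom None, identity 0, coverage 0).
    """
    qlen = len(sequence)
    hits: Dict[str, HomologyHit] = {}
    for letter, genome in panel.genomes.items():
        best: tuple | None = None
        for chrom in sorted_chroms(genome):
            subject = genome[chrom]
            idx = None
            if qlen * len(subject) > EXACT_CELLS:
                idx = panel.index_for(letter, chrom, min_seed)
            aln = align_local(sequence, subject, min_seed=min_seed, index=idx)
            if aln.score <= 0:
                continue
            key = (-aln.score, -aln.identity, chrom)
            if best is None or key < best[0]:
                best = (key, chrom, aln)
        if best is None:
            hits[letter] = HomologyHit(transcript_id, letter, None, 0.0, 0, 0.0, 0)
        else:
            _, chrom, aln = best
            hits[letter] = HomologyHit(
                transcript_id,
                letter,
                chrom,
                aln.identity,
                aln.aligned_columns,
                aln.query_coverage(qlen),
                aln.score,
            )
    return hits


def _effective(hit: HomologyHit, min_coverage: float) -> HomologyHit:
    """Apply the coverage floor: low-coverage hits become no-hits."""
    if hit.chrom is not None and hit.query_coverage < min_coverage:
        return HomologyHit(hit.transcript_id, hit.genome, None, 0.0, 0, 0.0, 0)
    return hit


def select_candidates(
    sequences: Mapping[str, str],
    expressed_ids: Collection[str],
    panel: GenomePanel,
    target_group: int = 4,
    id_max_recipient: float = ID_MAX_RECIPIENT,
    id_min_donor: float = ID_MIN_DONOR,
    min_coverage: float = MIN_QUERY_COVERAGE,
    min_seed: int = 11,
    compute_all: bool = False,
) -> tuple[pd.DataFrame, Dict[str, Dict[str, HomologyHit]]]:
    """Apply the three homology criteria on top of the expression filter.

    Per transcript: passes_I - best hit in at least one related genome lies
    on a target-group chromosome; passes_II - best-hit identity against the
    recipient reference strictly below ``id_max_recipient``; passes_III -
    best-hit identity against the donor proxy strictly above
    ``id_min_donor``.  A candidate passes expression and all three criteria.
    Homology is computed only for expression-passing transcripts unless
    ``compute_all``.  Returns the candidate table and the per-transcript
    best-hit records.
    """
    if not 1 <= target_group <= 7:
        raise ValueError("target_group must be in 1..7")
    expressed = set(expressed_ids)
    rows = []
    all_hits: Dict[str, Dict[str, HomologyHit]] = {}
    for tid, seq in sequences.items():
        passes_expr = tid in expressed
        if not passes_expr and not compute_all:
            rows.append((tid, False, False, False, False, False, None))
            continue
        hits = {
            g: _effective(h, min_coverage)
            for g, h in best_hit_per_genome(tid, seq, panel, min_seed=min_seed).items()
        }
        all_hits[tid] = hits
        related_groups = [hits[g].group for g in panel.related if hits[g].chrom]
        passes_i = target_group in related_groups
        passes_ii = hits[panel.recipient].identity < id_max_recipient
        passes_iii = hits[panel.donor_proxy].identity > id_min_donor
        assigned = target_group if passes_i else None
        rows.append(
            (
                tid,
                passes_expr,
                passes_i,
                passes_ii,
                passes_iii,
                passes_expr and passes_i and passes_ii and passes_iii,
                assigned,
            )
        )
    records = pd.DataFrame(
        rows,
        columns=[
            "transcript_id",
            "passes_expression",
            "passes_I",
            "passes_II",
            "passes_III",
            "candidate",
            "assigned_group",
        ],
    ).set_index("transcript_id")
    return records, all_hits


def cross_species_distribution(
    hits: Mapping[str, Mapping[str, HomologyHit]],
    related: Iterable[str],
    target_group: int = 4,
) -> tuple[pd.DataFrame, float]:
    """Per-genome fraction of transcripts whose best hit is on the target group.

    Also returns the overall fraction of transcripts for which at least one
    related genome agrees (best hit on a target-group chromosome).
    """
    related = list(related)
    n = len(hits)
    per_genome = []
    agree_any = 0
    for tid, by_genome in hits.items():
        if any(
            g in by_genome and by_genome[g].chrom and by_genome[g].group == target_group
            for g in related
        ):
            agree_any += 1
    for g in related:
        on_target = sum(
            1
            for by_genome in hits.values()
            if g in by_genome and by_genome[g].chrom and by_genome[g].group == target_group
        )
        per_genome.append((g, n, on_target, on_target / n if n else np.nan))
    table = pd.DataFrame(
        per_genome, columns=["genome", "n_transcripts", "n_on_target_group", "fraction"]
    ).set_index("genome")
    overall = agree_any / n if n else float("nan")
    return table, overall
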