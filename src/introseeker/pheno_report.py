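"""Summary statistics, disease-phenotype scoring, and the pipeline driver.

Percentages are computed exactly from integer numerator/denominator pairs
and rounded half-up to two decimals, matching how such proportions are
conventionally printed.  Stripe-rust infection types use the six-grade IT
scale (0, 0;, 1, 2, 3, 4 from immune to highest susceptible); Fusarium head
blight is scored as infected-spikelet rate (ISR), a severity level (SL 0-4)
from configurable ISR breakpoints, and a resistance evaluation category
(I/R/MR/MS/S).  ``run_pipeline`` chains simulation, array calling, capture
calling, candidate filtering, primer design/validation and the phenotype
summaries into one report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Dict, Iterable, Mapping, Optional, Sequence

import pandas as pd

from ._seq import mutate, parse_chrom
from .config import SimConfig
from . import synthetic_data as sd
from .array_caller import (
    call_substitution,
    chromosome_snp_summary,
    qc_filter,
    shared_locus_fraction,
)
from .capture_enrichment import chromosome_presence
from .alien_transcript_filter import (
    presence_absence_filter,
    differential_expression,
    deg_chromosome_distribution,
    select_candidates,
)
from .primer_engine import (
    PrimerConstraints,
    audit_primer_pair,
    classify_marker,
    design_primers,
    in_silico_pcr,
)

logger = logging.getLogger("introseeker")


def round_half_up(value: float | Decimal, ndigits: int = 2) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CountSummary:
    """An exact proportion: numerator / denominator with a 2 d.p. percentage."""

    label: str
    numerator: int
    denominator: int
    percent: float

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "numerator": self.numerator,
            "denominator": self.denominator,
            "percent": self.percent,
        }


def proportion_summary(numerator: int, denominator: int, label: str = "") -> CountSummary:
    """Exact percentage of numerator/denominator, rounded half-up to 2 d.p."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must lie in [0, denominator]")
    percent = float(
        (Decimal(numerator) * 100 / Decimal(denominator)).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
    )
    return CountSummary(label=label, numerator=numerator, denominator=denominator, percent=percent)


def marker_panel_summary(
    classes: Mapping[str, tuple[int, int]]
) -> Dict[str, CountSummary]:
    """Per-class and pooled shared-marker percentages.

    ``classes`` maps a marker-class label to (total markers, markers sharing
    the diagnostic band); the pooled summary is computed over the pooled
    numerator and denominator.
    """
    if not classes:
        raise ValueError("empty marker panel")
    out: Dict[str, CountSummary] = {}
    pooled_n, pooled_d = 0, 0
    for label, (total, shared) in classes.items():
        if shared > total:
            raise ValueError(f"{label}: shared exceeds total")
        out[label] = proportion_summary(shared, total, label)
        pooled_n += shared
        pooled_d += total
    out["overall"] = proportion_summary(pooled_n, pooled_d, "overall")
    return out


# ---------------------------------------------------------------------------
# disease scoring

IT_GRADES: Sequence[str] = ("0", "0;", "1", "2", "3", "4")
IT_CATEGORIES: Dict[str, str] = {
    "0": "immune",
    "0;": "nearly immune",
    "1": "very resistant",
    "2": "moderately resistant",
    "3": "moderately susceptible",
    "4": "highest susceptible",
}


@dataclass(frozen=True)
class ITGrade:
    grade: str
    category: str


def score_stripe_rust(grades: Iterable[str]) -> ITGrade:
    """Modal IT grade over plants; ties resolve toward the more susceptible grade."""
    grades = [str(g) for g in grades]
    if not grades:
        raise ValueError("no grades supplied")
    for g in grades:
        if g not in IT_GRADES:
            raise ValueError(f"unknown IT grade {g!r}; expected one of {IT_GRADES}")
    counts = {g: grades.count(g) for g in set(grades)}
    top = max(counts.values())
    modal = max(
        (g for g, c in counts.items() if c == top), key=IT_GRADES.index
    )
    return ITGrade(grade=modal, category=IT_CATEGORIES[modal])


#: default ISR (%) breakpoints mapping to severity levels 1..4; SL 0 means
#: no infected spikelet at all.  The national-standard table is not public,
#: so these breakpoints are explicit, configurable assumptions.
SL_BREAKS_DEFAULT: Sequence[float] = (10.0, 25.0, 50.0)
RE_FROM_SL: Dict[int, str] = {0: "I", 1: "R", 2: "MR", 3: "MS", 4: "S"}


@dataclass(frozen=True)
class FHBRecord:
    infected: int
    total: int
    isr_percent: float
    severity_level: int
    resistance_evaluation: str


def score_fhb(
    infected: int, total: int, sl_breaks: Sequence[float] = SL_BREAKS_DEFAULT
) -> FHBRecord:
    """Score Fusarium head blight from spikelet counts.

    ISR = infected / total * 100 (exact, 2 d.p.).  SL is 0 for zero infected
    spikelets, otherwise the number of breakpoints strictly below ISR plus
    one (defaults: <=10 -> 1, <=25 -> 2, <=50 -> 3, >50 -> 4); RE maps SL
    through I/R/MR/MS/S.
    """
    if total <= 0 or not 0 <= infected <= total:
        raise ValueError("require 0 <= infected <= total and total > 0")
    isr_raw = 100.0 * infected / total
    if infected == 0:
        sl = 0
    else:
        sl = 1 + sum(isr_raw > b for b in sl_breaks)
    return FHBRecord(
        infected=infected,
        total=total,
        isr_percent=proportion_summary(infected, total).percent,
        severity_level=sl,
        resistance_evaluation=RE_FROM_SL[sl],
    )


# ---------------------------------------------------------------------------
# pipeline

def _build_validation_panel(ds: sd.SyntheticDataset) -> tuple[Dict[str, Mapping[str, str]], Dict[str, str]]:
    """Validation genomes and roles for marker classification.

    Recipient cultivars (the recipient itself plus a lightly diverged second
    cultivar), the donor, donor-derived lines (the substitution line and the
    recipient+donor amphiploid), and the related-species panel genomes.  The
    donor-proxy reference is the marker-development target, not a validation
    member (in this synthetic world it is near-identical to the donor).
    """
    import numpy as np

    rng = np.random.default_rng(np.random.SeedSequence((ds.config.seed, 99)))
    cultivar2 = {c: mutate(s, 0.002, rng) for c, s in sorted(ds.recipient.items())}
    genomes: Dict[str, Mapping[str, str]] = {
        "recipient": ds.recipient,
        "recipient_cv2": cultivar2,
        "donor": ds.donor,
        "line": ds.line,
        "amphiploid": {**ds.recipient, **ds.donor},
    }
    roles = {
        "recipient": "recipient",
        "recipient_cv2": "recipient",
        "donor": "donor",
        "line": "donor_derived",
        "amphiploid": "donor_derived",
    }
    for letter in ds.panel.related:
        if letter in ds.config.recipient_subgenomes:
            continue  # subgenome stand-ins duplicate the recipient
        genomes[f"relative_{letter}"] = ds.panel.genomes[letter]
        roles[f"relative_{letter}"] = "relative"
    return genomes, roles


def run_pipeline(
    config: SimConfig,
    outdir: Optional[str | Path] = None,
    z_threshold: float = 3.0,
    max_pairs_per_candidate: int = 1,
    constraints: PrimerConstraints = PrimerConstraints(),
) -> dict:
    """Run the full characterisation pipeline on a simulated dataset.

    Stages: simulate -> array substitution call -> capture enrichment call
    -> expression + homology candidate filter -> primer design + in-silico
    validation -> phenotype summaries.  Returns the report dict; when
    ``outdir`` is given, writes report.json and report.md there.
    """
    logger.info("pipeline start: seed=%d", config.seed)
    ds = sd.make_dataset(config)

    # stage: SNP array
    try:
        geno = qc_filter(ds.genotypes)
        line_summary = chromosome_snp_summary(geno, "line")
        with_donor = shared_locus_fraction(geno, "line", "donor")
        with_parent = shared_locus_fraction(geno, "line", "parent")
        array_call = call_substitution(
            line_summary, with_donor, with_parent, z_threshold=z_threshold
        )
    except Exception as exc:  # pragma: no cover - stage attribution
        raise RuntimeError(f"array stage failed: {exc}") from exc

    # stage: capture enrichment
    try:
        line_enrich = chromosome_presence(ds.probe_depths["line"])
    except Exception as exc:  # pragma: no cover
        raise RuntimeError(f"capture stage failed: {exc}") from exc

    # stage: transcripts
    try:
        tx = ds.transcripts
        fpkm = tx.fpkm
        groups = tx.sample_groups
        expressed = presence_absence_filter(fpkm, groups["line"], groups["parent"])
        de = differential_expression(
            tx.counts, groups["parent"], groups["line"],
            lengths=tx.lengths, chrom_of=tx.chrom_of,
        )
        deg_dist = deg_chromosome_distribution(de)
        target_group = parse_chrom(config.substituted_chrom)[0]
        records, hits = select_candidates(
            tx.sequences, expressed, ds.panel, target_group=target_group
        )
        candidates = records.index[records["candidate"]].tolist()
    except Exception as exc:  # pragma: no cover
        raise RuntimeError(f"transcript stage failed: {exc}") from exc

    # stage: primers
    try:
        genomes, roles = _build_validation_panel(ds)
        designed, classes = [], []
        for tid in candidates:
            pairs = design_primers(
                tx.sequences[tid], constraints,
                max_pairs=max_pairs_per_candidate, template_id=tid,
            )
            for pair in pairs:
                if not audit_primer_pair(pair, constraints):
                    raise RuntimeError(f"audit failed for {pair.marker_id}")
                pattern = {
                    member: len(in_silico_pcr(pair, genome, genome_name=member)) > 0
                    for member, genome in genomes.items()
                }
                classes.append(classify_marker(pair.marker_id, pattern, roles))
                designed.append(pair)
    except Exception as exc:  # pragma: no cover
        raise RuntimeError(f"primer stage failed: {exc}") from exc

    # stage: phenotypes
    cyt = ds.phenotypes["cytology"]
    cytology = {
        row.stage: proportion_summary(int(row.numerator), int(row.denominator), row.stage).to_dict()
        for row in cyt.itertuples()
    }
    rust = ds.phenotypes["stripe_rust"]
    rust_scores = {
        sample: score_stripe_rust(sub["it_grade"]).__dict__
        for sample, sub in rust.groupby("sample")
    }
    fhb = ds.phenotypes["fhb"]
    fhb_scores = {}
    for sample, sub in fhb.groupby("sample"):
        rec = score_fhb(int(sub["infected_spikelets"].sum()), int(sub["total_spikelets"].sum()))
        fhb_scores[sample] = rec.__dict__

    class_counts = {c: 0 for c in ("donor_specific", "transferable", "non_specific", "failed")}
    for mc in classes:
        class_counts[mc.marker_class] += 1
    designed_ids = {p.template_id for p in designed}
    validated_ids = {
        mc.marker_id.rsplit("_p", 1)[0]
        for mc in classes
        if mc.marker_class == "donor_specific"
    }

    sub_label = None
    if array_call.substituted_chromosome and line_enrich.pair:
        sub_label = f"{line_enrich.pair[1]}({array_call.substituted_chromosome})"

    funnel = {
        "n_transcripts": int(len(tx.sequences)),
        "expression": int(len(expressed)),
        "criterion_I": int((records["passes_expression"] & records["passes_I"]).sum()),
        "criterion_II": int(
            (records["passes_expression"] & records["passes_I"] & records["passes_II"]).sum()
        ),
        "criterion_III": int(records["candidate"].sum()),
        "designed": len(designed_ids),
        "validated_donor_specific": len(validated_ids & designed_ids),
    }

    report = {
        "seed": config.seed,
        "parameters": config.to_dict(),
        "substitution": {
            "label": sub_label,
            "array_call": {
                "chromosome": array_call.substituted_chromosome,
                "confident": array_call.confident,
                "donor_sharing_rank": array_call.donor_sharing_rank,
                "z": {c: round(float(v), 3) for c, v in array_call.evidence.items()},
            },
            "capture_call": {
                "pair": list(line_enrich.pair) if line_enrich.pair else None,
                "status": dict(line_enrich.status),
            },
            "truth": ds.truth.to_dict() if ds.truth else None,
        },
        "candidate_funnel": funnel,
        "marker_classes": class_counts,
        "deg_distribution": {
            c: {"n_up": int(r.n_up), "n_down": int(r.n_down)}
            for c, r in deg_dist.iterrows()
        },
        "phenotypes": {
            "cytology": cytology,
            "stripe_rust": rust_scores,
            "fhb": fhb_scores,
        },
    }
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        with open(out / "report.md", "w") as fh:
            fh.write(_report_markdown(report))
        logger.info("report written to %s", out)
    return report


def _report_markdown(report: dict) -> str:
    sub = report["substitution"]
    lines = [
        "# Substitution-line characterisation report",
        "",
        f"Seed: {report['seed']}",
        "",
        "## Substitution call",
        f"- combined: **{sub['label']}**",
        f"- array: {sub['array_call']['chromosome']} (confident: {sub['array_call']['confident']})",
        f"- capture pair: {sub['capture_call']['pair']}",
        "",
        "## Candidate funnel",
    ]
    for key, val in report["candidate_funnel"].items():
        lines.append(f"- {key}: {val}")
    lines += ["", "## Marker classes"]
    for key, val in report["marker_classes"].items():
        lines.append(f"- {key}: {val}")
    lines += ["", "## Phenotypes"]
    for stage, entry in report["phenotypes"]["cytology"].items():
        lines.append(
            f"- {stage}: {entry['numerator']}/{entry['denominator']} ({entry['percent']}%)"
        )
    for sample, rec in report["phenotypes"]["stripe_rust"].items():
        lines.append(f"- stripe rust {sample}: IT {rec['grade']} ({rec['category']})")
    for sample, rec in report["phenotypes"]["fhb"].items():
        lines.append(
            f"- FHB {sample}: ISR {rec['isr_percent']}%, SL {rec['severity_level']}, RE {rec['resistance_evaluation']}"
        )
    return "\n".join(lines) + "\n"
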