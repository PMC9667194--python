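# introseeker

Diagnosing alien chromosome substitutions in wheat, and developing
chromosome-specific PCR markers to track them.

Wide hybridization introduces chromosomes from wild Triticeae relatives
(e.g. *Leymus*, *Psathyrostachys*) into bread wheat. In a **disomic
substitution line**, one pair of wheat chromosomes is replaced by the
homoeologous pair from the alien donor — for example 4Ns(4D): the wheat 4D
pair replaced by the donor's group-4 Ns chromosome. `introseeker`
implements, as a tested and reusable pipeline, the in-silico portion of
characterising such a line:

1. **SNP-array diagnosis** (`array_caller`). On the substituted chromosome
   the line's array probes lose their wheat target, so the missing-call and
   heterozygous-call rates jump while the residual calls track the donor.
   Per chromosome *c* the caller computes the anomaly score
   *s(c) = miss(c) + het(c)* and its robust z-score
   *z(c) = (s(c) − median s) / (1.4826 · MAD)*; it calls the argmax
   chromosome, confidently when *z > 3* **and** the same chromosome
   maximises the shared-allele fraction with the donor over co-called loci.
2. **Capture-depth dosage** (`capture_enrichment`). In
   genotyping-by-target-sequencing, per-probe depth reads out chromosome
   dosage. Depths are normalised to the median wheat-probe depth; a
   chromosome with median normalised depth < 0.1 is absent, > 0.5 present.
   The (missing wheat, enriched alien) pair is reported when their
   homoeologous-group numbers match.
3. **Candidate transcript selection** (`alien_transcript_filter`).
   Donor-chromosome transcripts are those with FPKM ≥ 1 in every line
   replicate and FPKM < 1 in every parent replicate, that additionally
   (I) best-hit a target-group chromosome in ≥ 1 related-species genome,
   (II) show < 50% best-local-alignment identity to the wheat reference,
   and (III) > 50% identity to the donor-proxy reference. The identity
   engine is a k-mer seeded, banded Smith–Waterman with affine gaps
   (match +1, mismatch −1, gap open −2, extend −1), exact at small problem
   sizes. A DESeq2-style stand-in (median-of-ratios normalisation, Welch
   test on log2 counts, Benjamini–Hochberg) provides the DEG summaries.
4. **Marker development** (`primer_engine`). Primer pairs are enumerated
   under the constraints length 18–27 bp, Tm 57–63 °C (unified
   nearest-neighbor thermodynamics, 50 mM Na⁺, 500 nM oligo), GC 40–60%,
   product 200–700 bp, pair ΔTm ≤ 3 °C, then screened by in-silico PCR
   (≤ 2 mismatches per primer, perfect 3′ pentamer clamp) against a
   validation panel and classified donor-specific / transferable /
   non-specific / failed.
5. **Reporting** (`pheno_report`). Exact proportion summaries (half-up,
   2 d.p.), stripe-rust infection types (IT 0–4), Fusarium head blight
   scoring (ISR / SL / RE), and the `run_pipeline` orchestrator.

Because the study's raw array/sequencing data live in an external archive,
a first-class synthetic generator (`synthetic_data`) emulates the full data
structure — hexaploid recipient (21 chromosome pairs, subgenomes A/B/D),
diploid-like Ns donor, substitution line, array calls, capture depths,
3-replicate transcript counts, reference panel, phenotype tables — with a
recorded ground truth, so every stage is testable end to end.

Intended users: wheat cytogenetics / pre-breeding groups evaluating
introgression lines, and developers of introgression-detection methods who
need a reproducible, truth-labelled benchmark.

## Worked example

```python
from introseeker import SimConfig, run_pipeline

report = run_pipeline(SimConfig(seed=1), outdir="out")
print(report["substitution"]["label"])
print(report["candidate_funnel"])
```

prints

```
4Ns(4D)
{'n_transcripts': 420, 'expression': 20, 'criterion_I': 20,
 'criterion_II': 20, 'criterion_III': 20, 'designed': 20,
 'validated_donor_specific': 20}
```

i.e. the pipeline recovers the simulated substitution — wheat 4D replaced
by donor 4Ns — from the array and capture signals; of 420 simulated
transcripts, exactly the 20 donor-chromosome transcripts survive the
expression filter and all three homology criteria, and all 20 yield
markers that amplify only in the donor and its derivative lines.
`out/report.json` and `out/report.md` hold the full report, including the
per-chromosome z-scores, presence statuses, DEG distribution and phenotype
scores. The same is available from a shell:

```bash
introseeker run --seed 1 --out out/
introseeker simulate --seed 1 --out data/        # write the dataset itself
introseeker array-call --genotypes data/genotypes.tsv \
    --qc data/genotype_qc.tsv --out array.json
```

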