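# Methods

## The problem being modelled

A disomic alien substitution line carries 20 wheat chromosome pairs plus
one homoeologous pair from a wild donor (here labelled Ns). Three
independent signals identify which wheat pair was replaced and develop PCR
markers for the alien chromosome: genotyping-array statistics, capture
sequencing depth, and transcript homology. This package implements each
signal as an explicit, parameterised rule, together with a synthetic data
generator that produces complete, truth-labelled datasets with the same
statistical structure.

## Array-based substitution calling

On the substituted chromosome the line's array probes no longer hybridise
to their intended wheat target: missing calls and spurious heterozygous
calls inflate, and the residual homozygous calls follow the donor
genotype. The caller formalises the qualitative "substantially higher than
other chromosomes" reading of such data as:

* anomaly score per chromosome `s(c) = miss_rate(c) + het_rate(c)`;
* robust z-score against the median and scaled MAD (×1.4826) of `s` over
  chromosomes with ≥ 10 informative loci (variance control at desk scale);
  if the MAD degenerates to zero with unequal scores, the population
  standard deviation is the fallback scale; all-equal scores yield no call;
* a confident call requires `z > 3` (configurable) **and** that the same
  chromosome maximises the shared-allele fraction with the donor.

Shared fractions are computed over co-called loci only (both samples
non-NoCall), so missingness is not conflated with discordance; chromosomes
with zero co-called loci are reported as NaN, never as 0. All tabular
positions are 1-based inclusive.

## Capture-depth presence calling

Depths are normalised by the median positive depth over wheat-chromosome
probes, making every downstream status scale-invariant. Per chromosome the
*median* normalised depth (robust to probe dropout) is thresholded:
absent < 0.1, present > 0.5, ambiguous in between; both thresholds are
exposed because real instruments differ in off-target capture. A
substitution pair is inferred only when exactly one wheat chromosome is
absent, at least one alien chromosome is present, and the leading-integer
group labels match. Chromosome labels must parse as
`<group><genome tag>`; unparsable labels are rejected at load.

## Local alignment engine

Affine-gap Smith–Waterman (Gotoh) with match +1, mismatch −1, gap open −2,
gap extend −1 (a gap of length L costs 2 + L); N matches nothing and
scores as a mismatch. Identity = matches / aligned columns with gap
columns counted as non-matches; query coverage = aligned query span /
query length. Both query strands are searched; the plus strand wins exact
ties.

Execution: problems with ≤ 10⁶ DP cells run the exact full dynamic
program; larger problems are seeded with exact k-mers (default k = 11),
seed diagonals are clustered (merge gap 16), and a banded DP (±12 around
the cluster's diagonal range, band capped at 128) is run over the top 8
clusters. With this scoring, local alignments extend only above ~50%
identity: homologues above that threshold are recovered at full coverage,
while more diverged sequences produce only short spurious segments. The
candidate criteria exploit exactly this behaviour (below).

Tie-breaking everywhere is deterministic (first-found best cell; by score,
then identity, then lexicographic chromosome label for best hits).

## Candidate selection

A transcript is a candidate when all four of the following hold:

1. **expression**: FPKM ≥ 1 in *all* line replicates and < 1 in *all*
   parent replicates (the all/any choice is switchable;
   FPKM = count·10⁹ / (length·library size), library size = column sum);
2. **criterion I**: its best hit in at least one related-species genome
   lies on a target-group chromosome;
3. **criterion II**: best-hit identity against the recipient (wheat)
   reference strictly below 50%;
4. **criterion III**: best-hit identity against the donor-proxy reference
   strictly above 50%.

"Identity" in II/III is best local-hit percent identity subject to a query
coverage floor of 30%: hits covering less are treated as no-hit (identity
0), so II passes and III fails. The floor is needed because short spurious
segments always exist at any divergence and their percent identity is
meaninglessly high; 30% is exposed in the API. The published criteria do
not state the identity denominator; this interpretation is recorded here
as the package's choice, not asserted as the original authors' intent.

## Differential expression stand-in

The DEG summaries use a deliberately simple, fully specified stand-in for
a negative-binomial GLM pipeline: median-of-ratios size factors
(geometric-mean reference over all-positive genes), log2 fold change of
normalised means with pseudocount 1, Welch's t-test on
log2(normalised + 1), Benjamini–Hochberg adjustment, and the thresholds
FPKM ≥ 1 (≥ 1 group mean), |log2FC| ≥ 1, adjusted p ≤ 0.05. With 3
replicates and one all-zero group the Welch degrees of freedom collapse to
2, so borderline transcripts can miss the padj cut-off; across seeds
~91–94% of truly line-specific transcripts are flagged up. This power
limitation is accepted: candidacy itself is decided by the
presence/absence rule, not by the test.

## Primer design and in-silico validation

Melting temperatures use the unified nearest-neighbor duplex parameters
(SantaLucia 1998, PNAS 95:1460; Allawi & SantaLucia 1997, Biochemistry
36:10581), vendored as an explicit table, with duplex initiation and
terminal A·T/G·C terms, the symmetry correction for self-complementary
oligos, Tm = 1000ΔH/(ΔS + R ln(C_T/x)) − 273.15, x = 4 (1 if
self-complementary), C_T = 500 nM, plus the Schildkraut–Lifson salt term
16.6·log₁₀[Na⁺] at 50 mM. The window enumerator uses prefix sums over the
same table; each emitted pair is re-audited with the scalar model, which
also guards the (vanishingly rare) self-complementary window whose
vectorised Tm would omit the symmetry term.

Constraints: per primer length 18–27 bp, Tm 57–63 °C, GC 40–60%, all
inclusive; product 200–700 bp; pair ΔTm ≤ 3 °C. Ranking (the constraints'
source gives no rule): sum of |Tm − 60| over the two primers, then
|product − 450|, then template coordinates — deterministic output. The
reverse primer is reported 5′→3′ as synthesised.

In-silico PCR accepts binding sites with ≤ 2 mismatches and a perfect
3′-terminal pentamer, and pairs convergent sites within 2000 bp; both
primer orientations are considered. Marker classes over a validation
panel: donor_specific (bands only in donor ∪ donor-derived), non_specific
(any recipient band), transferable (bands in other relatives but no
recipient band), failed (no band).

## The synthetic generator

What it emulates, per seed (every output is a deterministic function of
the seed via per-stage child streams):

* **Genomes.** Seven group ancestors; recipient subgenome copies (A/B/D)
  at 3% divergence from their ancestor; each donor chromosome derived from
  the recipient group-mate at 60% divergence. 60% places donor–wheat
  identity (~40%) below the ~50% local-alignment extension threshold, so
  donor transcripts genuinely satisfy criterion II — mirroring the real
  situation where alien marker candidates assemble from reads that fail to
  map to wheat. Chromosomes are 50 kb; every downstream rule is
  length-free. The mutation model is i.i.d. substitutions to a different
  base (observed mismatch fraction is exactly Binomial(L, d)/L; no indels
  by default).
* **Panel.** The recipient itself (criterion-II target); a donor proxy at
  2% divergence (criterion-III target); related genomes H/R/E/S derived
  from the donor at 25% divergence — close enough for full-coverage
  alignment (criterion I detectable) yet far enough that designed primers
  almost never amplify them (≤ 2 mismatches over 18–27 bp with a perfect
  pentamer is a ~2% event per marker across four relatives); and diploid
  A/B/D stand-ins copying the recipient subgenomes.
* **Array.** Parent: homozygous calls with NoCall rate 1% (the error
  rate). Donor: called at 50%, matching the parent allele at 35% of
  co-called loci — the background-sharing scale seen in cross-species
  hybridisation, and enough separation for reliable argmax calling. Line:
  copies the parent off the substituted chromosome; on it, the
  NoCall/AB/hom mixture 0.50/0.17/0.33 with residual homozygous calls
  copying the donor. The per-sample QC table carries the platform's
  chip-quality metrics; the donor's reported call rate stays above the
  90% threshold because cross-species missingness is biology, not chip
  failure.
* **Capture.** 100 probes per chromosome over all wheat and all alien
  chromosomes; negative-binomial depth (mean 30, dispersion 0.2 —
  capture data are overdispersed, so Poisson would understate variance)
  with an off-target residual of 2% of the mean for absent chromosomes
  (the real residual capture level is unpublished; 0.02 is a free
  parameter).
* **Transcripts.** 20 per line chromosome, 300–1500 bp subsequences;
  per-transcript means log-uniform in [50, 500] counts (detectably
  expressed unigenes — the only ones usable for marker development),
  negative-binomial dispersion 0.05 (typical gene-wise dispersion for
  biological replicates of inbred lines); donor-chromosome transcripts
  have exact zero counts in every parent replicate.
* **Phenotypes.** Cytological euploid/bivalent counts (~97% / ~94%
  stability), resistant-line vs susceptible-parent IT grades, and FHB
  spikelet counts at ~5% vs ~45% infection.

What it does **not** emulate — hence what passing tests do and do not show
about real data: read-level errors and mapping ambiguity, real probe
chemistry and GC-dependent capture bias, structural variation beyond the
clean swap (an optional terminal-swap flag is reserved but off),
paralogy/repeats (each group ancestor is independent random sequence, so
cross-group homology is absent by construction), and genome-scale
repetitive content that would stress the seeding heuristic. Recovery rates
near 100% here demonstrate the correctness of the decision rules under
their stated assumptions, not expected field performance.

## Validation panel for marker classification

The default panel is: the recipient, a second recipient cultivar (0.2%
diverged), the donor, the substitution line, the recipient+donor
amphiploid, and the four related genomes. The donor proxy is the
marker-*development* reference and is not a default validation member: at
2% divergence it is effectively the donor itself, so including it would
reclassify nearly every marker as "transferable" and measure the
generator's proxy distance rather than the classifier. With real data,
where the proxy is a distinct species, it belongs in the panel.

## Disease scoring

Stripe rust: six IT grades 0, 0;, 1, 2, 3, 4 (immune → highest
susceptible); the per-line report is the modal grade with ties resolved
toward the more susceptible grade (conservative resistance calling). FHB:
ISR = infected/total × 100 exactly; severity level from ISR breakpoints
(0 infected → 0; ≤ 10 → 1; ≤ 25 → 2; ≤ 50 → 3; > 50 → 4) mapped to
I/R/MR/MS/S. The underlying national-standard breakpoint table is not
public; these defaults are explicit, configurable assumptions.

## Numerical and interface conventions

Percentages print half-up at 2 d.p. (`decimal`-based, so 0.005 cases round
up). Rates per chromosome always satisfy miss + het + hom = 1 to 1e-12.
Coordinates are 1-based inclusive in all tables (BED-style export would
convert to 0-based half-open). Genotype alphabet {AA, BB, AB, NoCall} and
sequence alphabet A/C/G/T (+N where stated) are closed; anything else is
rejected at load. All simulation draws come from per-stage
`SeedSequence((seed, stream))` children, so fixed seeds give byte-identical
outputs and changing one stage's parameters leaves the others untouched.

## Problem sizes

Defaults — 50 kb chromosomes, 200 SNPs and 100 probes per chromosome, 20
transcripts per chromosome, 3 replicates — are the package's desk-scale
operating point: large enough that every statistical margin in the
acceptance checks is meaningful (e.g. ~10 standard errors between the
substituted chromosome's anomaly score and the background), small enough
that the full test suite and the acceptance script each run in minutes on
one CPU. Recovery-style checks use 25 seeds (array/capture) and 10 seeds
(candidates, markers).

## Known limitations

* The banded aligner is a heuristic above 10⁶ DP cells: an alignment whose
  optimal path leaves the seeded band can be under-scored. At the
  divergences that matter here (homologues ≥ 75% identity, no indels) the
  band always contains the optimum.
* The Welch-based DE stand-in is underpowered at 3 replicates (df → 2 with
  an all-zero group); it is a summary device, not the candidate filter.
* criterion II/III behaviour depends on the 30% coverage floor for tiny
  spurious hits; with real, repeat-rich genomes a masking step would be
  required upstream.
* In-silico PCR models primer annealing as mismatch counting with a clamp;
  no thermodynamic duplex/hairpin simulation, no multiplexing.
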