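# Methods

This note documents the models, procedures and design choices behind
`xps`, in the order the pipeline applies them.

## Study design and data model

The analysis targets an extreme-phenotype sampling (XPS) design: a cohort
followed longitudinally for a quantitative phenotype (fasting insulin),
from which the individuals at the far upper tail ("cases") are
deep-sequenced together with unaffected sequenced controls, and candidate
variants are screened against a larger population panel of unaffected
genomes.  The default geometry is 2 cases, 5 sequenced controls, a
31-genome panel and a 57-subject screening cohort.

All variants are normalized on ingestion: multiallelic records are
decomposed into one biallelic record per alternate allele (genotype
indices pointing at other alternates are recoded to reference and the
affected samples flagged), and each allele pair is reduced to its minimal
representation by trimming shared trailing bases, then shared leading
bases while both alleles retain at least one base.  Identical edits
written differently in different files therefore compare equal by
`(chrom, pos, ref, alt)`, which is what the panel-exclusion step relies
on.  Missing genotypes (`./.`) are preserved as missing and never
imputed.  Public coordinates are 1-based (VCF/GFF convention); all
internal interval arithmetic is 0-based half-open.

Symbolic and structural alleles are skipped with a warning; the pipeline
supports SNVs and short indels only.

## Site filters

Three filters run in a fixed order (cluster → repeat → region), each
recording its removals in a per-variant trace so that every removed
variant has exactly one attributed cause.  The filters are independent
predicates, so the order affects only the attribution, never the final
retained set.

**Cluster filter.**  A variant is removed iff some window of
`window_bp` = 25 consecutive bases contains its site together with at
least `min_variants` = 5 distinct variant sites, counted over the
cohort-wide site list (a density criterion for alignment artifacts).  All
variants in a dense window are removed, not just the excess.  Windows are
arbitrary intervals, not fixed tiles; since any qualifying window can be
slid left until its leftmost site anchors it, a two-pointer sweep over
the sorted distinct sites is exact, and the test suite verifies it
against a brute-force scan of every anchor position.  Unsorted input is
an error, never silently re-sorted.

**Repeat filter.**  A variant is removed iff its reference-allele span
overlaps any interval of a user-supplied tandem-repeat BED mask (merged,
0-based half-open; any overlap counts).  The pipeline does not detect
repeats itself.  Chromosomes absent from the mask are treated as
unmasked and logged.

**Region filter.**  A variant is retained iff its span overlaps coding
sequence or a splice-site window — by default the 2 canonical intronic
donor/acceptor bases flanking each CDS-containing exon's intron-facing
boundaries.  UTR-exonic and deep-intronic variants are removed.  The
matched region kind ("coding" wins over "splice_site") is recorded in
the trace.

## Consequence classification

The classifier is self-contained: it splices the CDS from the reference
in transcription order (minus-strand transcripts reverse-complemented)
and keeps an invertible map between genomic positions and
codon/position-in-codon.  An SNV in CDS mutates one codon, which is
re-translated with the (hard-coded) standard genetic code: a new stop is
`stop_gained`, a lost stop `stop_lost`, an amino-acid change `missense`,
none `synonymous`; a change destroying the initiator ATG is
`start_lost`.  Coding indels are `frameshift` or `inframe_indel` by
allele-length difference modulo 3.  Alleles overlapping a splice window
are `splice_site` unless they also touch CDS, in which case the CDS
effect wins — matching the severity role splice variants play in the
large-effect class.  Protein changes are labelled
`<refAA><codon><altAA>` with premature stops written `X` (e.g. `K410X`).
SNV reference alleles are checked against the genome; a mismatch is an
error.

When several transcripts overlap a variant, the per-variant call is the
most severe under the order stop_gained > frameshift > splice_site >
start_lost > stop_lost > missense > inframe_indel > synonymous >
noncoding, ties broken by lowest transcript id.  The default gene models
carry one transcript per gene.

The test suite validates the classifier against an independent oracle
that mutates the genome string, re-splices and re-translates the entire
mutant CDS with Biopython, over every possible SNV at every CDS position
of randomly generated multi-exon genes on both strands.

## Prioritization cascade

* **Step (i), case exclusivity** — retain variants whose alternate
  allele is carried by *every* case and by *no* sequenced control
  (`--min-case-carriers` relaxes the all-cases rule for larger designs).
  A case sample absent from the calls is an error, because exclusivity
  cannot be asserted without evidence; a missing control genotype is
  treated as non-carriage but logged.  Zygosity is reported, never
  filtered on.
* **Step (ii), effect partition** — an exact partition into large-effect
  variants ({stop_gained, frameshift, splice_site}; start/stop-loss can
  be added by configuration but are off by default), missense variants
  (kept as a separate secondary tier), and everything else (dropped).
* **Step (iii), panel exclusion** — drop any variant whose identical
  normalized allele is carried by at least one panel genome.  Missing
  panel genotypes do not count as carriage (absence of evidence is not
  presence).

Candidate sets can only shrink across stages, and steps (ii) and (iii)
commute; both properties are tested.  The report records per-stage
counts, the effect-class breakdown after step (ii), the final candidates
with per-case zygosity, and the full filter trace.

## Allelic imbalance and NMD

A heterozygous premature-stop allele subject to nonsense-mediated decay
(NMD) yields fewer RNA-seq reads from the mutant allele.  The model:
wild-type allele expression 1, mutant 1 − δ with δ ∈ [0, 1] the decay
efficiency, giving an expected mutant read fraction f = (1 − δ)/(2 − δ)
(1/2 at no decay, 0 at complete decay) and the inverse estimator
δ̂ = (1 − 2f̂)/(1 − f̂), clamped to 0 with a "no-decay" flag when
f̂ ≥ 1/2.

Significance is assessed with a two-sided Fisher's exact test on the 2×2
table (rows: observed RNA counts vs a null expectation; columns: WT,
mutant).  The null row is the site's DNA allele counts when available —
an exact conditional comparison in which both rows are genuinely
sampled — otherwise a balanced 1:1 pseudo-table with the RNA total
(`null_spec="balanced"`; odd totals split ceil/floor to the reference
column).  The pseudo-table treats a known expectation as if it were a
sample of the same depth, which is conservative; the choice of null is
recorded in the result.  The p-value sums hypergeometric probabilities
of all tables (margins fixed) no more probable than the observed one,
with a relative tolerance of 1e-12 on that comparison, computed in
log-factorial space (stable to totals ~1e6).  A result is
`nmd_consistent` only when significant at α (default 0.05) *and* in the
deficit direction; a significant mutant excess is reported but flagged
inconsistent.  Tissues are tested separately by default; `--pool` sums
counts first.  No meta-analytic combination is attempted.

## Metabolic phenotyping

* **HOMA-IR** = fasting glucose [mmol/L] × fasting insulin [µU/ml]
  / 22.5.  The constant is only meaningful in those units, so the
  phenotype loader rejects mg/dL rather than converting silently.
* **Excursion AUC**: composite trapezoid over the full IVGTT sampling
  span (0, 1, 3, 5, 10, 15, 20, 30, 45, 60 min); optional
  baseline-subtracted (incremental) variant with an optional zero floor,
  both off by default.
* **Extreme selection**: a subject is flagged when its value strictly
  exceeds mean + k·SD of a reference group (k = 3 default, SD with n−1).
  A subject belonging to the reference is excluded from its own
  threshold (leave-one-out).  The rule is deterministic and
  scale-equivariant.  Two practical recommendations are baked into the
  documented workflow: use the *whole cohort* as the reference, so that
  a second extreme individual inflates the SD by only ~1/√n and cannot
  mask the first; and summarize each subject by the *mean over the
  longitudinal follow-up*, since the phenotype of interest is prolonged
  elevation and averaging suppresses single-visit noise on both the
  cases and the reference.  With those choices the rule recovers exactly
  the planted 6-fold cases in effectively all simulated cohorts;
  single-timepoint selection against a small reference group is
  measurably worse (masking by the second case).  Iterative re-screening
  after removing flagged subjects was evaluated and rejected: with a
  heterogeneous (normal + MetS) reference the post-removal threshold
  drops enough to flag ordinary upper-tail subjects.
* **Comparison tests**: two-sided unpaired Student's t-test (pooled
  variance, as in the figure-legend convention; zero pooled variance is
  an error), two-way ANOVA with interaction using type-II sums of
  squares (balanced or unbalanced complete designs; saturated designs
  are an error), and a one-sample Kolmogorov–Smirnov normality check
  against a normal with estimated mean/SD — the common practice, whose
  anti-conservative p-value (Lilliefors caveat) is logged, not
  corrected.  The t-test and two-level one-factor ANOVA agree exactly
  (F = t²).

Ordinary model fits go through scipy/statsmodels; the exact test, the
NMD model and the selection rule are implemented here, with scipy used
as an independent cross-check in the tests.

## Synthetic study generator

The generator emits everything the pipeline consumes, as a pure function
of one seeded config (same config ⇒ byte-identical files).

* **Genome**: one chromosome (default ~7 kb) with 8 non-overlapping
  genes on random strands, 2–4 exons each, 40–80 codons, 20-bp UTRs,
  60–150-bp introns; every CDS starts ATG, ends with a stop and contains
  no internal stop.  Tandem `AC` tracts are embedded in intergenic gaps
  and reported as the repeat BED.
* **Cohort calls**: ~60 shared background polymorphisms at Beta(2,5)
  allele frequencies (by default each is guaranteed at least one control
  carrier, pinning its fate in the truth table); clustered decoys (6
  sites within 21 bp inside CDS); repeat-region decoys; and case-private
  decoys each violating exactly one cascade stage — carried by one case
  only, carried by a control, synonymous, in-frame, deep-intron, UTR,
  and large-effect decoys present in the panel (stop-gain, frameshift
  insertion, splice-site).  Exactly one planted causal variant — a
  heterozygous stop-gain shared by both cases, absent from controls and
  panel, clear of clusters and repeats — satisfies every stage.  A
  30-bp minimum spacing between unrelated sites prevents accidental
  clusters.  Every emitted variant appears once in a truth table with
  its intended fate, which the pipeline trace is checked against.
* **ASE counts**: per tissue (muscle, adipose), mutant RNA reads ~
  Binomial(depth, (1−δ)/(2−δ)) and DNA reads ~ Binomial(depth, 1/2);
  defaults δ = 0.8 and depth 100 (exome-era coverage scale).
* **Phenotypes**: fasting insulin log-normal per group — 39 normal
  subjects (median 25 µU/ml), 18 MetS non-case subjects (median
  60 µU/ml), log-SD 0.3 (~30% within-group biological CV), and the two
  cases as MetS draws multiplied by a 6-fold effect (within the 5–7-fold
  range the design targets), at five follow-up timepoints to 40 months.
  Glucose is mildly anti-correlated with the insulin deviation and
  slightly depressed in cases, reflecting insulin-driven glucose
  disposal.

What the generator does *not* emulate — read-level errors, mapping and
calling noise, genotype-likelihood uncertainty, linkage structure,
population stratification and relatedness — bounds what passing tests
show: they validate the analysis logic downstream of variant calls, not
robustness to upstream calling artifacts beyond the cluster/repeat
proxies.

## Problem sizes and numerical choices

The documented study conditions are desk-scale by design: 50-seed
pipeline-recovery batches, 2×2 exact-test verification over all tables
with total ≤ 60 against direct hypergeometric enumeration, 500-replicate
estimator-recovery and selection simulations, and 2,000/5,000-replicate
calibration runs — sizes at which every result reproduces in seconds to
a few minutes on one CPU.  Tolerances: 1e-10 against enumeration for the
exact test, 1e-9 for closed-form statistics (F = t², hand-decomposed
ANOVA sums of squares), exactness for set-valued filter comparisons.
Ties in worst-effect selection break by transcript id; the balanced
pseudo-table splits odd totals ceil-to-reference; degenerate inputs
(all-zero tables, constant samples, zero pooled variance, saturated
ANOVA designs, end≤start intervals) raise errors rather than returning
conventionals.

## Known limitations

* The filters operate at site level; per-sample depth/quality-based
  genotype filtering is out of scope (the pipeline starts from called
  genotypes).
* The classifier annotates against a single supplied gene-model set and
  implements the effect vocabulary the cascade consumes, not a full
  annotation ontology; regulatory effects are not modelled.
* The NMD test treats read counts as independent draws; mapping bias at
  the variant site and overdispersion are not modelled.
* With a single pair of cases the cascade is a deterministic screen, not
  an association test; burden-style statistics across many cases and
  polygenic models are out of scope.
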