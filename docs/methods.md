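# Methods

This note documents the models, defaults and numerical choices behind the
pipeline, and what the synthetic world does and does not establish.

## Variant screen

The cascade operates on *called, annotated* variants; alignment, primary
calling and predictor-score computation are upstream and out of scope.

* **Benign-polymorphism rule.** A variant is removed iff it has a dbSNP
  identifier *and* a reference-population minor allele frequency ≥ 0.01.
  The conjunction matters: dbSNP membership alone is not evidence of
  benignity, so a recorded allele with low or missing MAF is retained.
  The MAF boundary is inclusive (benign at exactly 1%); the three score
  thresholds are strict (SIFT < 0.05, PolyPhen-2 > 0.85,
  MutationTaster > 0.85), missing scores contribute false to the OR.
* **Deleterious-by-type.** Nonsense, frameshift, splice-site (canonical
  ±1/2 intronic positions), start-codon and large-deletion alleles skip
  the score rule, which is defined only for protein-changing point
  substitutions. In-frame indels are *not* in this set and must earn a
  score hit; with no scores they are excluded — a conservative choice a
  user can override by pre-setting the record's type.
* **HGVS classification.** The supported c. grammar is substitutions,
  del/dup/ins/delins (with base strings or position ranges) and intronic
  offsets. Precedence: large deletion > splicing > start codon >
  nonsense > frameshift > in-frame indel > missense > synonymous.
  Frameshift is decided by a `fs` protein annotation or a CDS length
  change not divisible by 3. A coding substitution with no protein
  annotation is classified `other` rather than guessed.
* **Read-pair consensus.** For overlapping mates from one cluster:
  agreement keeps the higher quality; disagreement takes the
  higher-quality base only when the gap is ≥ 10 Phred, otherwise the
  position is masked to `N` at quality 2. The gap and mask values are
  artifact choices (the source protocol states only that mates are
  merged into one corrected read).
* **Spectrum percentages** round half away from zero over distinct
  mutations (gene + cDNA change), not carriers. Note a published
  inconsistency: 30/51 missense is 58.8%, printed as 58%; this package's
  rule yields 59, and the acceptance check therefore pins the nonsense
  share (5/51 → 10%), which is rounding-stable.

## CNV and breakpoints

Probe copy ratios arrive already normalised (diploid expectation 1.0,
heterozygous loss 0.5). The assay publishes no cutoffs, so the state
bands are midpoints with a guard band: loss ≤ 0.65, normal 0.80–1.20,
gain ≥ 1.35, in-between indeterminate. Deletion segments are maximal
runs of ≥ 2 loss probes; indeterminate probes neither break a run nor
count toward its length. Each breakpoint is bounded by the neighbouring
probe target sites with different copy number — left in (last-normal,
first-deleted], right in [last-deleted, first-normal) — with unbounded
flags at track edges. Ratios ≈ 0 are annotated `deep` (homozygous loss)
but still called loss.

Junction sizing anchors the read's two ends by unique exact
`seed_length`-mers (default 20) and extends each anchor inward;
microhomology at the junction is assigned to the left flank
(left-aligned breakpoints). Coordinates are 0-based half-open, size =
right-flank start − left-flank end; a contiguous read reports
"no deletion" rather than size 0 silently. Sizing runs on synthetic or
user-provided references only; no genome download is involved.

## AEI model

Raw ratio = mutant/wild signal; a zero wild signal is flagged
(possible conversion or homozygosity) and excluded from testing rather
than treated as infinite. Each ratio is divided by the mean blood gDNA
raw ratio, so blood-normalised ratios average exactly 1 and any constant
per-allele assay factor cancels.

The default test is the two-sided pooled-variance Student t-test
(df = n1+n2−2) on raw normalised ratios at alpha 0.01, because that is
the named procedure; Welch and log-scale variants exist behind config
flags since multiplicative noise fits the t-test assumptions better on
the log scale. No multiple-testing correction is applied across lesions
by default (per-lesion 1% significance is the reported convention).
Degenerate input (both groups constant and equal) returns p = 1 with a
flag; fewer than 2 usable replicates per group is a no-call.

The gene-conversion candidate test requires a significant gDNA shift,
a mean LT gDNA normalised ratio ≥ `conversion_fold_min` = 2.0 (the
observed case was > 3; 2.0 separates conversion from noise while staying
below it) and no copy-number change in the gene.

A numerical note: dividing by the *mean* of lognormal blood ratios
biases normalised log-ratios low by ≈ σ² (about 1% at cv 0.10). This is
an inherent ratio-estimator property, identical in LT and NNS, so the
LT-vs-NNS test is unaffected; the generator's own raw log-ratios are
exactly centred and tested as such.

## RNA editing and phasing

An editing event is a variant present in LT cDNA but absent from LT
gDNA, NNS cDNA and (when assayed) blood gDNA; without an LT gDNA set the
detector returns a no-call, because a somatic DNA mutation cannot be
excluded. The detector is base-change-agnostic (the observed case is
G-to-A, consistent with deaminase chemistry, but that is reported, not
required). Read-based phasing demands ≥ 3 supporting observations in a
single germline-allele group for a cis call. Offspring-based phasing of
two variants in one gene assumes no intragenic recombination: a child
carrying exactly one proves trans, both-or-neither proves cis, and
jointly contradictory children raise a Mendelian-inconsistency error.

## Mechanism classifier

Rule order (CNV > conversion > editing > epigenetic-unknown) encodes
evidential strength: a physical copy-number change explains any ratio
shift; a gDNA shift without CNV is conversion; a cDNA-only variant is
editing; what remains — cDNA-only wild-allele loss with balanced gDNA
and an unmethylated promoter — is the methylation-independent silencing
category. A lesion with detected promoter methylation (mean methylated
fraction ≥ 0.2 over CpGs with coverage ≥ 10) is *never* given the
epigenetic-unknown label; since the study observed no methylated case
and defines no such category, it falls to `none` with an advisory.
The NMD side channel (`nns_mutant_reduction`) is not a mechanism: for
truncating germline alleles it records significant mutant under-
representation of NNS cDNA relative to the 1:1 genomic expectation
(one-sample t-test), the expected transcript-surveillance signature in
normal tissue.

## Synthetic world

Defaults are the study's stated conditions: 61 familial + 73 sporadic
index patients; per-gene carrier weights 0.46/0.29/0.07/0.03
(MVD/MVK/PMVK/FDPS, the observed 62/39/9/4 of 134) drawn as one
categorical per patient (the genes are nearly mutually exclusive) with a
rare second gene (p = 0.0075 ≈ 1/134); signal noise multiplicative
lognormal with cv 0.10 and σ = √ln(1+cv²) at mean 1; probe noise
Gaussian sd 0.05 truncated at 0; replicates 3 per stratum. The source
protocol states duplicate reverse transcription; 3 replicates keep the
t-test at df ≥ 4 and are configurable down to 2. Scenario means: null
1:1 everywhere; conversion LT gDNA 3 and LT cDNA 10; silencing LT cDNA 5
with balanced gDNA; CNV loss 3 in both molecules (one-copy wild-allele
loss in two-thirds of lesion cells — the study gives no number for this
scenario); truncating alleles get NMD-like mutant survival 0.3 in NNS
cDNA. Benign background polymorphisms (dbSNP id, MAF ≥ 1%, benign
scores) arrive at Poisson mean 1.5 per patient, configurable to 0.

Truth labels go to sidecar tables only, never into primary outputs.
What the synthetic world does **not** model: read-level sequencing
error, PCR bias beyond a constant per-allele factor, lesion purity
(normal-cell contamination enters only through the `none` class), and
population genetics of the cohort. A green recovery test therefore
establishes correctness of the *computation*, not robustness to assay
artefacts the generator does not emulate.

The 13-tissue-pair signal table is a labelled synthetic stand-in
(the study's supplementary table is not deposited): 2 conversion
lesions, 1 editing lesion without AEI, 8 silencing lesions, 2 without
mechanism — matching every reported per-lesion outcome, including the
10/13 wild-allele-reduction count.

## Known limitations

* The HGVS parser covers the subset above; exotic descriptions
  (inversions, mosaic alleles, uncertain ranges outside the large-
  deletion idiom) raise a classification error by design.
* Duplications are state-called (`gain`) but their breakpoints are not
  resolved.
* The cross-tab counts dual-gene patients in each of their gene columns
  (totals 135 over 134 patients, footnoted); the giant-plaque share uses
  the single-gene MVK denominator (38), the convention of the source's
  running text rather than its table header (39).
* Classifier recall degrades with cv; the ≥ 0.95 per-class recall holds
  at the default cv 0.10 with 3 replicates and is re-measured, not
  assumed, by the acceptance suite.
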