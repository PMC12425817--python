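# Methods

This note documents the models implemented in `mutscape`, the defaults
and why they were chosen, what the synthetic cohort generator does and
does not emulate, and the numerical choices that affect results.

## Variant integration and filtering

Per-caller call sets are merged on (sample, chromosome, position, ref,
alt); the caller set is the union of supporters and evidence fields are
taken from the supporting record with the greatest tumor depth.  The
default is union-then-filter (`min_support=1`): the post-calling filters,
not a caller vote, carry the specificity.  A vote rule is available via
`min_support`.

The four SNV criteria and their defaults:

| criterion | rule | default |
|---|---|---|
| normal_evidence | normal alt > 0 **and** two-sided Fisher on [[alt_t, ref_t], [alt_n, ref_n]] not significant | α = 0.05 |
| strand_bias | all mutant reads on one strand **and** alt-vs-ref strand Fisher significant | α = 0.05 |
| base_quality_drop | site mean base quality < flank mean − drop | drop = 10 Phred |
| poor_mapping | mean mapping quality of mutant reads < minimum | MQ = 20 |

Violations accumulate (no short-circuiting), so a rejection report lists
every criterion a call fails.  Records without strand counts are flagged
unevaluable and reported separately rather than silently passed — the
machine-readable replacement for a manual review step.  Indels are
rejected when a 1-bp event sits in a homopolymer run ≥ 6, when the
normal-evidence test fails, or when mapping quality is below MQ 20.

All Fisher p-values are computed by exact integer enumeration of the
hypergeometric support (two-sided p sums all tables whose probability
does not exceed the observed one, with exact tie handling).  This makes
the p-values reproducible to float rounding and independent of any
library's tie-tolerance conventions; the test-suite checks agreement
with a Fraction-arithmetic oracle to 1e-12 over every table with margins
up to 50.

Tumor mutational burden is SNV count divided by the 73.499 Mb target
size.  The hypermutation boundary is strictly `> 10` SNVs/Mb by default
and configurable to `>=`, since both conventions appear in practice.

## Confirmation statistics

A mutation re-sequenced by targeted amplicons is confirmed when the
tumor VAF exceeds the control's by a one-sided Fisher test at
α = 1e-9.  The criterion this models is quoted in the source literature
as "P < 10 × 10⁻¹⁰", read literally as 1e-9; the alternative reading
1e-10 is one keyword away (`alpha=1e-10`).  The test is one-sided
because the criterion is directional (tumor higher than control).
RNA-level detection uses an alt-read threshold of ≥ 1 read within
coverage strata (≥ 10×, ≥ 30×, ...); no read-count threshold beyond
presence is imposed because detection, not quantification, is the
question.  De novo panel scanning compares each tumor with the pooled
normals site-by-site under the same one-sided rule and flags calls with
VAF < 5% as low-VAF.

## Mutational signatures

Channel definitions follow COSMIC: 96 pyrimidine-strand trinucleotide
substitution classes and 83 indel classes (length × repeat context ×
microhomology).  Indel classification counts adjacent copies of the
indel motif on both flanks (alignment-invariant), and for non-repeat
deletions ≥ 2 bp measures the longest flanking microhomology.

De novo extraction fits KL-divergence NMF by multiplicative updates (the
objective is checked non-increasing per iteration in tests).  For each
candidate rank k, `n_replicates` fits run on bootstrap-resampled count
matrices; the pooled replicate signatures are clustered (average-linkage
agglomerative, cosine distance) into k consensus signatures, and each
cluster's silhouette is the signature's stability.  The selected rank is
the largest k with mean silhouette ≥ 0.8 and non-degenerate clusters
(every cluster populated by at least half the replicates, no
negative-silhouette signature).  This is a deliberate simplification of
the full solution-selection heuristics of the established extraction
tools; it reproduces their behavior on well-separated mixtures and is
fully deterministic under a fixed seed.

Two refitting routes are provided and used for different purposes:

- `decompose_to_reference` — per-sample NNLS against the catalog with
  backward elimination: a reference signature is dropped while the
  reconstruction cosine falls by < 0.01 per removal.  This produces
  sparse attributions for reporting which signatures are operative.
- `refit_exposures` — multiplicative KL updates with the catalog fixed,
  i.e. the Poisson maximum-likelihood refit.  This is the route used for
  subtype-grade activity estimates: on multinomial counts it has lower
  variance than least squares and no sparsity-induced bias of small
  activities.  It runs a fixed iteration budget (default 2000) because
  cohort-level objective-change stopping rules terminate before
  per-sample exposures stabilize.

The packaged reference catalogs (SBS1, SBS2, SBS3, SBS5, SBS13; ID2,
ID4, ID6, ID7, ID8) are synthetic stand-ins constructed deterministically
with the qualitative motif structure of the named signatures (CpG C>T
for SBS1, TpC APOBEC motifs for SBS2/SBS13, broad spectra for SBS3/SBS5);
pairwise cosines are ≤ 0.35.  They are intended for simulation and
round-trip validation; real COSMIC catalogs load from TSV via
`catalogs.load_catalog`.  Double-base substitutions are not modeled.

## HRD scar score

Components follow the published scar-score definitions (the source study
names only the scoring package and default parameters, so the numeric
rules are adopted from the scar-score literature and exposed in
`ScarParams`): LOH counts minor-allele-zero segments > 15 Mb not
spanning a whole chromosome; TAI counts allelic-imbalance segments
touching a telomere but not crossing the centromere; LST counts, per
chromosome arm, breakpoints between adjacent segments each ≥ 10 Mb after
discarding segments < 3 Mb and merging equal-CN neighbors (gap tolerance
< 3 Mb).  Arms are assigned by centromere midpoint and segments crossing
it are split.  Equal-CN adjacent segments are merged before scoring, so
splitting a segment into equal-CN pieces never changes any component.
Ploidy correction of LST is not applied (flag reserved).  HRD-high is
score ≥ 42 (inclusive) or any pathogenic germline/somatic BRCA1/2 event;
when the override fires below the threshold it is recorded.

## Subtypes, survival, actionability

Tertile cut points are the 33.33/66.67 empirical percentiles of the
analyzed cohort; values equal to a cut point go to the lower tertile.
Activities are absolute counts by default (proportions mode available).
Degenerate tertiles (more than a third of the cohort tied) raise an
error with guidance rather than producing arbitrary groups.

Group comparisons use the two-sided Wilcoxon rank-sum test, exact for
combined n ≤ 20 without ties.  The subtype-1-vs-3 odds model is a
logistic GLM (IRLS); odds ratios are rescaled to +10 years and +5 kg/m²;
on separation the model refits with a light L2 penalty and is flagged.
Survival uses Kaplan–Meier with log-rank tests and Cox proportional
hazards with Efron ties (via lifelines), with age, study and stage as
covariates (study as a covariate, not a stratum).  The endpoint is
all-cause mortality.

Cross-cohort gene-frequency comparisons are two-sided Fisher tests with
Benjamini–Hochberg control, flagged at q < 0.10.  Germline allele
frequencies against population references use chi-square when all
expected cells are ≥ 5, else Fisher.  Copy-number amplitudes are
discretized to the five-level scale with integer-CN cuts 0 → −2, 1 → −1,
2 → 0, 3–4 → 1, ≥ 5 → 2 (configurable; amplitude cut-offs relative to
ploidy are intentionally not inferred).  A neoantigen is counted when a
mutation has any peptide with IC50 < 500 nM and transcript read count
≥ 1.  Actionability combines the HRD-based chemotherapy-response call,
the best (lowest) OncoKB-style evidence level from a packaged,
versioned lookup snapshot (synthetic; live API deliberately not called,
for determinism and offline tests), the CD274 copy-number class, and the
neoantigen count.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
with full ground truth:

- **Burden**: log-normal SNVs/Mb, default median 1.29 with log-sd 1.0 —
  chosen to match a median of 1.29 with an observed range of roughly
  0.07–22 SNVs/Mb in cohorts of this size.  A `min_mutations` floor is
  implemented as left-truncation of the log-normal (not clamping, which
  would put an atom of identical burdens at the floor).
- **Signatures**: per-tumor mixing weights over the packaged catalog.
  By default the SBS3 weight and the planted HRD event counts rise
  together along a latent axis, and the aging weight (SBS1+SBS5) rises
  with a second axis that also shifts age and BMI upward — so SBS3
  correlates with HRD score and aging activity with age, as in real
  cohorts.  Independent (Dirichlet) profiles can be supplied for
  identifiability studies; under the default coupling SBS1 and SBS5
  exposures are nearly collinear and de novo extraction correctly finds
  fewer components than signatures, which mirrors real WES cohorts.
- **Subtype truth** is the tertile classification of the noise-free
  activities (or forced levels, when supplied); survival times are
  exponential with per-subtype hazard multipliers (default HR 2.6 for
  subtype 3 vs 1) under uniform administrative censoring at 12–120
  months (roughly 40% events at baseline).
- **Caller call sets**: each of four pseudo-callers sees each true
  mutation with 10% independent dropout (at least one caller always
  does).  Artifact calls are injected per type at configurable rates;
  each carries evidence violating exactly one filter criterion at a
  severity the filters are designed to reject (all mutant reads on one
  strand with balanced ref reads; matched normal contamination at the
  tumor VAF; a 15-Phred site base-quality drop; MQ 10 mutant reads), and
  each is labeled with its intended rejection reason.  True calls are
  drawn with at least one mutant read per strand so they are not
  spuriously strand-filtered.
- **Copy-number segments** tile a 24-chromosome toy genome (88 Mb
  chromosomes, 4 Mb centromeres, 42 Mb arms).  Each planted event
  occupies one arm using templates that contribute exactly one LOH, TAI
  or LST event and nothing else; filler segments are balanced, < 10 Mb
  and alternate copy state.  Planted counts therefore equal computed
  scores exactly, which is what the scar tests assert.
- **Confirmation data**: 2000× amplicon counts per panel mutation
  (binomial, control error 1e-3) and RNA counts with log-normal total
  depth, so RNA detection is depth-limited.

It does **not** emulate read-level data (FASTQ/BAM), FFPE damage
chemistry, caller-specific error profiles (the four pseudo-callers share
one dropout rate; no calibration to the real callers is claimed),
subclonal copy-number, or real genome architecture.  Passing tests
therefore demonstrate that the estimators recover the structure they
assume, not that they are robust to every real-data pathology.

## Problem sizes and numerical choices

The test-suite exercises the recovery pipeline at the sizes the analyses
are designed for: signature extraction on 200 tumors with ≥ 300
mutations each (rank range 1–7, 8 bootstrap replicates), subtype
recovery and Cox confidence-interval coverage on cohorts of 250 with 100
survival replicates, logistic recovery at n = 400 with 100 replicates.
NMF uses a 1000-iteration budget with relative-change stopping at 1e-6
for extraction and a fixed 2000-iteration budget for exposure refitting;
NNLS is exact (active set).  Ties in tertiles go to the lower bin;
Fisher two-sided ties are resolved exactly in integer arithmetic.
Degenerate inputs (empty cohorts, zero-count samples, all-tied
activities, no-event survival data) return typed empty results or raise
informative errors, as tested.

## Known limitations

- Rank selection is silhouette-based only; on strongly correlated
  exposures it intentionally selects fewer de novo signatures than the
  generating catalog.
- The exact Fisher enumeration is O(support) per table and meant for
  read-count-scale tables, not allele counts in the millions (the
  chi-square branch covers large, well-populated tables).
- The packaged signature catalogs and the OncoKB-style snapshot are
  synthetic stand-ins; substantive use requires the real reference
  files, loaded through the same TSV interfaces.
- Cox models treat `study` as a covariate; stratified baselines are not
  implemented.
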