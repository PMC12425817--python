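# mutscape

Somatic mutational-landscape analysis for triple-negative breast cancer
(TNBC) cohorts profiled by tumor/normal whole-exome sequencing.  The
package implements, as reusable and tested components, the analysis chain
used in WES studies of TNBC: multi-caller somatic variant integration and
post-calling filters, orthogonal mutation confirmation statistics,
mutational-signature extraction and refitting, genomic-scar HRD scoring,
an SBS-signature-based tumor subtype classifier with survival analysis,
and therapeutic-actionability classification.  Because patient-level WES
data of this kind is access-controlled, the package ships a synthetic
cohort generator that reproduces the statistical structure the analysis
assumes, with full ground truth, so every stage can be validated end to
end.

It is aimed at cancer-genomics analysts and methods developers who want
the individual pipeline stages as documented, seedable library functions
rather than a monolithic workflow.

## The models at the core

**Variant filtering.** Putative SNVs from four callers (Strelka, MuSE,
VarDict, Mutect) are merged by locus and allele, then filtered on four
criteria: (1) the alternative allele is present in the matched normal and
the tumor/normal contingency is *not* significant (Fisher exact,
two-sided); (2) mutant alleles occur on a single strand with significant
strand bias; (3) the site shows a systematic base-quality drop; (4)
mutant reads have poor mapping quality.  All Fisher tests use exact
integer enumeration of the hypergeometric support.

**Mutational signatures.** A tumor's SBS96 context counts are modeled as
a non-negative mixture, `V ≈ W H`, fit by KL-divergence NMF
(Poisson-consistent) with multiplicative updates.  De novo extraction
runs many bootstrap replicates per candidate rank, clusters replicate
signatures by cosine distance, and selects the largest rank whose mean
signature silhouette is ≥ 0.8 with non-degenerate clusters.  Samples are
refit against a reference catalog either by sparse NNLS with
backward elimination (`decompose_to_reference`) or by the Poisson
maximum-likelihood refit (`refit_exposures`).

**HRD scar score.** From allele-specific copy-number segments:
LOH (loss-of-heterozygosity segments > 15 Mb not spanning a chromosome) +
TAI (allelic imbalance reaching a telomere, not crossing the centromere) +
LST (arm-wise transitions between adjacent ≥ 10 Mb segments after 3 Mb
smoothing).  HRD-high is score ≥ 42, or any pathogenic BRCA1/2 event.

**SBS subtypes.** Aging activity (SBS1 + SBS5) and HRD activity (SBS3)
are cut into cohort tertiles and collapsed to low (T1/T2) vs high (T3):
subtype 1 = low aging / high HRD, 2 = low/low, 3 = high aging / low HRD,
4 = high/high.  Subtypes feed Wilcoxon comparisons, logistic odds models
(per +10 years of age, per +5 kg/m² BMI), Kaplan–Meier/log-rank curves
and Cox proportional-hazards models with Efron tie handling.

## Worked example

```sh
mutscape simulate --n-patients 8 --seed 4 --out cohort
mutscape filter --maf cohort/calls_strelka.maf.tsv --out strelka_passed.tsv
```

prints the per-criterion rejection report for one caller's call set:

```json
{"n_in": 2027, "n_passed": 1699, "rejections": {"normal_evidence": 71,
 "strand_bias": 92, "base_quality_drop": 91, "poor_mapping": 74,
 "homopolymer": 0, "unevaluable": 0}}
```

2,027 raw calls enter; 328 are rejected, each labeled with the filter
criterion it violated (the generator injected those artifact classes at a
5% rate each).  Scar-based HRD scoring on the same cohort:

```sh
mutscape hrd --seg cohort/segments.seg.tsv --annotation toy_annotation.tsv --out hrd.tsv
head -3 hrd.tsv
```

```text
sample_id  loh  tai  lst  hrd_score  status    brca_override
S0000      18   14   13   45         HRD-high  False
S0001      11   8    9    28         HRD-low   False
```

The component counts match the generator's planted event counts exactly
(`cohort/truth.json` records them: 45 and 28 for these two tumors), and
S0000 crosses the HRD-high threshold of 42.

The same operations are available as library calls
(`mutscape.mutation_core.apply_filters`, `mutscape.scar_hrd.score_cohort`,
`mutscape.signature_engine.extract_denovo`, ...), which is the interface
the test-suite exercises.

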