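# Methods notes

This note records the modelling and numerical choices behind `cellprs`,
what the synthetic cohorts do and do not emulate, and the conventions fixed
where the analysis design left room.

## Synthetic cohorts

**Genotypes.** The generator uses a block-exchangeable haplotype-copying
model: each of 20 linkage blocks has 8 founder haplotypes drawn i.i.d. at
frequencies uniform on [0.05, 0.5]; each of 200 panel haplotypes copies one
founder end to end (no within-block recombination) and then mutates each
site with probability 0.01.  Candidate variants whose realized minor-allele
frequency leaves the configured bounds are filtered; a block that cannot
supply enough in-bound variants after 50 redraws raises an explicit error.
Subjects are diploid draws of two panel haplotypes with replacement.  This
is the simplest structure that makes LD clumping non-trivial (strong,
founder-driven within-block r²; between-block r² at the ~1/n_haplotypes
noise floor) while keeping exact oracles tractable.  It does not attempt
realistic human LD decay, demography, or imputation error (dosages are
exact counts unless dosage noise is switched on).

Blocks sit on separate chromosomes with 1 kb variant spacing and a 10 Mb
per-block coordinate offset, so distinct blocks can never fall inside one
±500 kb clumping window.

**Summary statistics.** True log odds ratios are sparse: a causal fraction
(default 0.3) of the variants inside any gene-set window receives a
N(0, 0.05²) effect.  Estimates are drawn around the truth with the
large-sample standard error `se = 1/sqrt(2·N_eff·f(1−f))`,
`N_eff = 4/(1/n_cases + 1/n_controls)` at the discovery sizes 40,675 cases
and 64,643 controls, and the p-value is the two-sided normal tail.  With
~10⁵ effective samples, genuinely causal variants surface even at 5×10⁻⁸,
which is what makes the threshold ladder informative.  The reported effect
allele is randomized between REF and ALT (odds ratio inverted accordingly)
so that downstream allele alignment is always exercised.  About 10% of
variants receive an imputation INFO score below 0.7 and are expected to be
removed by QC.

**Gene sets.** Genes are tiled without overlap across each block; the three
cell-type sets are built by allocating disjoint pairwise-intersection chunks,
so each realized overlap equals `round(target·set_size)` genes exactly.  The
default targets (0.172, 0.199, 0.032) reproduce the published Rad–OPC,
OPC–Oli and Rad–Oli overlap percentages.  `synthetic_reference_gene_sets()`
builds 1000-gene stand-ins for the published top-5% lists (which are not
redistributable) with those overlaps exact; computing overlap percentages on
them validates the overlap arithmetic, not the published lists themselves.

**Phenotypes.** Covariates use population-plausible distributions: age
N(35, 10²) clipped to [18, 65], sex Bernoulli(0.5) with a 13 cm height
shift, handedness 90% right, ICV N(1.5, 0.12²)·10⁶ mm³ treated as a
subject-level constant across visits.  Baseline volumes scale with ICV
around FreeSurfer-style subfield means (CA1 322, CA2/3 976, CA4/DG
556 mm³, 8% lognormal-ish spread).  The standardized change in each
(subfield, hemisphere) is generated directly on the model scale:
small centered covariate effects (total variance ≈ 0.015) plus N(0, 0.8²)
residual, plus `−0.6 · z(true PRS)` in the single planted cell (left CA4/DG
of the exercising patient group).  Visit-3 volumes are reconstructed as
`V3 = V1 + change · 0.03 · subfield_mean`.  With the planted −0.6 and the
0.8 residual the generated change has variance ≈ 1, so the downstream
ICV correction and within-group re-standardization recover the planted
coefficient with ≲1% attenuation — confirmed empirically by the recovery
experiment (mean recovered coefficient −0.60 across 100 cohorts).

Because the planted effect acts on the *true* (pre-clumping, pre-threshold)
polygenic score, the threshold scan measures honest degradation: scores
estimated from clumped variant subsets are noisy proxies of the truth, and
their fitted coefficients (≈ −0.4 to −0.55) are attenuated relative to the
planted value by exactly that proxy correlation.  The unbiased recovery
check therefore regresses on the within-group z of the true score from the
ground-truth sidecar.

What passing tests show, and what they do not: the experiments demonstrate
that the *pipeline machinery* is calibrated and unbiased under this
generative model.  They say nothing about unmodelled features of real
cohorts — population stratification beyond two PCs, genotyping batch
effects, segmentation error correlated with ICV, non-normal change
distributions — all of which are screened for but not planted.

## Quality control conventions

* Filter order is fixed and reported: INFO → variant call rate → HWE →
  subject call rate → heterozygosity.  The thresholds themselves follow the
  standard inclusion wording: call rates survive on strict `> 0.98`; INFO
  exactly 0.7 is retained (`< 0.7` is removed).
* The Hardy–Weinberg test is the exact conditional test on hard-called
  genotype counts, computed with exact integer weights so that tied
  configurations contribute exactly; the test suite checks it against an
  independent rational-arithmetic enumeration for every count triple up to
  N = 50.
* Heterozygosity banding is single-pass: mean and SD are estimated once on
  the input subject set, not re-estimated after removals.
* Relatedness (IBS) is report-only: pairs above 0.9 are flagged, nobody is
  excluded.  Under the default panel size, occasional duplicate
  haplotype-pair draws are expected and flagged.
* Ancestry PCA standardizes dosages by `sqrt(2f(1−f))`, skips zero-variance
  variants, and fixes each component's sign by its largest-magnitude variant
  loading.  No high-LD region exclusion list is shipped: the synthetic
  genome has no such regions, and the generic pruning step (window 50,
  step 5, r² ≤ 0.2) plays that role.

## Scoring conventions

* Clumping runs once on the full gene-set variant list; thresholds then
  select nested subsets.  Ties in p are broken by (chromosome, position),
  making output order-deterministic.  The window is ±500 kb inclusive from
  the index position.
* LD is the squared Pearson correlation of dosages in the target cohort
  itself (no external reference panel); zero-variance vectors define r² = 0
  with a warning.
* Strand-ambiguous A/T and C/G pairs are dropped by default (configurable):
  with no strand information, their orientation is not decidable.  Missing
  dosages are mean-substituted per variant — simple, standard, and exact
  under the default no-missingness generator.
* `log` is the natural logarithm throughout.

## Outcome and inference conventions

* Each visit's volume is corrected by that visit's own ICV; the pooled mean
  ICV is taken over all analyzed participants and both visits.
* Standardization strata are the analysis groups (configurable), consistent
  with per-group regressions; SDs use the n−1 denominator.  Strata smaller
  than 3 or with zero change variance fail loudly.
* The KS normality check fits mean and SD from the data and is therefore
  anticonservative; it is labelled screening-only and gates nothing.
* Permutation inference permutes the raw outcome vector with the design
  fixed, as a literal outcome-resampling scheme; the Freedman–Lane residual
  scheme, which differs once covariates are in the model, is available as an
  option.  The add-one formula bounds the empirical p below by 1/(B+1).
  Within one (gene set, subfield, hemisphere, group) cell group the ten
  thresholds share a single permutation index matrix — deterministic given
  the seed and ten times cheaper, at the price of correlated (not biased)
  empirical p-values across thresholds of the same cell group.
* The optimal threshold per cell is the smallest empirical p, ties broken
  by larger partial R² (defined as the drop in residual sum of squares when
  the score enters, over the total sum of squares), then by the smaller
  threshold.  No multiplicity correction is applied across thresholds or
  cells beyond the permutation adjustment, matching per-threshold reporting.
* Covariate columns that are constant within a stratum (e.g. every subject
  right-handed in a small group) are dropped from that stratum's design
  rather than left to collide with the intercept.
* OLS is solved via the normal equations with classical standard errors and
  validated against statsmodels to 10⁻⁸; the permutation path reuses one
  `(X'X)⁻¹X'` factorization across all permutations of a cell.

## Experiment sizes

The repeated-cohort experiments use 100 cohorts for recovery/power (1000
permutations per cell) and 500 repetitions at 2000 permutations for null
calibration; the packaged default pipeline run uses the full 10,000
permutations.  These sizes give standard errors comfortably inside the
assertion bands (e.g. SE of the mean recovered coefficient ≈ 0.009).

## Known limitations

* The LD model has no recombination within blocks and no inter-block
  correlation, so clumping behaviour at realistic LD decay lengths is not
  probed.
* Summary-statistic noise ignores case/control imbalance effects beyond the
  effective-sample-size approximation and assumes independent variant
  estimates.
* The generator plants a linear, homoscedastic effect; robustness to
  heavy-tailed or heteroscedastic change distributions is untested.
* The distributional defaults for volumes and covariates are declared,
  plausible values, not estimates from any real cohort.
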