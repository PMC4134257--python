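# Methods

## Problem setting

`snpscreen` targets pharmacogenomic association studies that are small
by GWAS standards — a few dozen to a few hundred patients with a binary
adverse-event endpoint (a dichotomized NCI-CTC grade, e.g. diarrhea
grade ≥ 2) — where genome-wide multiplicity would swamp any signal.
The pipeline restores power in three complementary ways: a
knowledge-based restriction of the SNP universe, a two-stage screen
that re-uses the full cohort (joint analysis rather than independent
replication), and a permutation correction that prices the *entire*
selection procedure rather than each test in isolation.

## Data model

Genotypes are minor-allele dosages in {0, 1, 2, missing}.  The minor
allele is oriented once, on the full cohort, and fixed thereafter;
stage-1 (subset) statistics inherit this orientation so odds ratios
cannot flip sign between stages.  In VCF input a sample frequency tie
at 0.5 is broken toward the alphabetically smaller base and logged.
Patients with a missing endpoint grade are dropped globally at table
construction; patients with a missing genotype are dropped per SNP
(complete-case per test); covariate missingness is dropped per model
with a logged count.

## Knowledge-based selection

A SNP is kept iff at least one of its annotated genes carries at least
one GO accession from the target list.  The list is consumed verbatim;
closing it over `is_a`/`part_of` descendants of seed terms is an
explicit opt-in (`expand_term_set`), because curated target lists are
often not ontology closures and silently expanding them would change
the hypothesis set.  SNP→gene linkage comes from the annotation table,
never from coordinates.  Selection is monotone in the target list and
independent of input order.

## Quality control

* **MAF** = (2·hom_minor + het) / (2·n), excluded when < 0.05.
* **HWE**: the exact conditional test. Given n patients and the minor
  allele count, the heterozygote count follows the Levene–Haldane
  distribution; the two-sided p sums P(h) over all heterozygote counts
  with P(h) ≤ P(observed).  The implementation enumerates integer
  weights W(h) = n!·2^h / (((n_m−h)/2)!·h!·((n_M−h)/2)!) exactly (big
  integers), so probability-ordering ties are decided exactly and no
  mid-p or floating tolerance is needed.  Monomorphic SNPs return 1.
  SNPs with p < 0.2 are excluded.  Both exclusions are strict (<), so a
  SNP sitting exactly at a threshold passes.

The chi-squared HWE approximation was deliberately not used: at n ≈ 50
(the subset scale) its tails are unreliable exactly where the filter
operates.

## Fisher's exact test and odds ratios

Tables are built per genetic model: **allele** counts chromosomes (2
per patient, `a` = minor alleles among events), **dominant** counts
carriers (dosage ≥ 1), **recessive** counts minor homozygotes.  The
two-sided p follows the probability-ordering rule — sum the
hypergeometric point probabilities of every table no more probable
than the observed one — with a relative tie tolerance of 1e-7 in the
≤ comparison; degenerate margins give p = 1.  Odds ratios use
OR = a·d/(b·c) with a Woolf (log-OR normal) 95% interval,
exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d)); any zero cell triggers the
Haldane–Anscombe +0.5 correction of all four cells (switchable off, in
which case the OR is 0/∞ with an undefined CI).

## Two-stage screen and min-p permutation correction

Stage 1 tests candidates on the nested first dataset and keeps
p < α₁ (default 0.005, allele model).  Stage 2 re-tests survivors on
the full cohort.  The observed statistic is the minimum stage-2 p over
survivors (1.0 when none survive — a conservative convention that
keeps the null vector a fixed length).

The null replays the whole procedure: outcome labels are shuffled
uniformly across **all** patients of the full dataset (unstratified;
stratified-by-subset shuffling is available but not the default, since
the subset flag is assumed independent of outcome), the permuted first
dataset is re-extracted, both stages run, and the min stage-2 p is
recorded.  The adjusted p of a survivor is the plain fraction
k/n_perm of null minima at or below its stage-2 p — no (k+1)/(N+1)
correction — so p_per = 0 is possible and is rendered as
"< 1/n_perm" in text output.  One master seed spawns an independent
child RNG stream per replicate, so the null is reproducible and
independent of execution order.

**Replay cost.** With genotypes fixed and labels shuffled, a SNP's
table margins are fixed up to the per-SNP missingness pattern, so the
p-value is a function of one cell.  Every distinct margin triple is
enumerated once into a lookup vector; a permutation then costs one
matrix-vector product plus vectorized lookups (SNPs with missing calls
fall back to cached scalar lookups).  100,000 replays over a few
hundred SNPs take seconds, not days, without changing a single
p-value: the fast path and the scalar path share the same enumeration.

## Multiplicity (single-stage scan)

For the full-cohort-only scan, Benjamini–Hochberg q-values are
computed over m = all QC-passing candidate SNPs (not just stage-1
survivors): q_(i) = min_{j≥i} min(1, p_(j)·m/j).  The step-up itself is
statsmodels' `fdr_bh`; tests check it against a quadratic-time oracle.

## Covariate scans and modeling

Clinical covariates are screened by tied-rank (midrank) Spearman
correlation against the endpoint, with the two-sided p from
t = ρ·√((n−2)/(1−ρ²)) on n−2 df.  Covariates constant within the
chosen dataset are reported NA (a concomitant drug absent in a
monotherapy subset cannot be scored there).  |ρ| within 1e-13 of 1 is
reported as exactly ±1 with p = 0.

Model comparison fits binary-outcome logistic regressions by maximum
likelihood (Newton; lbfgs fallback when separation makes the Hessian
singular).  Genotype enters additively as 0/1/2 — a per-allele odds
multiplier; with a binary outcome this is the natural reading of a
"proportional odds" genotype effect, since a true ordinal-outcome
model does not apply.  AIC = −2·logLik + 2·n_par ranks the models
(the intercept-only NULL model is always included, fitted in closed
form).  Quasi-separation (any |coefficient| > 15 on the logit scale)
is flagged, not penalized — no Firth correction by default — because
the comparison cares about the achieved likelihood.  Discrimination is
the rank-based (Mann–Whitney) AUC with ties counted ½; the reported
operating point maximizes Youden's J (ties broken toward higher
sensitivity), and the full curve is always emitted so any other
convention can be read off.

## Permutation-count validity

The binomial point probability C(n,k)·p_B^k·(1−p_B)^(n−k) of the
observed exceedance count k under the significance level p_B assesses
whether n permutations suffice.  Values like 10^-241 underflow naive
double-precision arithmetic, so the computation lives in log space via
log-gamma and is reported as log10 plus a mantissa×10^exponent
rendering at 3 significant figures.  Symmetry at p_B = 0.5 and
agreement with exact rational arithmetic hold to ~1e-12 relative (the
log-gamma evaluation order prevents bit-exact symmetry).

## Synthetic cohorts

The generator emulates the study design the pipeline assumes: n = 168
patients by default with a 53-patient monotherapy subset assigned at
random independently of genotype and outcome (exactly the
exchangeability the permutation scheme needs), independent SNPs drawn
under HWE with MAF uniform on [0.05, 0.5], genes with GO annotations of
which a configurable fraction carry target terms (5% of SNPs
intergenic), binary/ordinal/continuous covariates, and an outcome from
logit P = baseline + Σβ_snp·dosage + Σβ_cov·x with baseline
log(36/132) (event rate ≈ 36/168).  Genotype missingness is applied to
the observed matrix only, after the phenotype is drawn from the true
genotypes.  An optional Gaussian-copula block-LD mode (block size and
correlation configurable) exists for stress testing and is off by
default — the analysis itself nowhere models LD.

What the generator does **not** emulate: realistic genome-wide LD
maps, population stratification, genotyping-batch artifacts,
covariate-genotype confounding, or array intensity data.  Passing
tests therefore demonstrate the statistical machinery is correct and
calibrated under the stated model, not that the pipeline is robust to
those real-data complications.

## Problem sizes used in the checks

The family-wise calibration experiment uses 100 null cohorts of 168
patients × 300 post-QC SNPs with 500 replays each; parameter recovery
uses 200 replicates at n = 2,000; the HWE oracle sweep covers every
genotype triple up to 50 patients; the Fisher oracle sweep uses 220
random tables with margins ≤ 60.  These sizes give the binomial
acceptance bands stated in each test while keeping the whole suite
runnable on a laptop.

## Known limitations

* The exact Fisher probability-ordering rule differs from some other
  two-sided conventions (doubling the one-sided p); q-values and
  adjusted p-values inherit that choice.
* Adjusted p = k/N is slightly anti-conservative relative to
  (k+1)/(N+1); at n_perm = 100,000 the difference is negligible, at
  n_perm ≤ 100 it is not — raise n_perm rather than reading small
  p_per literally.
* Per-SNP complete-case handling of missing genotypes is unbiased only
  under missingness independent of outcome.
* In-sample AUC/sensitivity/specificity are optimistic; no
  cross-validation is provided.
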