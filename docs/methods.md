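# Methods

## The severity score

SATB2-associated syndrome (SAS) is a multisystemic autosomal dominant
neurodevelopmental disorder. The SAS severity score quantifies its
phenotype as an organ-system rubric of 15 ordinal clinical categories,
each scored from 0 (least severe) to a per-category maximum between 2
and 5 points. Categories belong to one of two subscales; the composites
are

- neurodevelopmental = sum of the neurodevelopmental category points,
- systemic = sum of the systemic category points,
- total = neurodevelopmental + systemic,

with a maximum total of 47 points under the packaged default schema.
Scoring rules:

- only individuals aged **≥ 3.0 decimal years** are scored (the
  neurodevelopmental items are not meaningful earlier); younger records
  go to an exclusion log with the reason;
- an unobserved item contributes **0 points** (default-zero imputation)
  and increments `n_imputed`, so low-information records are
  identifiable downstream; no filtering on `n_imputed` is applied by
  default.

The engine is entirely schema-driven (`sasscore/data/rubric_default.json`).
The published rubric's exact item wording and per-category maxima live in
supplementary material that is not redistributed here, so the default
schema is a documented stand-in: the 14 clinical category names reported
for the syndrome (cognitive/adaptive, verbal, expressive communication,
ambulation, behavior, sleep, sialorrhea; palate, feeding and growth,
seizure, dental, bone, scoliosis, strabismus) plus a placeholder
fifteenth category (`hearing`, flagged `"placeholder": true`), with
maxima chosen inside [2, 5] to sum to 47 (neurodevelopmental
5+5+4+3+3+3+2 = 25; systemic 3+4+3+3+3+2+2+2 = 22). Replacing the file
with the true rubric requires no code change; every structural
constraint (15 categories, maxima bounds, sum 47, both subscales
non-empty) is validated at load time.

## Variant classification

Findings are SATB2 alterations given as a protein-level HGVS change, a
cDNA-level change, or a structural deletion/duplication with size and an
intragenic flag. Pathogenicity labels are inputs and are carried through
untouched — no ACMG interpretation is performed.

Broad categories: **null** (nonsense, frameshift, canonical ±1/±2
splice-site, intragenic exonic deletion), **missense** (amino-acid
substitution), **chromosomal** (non-intragenic large deletion or
duplication), and **other_intronic** for non-canonical intronic changes,
which stay in overall scoring but are excluded from molecular group
comparisons.

Subcategories, in rule order: (1) the recurrent Arg389Cys substitution
(which is never relabelled as generic CUT1 missense although codon 389
lies in CUT1); (2–5) other substitutions by domain — CUT1, CUT2, HOX
(homeodomain), or outside all three; (6) splice variants; (7) intragenic
deletions; (8–9) truncating variants with first affected codon before vs
at/after **codon 350**, the start of the CUT1 domain ("at or after" is
inclusive); (10–11) chromosomal deletions of < 6 Mb vs **≥ 6 Mb**
(inclusive upper class). Anything else — duplications, non-canonical
intronic changes — is `UNASSIGNED`, a value rather than an error.

Domain coordinates are configuration
(`sasscore/data/domains_default.json`): CUT1 [350, 437], CUT2
[482, 560], HOX [614, 677] (1-based inclusive amino acids). Only the
CUT1 start is fixed by the scoring convention; the interval ends follow
the UniProt annotation of SATB2 (Q9UPW6) and can be replaced. For
frameshifts the "position" is the first affected codon of the
protein-level description, the only position that notation guarantees.
Intragenic duplications have no defined subcategory; they are broad
`chromosomal` and subcategory `UNASSIGNED`. The HGVS support is a
deliberate subset (three-letter amino acids, `Ter`/`*`, `fs`, ±1/±2
intronic offsets); a cDNA-only coding change without a protein-level
description is a per-row parse error, reported and non-fatal for the
rest of the cohort.

## Statistics

**Age groups.** Eligible ages are binned [3, 6), [6, 11), [11, 18),
[18, ∞) — "3–5", "6–10", "11–17", "≥18" with integer-age semantics.

**ANOVA.** One-way ANOVA compares a composite score across sex, age
group, or broad category; empty levels are dropped with a warning.

**Adjusted means.** For each score and grouping a linear model
`score ~ group + sex + age_group` is fit by OLS with treatment coding.
The adjusted (LS-) mean of group *g* is the model prediction with the
group set to *g*, averaged over a covariate distribution:

- `observed` (default): the observed cohort sex × age-group
  distribution (population-margins convention);
- `balanced`: equal weight on every sex × age-group cell (the classical
  LSMEANS convention).

Both are exposed because the convention behind published LS-means is
rarely stated; the two coincide when covariates are balanced. CIs use
t quantiles on the residual degrees of freedom (normal quantiles
optional). The per-group contrast against the reference — by default
the group with the lowest raw mean, i.e. least severe — is the
treatment-coded coefficient; its estimate, CI and p-value are reported
alongside (the contrast equals the difference of adjusted means because
the margin terms cancel). Groups of n = 1 are allowed; their intervals
are wide, not suppressed. A design in which grouping and covariates are
confounded is rejected with a rank-deficiency error rather than
silently pseudo-inverted.

**Standardized adjusted means (radar matrix).** Because category point
ranges differ, cross-category comparison first z-standardizes each score
over the analyzed cohort (mean 0, SD 1, divisor n − 1) and then applies
the adjusted-means model, yielding a groups × scores matrix for radar
plotting. Zero-variance scores are dropped with a warning.

**Trends.** For null coding variants, severity is regressed on the first
affected codon; for chromosomal deletions, on deletion size in Mb. The
default model includes the sex and age-group covariates (an unadjusted
simple regression is an option). A constant outcome returns slope 0 with
an undefined p-value.

**Multiple testing.** The Bonferroni threshold `0.05 / n` applies to the
15 per-category comparisons (0.05/15 ≈ 0.0033); composite-score
comparisons use α = 0.05.

## Synthetic registry generator

No patient-level data is distributed, so the pipeline is validated on
synthetic registries. Defaults encode the published cohort margins:
n = 164; P(male) = 86/164 ≈ 0.524; age-group weights (29, 70, 41, 24)/164
with ages drawn uniformly inside [3, 6), [6, 11), [11, 18), [18, 38]
years; molecular mix 93 null / 45 missense / 25 chromosomal out of 163,
split uniformly across the subcategories within each broad class.

Rubric levels come from a **discretized latent Gaussian**: for each
category with maximum *m*, a latent value
`z ~ Normal(base + shift(subcategory), 1)` is cut at the
equal-probability thresholds `Φ⁻¹(j/(m+1))`, j = 1..m. This model is a
design choice of this package (the study itself has no generative
model): a single latent shift moves every level of the ordinal
distribution monotonically, and the implied mean score is available in
closed form (`expected_category_mean`), so parameter-recovery and
coverage experiments have an exact truth to compare against. Defaults:

- `base_level_mean = −0.25` latent SD — chosen from the closed form so
  the expected cohort total is ≈ 19.5 of 47, matching the reported
  cohort mean of 19.6;
- `effect_shift` — latent shifts per subcategory (±0.1 to ±0.45 SD)
  echoing the reported qualitative severity ordering: HOX-domain and
  out-of-domain missense variants least severe; Arg389Cys, distal
  truncating variants, intragenic deletions, and ≥ 6 Mb deletions more
  severe;
- `missing_prob = 0.02` per item, reflecting the rare unavailable rubric
  item.

A molecular finding guaranteed to classify into the drawn subcategory is
synthesized per individual (codons sampled in the correct interval of
the 733-aa protein, deletion sizes sampled on the correct side of 6 Mb,
the literal `p.Arg389Cys` for its class). The generating truth is stored
on the registry object and in `truth.json`, never inside the analysis
input files.

What the generator does **not** emulate: sex or age effects on severity
(the published cohort shows an age trend), correlation between rubric
categories beyond the shared subcategory shift, informative missingness,
realistic cDNA numbering, and recurrent-variant clustering. Passing
recovery tests therefore demonstrate that the estimators are correct
under the stated model, not that the clinical effect sizes are
realistic.

## Problem sizes in the test suite

The suite validates the statistical machinery at sizes chosen to keep
Monte Carlo error well below the tolerances asserted: oracle equivalence
on ≤ 20-row fixtures at 10 significant figures; CI coverage over 600
simulated cohorts of n = 120 (93–97% band); trend type-I error over
2000 null replicates of n = 60 (3.5–6.5% band); simulate→classify
round-trip at n = 10⁴; effect recovery at n = 600–2000. The whole suite
runs in well under a minute on one CPU.

## Known limitations

- The default rubric's per-category maxima and the fifteenth category
  are placeholders pending the published supplementary rubric table.
- Domain interval ends beyond the CUT1 start are UniProt-informed
  defaults, not the authors' exact coordinates.
- Whether published LS-means used observed or balanced margins, and t or
  normal CIs, is unknown; both are options here and neither is asserted
  as the original choice.
- Cohort-specific regression results from the unreleased patient-level
  registry are out of scope; the pipeline reproduces the machinery and
  validates it on synthetic data.
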