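# Methods

This note documents the models and procedures implemented in `amdgxe`,
the choices made where the design was genuinely open, and what the
synthetic-data generator does and does not emulate.

## Diet scoring

FFQ answers are converted to average daily grams per item as

    grams/day = occasions/day × servings/occasion × grams/serving × s,

with s = 0.25 for seasonal items (available roughly three months a year)
and 1 otherwise. The nine frequency categories map to occasions/day by
their midpoints on a per-month (30.44 days), per-week or per-day basis:
0, 2/30.44, 1/7, 3/7, 5.5/7, 1, 2.5, 4.5 and 6. The lowest category
("never or less than 1 time/month") maps to 0 by convention. The mapping
is a standard FFQ convention and is overridable.

Item intakes aggregate into eight food-group totals plus the MUFA/SFA
ratio, Σ(grams·MUFA/100 g) / Σ(grams·SFA/100 g) over *all* items
(`fat_only` items count only here; `other` items count only here). The
ratio is missing when total saturated fat is zero; the fat component then
scores 0 and the subject is flagged.

Component rules and conventions:

- Beneficial groups score 1 strictly above the sex-specific median; a
  value exactly at the median scores 0 (literal reading of "above").
  Detrimental groups score 1 at or below the median.
- Alcohol windows (10–50 g/day men, 5–25 g/day women) are inclusive at
  both endpoints and denominated in ethanol grams/day — the catalog is
  responsible for expressing alcohol items in ethanol grams (the bundled
  catalog's wine item carries 14 g/serving). This is an assumption: a
  catalog denominated in beverage grams would shift the window's meaning.
- Medians use the midpoint-of-middle-two convention for even counts,
  everywhere (diet cut-offs and GRS dichotomization alike).
- Cut-offs are computed on the scored cohort by default; fixed external
  cut-offs (e.g. from a larger reference population) can be loaded
  instead, since reference and analysis populations need not coincide.

High adherence is a total of 6 or more out of 9.

## Genetic risk score

GRS = Σᵢ Nᵢβᵢ with Nᵢ the risk-allele count at variant i and βᵢ its
per-allele log odds ratio. Reading from VCF, counts are oriented against
the declared risk allele — never assumed to be ALT — using GT only
(phased or unphased); dosage fields are ignored because only counts
matter. Missing genotypes are never imputed: a missing non-major variant
contributes 0, which makes scores non-comparable across missingness
patterns, so each result carries `n_missing_variants` for downstream
filtering. A missing *major* variant (any of the five named in the
README) nullifies the score and excludes the subject. The median split
(high = score ≥ median of included subjects) is computed after those
exclusions; computing it before is a one-line change on the result table
and is deliberately not a hidden option.

The packaged 52-variant weight table is a synthetic stand-in (real rsIDs
for the five majors, literature-scale magnitudes elsewhere); analyses of
real data should supply their own weights CSV.

## Case/control definition and eye records

Disease is defined by the most severe gradable eye: stages 2a, 2b, 3, 4
are cases; stage 0 is a control only above age 60, stage 1 only above 70
(strict inequalities, age at examination); everyone else is excluded with
a logged reason. Analysis records are per eye, with outcome 1 when that
eye's own stage is in the case set — so a case subject can contribute a
healthy fellow eye with outcome 0. Age categories for adjustment are the
disjoint half-open bins [·,70), [70,75), [75,∞), labelled 60–70
(reference), 70–75 and >75; subjects aged 55–60 (possible for cases,
since enrolment starts at 55) fall into the reference bin.

## GEE

The eye-level model is logistic with covariates high GRS, diet adherence
(protective or risk coding per analysis), sex, age category, smoking and
exercise; eyes cluster by subject under an exchangeable working
correlation. The solver iterates Fisher scoring with the moment estimator
for the common correlation α each iteration (scale = Σr²/(N−p),
α = Σ within-cluster residual cross-products / (scale·(n_pairs−p)),
Pearson residuals r), using the closed-form inverse of the exchangeable
correlation matrix so the update vectorises over clusters. Convergence is
a maximum absolute parameter change below 1e−8 within 100 iterations;
non-convergence returns the last iterate flagged, never raises. The only
reported variance is the robust (sandwich) estimator. α is constrained to
(−1/(max cluster size − 1), 1). With singleton clusters the fit reduces
exactly to ordinary logistic regression — one of the test suite's
closed-form anchors; the other is agreement with an independent GEE
implementation to ~1e−6 on correlated data.

Degenerate inputs: rank-deficient designs raise an error naming the first
aliased column; fitted probabilities are clipped to [1e−10, 1−1e−10];
a fit with any |coefficient| > 15 is flagged as suspected separation.

## Interaction measures

Both exposures are dichotomous and risk-coded (exposure D = low
adherence), making (high adherence, low GRS) the joint reference — the
lowest-risk stratum, as additive measures require. All quantities are
smooth functions of (β_G, β_D, β_GD); identities such as
OR₁₁/(OR₀₁·OR₁₀) = e^{β_GD} hold to machine precision by construction.

Inference:

- Delta method on the robust covariance, with analytic gradients
  (finite-difference checked in tests). RERI and AP are tested against 0
  on their natural scales; SI is handled on the log scale with the CI
  back-transformed, standard practice that also explains how SI can reach
  significance when RERI and AP do not. SI is undefined (flagged) when
  (OR₀₁−1)+(OR₁₀−1) = 0, and its log-scale CI requires OR₁₁ > 1 and
  OR₀₁+OR₁₀ > 2.
- Percentile bootstrap resampling *subjects* with replacement (both eyes
  travel together, preserving the inter-eye correlation), refitting the
  full GEE per replicate; default 2,000 replicates; non-converged
  replicates are dropped, counted, and flagged when they exceed 20%.
  Both CI types are always reported side by side.

Within-stratum ORs come from two routes: linear combinations of the
interaction fit (e^{β_D + g·β_GD}) and stratum-specific refits; tests
check the two agree on large cohorts. Protective-direction ORs are the
reciprocals of the risk-coded ones.

## Synthetic cohorts

The generator emulates a population-based paired-eye case-control study:

- genotypes Binomial(2, MAF) per variant, independent across variants
  (linkage equilibrium — irrelevant to the additive score arithmetic);
- FFQ answers driven by a latent per-subject diet-quality trait (ordinal
  category draws shifted up for beneficial and down for detrimental
  items), independent of genotype unless a dependence knob is set;
- paired-eye outcomes from a logistic model in the *dichotomized*
  exposures (as analysed) with an interaction term, covariate effects and
  a shared per-subject effect.

The shared effect uses a marginal-preserving latent-threshold device:
with u_s ~ N(0, σ²) per subject and e ~ N(0,1) per eye, the outcome is
1 iff Φ((u_s+e)/√(1+σ²)) < expit(η). Placing u_s inside the linear
predictor instead would make the generating coefficients conditional
ones, which the marginal GEE systematically attenuates; the threshold
construction keeps P(outcome) = expit(η) exactly for any σ while σ
controls inter-eye concordance, so parameter-recovery tests are
meaningful. This is the package's deliberate reading of "logistic model
with a shared subject effect" for a GEE-analysed design.

Defaults mirror a 612-subject coastal-Portugal study's margins: case
fraction ≈ 0.26, ~1216 analysed eyes (per-eye missingness 0.0065),
exposure effects β_G = log 1.788, β_D = log 2.327, β_GD = log 1.111,
covariate effects at the study's adjusted ORs, subject effect σ = 1.5.
One margin is structurally out of reach: because every mediSCORE
component is a median split on the scored cohort itself, component
prevalences are pinned near 0.5 and the mean score near 4.4, so the
high-adherence fraction cannot fall to the study's ≈ 0.20 from
within-cohort cut-offs; defaults yield ≈ 0.28. All draws flow from one
PCG64 generator (`numpy.random.default_rng(seed)`), recorded in the
manifest.

What passing tests on these cohorts do *not* show about real data: no
linkage disequilibrium, no realistic nutrient correlation structure
beyond the single latent trait, no genotyping batch effects, stages
attached to outcomes by a fixed draw (no stage-severity model), and
exposure–covariate independence by default.

## Problem sizes in the validation suite

The replication studies in the test suite use sizes chosen to make
Monte-Carlo error small relative to the effects under test while keeping
the suite quick: parameter recovery averages 200 cohorts of 2,000
subjects; the delta-vs-bootstrap comparison uses one 5,000-subject cohort
with 500 bootstrap replicates. That comparison's scenario sets
β_GD = 0.4 rather than the default 0.105: endpoint-relative agreement is
ill-posed when an endpoint sits near zero, so the check is run where both
RERI interval endpoints are clearly positive.

## Known limitations

- The bundled variant weights and food catalog are synthetic stand-ins;
  substantive use requires real effect sizes and a full composition
  table.
- Fisher's exact fallback in the descriptive comparison applies to 2×2
  tables only; larger sparse tables keep the chi-squared result with a
  flagged note.
- No energy adjustment, nutrient-level analysis (beyond the lipid
  ratio), genotype imputation, or risk-difference-scale interaction.
- The GEE supports the logit link and exchangeable correlation only —
  exactly the analysis design — not AR(1)/unstructured alternatives.
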