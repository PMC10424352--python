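"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a population-based AMD case-control study: common
variants drawn under Hardy-Weinberg equilibrium (linkage equilibrium
between variants), food-frequency answers driven by a latent per-subject
diet-quality trait, and paired-eye binary outcomes from a logistic model
in the *dichotomized* exposures (high GRS, low adherence) with an
interaction term, covariate effects and a shared within-subject effect.

Outcome construction.  Eye outcomes must carry the marginal
probabilities the GEE estimates, so the shared effect enters through a
marginal-preserving latent-threshold device rather than inside the
linear predictor: with subject effect u_s ~ N(0, sigma^2) and eye noise
e ~ N(0,1), the eye latent z = (u_s + e)/sqrt(1+sigma^2) is standard
normal, and the outcome is 1 iff Phi(z) < expit(eta).  The marginal
P(outcome) is exactly expit(eta) for any sigma, while sigma controls
inter-eye concordance — the correlation the exchangeable GEE absorbs.
All randomness flows from one ``numpy.random.default_rng`` (PCG64)
seeded by the config, so cohorts are fully reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from . import diet as diet_mod
from . import grs as grs_mod
from .io import (
    CohortIOError,
    FREQUENCY_LEVELS,
    default_variant_weights,
    validate_ffq,
    validate_food_catalog,
    validate_genotypes,
    validate_phenotypes,
)

__all__ = [
    "DietProfile",
    "SimulationConfig",
    "default_food_catalog",
    "default_mafs",
    "simulate_genotypes",
    "simulate_ffq",
    "simulate_outcomes",
    "simulate_eye_records",
    "simulate_cohort",
    "write_cohort",
]


@dataclass
class DietProfile:
    """Parameters of the FFQ answer distributions.

    Each item's frequency category is an ordinal draw: a continuous score
    centred on the item's habitual level, shifted by the subject's latent
    diet-quality trait (up for beneficial items, down for detrimental
    ones) and rounded to the nearest of the nine categories.
    ``point_mass`` short-circuits everything: every answer becomes that
    (category, servings, non-seasonal) triple — handy for arithmetic
    checks.
    """

    #: strength of the latent diet-quality trait on the category scale
    gamma: float = 0.25
    #: sd of item-level noise on the category scale
    freq_sd: float = 1.1
    #: lognormal sigma for servings per occasion (median 1 serving)
    servings_sigma: float = 0.3
    point_mass: tuple[str, float] | None = None


@dataclass
class SimulationConfig:
    """Generating parameters for one synthetic cohort.

    Effect sizes are log odds ratios; the exposure effects apply to the
    dichotomized GRS (``beta_grs_high``), the risk-coded diet indicator
    (``beta_diet_low``, 1 = low adherence) and their product.  Defaults
    mirror the margins of a 612-subject coastal-Portugal study sample
    (case fraction ~0.26, high-adherence fraction ~0.20, ~1216 analysed
    eyes) and its reported adjusted effect sizes.
    """

    n_subjects: int = 612
    seed: int = 0
    mafs: np.ndarray | None = None          # per-variant risk-allele frequencies
    betas: np.ndarray | None = None         # per-variant log-ORs (default: packaged table)
    intercept: float = -2.59
    beta_grs_high: float = 0.581            # log 1.788
    beta_diet_low: float = 0.845            # log 2.327
    beta_interaction: float = 0.105         # log 1.111
    covariate_effects: dict = field(
        default_factory=lambda: {
            "age_70_75": 0.383,             # log 1.467
            "age_gt75": 1.043,              # log 2.839
            "sex_male": -0.666,             # log 0.514
            "smoker": 0.729,                # log 2.072
            "exercise_yes": -0.374,         # log 0.688
        }
    )
    subject_effect_sd: float = 1.5
    missing_eye_prob: float = 0.0065
    missing_genotype_prob: float = 0.0
    diet_profile: DietProfile = field(default_factory=DietProfile)
    #: correlation knob between the diet-quality trait and the (standardized)
    #: GRS; 0 = independence (the default assumption)
    diet_genetic_dependence: float = 0.0
    #: exposure prevalences for the direct eye-record generator
    p_high_grs: float = 0.5
    p_diet_low: float = 0.8
    #: covariate distributions
    age_mean: float = 72.3
    age_sd: float = 6.5
    age_range: tuple[float, float] = (61.0, 92.0)
    p_male: float = 0.425
    p_smoker: float = 0.144
    p_exercise: float = 0.443

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise CohortIOError("n_subjects must be >= 2")
        if self.subject_effect_sd < 0:
            raise CohortIOError("subject_effect_sd must be >= 0")
        for name in ("missing_eye_prob", "missing_genotype_prob", "p_high_grs",
                     "p_diet_low", "p_male", "p_smoker", "p_exercise"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise CohortIOError(f"{name} must be in [0, 1], got {v}")
        if self.mafs is not None:
            m = np.asarray(self.mafs, dtype=float)
            if ((m < 0) | (m > 1)).any():
                raise CohortIOError("all mafs must be in [0, 1]")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def to_manifest(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        d["diet_profile"] = dataclasses.asdict(self.diet_profile)
        d["rng_algorithm"] = "numpy.random.default_rng (PCG64)"
        return d


def default_mafs(n: int = 52) -> np.ndarray:
    """Deterministic, realistically spread risk-allele frequencies.

    The five leading (major-variant) slots get common-variant frequencies;
    the rest follow a golden-ratio low-discrepancy sequence over
    [0.05, 0.5].
    """
    major = [0.42, 0.36, 0.28, 0.30, 0.25]
    rest = [0.05 + 0.45 * ((i * 0.6180339887) % 1.0) for i in range(1, n - len(major) + 1)]
    return np.array((major + rest)[:n])


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


def _subject_ids(n: int) -> list[str]:
    return [f"S{i:05d}" for i in range(1, n + 1)]


def simulate_genotypes(config: SimulationConfig,
                       rng: np.random.Generator | None = None,
                       weights: pd.DataFrame | None = None) -> pd.DataFrame:
    """Hardy-Weinberg risk-allele counts: Binomial(2, maf) per variant.

    Variants are drawn independently (linkage equilibrium).  With
    ``missing_genotype_prob`` > 0, calls are masked to missing at random.
    """
    rng = config.rng() if rng is None else rng
    weights = default_variant_weights() if weights is None else weights
    mafs = default_mafs(len(weights)) if config.mafs is None else np.asarray(config.mafs, float)
    if len(mafs) != len(weights):
        raise CohortIOError(
            f"mafs length {len(mafs)} does not match the {len(weights)}-variant weight table"
        )
    counts = rng.binomial(2, mafs, size=(config.n_subjects, len(mafs))).astype(float)
    if config.missing_genotype_prob > 0:
        mask = rng.random(counts.shape) < config.missing_genotype_prob
        counts[mask] = np.nan
    matrix = pd.DataFrame(
        counts,
        index=pd.Index(_subject_ids(config.n_subjects), name="subject_id"),
        columns=list(weights["variant_id"]),
    )
    return validate_genotypes(matrix)


# ---------------------------------------------------------------------------
# Food catalog and FFQ answers
# ---------------------------------------------------------------------------

# item_id, grams/serving, MUFA g/100g, SFA g/100g, group, habitual freq index
# (0..8 on the nine-category scale), trait direction (+1 beneficial, -1
# detrimental, 0 neutral), seasonal flag
_CATALOG_SPEC = [
    ("veg_cabbage",    120.0, 0.02, 0.03, "vegetables", 4, +1, False),
    ("veg_tomato",     100.0, 0.05, 0.05, "vegetables", 4, +1, False),
    ("veg_carrot",      80.0, 0.01, 0.04, "vegetables", 3, +1, False),
    ("veg_salad",       60.0, 0.02, 0.02, "vegetables", 4, +1, False),
    ("leg_beans",      110.0, 0.10, 0.12, "legumes",    3, +1, False),
    ("leg_chickpeas",  110.0, 0.60, 0.25, "legumes",    2, +1, False),
    ("fruit_orange",   160.0, 0.02, 0.02, "fruits",     4, +1, True),
    ("fruit_apple",    150.0, 0.01, 0.03, "fruits",     4, +1, False),
    ("fruit_banana",   120.0, 0.04, 0.11, "fruits",     3, +1, False),
    ("fruit_melon",    200.0, 0.02, 0.03, "fruits",     2, +1, True),
    ("cer_bread",       50.0, 0.30, 0.30, "cereals",    5, +1, False),
    ("cer_rice",       150.0, 0.10, 0.15, "cereals",    4, +1, False),
    ("cer_pasta",      150.0, 0.15, 0.20, "cereals",    3, +1, False),
    ("fish_sardine",   100.0, 2.50, 2.60, "fish",       3, +1, True),
    ("fish_cod",       120.0, 0.10, 0.15, "fish",       3, +1, False),
    ("fish_hake",      110.0, 0.40, 0.30, "fish",       3, +1, False),
    ("meat_beef",      120.0, 5.50, 5.10, "meat",       3, -1, False),
    ("meat_pork",      120.0, 6.20, 4.90, "meat",       3, -1, False),
    ("meat_chicken",   130.0, 3.80, 2.40, "meat",       4, -1, False),
    ("dairy_milk",     240.0, 0.90, 2.10, "dairy",      5, -1, False),
    ("dairy_cheese",    40.0, 7.50, 16.0, "dairy",      3, -1, False),
    ("dairy_yogurt",   125.0, 0.90, 2.00, "dairy",      3, -1, False),
    # alcohol intakes are ethanol grams: one glass of wine ~ 14 g ethanol
    ("alc_wine",        14.0, 0.0,  0.0,  "alcohol",    3,  0, False),
    ("fat_olive_oil",   10.0, 73.0, 14.0, "fat_only",   5, +1, False),
    ("fat_butter",      10.0, 21.0, 51.0, "fat_only",   2, -1, False),
    ("other_pastry",    70.0, 9.00, 8.00, "other",      3, -1, False),
]


def default_food_catalog() -> pd.DataFrame:
    """The built-in 26-item food catalog (composition + group mapping).

    A deliberately small, synthetic stand-in for a full 86-item national
    questionnaire catalog: every mediSCORE group is represented, lipid
    profiles are realistic per 100 g, and the alcohol item is denominated
    in ethanol grams.
    """
    df = pd.DataFrame(
        [row[:5] for row in _CATALOG_SPEC],
        columns=["item_id", "grams_per_serving", "mufa_per_100g", "sfa_per_100g", "group"],
    )
    return validate_food_catalog(df)


def simulate_ffq(config: SimulationConfig,
                 rng: np.random.Generator | None = None,
                 catalog: pd.DataFrame | None = None,
                 latent_shift: np.ndarray | None = None
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate FFQ answers for every subject x catalog item.

    Returns ``(ffq, catalog)``.  ``latent_shift`` (per subject, standard
    scale) is added to the latent diet-quality trait — the hook used to
    induce diet-genotype dependence.
    """
    rng = config.rng() if rng is None else rng
    catalog = default_food_catalog() if catalog is None else catalog
    if len(catalog) == 0:
        raise CohortIOError("cannot simulate FFQ answers from an empty catalog")
    subjects = _subject_ids(config.n_subjects)
    prof = config.diet_profile

    spec_by_item = {row[0]: row for row in _CATALOG_SPEC}
    rows = []
    if prof.point_mass is not None:
        category, servings = prof.point_mass
        for sid in subjects:
            for item in catalog["item_id"]:
                rows.append((sid, item, category, float(servings), False))
        ffq = pd.DataFrame(rows, columns=["subject_id", "item_id", "frequency_category",
                                          "servings_per_occasion", "seasonal"])
        return validate_ffq(ffq, catalog), catalog

    trait = rng.normal(0.0, 1.0, config.n_subjects)
    if latent_shift is not None:
        trait = trait + np.asarray(latent_shift, dtype=float)
    for s_idx, sid in enumerate(subjects):
        for item in catalog["item_id"]:
            spec = spec_by_item.get(item)
            base, direction, seasonal = (spec[5], spec[6], spec[7]) if spec else (3, 0, False)
            score = base + direction * prof.gamma * trait[s_idx] + rng.normal(0, prof.freq_sd)
            level = int(np.clip(np.rint(score), 0, 8))
            servings = float(np.exp(rng.normal(0.0, prof.servings_sigma)))
            rows.append((sid, item, FREQUENCY_LEVELS[level], servings, seasonal))
    ffq = pd.DataFrame(rows, columns=["subject_id", "item_id", "frequency_category",
                                      "servings_per_occasion", "seasonal"])
    return validate_ffq(ffq, catalog), catalog


# ---------------------------------------------------------------------------
# Covariates and outcomes
# ---------------------------------------------------------------------------


def _simulate_covariates(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_subjects
    age = np.clip(rng.normal(config.age_mean, config.age_sd, n), *config.age_range)
    return pd.DataFrame(
        {
            "subject_id": _subject_ids(n),
            "age": age,
            "sex": np.where(rng.random(n) < config.p_male, "male", "female"),
            "smoking": np.where(rng.random(n) < config.p_smoker, "smoker/ex-smoker", "non-smoker"),
            "exercise": rng.random(n) < config.p_exercise,
        }
    )


def _linear_predictor(config: SimulationConfig, grs_high: np.ndarray, diet_low: np.ndarray,
                      covariates: pd.DataFrame) -> np.ndarray:
    ce = config.covariate_effects
    age = covariates["age"].to_numpy(dtype=float)
    eta = (
        config.intercept
        + config.beta_grs_high * grs_high
        + config.beta_diet_low * diet_low
        + config.beta_interaction * grs_high * diet_low
        + ce.get("age_70_75", 0.0) * ((age >= 70) & (age < 75))
        + ce.get("age_gt75", 0.0) * (age >= 75)
        + ce.get("sex_male", 0.0) * (covariates["sex"].to_numpy() == "male")
        + ce.get("smoker", 0.0) * (covariates["smoking"].to_numpy() == "smoker/ex-smoker")
        + ce.get("exercise_yes", 0.0) * covariates["exercise"].to_numpy(dtype=bool)
    )
    return eta


def simulate_outcomes(config: SimulationConfig, grs_high, diet_low,
                      covariates: pd.DataFrame,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Paired-eye binary outcomes under the generating logistic model.

    Returns one row per *present* eye (each eye is absent independently
    with ``missing_eye_prob``, but at least one eye is always kept):
    columns subject_id, eye, outcome.  Marginal P(outcome=1) equals
    expit(eta) exactly; ``subject_effect_sd`` sets inter-eye concordance
    via the shared latent threshold construction (module docstring).
    """
    rng = config.rng() if rng is None else rng
    g = np.asarray(grs_high, dtype=float)
    d = np.asarray(diet_low, dtype=float)
    n = config.n_subjects
    if not (len(g) == len(d) == len(covariates) == n):
        raise CohortIOError("grs_high, diet_low and covariates must have n_subjects entries")
    p = expit(_linear_predictor(config, g, d, covariates))

    sd = config.subject_effect_sd
    u = rng.normal(0.0, sd, n)
    denom = np.sqrt(1.0 + sd**2)
    rows = []
    for eye_pos, eye in enumerate(("right", "left")):
        e = rng.normal(0.0, 1.0, n)
        z = (u + e) / denom
        y = (norm.cdf(z) < p).astype(int)
        present = rng.random(n) >= config.missing_eye_prob
        for i in range(n):
            rows.append((covariates["subject_id"].iloc[i], eye, int(y[i]), bool(present[i])))
    df = pd.DataFrame(rows, columns=["subject_id", "eye", "outcome", "present"])
    # guarantee at least one gradable eye per subject
    both_missing = ~df.groupby("subject_id")["present"].transform("any")
    df.loc[both_missing & (df["eye"] == "right"), "present"] = True
    return df[df["present"]].drop(columns="present").reset_index(drop=True)


def simulate_eye_records(config: SimulationConfig,
                         rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Directly generate an analysis-ready eye-record table.

    Exposure flags are drawn Bernoulli(``p_high_grs``, ``p_diet_low``)
    independently — the genotype->GRS and FFQ->mediSCORE stages are
    bypassed — so this is the fast path for parameter-recovery and
    calibration studies of the modelling stages.
    """
    rng = config.rng() if rng is None else rng
    cov = _simulate_covariates(config, rng)
    g = rng.random(config.n_subjects) < config.p_high_grs
    d = rng.random(config.n_subjects) < config.p_diet_low
    outcomes = simulate_outcomes(config, g, d, cov, rng)

    from .phenotype import age_category

    cov = cov.set_index("subject_id")
    flags = pd.DataFrame({"high_grs": g, "high_mediscore": ~d}, index=cov.index)
    rec = outcomes.merge(cov, on="subject_id").merge(flags, on="subject_id")
    rec["age_cat"] = [age_category(a) for a in rec["age"]]
    return rec


# ---------------------------------------------------------------------------
# Full cohort
# ---------------------------------------------------------------------------

_CASE_STAGE_PROBS = {"2a": 0.35, "2b": 0.15, "3": 0.30, "4": 0.20}


def simulate_cohort(config: SimulationConfig) -> dict:
    """Generate the five pipeline inputs for one cohort.

    Returns a dict with keys ``ffq``, ``catalog``, ``weights``,
    ``genotypes``, ``phenotypes`` (DataFrames) and ``manifest`` (the
    config as a plain dict).  Eye outcomes are mapped to Rotterdam
    stages: affected eyes draw a stage from {2a, 2b, 3, 4}, unaffected
    eyes are stage 0; ages are kept above 60 so stage-0 subjects satisfy
    the control age rule.
    """
    rng = config.rng()
    weights = default_variant_weights()
    if config.betas is not None:
        weights = weights.copy()
        weights["beta"] = np.asarray(config.betas, dtype=float)

    genotypes = simulate_genotypes(config, rng, weights)
    grs_table = grs_mod.grs_table(genotypes, weights)
    # subjects with an invalid GRS (missing major variant) get a placeholder
    # low flag here; the pipeline drops them at record-building time anyway
    high_grs = grs_table["high_grs"].fillna(False).to_numpy(dtype=bool)

    shift = None
    dep = config.diet_genetic_dependence
    if dep != 0.0:
        scores = grs_table["grs"].to_numpy(dtype=float)
        mean = np.nanmean(scores)
        sd = np.nanstd(scores) or 1.0
        shift = dep * np.nan_to_num((scores - mean) / sd)
    ffq, catalog = simulate_ffq(config, rng, latent_shift=shift)

    covariates = _simulate_covariates(config, rng)
    scores, _ = diet_mod.score_cohort(ffq, catalog, covariates)
    diet_low = ~scores.set_index("subject_id")["high_adherence"].reindex(
        covariates["subject_id"]
    ).to_numpy(dtype=bool)

    outcomes = simulate_outcomes(config, high_grs, diet_low, covariates, rng)

    stage_names = list(_CASE_STAGE_PROBS)
    stage_p = np.array(list(_CASE_STAGE_PROBS.values()))
    eye_stage = {}
    for _, row in outcomes.iterrows():
        stage = rng.choice(stage_names, p=stage_p) if row["outcome"] else "0"
        eye_stage[(row["subject_id"], row["eye"])] = stage

    phen = covariates.copy()
    phen["stage_right"] = [eye_stage.get((sid, "right"), "missing") for sid in phen["subject_id"]]
    phen["stage_left"] = [eye_stage.get((sid, "left"), "missing") for sid in phen["subject_id"]]
    phenotypes = validate_phenotypes(phen)

    return {
        "ffq": ffq,
        "catalog": catalog,
        "weights": weights,
        "genotypes": genotypes,
        "phenotypes": phenotypes,
        "manifest": config.to_manifest(),
    }


def write_cohort(config: SimulationConfig, out_dir) -> dict:
    """Simulate a cohort and write the five inputs plus a manifest to ``out_dir``.

    Genotypes are written as an uncompressed VCF (risk alleles placed on
    alternating REF/ALT sides to exercise orientation) and the tables as
    CSV.  Returns the paths written.
    """
    import json
    from pathlib import Path

    from . import io as io_mod

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(config)
    paths = {
        "ffq": out / "ffq.csv",
        "catalog": out / "food_catalog.csv",
        "weights": out / "variant_weights.csv",
        "genotypes": out / "genotypes.vcf",
        "phenotypes": out / "phenotypes.csv",
        "manifest": out / "manifest.json",
    }
    io_mod.write_ffq_table(cohort["ffq"], paths["ffq"])
    io_mod.write_food_catalog(cohort["catalog"], paths["catalog"])
    io_mod.write_variant_weights(cohort["weights"], paths["weights"])
    orient = [i % 2 == 0 for i in range(cohort["genotypes"].shape[1])]
    io_mod.write_genotypes_vcf(cohort["genotypes"], cohort["weights"], paths["genotypes"],
                               risk_as_alt=orient)
    io_mod.write_phenotypes(cohort["phenotypes"], paths["phenotypes"])
    with open(paths["manifest"], "w") as fh:
        json.dump(cohort["manifest"], fh, indent=2, default=str)
    return {k: str(v) for k, v in paths.items()}
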