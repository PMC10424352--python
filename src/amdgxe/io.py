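"""Readers, writers and load-time validation for cohort tables and genotypes.

All tabular inputs are plain CSV; genotypes may additionally come from a
VCF (v4.2+, ``GT`` field only).  Tables are carried in memory as pandas
DataFrames with canonical dtypes; validation happens at load time and
raises :class:`CohortIOError` naming the offending row, so downstream
modules can assume clean inputs.

Genotype counts are always *risk-allele* counts: when reading a VCF, each
call is oriented against the risk allele declared in the variant-weight
table, never assumed to be ALT.  The CSV genotype alternative is
documented as already risk-oriented.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CohortIOError",
    "FREQUENCY_LEVELS",
    "FOOD_GROUPS",
    "MEDISCORE_BENEFICIAL",
    "MEDISCORE_DETRIMENTAL",
    "MAJOR_VARIANTS",
    "ROTTERDAM_STAGES",
    "CASE_STAGES",
    "ENROLMENT_AGE_FLOOR",
    "read_ffq_table",
    "read_food_catalog",
    "read_variant_weights",
    "read_genotypes",
    "read_genotypes_csv",
    "read_genotypes_vcf",
    "read_phenotypes",
    "write_ffq_table",
    "write_food_catalog",
    "write_variant_weights",
    "write_genotypes_csv",
    "write_genotypes_vcf",
    "write_phenotypes",
    "default_variant_weights",
    "worked_example_joint_ors",
]


class CohortIOError(ValueError):
    """Raised when an input table fails validation at load time."""


#: The nine frequency-of-intake categories of the food questionnaire,
#: ordered from least to most frequent.
FREQUENCY_LEVELS: tuple[str, ...] = (
    "never or less than 1 time/month",
    "1-3 times/month",
    "1 time/week",
    "2-4 times/week",
    "5-6 times/week",
    "1 time/day",
    "2-3 times/day",
    "4-5 times/day",
    "6 or more times/day",
)

#: Food groups an item may belong to.  ``fat_only`` items contribute only
#: to the MUFA/SFA lipid ratio; ``other`` items contribute to nothing.
FOOD_GROUPS: tuple[str, ...] = (
    "vegetables",
    "legumes",
    "fruits",
    "cereals",
    "fish",
    "meat",
    "dairy",
    "alcohol",
    "fat_only",
    "other",
)

MEDISCORE_BENEFICIAL: tuple[str, ...] = ("vegetables", "legumes", "fruits", "cereals", "fish")
MEDISCORE_DETRIMENTAL: tuple[str, ...] = ("meat", "dairy")

#: The five major AMD risk variants whose complete genotyping is required
#: for a valid genetic risk score (two in CFH, one each in C2/CFB/SKIV2L,
#: ARMS2/HTRA1 and C3).
MAJOR_VARIANTS: tuple[str, ...] = (
    "rs570618",
    "rs10922109",
    "rs429608",
    "rs3750846",
    "rs2230199",
)

ROTTERDAM_STAGES: tuple[str, ...] = ("0", "1", "2a", "2b", "3", "4")
CASE_STAGES: frozenset[str] = frozenset({"2a", "2b", "3", "4"})
STAGE_MISSING = "missing"

#: Study enrolment floor (years); younger subjects are rejected at load.
ENROLMENT_AGE_FLOOR = 55.0

_SEXES = ("female", "male")
_SMOKING = ("non-smoker", "smoker/ex-smoker")

_TRUTHY = {"true", "yes", "1", "t", "y"}
_FALSY = {"false", "no", "0", "f", "n"}


def _parse_bool(value, *, field: str, row: int):
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    text = str(value).strip().lower()
    if text in _TRUTHY:
        return True
    if text in _FALSY:
        return False
    raise CohortIOError(f"row {row}: cannot interpret {field}={value!r} as a boolean")


def _require_columns(df: pd.DataFrame, columns: Sequence[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise CohortIOError(f"{what}: missing required column(s) {missing}; found {list(df.columns)}")


# ---------------------------------------------------------------------------
# FFQ responses and food catalog
# ---------------------------------------------------------------------------

FFQ_COLUMNS = ("subject_id", "item_id", "frequency_category", "servings_per_occasion", "seasonal")
CATALOG_COLUMNS = ("item_id", "grams_per_serving", "mufa_per_100g", "sfa_per_100g", "group")


def validate_ffq(df: pd.DataFrame, catalog: pd.DataFrame | None = None) -> pd.DataFrame:
    """Validate an FFQ response table, returning a canonical copy.

    Each row is one subject x food-item answer.  Frequency categories must
    be one of the nine enumerated levels; serving counts must be positive;
    item ids must resolve against ``catalog`` when one is given.
    """
    _require_columns(df, FFQ_COLUMNS, "FFQ table")
    out = df.loc[:, list(FFQ_COLUMNS)].copy()
    out["subject_id"] = out["subject_id"].astype(str)
    out["item_id"] = out["item_id"].astype(str)
    known_items = None if catalog is None else set(catalog["item_id"].astype(str))
    levels = set(FREQUENCY_LEVELS)
    seasonal = []
    for pos, (idx, row) in enumerate(out.iterrows(), start=1):
        if row["frequency_category"] not in levels:
            raise CohortIOError(
                f"row {pos}: unknown frequency category {row['frequency_category']!r}; "
                f"expected one of the nine enumerated levels"
            )
        if known_items is not None and row["item_id"] not in known_items:
            raise CohortIOError(f"row {pos}: unknown item_id {row['item_id']!r}")
        servings = float(row["servings_per_occasion"])
        if not servings > 0:
            raise CohortIOError(f"row {pos}: servings_per_occasion must be > 0, got {servings}")
        seasonal.append(_parse_bool(row["seasonal"], field="seasonal", row=pos))
    out["servings_per_occasion"] = out["servings_per_occasion"].astype(float)
    out["seasonal"] = seasonal
    return out.reset_index(drop=True)


def read_ffq_table(path, catalog: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read and validate an FFQ response CSV (one row per subject x item)."""
    df = pd.read_csv(path, dtype={"subject_id": str, "item_id": str})
    return validate_ffq(df, catalog)


def validate_food_catalog(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, CATALOG_COLUMNS, "food catalog")
    out = df.loc[:, list(CATALOG_COLUMNS)].copy()
    out["item_id"] = out["item_id"].astype(str)
    if out["item_id"].duplicated().any():
        dup = out.loc[out["item_id"].duplicated(), "item_id"].iloc[0]
        raise CohortIOError(f"food catalog: duplicated item_id {dup!r}")
    for pos, (_, row) in enumerate(out.iterrows(), start=1):
        if not float(row["grams_per_serving"]) > 0:
            raise CohortIOError(f"row {pos}: grams_per_serving must be > 0")
        if float(row["mufa_per_100g"]) < 0 or float(row["sfa_per_100g"]) < 0:
            raise CohortIOError(f"row {pos}: lipid contents must be >= 0")
        if row["group"] not in FOOD_GROUPS:
            raise CohortIOError(f"row {pos}: unknown food group {row['group']!r}")
    for col in ("grams_per_serving", "mufa_per_100g", "sfa_per_100g"):
        out[col] = out[col].astype(float)
    return out.reset_index(drop=True)


def read_food_catalog(path) -> pd.DataFrame:
    """Read and validate a food composition/mapping CSV."""
    return validate_food_catalog(pd.read_csv(path, dtype={"item_id": str}))


# ---------------------------------------------------------------------------
# Variant weights
# ---------------------------------------------------------------------------

WEIGHTS_COLUMNS = ("variant_id", "risk_allele", "beta", "is_major")


def validate_variant_weights(df: pd.DataFrame, *, require_canonical: bool = False) -> pd.DataFrame:
    """Validate a per-variant effect-size table.

    With ``require_canonical=True`` the table must have exactly 52 rows of
    which exactly five are flagged major, and the five majors must be the
    canonical major risk variants (CFH rs570618, CFH rs10922109,
    C2/CFB/SKIV2L rs429608, ARMS2/HTRA1 rs3750846, C3 rs2230199).
    """
    _require_columns(df, WEIGHTS_COLUMNS, "variant weights")
    out = df.loc[:, list(WEIGHTS_COLUMNS)].copy()
    out["variant_id"] = out["variant_id"].astype(str)
    out["risk_allele"] = out["risk_allele"].astype(str)
    out["beta"] = out["beta"].astype(float)
    out["is_major"] = [
        _parse_bool(v, field="is_major", row=i) for i, v in enumerate(out["is_major"], start=1)
    ]
    if out["variant_id"].duplicated().any():
        dup = out.loc[out["variant_id"].duplicated(), "variant_id"].iloc[0]
        raise CohortIOError(f"variant weights: duplicated variant_id {dup!r}")
    if require_canonical:
        if len(out) != 52:
            raise CohortIOError(f"canonical weight table must have 52 rows, got {len(out)}")
        majors = set(out.loc[out["is_major"], "variant_id"])
        if majors != set(MAJOR_VARIANTS):
            raise CohortIOError(
                f"canonical weight table must flag exactly the five major variants "
                f"{sorted(MAJOR_VARIANTS)}, got {sorted(majors)}"
            )
    return out.reset_index(drop=True)


def read_variant_weights(path, *, require_canonical: bool = False) -> pd.DataFrame:
    """Read a variant-weight CSV: variant_id, risk_allele, beta, is_major."""
    return validate_variant_weights(
        pd.read_csv(path, dtype={"variant_id": str, "risk_allele": str}),
        require_canonical=require_canonical,
    )


def default_variant_weights() -> pd.DataFrame:
    """The packaged 52-variant weight table.

    The five major risk variants carry their field rsIDs; the remaining 47
    entries (ids, risk alleles and effect sizes) are synthetic stand-ins at
    literature-typical magnitudes, shipped so the whole pipeline runs
    without external weight data.
    """
    from importlib.resources import files

    path = files("amdgxe.data").joinpath("synthetic_variant_weights.csv")
    with path.open("r") as fh:
        return read_variant_weights(fh, require_canonical=True)


def worked_example_joint_ors() -> dict:
    """Packaged worked example: adjusted joint-exposure odds ratios.

    Three ORs for dichotomized GRS x Mediterranean-diet adherence versus
    the joint reference (high adherence, low GRS), as reported by an
    eye-level GEE analysis of a Portuguese AMD case-control cohort.  Used
    by the examples and the acceptance script to exercise the interaction
    formulas on published-scale numbers.
    """
    import json
    from importlib.resources import files

    path = files("amdgxe.data").joinpath("worked_example_joint_ors.json")
    with path.open("r") as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


def validate_genotypes(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a subjects x variants matrix of risk-allele counts.

    Values must be in {0, 1, 2} or missing (NaN); anything else is
    rejected.  Index is subject_id, columns are variant ids.
    """
    out = df.astype(float)
    values = out.to_numpy()
    bad = ~(np.isnan(values) | (values == 0) | (values == 1) | (values == 2))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise CohortIOError(
            f"genotype matrix: invalid count {values[i, j]!r} for subject "
            f"{out.index[i]!r} at variant {out.columns[j]!r}; allowed values are 0, 1, 2 or missing"
        )
    out.index = out.index.astype(str)
    out.index.name = "subject_id"
    out.columns = out.columns.astype(str)
    return out


def read_genotypes_csv(path) -> pd.DataFrame:
    """Read an already risk-oriented genotype count CSV.

    Layout: first column ``subject_id``, one column per variant_id, values
    0/1/2 or NA.
    """
    df = pd.read_csv(path, dtype={"subject_id": str}).set_index("subject_id")
    return validate_genotypes(df)


def read_genotypes_vcf(path, weights: pd.DataFrame) -> pd.DataFrame:
    """Read genotypes from a VCF, orienting counts to the declared risk allele.

    Only the GT field is used; phased and unphased separators are both
    accepted.  Variants absent from ``weights`` are skipped with a logged
    warning; malformed or partial genotypes, and variants whose declared
    risk allele matches neither REF nor ALT, become missing.
    """
    import pysam

    weights = validate_variant_weights(weights)
    risk_by_variant = dict(zip(weights["variant_id"], weights["risk_allele"]))

    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        counts: dict[str, np.ndarray] = {}
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            vid = rec.id
            if vid is None or vid not in risk_by_variant:
                logger.warning("VCF variant %r not in weight table; skipped", vid)
                continue
            risk = risk_by_variant[vid]
            alleles = tuple(rec.alleles or ())
            col = np.full(len(samples), np.nan)
            if risk not in alleles:
                logger.warning(
                    "variant %s: risk allele %r matches neither REF nor ALT %s; all calls missing",
                    vid, risk, alleles,
                )
                counts[vid] = col
                continue
            for s_idx, sample in enumerate(samples):
                gt = rec.samples[sample].get("GT")
                if gt is None or len(gt) == 0 or any(a is None for a in gt):
                    continue  # missing / partial call
                try:
                    col[s_idx] = sum(1 for a in gt if alleles[a] == risk)
                except (IndexError, TypeError):
                    continue  # malformed GT -> missing
            counts[vid] = col

    matrix = pd.DataFrame(counts, index=pd.Index(samples, name="subject_id"))
    return validate_genotypes(matrix)


def read_genotypes(path, weights: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read genotypes from a VCF (requires ``weights``) or a count CSV."""
    suffix = Path(str(path)).suffix.lower()
    if suffix == ".vcf":
        if weights is None:
            raise CohortIOError("reading a VCF requires a variant-weight table for risk orientation")
        return read_genotypes_vcf(path, weights)
    return read_genotypes_csv(path)


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

PHENOTYPE_COLUMNS = ("subject_id", "age", "sex", "smoking", "exercise", "stage_right", "stage_left")


def _canonical_stage(value, *, row: int) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return STAGE_MISSING
    text = str(value).strip().lower()
    if text in ("", "na", "nan", STAGE_MISSING):
        return STAGE_MISSING
    # numeric stages may arrive as "3.0" from CSV round-trips
    if text.endswith(".0"):
        text = text[:-2]
    if text not in ROTTERDAM_STAGES:
        raise CohortIOError(
            f"row {row}: invalid Rotterdam stage {value!r}; expected one of "
            f"{ROTTERDAM_STAGES} or missing"
        )
    return text


def validate_phenotypes(df: pd.DataFrame) -> pd.DataFrame:
    """Validate per-subject phenotype records.

    Enforces the enrolment age floor (55 years), canonical sex/smoking
    levels, valid Rotterdam stages and at least one gradable eye.
    """
    _require_columns(df, PHENOTYPE_COLUMNS, "phenotype table")
    out = df.loc[:, list(PHENOTYPE_COLUMNS)].copy()
    out["subject_id"] = out["subject_id"].astype(str)
    if out["subject_id"].duplicated().any():
        dup = out.loc[out["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise CohortIOError(f"phenotype table: duplicated subject_id {dup!r}")
    exercise, stage_r, stage_l = [], [], []
    for pos, (_, row) in enumerate(out.iterrows(), start=1):
        age = float(row["age"])
        if age < ENROLMENT_AGE_FLOOR:
            raise CohortIOError(
                f"row {pos}: age {age} is below the enrolment floor of {ENROLMENT_AGE_FLOOR}"
            )
        if row["sex"] not in _SEXES:
            raise CohortIOError(f"row {pos}: sex must be one of {_SEXES}, got {row['sex']!r}")
        if row["smoking"] not in _SMOKING:
            raise CohortIOError(f"row {pos}: smoking must be one of {_SMOKING}, got {row['smoking']!r}")
        exercise.append(_parse_bool(row["exercise"], field="exercise", row=pos))
        sr = _canonical_stage(row["stage_right"], row=pos)
        sl = _canonical_stage(row["stage_left"], row=pos)
        if sr == STAGE_MISSING and sl == STAGE_MISSING:
            raise CohortIOError(f"row {pos}: subject {row['subject_id']} has no gradable eye")
        stage_r.append(sr)
        stage_l.append(sl)
    out["age"] = out["age"].astype(float)
    out["exercise"] = exercise
    out["stage_right"] = stage_r
    out["stage_left"] = stage_l
    return out.reset_index(drop=True)


def read_phenotypes(path) -> pd.DataFrame:
    """Read and validate the per-subject phenotype CSV."""
    df = pd.read_csv(path, dtype={"subject_id": str, "stage_right": str, "stage_left": str})
    return validate_phenotypes(df)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_ffq_table(df: pd.DataFrame, path) -> None:
    df.loc[:, list(FFQ_COLUMNS)].to_csv(path, index=False)


def write_food_catalog(df: pd.DataFrame, path) -> None:
    df.loc[:, list(CATALOG_COLUMNS)].to_csv(path, index=False)


def write_variant_weights(df: pd.DataFrame, path) -> None:
    df.loc[:, list(WEIGHTS_COLUMNS)].to_csv(path, index=False)


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.loc[:, list(PHENOTYPE_COLUMNS)].to_csv(path, index=False)


def write_genotypes_csv(matrix: pd.DataFrame, path) -> None:
    """Write a risk-oriented count matrix (NaN rendered as empty = NA)."""
    out = matrix.copy()
    # keep 0/1/2 as integers in the CSV where present
    out = out.map(lambda v: "" if pd.isna(v) else str(int(v)))
    out.to_csv(path, index=True, index_label="subject_id")


_BASES = ("A", "C", "G", "T")


def write_genotypes_vcf(matrix: pd.DataFrame, weights: pd.DataFrame, path,
                        risk_as_alt: bool | Sequence[bool] = True) -> None:
    """Write risk-allele counts to an (uncompressed) VCF.

    ``risk_as_alt`` controls whether each variant's risk allele is placed
    on the ALT side (True) or on the REF side (False); a sequence gives a
    per-variant choice, which exercises both orientations of the reader.
    Counts are encoded as unphased GT calls on a single synthetic contig.
    """
    import pysam

    weights = validate_variant_weights(weights)
    info = weights.set_index("variant_id")
    variants = list(matrix.columns)
    if isinstance(risk_as_alt, (bool, np.bool_)):
        orient = [bool(risk_as_alt)] * len(variants)
    else:
        orient = [bool(v) for v in risk_as_alt]
        if len(orient) != len(variants):
            raise CohortIOError("risk_as_alt sequence length must match the number of variants")

    header = pysam.VariantHeader()
    header.add_line("##contig=<ID=1,length=250000000>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for sid in matrix.index:
        header.add_sample(str(sid))

    gt_map = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for j, vid in enumerate(variants):
            if vid not in info.index:
                raise CohortIOError(f"variant {vid!r} missing from the weight table")
            risk = info.loc[vid, "risk_allele"]
            other = next(b for b in _BASES if b != (risk[0] if risk else "A"))
            ref, alt = (other, risk) if orient[j] else (risk, other)
            rec = vcf.new_record(contig="1", start=1000 * (j + 1), alleles=(ref, alt), id=vid)
            for sid in matrix.index:
                count = matrix.at[sid, vid]
                if pd.isna(count):
                    rec.samples[str(sid)]["GT"] = (None, None)
                    continue
                alt_count = int(count) if orient[j] else 2 - int(count)
                rec.samples[str(sid)]["GT"] = gt_map[alt_count]
                rec.samples[str(sid)].phased = False
            vcf.write(rec)
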