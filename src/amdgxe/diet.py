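"""Mediterranean-diet adherence scoring from food-frequency questionnaires.

The pipeline here is: questionnaire answer -> average daily grams per food
item -> per-subject food-group totals (plus a MUFA/SFA lipid ratio) ->
nine 0/1 components judged against sex-specific median cut-offs -> a 0-9
adherence score (the "mediSCORE"), dichotomized at >= 6 for high
adherence.

Component rules
---------------
* Beneficial groups (vegetables, legumes, fruits, cereals, fish): one
  point for consumption strictly above the sex-specific median.
* Detrimental groups (meat, dairy): one point for consumption at or below
  the median.
* Alcohol: one point for moderate intake — 10-50 g/day for men, 5-25
  g/day for women, endpoints inclusive.  Intakes are ethanol grams/day as
  supplied by the catalog (an assumption the catalog must honour).
* Lipids: one point when the ratio of monounsaturated to saturated fat
  grams across all items is strictly above the sex-specific median ratio.

Cut-offs may be computed on the scored cohort itself or loaded from an
external reference population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    CohortIOError,
    FREQUENCY_LEVELS,
    MEDISCORE_BENEFICIAL,
    MEDISCORE_DETRIMENTAL,
)

__all__ = [
    "DEFAULT_FREQUENCY_MAPPING",
    "ALCOHOL_RANGES",
    "HIGH_ADHERENCE_THRESHOLD",
    "MediScoreCutoffs",
    "frequency_to_daily",
    "item_daily_grams",
    "daily_intakes",
    "aggregate_groups",
    "sex_specific_medians",
    "mediscore",
    "score_cohort",
]

#: Occasions/day for each of the nine frequency categories: category
#: midpoints on a per-month (30.44-day), per-week or per-day basis; the
#: lowest category is mapped to zero by convention.
DEFAULT_FREQUENCY_MAPPING: dict[str, float] = {
    FREQUENCY_LEVELS[0]: 0.0,          # never or less than 1 time/month
    FREQUENCY_LEVELS[1]: 2.0 / 30.44,  # 1-3 times/month
    FREQUENCY_LEVELS[2]: 1.0 / 7.0,    # 1 time/week
    FREQUENCY_LEVELS[3]: 3.0 / 7.0,    # 2-4 times/week
    FREQUENCY_LEVELS[4]: 5.5 / 7.0,    # 5-6 times/week
    FREQUENCY_LEVELS[5]: 1.0,          # 1 time/day
    FREQUENCY_LEVELS[6]: 2.5,          # 2-3 times/day
    FREQUENCY_LEVELS[7]: 4.5,          # 4-5 times/day
    FREQUENCY_LEVELS[8]: 6.0,          # 6 or more times/day
}

#: Down-weighting applied to seasonal items (available ~3 months/year).
SEASONAL_FACTOR = 0.25

#: Moderate-alcohol windows in ethanol grams/day, endpoints inclusive.
ALCOHOL_RANGES: dict[str, tuple[float, float]] = {
    "male": (10.0, 50.0),
    "female": (5.0, 25.0),
}

HIGH_ADHERENCE_THRESHOLD = 6

_CONTINUOUS_GROUPS = MEDISCORE_BENEFICIAL + MEDISCORE_DETRIMENTAL  # median-based components
GROUP_COLUMNS = _CONTINUOUS_GROUPS + ("alcohol",)
COMPONENT_NAMES = _CONTINUOUS_GROUPS + ("alcohol", "fat_ratio")


@dataclass
class MediScoreCutoffs:
    """Sex-specific cut-offs for the nine adherence components.

    ``medians`` maps sex -> {group or "mufa_sfa_ratio" -> median grams/day
    (or ratio)}; alcohol uses fixed per-sex windows instead of a median.
    """

    medians: dict[str, dict[str, float]]
    alcohol_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(ALCOHOL_RANGES)
    )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"sex": sex, "variable": var, "median": val}
            for sex, d in self.medians.items()
            for var, val in d.items()
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MediScoreCutoffs":
        medians: dict[str, dict[str, float]] = {}
        for _, row in df.iterrows():
            medians.setdefault(str(row["sex"]), {})[str(row["variable"])] = float(row["median"])
        return cls(medians=medians)


def frequency_to_daily(frequency_category: str,
                       mapping: dict[str, float] | None = None) -> float:
    """Occasions per day for one of the nine frequency categories."""
    mapping = DEFAULT_FREQUENCY_MAPPING if mapping is None else mapping
    try:
        return mapping[frequency_category]
    except KeyError:
        raise CohortIOError(f"unknown frequency category {frequency_category!r}") from None


def item_daily_grams(frequency_category: str, servings_per_occasion: float,
                     grams_per_serving: float, seasonal: bool,
                     mapping: dict[str, float] | None = None) -> float:
    """Average daily grams for one questionnaire answer.

    occasions/day x servings/occasion x grams/serving, scaled by 0.25 when
    the item is seasonal (available about three months of the year).
    """
    grams = (
        frequency_to_daily(frequency_category, mapping)
        * float(servings_per_occasion)
        * float(grams_per_serving)
    )
    return grams * SEASONAL_FACTOR if seasonal else grams


def daily_intakes(ffq: pd.DataFrame, catalog: pd.DataFrame,
                  mapping: dict[str, float] | None = None) -> pd.DataFrame:
    """Per-answer daily gram intakes (columns: subject_id, item_id, grams_per_day)."""
    info = catalog.set_index("item_id")
    missing = set(ffq["item_id"]) - set(info.index)
    if missing:
        raise CohortIOError(f"FFQ references items absent from the catalog: {sorted(missing)[:5]}")
    mapping = DEFAULT_FREQUENCY_MAPPING if mapping is None else mapping
    freq = ffq["frequency_category"].map(mapping)
    if freq.isna().any():
        bad = ffq.loc[freq.isna(), "frequency_category"].iloc[0]
        raise CohortIOError(f"unknown frequency category {bad!r}")
    grams = (
        freq.to_numpy()
        * ffq["servings_per_occasion"].to_numpy(dtype=float)
        * info.loc[ffq["item_id"], "grams_per_serving"].to_numpy()
        * np.where(ffq["seasonal"].to_numpy(dtype=bool), SEASONAL_FACTOR, 1.0)
    )
    return pd.DataFrame(
        {"subject_id": ffq["subject_id"].to_numpy(), "item_id": ffq["item_id"].to_numpy(),
         "grams_per_day": grams}
    )


def aggregate_groups(intakes: pd.DataFrame, catalog: pd.DataFrame,
                     phenotypes: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-subject food-group totals and the MUFA/SFA lipid ratio.

    ``fat_only`` items contribute only to the lipid ratio; ``other`` items
    contribute to nothing but the ratio's numerator/denominator (every
    item's lipids count).  The ratio is missing (NaN) when total saturated
    fat is zero.  If ``phenotypes`` is given, a ``sex`` column is merged in.
    """
    info = catalog.set_index("item_id")
    df = intakes.copy()
    df["group"] = info.loc[df["item_id"], "group"].to_numpy()
    df["mufa_g"] = df["grams_per_day"] * info.loc[df["item_id"], "mufa_per_100g"].to_numpy() / 100.0
    df["sfa_g"] = df["grams_per_day"] * info.loc[df["item_id"], "sfa_per_100g"].to_numpy() / 100.0

    subjects = pd.Index(pd.unique(df["subject_id"]), name="subject_id")
    out = pd.DataFrame(0.0, index=subjects, columns=list(GROUP_COLUMNS))
    totals = df[df["group"].isin(GROUP_COLUMNS)].pivot_table(
        index="subject_id", columns="group", values="grams_per_day", aggfunc="sum"
    )
    for col in totals.columns:
        out.loc[totals.index, col] = totals[col].fillna(0.0)

    lipid = df.groupby("subject_id")[["mufa_g", "sfa_g"]].sum()
    ratio = np.where(lipid["sfa_g"] > 0, lipid["mufa_g"] / lipid["sfa_g"].replace(0, np.nan), np.nan)
    out["mufa_sfa_ratio"] = pd.Series(ratio, index=lipid.index).reindex(subjects)

    out = out.reset_index()
    if phenotypes is not None:
        out = out.merge(phenotypes[["subject_id", "sex"]], on="subject_id", how="left")
        if out["sex"].isna().any():
            missing = out.loc[out["sex"].isna(), "subject_id"].iloc[0]
            raise CohortIOError(f"subject {missing!r} has intakes but no phenotype record")
    return out


def _median(values: np.ndarray) -> float:
    # midpoint-of-middle-two convention for even counts (numpy default)
    return float(np.median(values))


def sex_specific_medians(group_intakes: pd.DataFrame) -> MediScoreCutoffs:
    """Per-sex medians for the seven median-based groups and the lipid ratio."""
    if "sex" not in group_intakes.columns:
        raise CohortIOError("group intakes need a 'sex' column to compute sex-specific medians")
    medians: dict[str, dict[str, float]] = {}
    for sex in ("female", "male"):
        stratum = group_intakes[group_intakes["sex"] == sex]
        if stratum.empty:
            raise CohortIOError(f"cannot compute medians: no subjects with sex {sex!r}")
        d = {g: _median(stratum[g].to_numpy()) for g in _CONTINUOUS_GROUPS}
        ratios = stratum["mufa_sfa_ratio"].dropna().to_numpy()
        d["mufa_sfa_ratio"] = _median(ratios) if len(ratios) else np.nan
        medians[sex] = d
    return MediScoreCutoffs(medians=medians)


def mediscore(group_intakes: pd.DataFrame, cutoffs: MediScoreCutoffs) -> pd.DataFrame:
    """Score each subject's nine adherence components.

    Returns one row per subject: the nine 0/1 components, their sum
    (``total``, 0-9) and ``high_adherence`` (total >= 6).  Subjects with a
    missing lipid ratio get a zero fat component and ``ratio_missing`` set.
    """
    if "sex" not in group_intakes.columns:
        raise CohortIOError("group intakes need a 'sex' column for sex-specific scoring")
    rows = []
    for _, rec in group_intakes.iterrows():
        sex = rec["sex"]
        med = cutoffs.medians[sex]
        comp = {}
        for g in MEDISCORE_BENEFICIAL:
            comp[g] = int(rec[g] > med[g])
        for g in MEDISCORE_DETRIMENTAL:
            comp[g] = int(rec[g] <= med[g])
        lo, hi = cutoffs.alcohol_ranges[sex]
        comp["alcohol"] = int(lo <= rec["alcohol"] <= hi)
        ratio = rec["mufa_sfa_ratio"]
        ratio_missing = pd.isna(ratio) or pd.isna(med["mufa_sfa_ratio"])
        comp["fat_ratio"] = 0 if ratio_missing else int(ratio > med["mufa_sfa_ratio"])
        total = sum(comp.values())
        rows.append(
            {"subject_id": rec["subject_id"], **comp, "total": total,
             "high_adherence": total >= HIGH_ADHERENCE_THRESHOLD,
             "ratio_missing": bool(ratio_missing)}
        )
    return pd.DataFrame(rows)


def score_cohort(ffq: pd.DataFrame, catalog: pd.DataFrame, phenotypes: pd.DataFrame,
                 cutoffs: MediScoreCutoffs | None = None,
                 mapping: dict[str, float] | None = None) -> tuple[pd.DataFrame, MediScoreCutoffs]:
    """FFQ answers -> mediSCORE table, computing cut-offs on the cohort if not given."""
    intakes = daily_intakes(ffq, catalog, mapping)
    groups = aggregate_groups(intakes, catalog, phenotypes)
    if cutoffs is None:
        cutoffs = sex_specific_medians(groups)
    return mediscore(groups, cutoffs), cutoffs
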