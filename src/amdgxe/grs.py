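"""Weighted genetic risk score (GRS) over AMD-associated variants.

GRS = sum over variants of (risk-allele count x per-allele log odds
ratio).  A subject's score is valid only if all five major risk variants
are genotyped; missing non-major genotypes contribute zero (no
imputation), and a per-subject count of missing variants is carried so
downstream analyses can filter on missingness if they wish.  High genetic
risk is defined as a score at or above the median of the included
population.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import CohortIOError, validate_variant_weights

__all__ = ["compute_grs", "dichotomize_grs", "grs_table"]


def compute_grs(genotypes: pd.DataFrame, weights: pd.DataFrame) -> pd.DataFrame:
    """Per-subject weighted risk score.

    Returns a DataFrame with columns ``subject_id``, ``grs`` (NaN when
    invalid), ``n_missing_variants`` and ``included``.  A subject is
    excluded (grs = NaN) when any major variant's genotype is missing.
    """
    weights = validate_variant_weights(weights)
    unknown = set(genotypes.columns) - set(weights["variant_id"])
    if unknown:
        raise CohortIOError(f"genotype matrix has variants absent from the weight table: {sorted(unknown)[:5]}")

    beta = weights.set_index("variant_id")["beta"].reindex(genotypes.columns)
    majors = [v for v in weights.loc[weights["is_major"], "variant_id"] if v in genotypes.columns]

    counts = genotypes.to_numpy(dtype=float)
    missing = np.isnan(counts)
    # missing non-major variants contribute 0; validity handled separately
    score = np.nansum(counts * beta.to_numpy(), axis=1)

    if majors:
        major_missing = genotypes[majors].isna().to_numpy().any(axis=1)
    else:
        major_missing = np.zeros(len(genotypes), dtype=bool)
    included = ~major_missing
    score = np.where(included, score, np.nan)

    return pd.DataFrame(
        {
            "subject_id": genotypes.index.astype(str),
            "grs": score,
            "n_missing_variants": missing.sum(axis=1),
            "included": included,
        }
    )


def dichotomize_grs(results: pd.DataFrame) -> pd.DataFrame:
    """Set ``high_grs`` = (grs >= median over included subjects).

    The median uses the midpoint-of-middle-two convention for even counts;
    a score exactly at the median counts as high.  ``high_grs`` is left NA
    for excluded subjects.
    """
    out = results.copy()
    valid = out.loc[out["included"], "grs"].to_numpy(dtype=float)
    if len(valid) == 0:
        raise CohortIOError("cannot dichotomize: no subject has a valid GRS")
    median = float(np.median(valid))
    high = pd.array(out["grs"].to_numpy(dtype=float) >= median, dtype="boolean")
    high[~out["included"].to_numpy(dtype=bool)] = pd.NA
    out["high_grs"] = high
    out.attrs["grs_median"] = median
    return out


def grs_table(genotypes: pd.DataFrame, weights: pd.DataFrame) -> pd.DataFrame:
    """Convenience wrapper: compute scores then dichotomize at the median."""
    return dichotomize_grs(compute_grs(genotypes, weights))
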