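"""Descriptive case/control comparison and end-to-end pipeline orchestration.

``compare_cases_controls`` builds the customary first table of a
case-control paper: counts and percentages (categorical) or mean and SD
(continuous) per group, compared with the rank-sum test for continuous
variables and the chi-squared test for categorical ones, switching to
Fisher's exact test for 2x2 tables when any expected cell count falls
below 5 (the textbook rule, configurable).

``run_pipeline`` chains every stage — simulate-or-load, diet scoring,
GRS, case/control classification, GEE fits with and without the
interaction term, interaction measures — into one reproducible bundle
with an exclusion log and a manifest (config hash, seed, version).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from . import diet as diet_mod
from . import grs as grs_mod
from . import io as io_mod
from .gee import ModelSpec, fit_records, odds_ratios
from .interaction import interaction_report
from .phenotype import build_eye_records, classify_subject
from .simulate import SimulationConfig, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = ["compare_cases_controls", "PipelineError", "run_pipeline"]

DEFAULT_CONTINUOUS = ("age", "grs", "mediscore")
DEFAULT_CATEGORICAL = ("sex", "smoking", "exercise", "high_grs", "high_mediscore")


def _fmt_count(n: int, total: int) -> str:
    pct = 100.0 * n / total if total else 0.0
    return f"{n} ({pct:.1f}%)"


def compare_cases_controls(subjects: pd.DataFrame,
                           continuous: tuple[str, ...] = DEFAULT_CONTINUOUS,
                           categorical: tuple[str, ...] = DEFAULT_CATEGORICAL,
                           expected_min: float = 5.0) -> pd.DataFrame:
    """Group comparison table over a per-subject frame with a ``status`` column.

    Returns one row per variable level: formatted summaries for cases and
    controls, the test used ("rank-sum", "chi-squared", "exact" or
    "skipped"), its p-value (on the variable's first row) and any note.
    """
    if "status" not in subjects.columns:
        raise ValueError("subject table needs a 'status' column with case/control labels")
    cases = subjects[subjects["status"] == "case"]
    controls = subjects[subjects["status"] == "control"]
    rows = []

    for var in continuous:
        if var not in subjects.columns:
            continue
        x, y = cases[var].dropna(), controls[var].dropna()
        if len(x) and len(y):
            stat = stats.mannwhitneyu(x, y, alternative="two-sided")
            test, p, note = "rank-sum", float(stat.pvalue), ""
        else:
            test, p, note = "skipped", np.nan, "a group is empty"
        rows.append({
            "variable": var, "level": "mean (SD)",
            "cases": f"{x.mean():.1f} ({x.std():.1f})",
            "controls": f"{y.mean():.1f} ({y.std():.1f})",
            "test": test, "p": p, "note": note,
        })

    for var in categorical:
        if var not in subjects.columns:
            continue
        table = pd.crosstab(subjects[var], subjects["status"])
        for grp in ("case", "control"):
            if grp not in table.columns:
                table[grp] = 0
        levels = list(table.index)
        if len(levels) < 2:
            test, p, note = "skipped", np.nan, "single level"
        else:
            counts = table[["case", "control"]].to_numpy()
            expected = stats.contingency.expected_freq(counts)
            if (expected < expected_min).any() and counts.shape == (2, 2):
                _, p = stats.fisher_exact(counts)
                test, note = "exact", ""
            else:
                chi2 = stats.chi2_contingency(counts, correction=False)
                test, p = "chi-squared", float(chi2.pvalue)
                note = ("expected count < 5 but table is not 2x2; chi-squared retained"
                        if (expected < expected_min).any() else "")
        for i, level in enumerate(levels):
            rows.append({
                "variable": var, "level": str(level),
                "cases": _fmt_count(int(table.loc[level, "case"]), len(cases)),
                "controls": _fmt_count(int(table.loc[level, "control"]), len(controls)),
                "test": test if i == 0 else "",
                "p": p if i == 0 else np.nan,
                "note": note if i == 0 else "",
            })
    return pd.DataFrame(rows)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                result = fn(*args, **kwargs)
            except Exception as err:
                raise PipelineError(f"stage {name!r} failed: {err}") from err
            logger.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)
            return result
        return wrapper
    return deco


@_stage("load")
def _load_inputs(config: dict) -> dict:
    if "simulate" in config:
        sim_cfg = SimulationConfig(**config["simulate"])
        return simulate_cohort(sim_cfg)
    paths = config["inputs"]
    catalog = io_mod.read_food_catalog(paths["catalog"])
    weights = io_mod.read_variant_weights(paths["weights"])
    return {
        "ffq": io_mod.read_ffq_table(paths["ffq"], catalog),
        "catalog": catalog,
        "weights": weights,
        "genotypes": io_mod.read_genotypes(paths["genotypes"], weights),
        "phenotypes": io_mod.read_phenotypes(paths["phenotypes"]),
        "manifest": {"inputs": {k: str(v) for k, v in paths.items()}},
    }


@_stage("score-diet")
def _score_diet(cohort: dict, config: dict):
    cutoffs_cfg = config.get("cutoffs", "auto")
    cutoffs = None
    if cutoffs_cfg != "auto":
        cutoffs = diet_mod.MediScoreCutoffs.from_frame(pd.read_csv(cutoffs_cfg))
    return diet_mod.score_cohort(cohort["ffq"], cohort["catalog"], cohort["phenotypes"],
                                 cutoffs=cutoffs)


@_stage("grs")
def _grs(cohort: dict) -> pd.DataFrame:
    return grs_mod.grs_table(cohort["genotypes"], cohort["weights"])


@_stage("classify")
def _classify(cohort: dict, grs_results, scores):
    return build_eye_records(cohort["phenotypes"], grs_results, scores)


@_stage("fit")
def _fit(records: pd.DataFrame):
    fit = fit_records(records, ModelSpec(diet_coding="protective", include_interaction=False))
    return fit, odds_ratios(fit)


@_stage("interact")
def _interact(records: pd.DataFrame, config: dict):
    boot = config.get("bootstrap", {})
    return interaction_report(records, n_boot=int(boot.get("n_boot", 0)),
                              seed=int(boot.get("seed", 0)))


def run_pipeline(config: dict, out_dir=None) -> dict:
    """Execute the full analysis and return the result bundle.

    ``config`` either holds a ``simulate`` section (SimulationConfig
    fields) or an ``inputs`` section with the five file paths; optional
    keys: ``cutoffs`` ("auto" or a CSV path) and ``bootstrap``
    ({n_boot, seed}).  With ``out_dir`` set, the bundle is also written
    as CSV/JSON files.  Any stage failure raises :class:`PipelineError`
    naming the stage.
    """
    cohort = _load_inputs(config)
    scores, cutoffs = _score_diet(cohort, config)
    grs_results = _grs(cohort)
    records, exclusions = _classify(cohort, grs_results, scores)
    if records.empty:
        raise PipelineError("stage 'classify' failed: no analysable eye records remain")
    fit, or_table = _fit(records)
    interact = _interact(records, config)

    subjects = records.drop_duplicates("subject_id")
    table1 = compare_cases_controls(subjects)

    config_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest = {
        **cohort["manifest"],
        "config_hash": config_hash,
        "package_version": __version__,
        "n_subjects_input": int(len(cohort["phenotypes"])),
        "n_subjects_retained": int(subjects["subject_id"].nunique()),
        "n_eyes": int(len(records)),
        "n_excluded": int(len(exclusions)),
    }

    bundle = {
        "table1": table1,
        "main_ors": or_table,
        "main_fit": fit,
        "interaction": interact,
        "records": records,
        "exclusions": exclusions,
        "cutoffs": cutoffs,
        "manifest": manifest,
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table1.to_csv(out / "table1_comparison.csv", index=False)
        or_table.to_csv(out / "main_ors.csv")
        records.to_csv(out / "eye_records.csv", index=False)
        exclusions.to_csv(out / "exclusions.csv", index=False)
        cutoffs.to_frame().to_csv(out / "mediscore_cutoffs.csv", index=False)
        with open(out / "interaction.json", "w") as fh:
            json.dump(interact.to_dict(), fh, indent=2, default=float)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    return bundle
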