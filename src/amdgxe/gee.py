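"""Eye-level logistic regression via generalized estimating equations.

The analysis unit is the individual eye; the two eyes of a subject form a
cluster whose within-cluster association is absorbed by an exchangeable
working correlation.  The solver iterates the standard GEE loop: given
the current coefficients, Pearson residuals yield a moment estimate of
the common correlation alpha (and scale), then a Fisher-scoring step
updates the coefficients using the working covariance.  Variances are the
robust (sandwich) kind throughout — the only variance reported.

For an exchangeable correlation matrix R = (1-a)I + aJ the inverse is
available in closed form, R^-1 = I/(1-a) - a J / ((1-a)(1+(s-1)a)) for
cluster size s, so the whole update is vectorised over clusters; with
singleton clusters and alpha fixed at zero the fit reduces exactly to
ordinary logistic regression.

Conventions match the usual moment estimator: scale = sum(r^2)/(N-p) and
alpha = sum of within-cluster residual cross-products / (scale *
(n_pairs - p)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

__all__ = ["GeeError", "ModelSpec", "GeeFit", "build_design", "fit_gee_logistic",
           "fit_records", "odds_ratios"]


class GeeError(RuntimeError):
    """Raised for rank-deficient designs or other unfittable models."""


@dataclass
class ModelSpec:
    """Which covariates enter the eye-level logistic model.

    diet_coding:
        "protective" — the diet indicator is 1 for high adherence (the
        usual coding); "risk" — 1 for low adherence, which makes both
        exposures risk factors and (high adherence, low GRS) the joint
        reference, as interaction measures require.
    include_interaction:
        add the GRS x diet product term.
    adjusted:
        include sex, age category, smoking and exercise.
    """

    diet_coding: str = "protective"
    include_interaction: bool = False
    adjusted: bool = True

    def __post_init__(self) -> None:
        if self.diet_coding not in ("protective", "risk"):
            raise ValueError("diet_coding must be 'protective' or 'risk'")

    @property
    def diet_term(self) -> str:
        return "high_mediscore" if self.diet_coding == "protective" else "low_mediscore"


def build_design(records: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Design matrix (with intercept) for the eye-level model.

    Reference levels: low GRS, the unexposed diet level, female sex, age
    60-70, non-smoker, no exercise.
    """
    X = pd.DataFrame(index=records.index)
    X["intercept"] = 1.0
    X["high_grs"] = records["high_grs"].astype(float)
    if spec.diet_coding == "protective":
        diet = records["high_mediscore"].astype(float)
    else:
        diet = 1.0 - records["high_mediscore"].astype(float)
    X[spec.diet_term] = diet
    if spec.include_interaction:
        X["grs_x_diet"] = X["high_grs"] * diet
    if spec.adjusted:
        X["sex_male"] = (records["sex"] == "male").astype(float)
        X["age_70_75"] = (records["age_cat"] == "70-75").astype(float)
        X["age_gt75"] = (records["age_cat"] == ">75").astype(float)
        X["smoker"] = (records["smoking"] == "smoker/ex-smoker").astype(float)
        X["exercise_yes"] = records["exercise"].astype(float)
    return X


@dataclass
class GeeFit:
    """A fitted GEE: coefficients, robust covariance and bookkeeping."""

    params: pd.Series
    cov: pd.DataFrame              # robust (sandwich) covariance
    alpha: float                   # exchangeable working correlation
    scale: float
    n_clusters: int
    n_records: int
    converged: bool
    n_iter: int
    separation_suspected: bool = False
    spec: ModelSpec | None = field(default=None, repr=False)

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov.to_numpy())), index=self.params.index)

    def linear_combination(self, weights: dict[str, float]) -> tuple[float, float]:
        """Estimate and robust SE of sum_k w_k * beta_k."""
        w = pd.Series(0.0, index=self.params.index)
        for name, val in weights.items():
            w[name] = val
        est = float(w @ self.params)
        var = float(w @ self.cov @ w)
        return est, float(np.sqrt(max(var, 0.0)))


def _check_full_rank(X: np.ndarray, names) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return
    # name the first column that is linearly dependent on its predecessors
    for j in range(1, X.shape[1]):
        if np.linalg.matrix_rank(X[:, : j + 1]) <= np.linalg.matrix_rank(X[:, :j]):
            raise GeeError(f"design matrix is rank deficient: column {names[j]!r} is aliased")
    raise GeeError("design matrix is rank deficient")


def fit_gee_logistic(y, X, clusters, *, alpha: float | None = None,
                     max_iter: int = 100, tol: float = 1e-8) -> GeeFit:
    """Solve the logistic GEE with exchangeable working correlation.

    Parameters
    ----------
    y, X, clusters
        Binary outcome, design matrix (DataFrame or array; include your
        own intercept) and cluster labels, all of equal length.
    alpha
        Fix the working correlation at this value instead of estimating it
        by the moment estimator each iteration (``alpha=0.0`` gives the
        independence working model; the sandwich covariance still accounts
        for clustering).

    Raises :class:`GeeError` on a rank-deficient design; non-convergence
    within ``max_iter`` is reported via ``converged=False`` on the result,
    which carries the last iterate.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        names = [f"x{j}" for j in range(Xv.shape[1])]
    yv = np.asarray(y, dtype=float).ravel()
    cl = np.asarray(clusters)
    n, p = Xv.shape
    if not (len(yv) == n == len(cl)):
        raise GeeError("y, X and clusters must have equal length")
    if not np.isin(yv, (0.0, 1.0)).all():
        raise GeeError("outcome must be binary 0/1")
    _check_full_rank(Xv, names)

    # sort rows so each cluster is contiguous
    _, inv = np.unique(cl, return_inverse=True)
    order = np.argsort(inv, kind="stable")
    Xv, yv, inv = Xv[order], yv[order], inv[order]
    n_clusters = inv[-1] + 1 if n else 0
    starts = np.searchsorted(inv, np.arange(n_clusters))
    sizes = np.diff(np.append(starts, n))
    max_size = int(sizes.max()) if n else 1
    n_pairs = float((sizes * (sizes - 1) / 2).sum())

    beta = np.zeros(p)
    if "intercept" in names:
        ybar = min(max(yv.mean(), 1e-6), 1 - 1e-6)
        beta[names.index("intercept")] = np.log(ybar / (1 - ybar))

    estimate_alpha = alpha is None
    a = 0.0 if estimate_alpha else float(alpha)
    converged = False
    it = 0
    phi = 1.0
    for it in range(1, max_iter + 1):
        mu = expit(Xv @ beta)
        mu = np.clip(mu, 1e-10, 1 - 1e-10)
        w = mu * (1 - mu)
        r = (yv - mu) / np.sqrt(w)

        phi = float(r @ r) / max(n - p, 1)
        if estimate_alpha and n_pairs > p:
            Sr = np.add.reduceat(r, starts)
            ssr = np.add.reduceat(r * r, starts)
            cross = float(((Sr**2 - ssr) / 2).sum())
            a = cross / phi / (n_pairs - p)
            lo = -1.0 / (max_size - 1) + 1e-6 if max_size > 1 else -0.999
            a = float(np.clip(a, lo, 0.999))

        c1 = 1.0 / (1.0 - a)
        c2 = -a / ((1.0 - a) * (1.0 + (sizes - 1) * a))  # per cluster

        U = Xv * np.sqrt(w)[:, None]
        SU = np.add.reduceat(U, starts, axis=0)
        Sr = np.add.reduceat(r, starts)

        B = c1 * (U.T @ U) + (SU * c2[:, None]).T @ SU
        g = c1 * (U.T @ r) + SU.T @ (c2 * Sr)
        try:
            delta = np.linalg.solve(B, g)
        except np.linalg.LinAlgError as err:
            raise GeeError(f"singular working information matrix: {err}") from err
        beta = beta + delta
        if np.max(np.abs(delta)) < tol:
            converged = True
            break

    # sandwich covariance at the final iterate
    mu = np.clip(expit(Xv @ beta), 1e-10, 1 - 1e-10)
    w = mu * (1 - mu)
    r = (yv - mu) / np.sqrt(w)
    c1 = 1.0 / (1.0 - a)
    c2 = -a / ((1.0 - a) * (1.0 + (sizes - 1) * a))
    U = Xv * np.sqrt(w)[:, None]
    SU = np.add.reduceat(U, starts, axis=0)
    Sr = np.add.reduceat(r, starts)
    B = c1 * (U.T @ U) + (SU * c2[:, None]).T @ SU
    P = np.add.reduceat(U * r[:, None], starts, axis=0)
    G_cl = c1 * P + SU * (c2 * Sr)[:, None]
    M = G_cl.T @ G_cl
    Binv = np.linalg.inv(B)
    cov = Binv @ M @ Binv
    cov = (cov + cov.T) / 2

    return GeeFit(
        params=pd.Series(beta, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        alpha=float(a),
        scale=phi,
        n_clusters=int(n_clusters),
        n_records=int(n),
        converged=converged,
        n_iter=it,
        separation_suspected=bool(np.max(np.abs(beta)) > 15),
    )


def fit_records(records: pd.DataFrame, spec: ModelSpec | None = None, **kwargs) -> GeeFit:
    """Fit the eye-level model on a table of eye records."""
    spec = spec or ModelSpec()
    X = build_design(records, spec)
    fit = fit_gee_logistic(records["outcome"], X, records["subject_id"], **kwargs)
    fit.spec = spec
    return fit


def odds_ratios(fit: GeeFit, conf_level: float = 0.95) -> pd.DataFrame:
    """Per-covariate odds ratios with Wald confidence intervals and p-values.

    OR = exp(beta); CI = exp(beta +/- z * robust SE); p from the Wald z
    statistic.  The intercept is omitted.
    """
    z = norm.ppf(0.5 + conf_level / 2)
    rows = []
    se = fit.se
    for name, coef in fit.params.items():
        if name == "intercept":
            continue
        s = se[name]
        zstat = coef / s if s > 0 else np.inf * np.sign(coef)
        rows.append(
            {
                "term": name,
                "or": np.exp(coef),
                "ci_low": np.exp(coef - z * s),
                "ci_high": np.exp(coef + z * s),
                "p": 2 * norm.sf(abs(zstat)) if np.isfinite(zstat) else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("term")
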