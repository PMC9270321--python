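"""Design-aware association models.

Prevalence ratios for a binary outcome come from a weighted Poisson
regression with a log link and a PSU-clustered robust (sandwich) variance —
the standard way to estimate PRs directly instead of odds ratios.
Readmission counts and length of stay are modelled by weighted least squares
with the same clustered sandwich.  The Goodman–Kruskal gamma quantifies
monotone association between two ordinal variables.

Point estimation is delegated to statsmodels' IRLS/WLS; the CR0 cluster
sandwich (weights inside the meat, no small-sample correction) is computed
here so its definition is exact: with one observation per cluster and unit
weights it reduces to the classical HC0 estimator.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.linalg import qr
from scipy.special import gammaln

from .cohort_io import CohortTable, Z95

logger = logging.getLogger(__name__)


class FitError(RuntimeError):
    """A model could not be fitted."""


@dataclass(frozen=True)
class Term:
    """One row of a regression table: a covariate level (or numeric term)."""

    variable: str
    level: str | None
    is_reference: bool = False

    @property
    def label(self) -> str:
        return self.variable if self.level is None else f"{self.variable}[{self.level}]"


@dataclass
class RegressionResult:
    """Coefficients with cluster-robust inference on the effect scale.

    ``effect`` is ``exp(coef)`` (a prevalence ratio) for the Poisson family
    and the raw ``coef`` (a β in outcome units) for the linear family.
    Reference levels carry effect 1 (PR) or 0 (β) with an empty CI.
    """

    terms: list[Term]
    coef: np.ndarray
    robust_se: np.ndarray
    effect: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_used: int
    model_family: str

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, t in enumerate(self.terms):
            rows.append(
                {
                    "term": t.variable,
                    "level": t.level if t.level is not None else "",
                    "reference": t.is_reference,
                    "coef": self.coef[i],
                    "robust_se": self.robust_se[i],
                    "effect": self.effect[i],
                    "ci_low": self.ci_low[i],
                    "ci_high": self.ci_high[i],
                    "significant": (
                        not t.is_reference
                        and np.isfinite(self.ci_low[i])
                        and np.isfinite(self.ci_high[i])
                        and (
                            (self.ci_low[i] > 1.0 or self.ci_high[i] < 1.0)
                            if self.model_family == "poisson"
                            else (self.ci_low[i] > 0.0 or self.ci_high[i] < 0.0)
                        )
                    ),
                }
            )
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        return self.to_frame().to_json(orient="records")


# ---------------------------------------------------------------------------
# design matrices


def build_design(
    table: CohortTable, covariates: list[str], extra: pd.DataFrame | None = None
) -> tuple[np.ndarray, list[Term]]:
    """Intercept + treatment-coded design matrix with term metadata.

    Categorical covariates are expanded to dummies against their declared
    reference level; binary/count/continuous covariates enter as-is.
    ``extra`` allows caller-provided columns (e.g. a derived multimorbidity
    category) declared as ordered categoricals.
    """
    n = len(table)
    cols: list[np.ndarray] = [np.ones(n)]
    terms: list[Term] = [Term("intercept", None)]
    ref_terms: list[Term] = []
    source = table.df if extra is None else pd.concat([table.df, extra], axis=1)
    for name in covariates:
        s = source[name]
        if name in table.schema and table.schema[name].vtype == "categorical":
            levels = list(table.schema[name].levels)
            ref = table.schema[name].reference or levels[0]
        elif isinstance(s.dtype, pd.CategoricalDtype):
            levels = list(s.cat.categories)
            ref = levels[0]
        else:
            cols.append(s.astype(float).to_numpy())
            terms.append(Term(name, None))
            continue
        ref_terms.append(Term(name, ref, is_reference=True))
        for lev in levels:
            if lev == ref:
                continue
            cols.append((s.astype(str) == lev).astype(float).to_numpy())
            terms.append(Term(name, lev))
    X = np.column_stack(cols)
    return X, terms + ref_terms  # reference terms appended for reporting


def _check_rank(X: np.ndarray, terms: list[Term]) -> None:
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        _, _, piv = qr(X, pivoting=True)
        aliased = sorted(piv[r:])
        names = [terms[j].label for j in aliased if j < len(terms)]
        raise FitError(f"rank-deficient design; aliased terms: {names}")


def _cluster_sandwich(
    X: np.ndarray, score_resid: np.ndarray, irls_w: np.ndarray, clusters: np.ndarray
) -> np.ndarray:
    """CR0 sandwich: bread from the IRLS information, meat from summed
    per-cluster score contributions ``s_i = score_resid_i * x_i``."""
    bread = np.linalg.pinv(X.T @ (irls_w[:, None] * X))
    scores = score_resid[:, None] * X
    frame = pd.DataFrame(scores)
    frame["__g"] = clusters
    g = frame.groupby("__g", observed=True).sum().to_numpy()
    meat = g.T @ g
    return bread @ meat @ bread


def _finish(
    terms, beta, cov, n_used, family, zero_event_terms=()
) -> RegressionResult:
    k = len(beta)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    coef = np.concatenate([beta, np.zeros(len(terms) - k)])
    rse = np.concatenate([se, np.full(len(terms) - k, np.nan)])
    if family == "poisson":
        effect = np.exp(coef)
        lo = np.exp(coef - Z95 * rse)
        hi = np.exp(coef + Z95 * rse)
    else:
        effect = coef.copy()
        lo = coef - Z95 * rse
        hi = coef + Z95 * rse
    for i, t in enumerate(terms):
        if t.is_reference:
            effect[i] = 1.0 if family == "poisson" else 0.0
            coef[i] = 0.0
            lo[i] = hi[i] = np.nan
        elif t.label in zero_event_terms:
            lo[i] = 0.0 if family == "poisson" else -np.inf
            hi[i] = np.inf
    return RegressionResult(
        terms=list(terms),
        coef=coef,
        robust_se=rse,
        effect=effect,
        ci_low=lo,
        ci_high=hi,
        n_used=n_used,
        model_family=family,
    )


def _prepare(table, outcome, covariates, weights, cluster, extra):
    source = table.df if extra is None else pd.concat([table.df, extra], axis=1)
    needed = [outcome] + list(covariates)
    mask = source[needed].notna().all(axis=1)
    sub = CohortTable(table.df.loc[mask].reset_index(drop=True), table.schema)
    extra_sub = None if extra is None else extra.loc[mask].reset_index(drop=True)
    y = source.loc[mask, outcome].astype(float).to_numpy()
    w = (
        sub.weights.to_numpy()
        if weights is None
        else np.asarray(pd.Series(weights).loc[mask], dtype=float)
    )
    if np.any(w <= 0) or not np.isfinite(w).all():
        raise ValueError("weights must be positive and finite")
    cl = (
        sub.psu.to_numpy()
        if cluster is None
        else np.asarray(pd.Series(cluster).loc[mask])
    )
    X, terms = build_design(sub, list(covariates), extra_sub)
    return X, y, w, cl, terms, int(mask.sum())


def fit_poisson_pr(
    table: CohortTable,
    outcome: str,
    covariates: list[str],
    weights: pd.Series | np.ndarray | None = None,
    cluster: pd.Series | np.ndarray | None = None,
    extra: pd.DataFrame | None = None,
) -> RegressionResult:
    """Prevalence ratios from weighted Poisson regression with robust variance.

    Fits a log-link Poisson model of a binary outcome by IRLS (relative
    deviance change below 1e-10 or 100 iterations), then applies the
    PSU-clustered CR0 sandwich.  ``weights`` defaults to the survey weight
    column, ``cluster`` to the PSU column.
    """
    X, y, w, cl, terms, n_used = _prepare(table, outcome, covariates, weights, cluster, extra)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError(f"outcome {outcome!r} is not binary")
    if y.sum() == 0:
        raise FitError("no events: outcome is constant 0")
    _check_rank(X, terms)

    # zero-event covariate levels make the MLE diverge to -inf
    zero_events = set()
    k_fit = X.shape[1]
    for j in range(1, k_fit):
        if set(np.unique(X[:, j])) <= {0.0, 1.0} and y[X[:, j] == 1].sum() == 0:
            zero_events.add(terms[j].label)
    if zero_events:
        warnings.warn(
            f"covariate levels with zero outcome events: {sorted(zero_events)}; "
            "their CIs are reported as unbounded",
            stacklevel=2,
        )

    model = sm.GLM(y, X, family=sm.families.Poisson(), var_weights=w)
    fit = model.fit(maxiter=100, tol=1e-10)
    if not fit.converged and not zero_events:
        raise FitError(
            f"IRLS did not converge in 100 iterations (deviance trace tail: "
            f"{getattr(fit, 'fit_history', {}).get('deviance', [])[-3:]})"
        )
    beta = np.asarray(fit.params)
    mu = np.exp(np.clip(X @ beta, -30, 30))
    cov = _cluster_sandwich(X, w * (y - mu), w * mu, cl)
    return _finish(terms, beta, cov, n_used, "poisson", zero_events)


def fit_linear(
    table: CohortTable,
    outcome: str,
    covariates: list[str],
    weights: pd.Series | np.ndarray | None = None,
    cluster: pd.Series | np.ndarray | None = None,
    extra: pd.DataFrame | None = None,
) -> RegressionResult:
    """Weighted least squares with PSU-clustered sandwich standard errors.

    Used for readmission counts and length of stay on the hospitalised
    subset, where those outcomes are defined.
    """
    X, y, w, cl, terms, n_used = _prepare(table, outcome, covariates, weights, cluster, extra)
    _check_rank(X, terms)
    XtW = X.T * w
    beta = np.linalg.solve(XtW @ X, XtW @ y)
    resid = y - X @ beta
    cov = _cluster_sandwich(X, w * resid, w, cl)
    return _finish(terms, beta, cov, n_used, "linear")


# ---------------------------------------------------------------------------
# Goodman–Kruskal gamma


@dataclass(frozen=True)
class GammaResult:
    gamma: float
    se: float
    concordant: float
    discordant: float

    @property
    def ci_low(self) -> float:
        return self.gamma - Z95 * self.se

    @property
    def ci_high(self) -> float:
        return self.gamma + Z95 * self.se


def goodman_kruskal_gamma(crosstab) -> GammaResult:
    """Gamma statistic for an ordered r x c contingency table.

    ``γ = (C − D) / (C + D)`` with C/D the concordant/discordant pair counts;
    the standard asymptotic SE (Goodman–Kruskal) accompanies it.  Cell-wise
    concordance counts are accumulated with cumulative-sum tables rather than
    pair enumeration.
    """
    t = np.asarray(crosstab, dtype=float)
    if t.ndim != 2 or (t < 0).any():
        raise ValueError("crosstab must be a 2-D non-negative count table")
    r, c = t.shape
    # A[i,j]: concordant partners of cell (i,j); B[i,j]: discordant partners
    A = np.zeros_like(t)
    B = np.zeros_like(t)
    for i in range(r):
        for j in range(c):
            A[i, j] = t[:i, :j].sum() + t[i + 1 :, j + 1 :].sum()
            B[i, j] = t[:i, j + 1 :].sum() + t[i + 1 :, :j].sum()
    C = float((t * A).sum() / 2.0)
    D = float((t * B).sum() / 2.0)
    if C + D == 0:
        raise ValueError("gamma undefined: no concordant or discordant pairs")
    gamma = (C - D) / (C + D)
    var = 16.0 * float((t * (D * A - C * B) ** 2).sum()) / (C + D) ** 4
    return GammaResult(gamma, float(np.sqrt(var)), C, D)
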