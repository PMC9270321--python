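"""Regularised graphical-model estimation.

Networks over morbidity (and outcome) nodes are estimated nodewise: each
node is regressed on all others with an l1-penalised GLM whose family
matches the node type (binary → logistic, count → Poisson with log link,
continuous → Gaussian), the penalty is chosen per node by the Extended
Bayesian Information Criterion (EBIC, hyperparameter γ = 0.25 by default),
and the directed estimates are symmetrised by the AND rule (edge kept only
if both directions are nonzero) with the retained weight the mean of the two
nodewise coefficients.  Edges therefore encode conditional association
between two nodes controlling for all remaining nodes.

The coordinate-descent path solver and EBIC scorer are shared machinery for
the binary-only Ising network and the mixed graphical model used when a
count (readmission) or continuous (length of stay) node joins the binary
morbidities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import gammaln

from ._kernels import (
    FAMILY_GAUSSIAN,
    FAMILY_LOGISTIC,
    FAMILY_POISSON,
    glm_cd_path,
)

_FAMILY_CODES = {
    "gaussian": FAMILY_GAUSSIAN,
    "logistic": FAMILY_LOGISTIC,
    "poisson": FAMILY_POISSON,
}
_TYPE_FAMILY = {"binary": "logistic", "count": "poisson", "continuous": "gaussian"}


@dataclass(frozen=True)
class EBICConfig:
    """Model-selection settings for the nodewise fits."""

    gamma: float = 0.25
    n_lambdas: int = 100
    lambda_min_ratio: float = 0.01
    rule: str = "AND"

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.n_lambdas < 2:
            raise ValueError("n_lambdas must be >= 2")
        if not 0 < self.lambda_min_ratio < 1:
            raise ValueError("lambda_min_ratio must be in (0, 1)")
        if self.rule not in ("AND", "OR"):
            raise ValueError("rule must be 'AND' or 'OR'")


@dataclass
class LassoPath:
    """Coefficient path of one penalised GLM.

    Coefficients are reported on the original predictor scale;
    ``coef_std``/``x_mean``/``x_sd`` expose the internally standardised
    problem (the scale on which the penalty acts and KKT conditions hold).
    """

    family: str
    lambdas: np.ndarray
    intercept: np.ndarray
    coef: np.ndarray          # (k, p) original scale
    coef_std: np.ndarray      # (k, p) standardised scale
    intercept_std: np.ndarray
    loglik: np.ndarray
    df: np.ndarray
    x_mean: np.ndarray
    x_sd: np.ndarray


def _log_likelihood(family: str, y: np.ndarray, eta: np.ndarray) -> float:
    if family == "gaussian":
        rss = float(((y - eta) ** 2).sum())
        n = len(y)
        sigma2 = max(rss / n, 1e-300)
        return -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
    if family == "logistic":
        return float((y * eta - np.logaddexp(0.0, eta)).sum())
    mu = np.exp(np.clip(eta, -30, 30))
    return float((y * eta - mu - gammaln(y + 1.0)).sum())


def lambda_max(Z: np.ndarray, y: np.ndarray, family: str) -> float:
    """Smallest penalty at which every penalised coefficient is zero.

    With the intercept at its null-model optimum, the KKT condition gives
    ``λ_max = max_j |(1/n) Z_jᵀ (y − μ̄)|`` for the standardised predictors.
    """
    n = len(y)
    mu0 = np.full(n, y.mean())
    return float(np.abs(Z.T @ (y - mu0)).max() / n)


def glm_lasso_path(
    X: np.ndarray,
    y: np.ndarray,
    family: str = "logistic",
    lambdas: np.ndarray | None = None,
    n_lambdas: int = 100,
    lambda_min_ratio: float = 0.01,
    tol: float = 1e-7,
) -> LassoPath:
    """l1-penalised GLM coefficient path by cyclic coordinate descent.

    For each λ (descending, warm-started) the coefficients minimise
    ``(1/n)·NLL + λ·Σ|β_j|`` with an unpenalised intercept; predictors are
    standardised internally and convergence is declared when the largest
    absolute coefficient update falls below ``tol``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if family not in _FAMILY_CODES:
        raise ValueError(f"unknown family {family!r}")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite entries in X or y")
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("X must be 2-D with one row per element of y")
    if family == "logistic":
        u = np.unique(y)
        if not set(u) <= {0.0, 1.0}:
            raise ValueError("logistic family requires a 0/1 response")
        if len(u) < 2:
            raise ValueError("logistic family refused: constant response")
    if family == "poisson" and (y < 0).any():
        raise ValueError("poisson family requires a non-negative response")

    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    if (sd == 0).any():
        bad = list(np.flatnonzero(sd == 0))
        raise ValueError(f"zero-variance predictor columns: {bad}")
    Z = (X - mean) / sd

    if lambdas is None:
        lmax = lambda_max(Z, y, family)
        if lmax <= 0:
            lmax = 1e-3
        lambdas = np.geomspace(lmax, lmax * lambda_min_ratio, n_lambdas)
    else:
        lambdas = np.asarray(lambdas, dtype=float)
        if len(lambdas) > 1 and not (np.diff(lambdas) < 0).all():
            raise ValueError("lambdas must be strictly decreasing")

    b0s, betas = glm_cd_path(
        Z, y, _FAMILY_CODES[family], lambdas, tol, 1000, 100
    )
    betas = np.where(np.abs(betas) < 1e-12, 0.0, betas)
    coef = betas / sd
    intercept = b0s - coef @ mean
    loglik = np.array(
        [_log_likelihood(family, y, b0s[i] + Z @ betas[i]) for i in range(len(lambdas))]
    )
    df = (betas != 0).sum(axis=1)
    return LassoPath(
        family=family,
        lambdas=lambdas,
        intercept=intercept,
        coef=coef,
        coef_std=betas,
        intercept_std=b0s,
        loglik=loglik,
        df=df,
        x_mean=mean,
        x_sd=sd,
    )


def ebic(loglik: float, df: int, n: int, p_candidates: int, gamma: float) -> float:
    """EBIC score: ``−2·loglik + df·log n + 2γ·df·log p_candidates``."""
    extra = 0.0 if p_candidates <= 1 else 2.0 * gamma * df * np.log(p_candidates)
    return -2.0 * loglik + df * np.log(n) + extra


def ebic_select(
    loglik: np.ndarray,
    df: np.ndarray,
    n: int,
    p_candidates: int,
    gamma: float = 0.25,
) -> int:
    """Index of the λ minimising EBIC along a path; ties go to the sparser
    (larger-λ, earlier) model."""
    loglik = np.asarray(loglik, dtype=float)
    if loglik.size == 0:
        raise ValueError("empty path")
    if not np.isfinite(loglik).all():
        raise ValueError("non-finite log-likelihoods")
    scores = np.array(
        [ebic(ll, int(d), n, p_candidates, gamma) for ll, d in zip(loglik, df)]
    )
    return int(np.argmin(scores))  # first minimum = largest λ on a descending path


# ---------------------------------------------------------------------------
# networks


@dataclass
class IsingNetwork:
    """Symmetric pairwise network over binary nodes."""

    labels: list[str]
    weights: np.ndarray
    thresholds: np.ndarray
    n_fit: int
    config: EBICConfig

    def edge_list(self) -> pd.DataFrame:
        return _edge_list(self.labels, self.weights, np.sign(self.weights))

    def to_json(self) -> str:
        return json.dumps(
            {
                "labels": self.labels,
                "weights": self.weights.tolist(),
                "thresholds": self.thresholds.tolist(),
                "n_fit": self.n_fit,
                "config": asdict(self.config),
            }
        )


@dataclass
class MGMNetwork:
    """Pairwise network over mixed binary/count/continuous nodes.

    ``weights`` holds non-negative aggregated edge strengths; ``signs`` is
    +1/−1 where the two directed coefficients agree in sign and 0
    (undetermined) otherwise.
    """

    labels: list[str]
    node_types: list[str]
    weights: np.ndarray
    signs: np.ndarray
    intercepts: np.ndarray
    n_fit: int
    config: EBICConfig

    def edge_list(self) -> pd.DataFrame:
        return _edge_list(self.labels, self.weights, self.signs)

    def to_json(self) -> str:
        return json.dumps(
            {
                "labels": self.labels,
                "node_types": self.node_types,
                "weights": self.weights.tolist(),
                "signs": self.signs.tolist(),
                "intercepts": self.intercepts.tolist(),
                "n_fit": self.n_fit,
                "config": asdict(self.config),
            }
        )


def network_from_json(payload: str | dict):
    """Rebuild an :class:`IsingNetwork` or :class:`MGMNetwork` from its JSON."""
    d = json.loads(payload) if isinstance(payload, str) else payload
    cfg = EBICConfig(**d["config"])
    if "node_types" in d:
        return MGMNetwork(
            labels=list(d["labels"]),
            node_types=list(d["node_types"]),
            weights=np.asarray(d["weights"], dtype=float),
            signs=np.asarray(d["signs"], dtype=float),
            intercepts=np.asarray(d["intercepts"], dtype=float),
            n_fit=int(d["n_fit"]),
            config=cfg,
        )
    return IsingNetwork(
        labels=list(d["labels"]),
        weights=np.asarray(d["weights"], dtype=float),
        thresholds=np.asarray(d["thresholds"], dtype=float),
        n_fit=int(d["n_fit"]),
        config=cfg,
    )


def _edge_list(labels, weights, signs) -> pd.DataFrame:
    rows = []
    p = len(labels)
    for i in range(p):
        for j in range(i + 1, p):
            if weights[i, j] != 0:
                rows.append(
                    {
                        "node_i": labels[i],
                        "node_j": labels[j],
                        "weight": float(weights[i, j]),
                        "sign": int(signs[i, j]),
                    }
                )
    return pd.DataFrame(rows, columns=["node_i", "node_j", "weight", "sign"])


def _nodewise_fits(X: np.ndarray, families: list[str], config: EBICConfig):
    """Directed coefficient matrix B (B[j, i] = effect of node i in the model
    of node j) and per-node intercepts, by EBIC-selected l1 paths."""
    n, p = X.shape
    B = np.zeros((p, p))
    intercepts = np.zeros(p)
    for j in range(p):
        y = X[:, j]
        others = np.delete(np.arange(p), j)
        path = glm_lasso_path(
            X[:, others],
            y,
            family=families[j],
            n_lambdas=config.n_lambdas,
            lambda_min_ratio=config.lambda_min_ratio,
        )
        k = ebic_select(path.loglik, path.df, n, p - 1, config.gamma)
        B[j, others] = path.coef[k]
        intercepts[j] = path.intercept[k]
    return B, intercepts


def _validate_block(X: np.ndarray, labels: list[str]) -> None:
    if X.shape[1] < 3:
        raise ValueError("network estimation needs at least 3 nodes")
    if np.isnan(X).any():
        raise ValueError("node block contains missing cells; pass complete cases")
    sd = X.std(axis=0)
    dead = [labels[i] for i in np.flatnonzero(sd == 0)]
    if dead:
        raise ValueError(f"zero-variance nodes: {dead}")


def _as_block(table) -> tuple[np.ndarray, list[str]]:
    if isinstance(table, pd.DataFrame):
        return table.astype(float).to_numpy(), list(table.columns)
    X = np.asarray(table, dtype=float)
    return X, [f"x{i + 1}" for i in range(X.shape[1])]


def fit_ising(table, config: EBICConfig | None = None) -> IsingNetwork:
    """Regularised Ising network over a complete-case block of binary nodes.

    Each node is regressed on all others with an l1 logistic path, the
    penalty chosen per node by EBIC, and edges symmetrised by
    ``config.rule`` with weight the mean of the two directed coefficients
    (an absent direction counts as 0 under OR).  Thresholds are the selected
    nodewise intercepts.
    """
    config = config or EBICConfig()
    X, labels = _as_block(table)
    _validate_block(X, labels)
    if not set(np.unique(X[np.isfinite(X)])) <= {0.0, 1.0}:
        raise ValueError("Ising nodes must be binary 0/1")
    p = X.shape[1]
    B, intercepts = _nodewise_fits(X, ["logistic"] * p, config)
    W = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            a, b = B[i, j], B[j, i]
            keep = (a != 0 and b != 0) if config.rule == "AND" else (a != 0 or b != 0)
            if keep:
                W[i, j] = W[j, i] = (a + b) / 2.0
    return IsingNetwork(labels, W, intercepts, X.shape[0], config)


def fit_mgm(
    table, node_types: list[str] | None = None, config: EBICConfig | None = None
) -> MGMNetwork:
    """Mixed graphical model over binary, count and continuous nodes.

    Families follow node types; continuous nodes are standardised to unit
    variance before fitting, count nodes enter raw with a log link.  Edge
    strength is the mean absolute value of the two directed coefficients
    with a sign attribute (+1/−1 when the directions agree, 0 when
    undetermined).
    """
    config = config or EBICConfig()
    X, labels = _as_block(table)
    _validate_block(X, labels)
    if node_types is None:
        node_types = [
            "binary" if set(np.unique(col)) <= {0.0, 1.0} else "continuous"
            for col in X.T
        ]
    if len(node_types) != X.shape[1]:
        raise ValueError("node_types length must match the number of nodes")
    bad = [t for t in node_types if t not in _TYPE_FAMILY]
    if bad:
        raise ValueError(f"unsupported node types: {sorted(set(bad))}")
    X = X.copy()
    for i, t in enumerate(node_types):
        if t == "continuous":
            X[:, i] = (X[:, i] - X[:, i].mean()) / X[:, i].std(ddof=0)
        if t == "count" and ((X[:, i] < 0).any() or (X[:, i] % 1 != 0).any()):
            raise ValueError(f"count node {labels[i]!r} must hold non-negative integers")
    families = [_TYPE_FAMILY[t] for t in node_types]
    p = X.shape[1]
    B, intercepts = _nodewise_fits(X, families, config)
    W = np.zeros((p, p))
    S = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            a, b = B[i, j], B[j, i]
            keep = (a != 0 and b != 0) if config.rule == "AND" else (a != 0 or b != 0)
            if keep:
                W[i, j] = W[j, i] = (abs(a) + abs(b)) / 2.0
                sa, sb = np.sign(a), np.sign(b)
                if sa == sb or sb == 0:
                    s = sa
                elif sa == 0:
                    s = sb
                else:
                    s = 0
                S[i, j] = S[j, i] = s
    return MGMNetwork(labels, list(node_types), W, S, intercepts, X.shape[0], config)


def kkt_violation(path: LassoPath, Z: np.ndarray, y: np.ndarray, k: int) -> float:
    """Largest KKT violation at path index ``k`` on the standardised scale.

    Zero coefficients must satisfy ``|g_j| ≤ λ``; nonzero ones
    ``g_j = −λ·sign(β_j)`` with ``g`` the gradient of the mean negative
    log-likelihood.  Used as a solver self-check.
    """
    n = len(y)
    eta = path.intercept_std[k] + Z @ path.coef_std[k]
    if path.family == "gaussian":
        mu = eta
    elif path.family == "logistic":
        mu = 1.0 / (1.0 + np.exp(-eta))
    else:
        mu = np.exp(np.clip(eta, -30, 30))
    g = Z.T @ (mu - y) / n
    lam = path.lambdas[k]
    beta = path.coef_std[k]
    viol = 0.0
    for j in range(len(beta)):
        if beta[j] == 0:
            viol = max(viol, abs(g[j]) - lam)
        else:
            viol = max(viol, abs(g[j] + lam * np.sign(beta[j])))
    return viol
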