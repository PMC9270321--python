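"""Schema-validated cohort tables, exclusion accounting, inverse probability
weighting, asset-index construction, multimorbidity categorisation and
design-based prevalence estimation.

A cohort is a subject x variable rectangle described by a
:class:`VariableSchema`: binary disease indicators, categorical/continuous
covariates, the three hospitalisation outcomes, and the complex-survey design
columns (stratum, primary sampling unit, sampling weight).  Every downstream
stage of the pipeline consumes a :class:`CohortTable`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import yaml

logger = logging.getLogger(__name__)

VALID_TYPES = ("binary", "categorical", "count", "continuous")
VALID_ROLES = ("disease", "covariate", "outcome", "design", "id")
DESIGN_SUBTYPES = ("psu", "stratum", "weight")

#: z quantile used for all 95% intervals in the package
Z95 = 1.959964


class SchemaError(ValueError):
    """A cohort file or frame does not conform to its declared schema."""


@dataclass(frozen=True)
class Variable:
    """One column of a cohort table.

    Parameters
    ----------
    name : column name in the CSV header.
    vtype : one of ``binary | categorical | count | continuous``.
    role : one of ``disease | covariate | outcome | design | id``.
    subtype : for ``role='design'`` only: ``psu | stratum | weight``.
    levels : category labels, for categorical variables.
    reference : reference level used when building design matrices.
    """

    name: str
    vtype: str
    role: str
    subtype: str | None = None
    levels: tuple[str, ...] | None = None
    reference: str | None = None

    def __post_init__(self) -> None:
        if self.vtype not in VALID_TYPES:
            raise SchemaError(f"unknown variable type {self.vtype!r} for {self.name!r}")
        if self.role not in VALID_ROLES:
            raise SchemaError(f"unknown role {self.role!r} for {self.name!r}")
        if self.role == "design" and self.subtype not in DESIGN_SUBTYPES:
            raise SchemaError(
                f"design variable {self.name!r} needs subtype psu|stratum|weight"
            )
        if self.vtype == "categorical":
            if not self.levels:
                raise SchemaError(f"categorical variable {self.name!r} needs levels")
            if self.reference is not None and self.reference not in self.levels:
                raise SchemaError(
                    f"reference {self.reference!r} of {self.name!r} not in levels"
                )


class VariableSchema:
    """Ordered collection of :class:`Variable` records with design lookups."""

    def __init__(self, variables: Sequence[Variable]):
        self.variables = tuple(variables)
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate variable names in schema")
        self._by_name = {v.name: v for v in self.variables}
        for sub in DESIGN_SUBTYPES:
            found = [v for v in self.variables if v.role == "design" and v.subtype == sub]
            if len(found) != 1:
                raise SchemaError(
                    f"schema must declare exactly one design variable of subtype {sub!r}"
                )
        if len(self.disease_names()) < 2:
            raise SchemaError("schema must declare at least two disease variables")
        for v in self.variables:
            if v.role == "disease" and v.vtype != "binary":
                raise SchemaError(f"disease variable {v.name!r} must be binary")

    def __iter__(self):
        return iter(self.variables)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> Variable:
        try:
            return self._by_name[name]
        except KeyError:
            raise SchemaError(f"variable {name!r} not in schema") from None

    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    def disease_names(self) -> list[str]:
        return [v.name for v in self.variables if v.role == "disease"]

    def covariate_names(self) -> list[str]:
        return [v.name for v in self.variables if v.role == "covariate"]

    def outcome_names(self) -> list[str]:
        return [v.name for v in self.variables if v.role == "outcome"]

    def design_name(self, subtype: str) -> str:
        return next(
            v.name
            for v in self.variables
            if v.role == "design" and v.subtype == subtype
        )

    @property
    def psu(self) -> str:
        return self.design_name("psu")

    @property
    def stratum(self) -> str:
        return self.design_name("stratum")

    @property
    def weight(self) -> str:
        return self.design_name("weight")

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> list[dict]:
        out = []
        for v in self.variables:
            d: dict = {"name": v.name, "type": v.vtype, "role": v.role}
            if v.subtype:
                d["subtype"] = v.subtype
            if v.levels:
                d["levels"] = list(v.levels)
            if v.reference:
                d["reference"] = v.reference
            out.append(d)
        return out

    @classmethod
    def from_dict(cls, records: Iterable[Mapping]) -> "VariableSchema":
        variables = [
            Variable(
                name=r["name"],
                vtype=r["type"],
                role=r["role"],
                subtype=r.get("subtype"),
                levels=tuple(r["levels"]) if r.get("levels") else None,
                reference=r.get("reference"),
            )
            for r in records
        ]
        return cls(variables)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump({"variables": self.to_dict()}, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "VariableSchema":
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh)
        return cls.from_dict(payload["variables"])


@dataclass
class CohortTable:
    """A validated cohort frame plus its schema.

    ``df`` holds one row per subject; missing cells are pandas ``NA``/``NaN``.
    The survey design (stratum, PSU, weight) is reachable through the schema.
    """

    df: pd.DataFrame
    schema: VariableSchema

    def __post_init__(self) -> None:
        missing_cols = [n for n in self.schema.names() if n not in self.df.columns]
        if missing_cols:
            raise SchemaError(f"columns missing from table: {missing_cols}")
        w = pd.to_numeric(self.df[self.schema.weight], errors="coerce")
        if (w <= 0).any() or w.isna().any():
            raise SchemaError("survey weights must be strictly positive on all rows")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def weights(self) -> pd.Series:
        return self.df[self.schema.weight].astype(float)

    @property
    def psu(self) -> pd.Series:
        return self.df[self.schema.psu]

    @property
    def stratum(self) -> pd.Series:
        return self.df[self.schema.stratum]

    def copy(self) -> "CohortTable":
        return CohortTable(self.df.copy(), self.schema)


@dataclass(frozen=True)
class ExclusionReport:
    """Complete-case exclusion bookkeeping."""

    n_baseline: int
    n_missing: int
    pct_missing: float
    n_final: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_baseline": self.n_baseline,
                "n_missing": self.n_missing,
                "pct_missing": self.pct_missing,
                "n_final": self.n_final,
            }
        )


@dataclass(frozen=True)
class PrevalenceEstimate:
    """Design-based weighted proportion with a 95% confidence interval."""

    estimate: float
    ci_low: float
    ci_high: float
    n_unweighted: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "estimate": self.estimate,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "n_unweighted": self.n_unweighted,
            }
        )


# ---------------------------------------------------------------------------
# reading / writing


def _coerce_column(raw: pd.Series, var: Variable) -> tuple[pd.Series, list[tuple[int, str]]]:
    """Coerce a raw string column to its declared type.

    Returns the typed column and a list of (row, message) for out-of-domain
    cells.  Empty strings are missing.
    """
    bad: list[tuple[int, str]] = []
    s = raw.replace({"": pd.NA}).astype("string")
    if var.vtype in ("binary", "count", "continuous"):
        num = pd.to_numeric(s, errors="coerce")
        for idx in s.index[num.isna() & s.notna()]:
            bad.append((int(idx), f"non-numeric value {s[idx]!r}"))
        if var.vtype == "binary":
            ok = num.isin([0, 1]) | num.isna()
            for idx in s.index[~ok]:
                bad.append((int(idx), f"non-binary value {s[idx]!r}"))
            return num.astype("Float64"), bad
        if var.vtype == "count":
            frac = (num.dropna() % 1 != 0) | (num.dropna() < 0)
            for idx in frac.index[frac]:
                bad.append((int(idx), f"not a non-negative integer: {s[idx]!r}"))
            return num.astype("Float64"), bad
        return num.astype("Float64"), bad
    # categorical
    if var.levels is not None:
        ok = s.isin(var.levels) | s.isna()
        for idx in s.index[~ok]:
            bad.append((int(idx), f"value {s[idx]!r} not in levels {list(var.levels)}"))
    return s, bad


def read_cohort(path, schema: VariableSchema) -> CohortTable:
    """Read a cohort CSV and validate it against ``schema``.

    Missing cells are empty strings in the file.  Any out-of-domain cell is a
    fatal :class:`SchemaError` naming the row and column.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_design = [
        schema.design_name(sub)
        for sub in DESIGN_SUBTYPES
        if schema.design_name(sub) not in raw.columns
    ]
    if missing_design:
        raise SchemaError(f"design columns missing from {path}: {missing_design}")
    missing_cols = [n for n in schema.names() if n not in raw.columns]
    if missing_cols:
        raise SchemaError(f"columns missing from {path}: {missing_cols}")

    out = {}
    problems: list[str] = []
    for var in schema:
        if var.name in ("",):
            continue
        col, bad = _coerce_column(raw[var.name], var)
        out[var.name] = col
        problems.extend(f"row {r}, column {var.name!r}: {msg}" for r, msg in bad)
    if problems:
        raise SchemaError("out-of-domain cells:\n" + "\n".join(problems))
    df = pd.DataFrame(out)[schema.names()]
    return CohortTable(df, schema)


def write_cohort(table: CohortTable, path) -> None:
    """Write a cohort table as UTF-8 CSV with empty cells for missing."""
    df = table.df.copy()
    for var in table.schema:
        if var.vtype in ("binary", "count"):
            # keep integer formatting so a round-trip is byte-stable
            df[var.name] = df[var.name].map(
                lambda v: "" if pd.isna(v) else str(int(v))
            )
    df.to_csv(path, index=False, na_rep="")


# ---------------------------------------------------------------------------
# exclusion accounting


def exclusion_report(
    table: CohortTable, analysis_vars: Sequence[str]
) -> tuple[ExclusionReport, CohortTable]:
    """Count and drop rows missing any analysis variable.

    Mirrors a complete-case workflow: of the baseline rows, those missing at
    least one of ``analysis_vars`` are flagged, counted and removed.
    """
    if not analysis_vars:
        raise ValueError("analysis_vars must be non-empty")
    unknown = [v for v in analysis_vars if v not in table.schema]
    if unknown:
        raise SchemaError(f"analysis variables not in schema: {unknown}")
    n_baseline = len(table)
    incomplete = table.df[list(analysis_vars)].isna().any(axis=1)
    n_missing = int(incomplete.sum())
    n_final = n_baseline - n_missing
    pct = round(100.0 * n_missing / n_baseline, 1) if n_baseline else 0.0
    if n_final == 0:
        logger.warning("exclusion_report: all %d rows excluded", n_baseline)
    report = ExclusionReport(n_baseline, n_missing, pct, n_final)
    kept = CohortTable(table.df.loc[~incomplete].reset_index(drop=True), table.schema)
    return report, kept


# ---------------------------------------------------------------------------
# inverse probability weighting


def complete_case_indicator(table: CohortTable, analysis_vars: Sequence[str]) -> pd.Series:
    """1 where the row is complete on ``analysis_vars``, else 0."""
    return (~table.df[list(analysis_vars)].isna().any(axis=1)).astype(int)


def compute_ipw(
    table: CohortTable,
    predictors: Sequence[str],
    analysis_vars: Sequence[str] | None = None,
) -> pd.Series:
    """Inverse-probability-of-being-complete multipliers.

    Fits a logit of the complete-case indicator on fully observed
    ``predictors`` by maximum likelihood.  Complete rows receive
    ``1 / p_hat(complete)``; incomplete rows receive ``NaN`` (no multiplier —
    they are excluded downstream).  Multipliers are meant to be combined
    multiplicatively with the survey weight.
    """
    if analysis_vars is None:
        analysis_vars = table.schema.disease_names() + table.schema.outcome_names()
    for p in predictors:
        if table.df[p].isna().any():
            raise ValueError(f"IPW predictor {p!r} is not fully observed")
    complete = complete_case_indicator(table, analysis_vars)
    if complete.nunique() == 1:
        if complete.iloc[0] == 1:
            # no missing rows at all: multiplier is exactly 1 everywhere
            return pd.Series(1.0, index=table.df.index)
        raise ValueError("complete-case indicator is constant (no complete rows)")
    X = _dummy_design(table, predictors)
    try:
        fit = sm.Logit(complete.to_numpy(), X).fit(disp=0, maxiter=200)
    except Exception as exc:  # pragma: no cover - statsmodels-specific failure
        raise ValueError(f"IPW logit failed to fit: {exc}") from exc
    phat = np.asarray(fit.predict(X), dtype=float)
    if np.any(phat < 1e-10) or np.any(phat > 1 - 1e-10):
        raise ValueError(
            "perfect separation in the complete-case model; IPW undefined"
        )
    mult = pd.Series(np.where(complete == 1, 1.0 / phat, np.nan), index=table.df.index)
    return mult


def _dummy_design(table: CohortTable, predictors: Sequence[str]) -> np.ndarray:
    """Intercept + dummy/numeric design block for schema variables."""
    cols = [np.ones(len(table))]
    for name in predictors:
        var = table.schema[name]
        s = table.df[name]
        if var.vtype == "categorical":
            levels = list(var.levels or sorted(s.dropna().unique()))
            ref = var.reference or levels[0]
            for lev in levels:
                if lev == ref:
                    continue
                cols.append((s == lev).astype(float).to_numpy())
        else:
            cols.append(s.astype(float).to_numpy())
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# asset index


def asset_index(
    table: CohortTable,
    asset_vars: Sequence[str],
    weights: pd.Series | None = None,
    n_quantiles: int = 5,
):
    """Socio-economic score and quintile categories from household assets.

    The score is the first principal component of the standardised asset
    block.  Because a principal axis has no intrinsic sign, the score is
    canonicalised from its own distribution: the sign with non-negative
    weighted skewness is kept (asset scores are right-skewed: few households
    hold many assets), with correlation against the standardised column mean
    as the tie-break.  Categories are weighted quantile cuts of the score,
    left-closed/right-open except the last.

    Returns ``(categories, scores, boundaries)``.
    """
    if len(asset_vars) < 12:
        raise ValueError(f"asset index requires 12 variables, got {len(asset_vars)}")
    block = table.df[list(asset_vars)].astype(float)
    if block.isna().any().any():
        raise ValueError("asset variables must be complete")
    X = block.to_numpy()
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.all():
        dropped = [asset_vars[i] for i in np.flatnonzero(~keep)]
        logger.warning("asset_index: dropping zero-variance columns %s", dropped)
        X = X[:, keep]
        sd = sd[keep]
    Z = (X - X.mean(axis=0)) / sd
    # first principal axis of the correlation matrix
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    score = Z @ vt[0]

    w = np.ones(len(score)) if weights is None else np.asarray(weights, float)
    mu = np.average(score, weights=w)
    s2 = np.average((score - mu) ** 2, weights=w)
    skew = np.average((score - mu) ** 3, weights=w) / max(s2, 1e-300) ** 1.5
    if abs(skew) < 1e-12:
        anchor = float(np.corrcoef(score, Z.mean(axis=1))[0, 1])
        flip = anchor < 0
    else:
        flip = skew < 0
    if flip:
        score = -score

    boundaries = _weighted_quantiles(score, w, n_quantiles)
    cats = np.digitize(score, boundaries[1:-1], right=False)  # 0..n_quantiles-1
    labels = [f"q{i + 1}" for i in range(n_quantiles)]
    categories = pd.Series(
        pd.Categorical([labels[c] for c in cats], categories=labels, ordered=True),
        index=table.df.index,
    )
    return categories, pd.Series(score, index=table.df.index), boundaries


def _weighted_quantiles(x: np.ndarray, w: np.ndarray, k: int) -> np.ndarray:
    order = np.argsort(x, kind="stable")
    cw = np.cumsum(w[order])
    cw = cw / cw[-1]
    probs = np.linspace(0, 1, k + 1)
    idx = np.searchsorted(cw, probs[1:-1], side="left")
    inner = x[order][np.clip(idx, 0, len(x) - 1)]
    return np.concatenate([[x.min()], inner, [x.max()]])


# ---------------------------------------------------------------------------
# multimorbidity


MULTIMORBIDITY_LEVELS = ("<=1", "2", ">=3")


def multimorbidity_category(table: CohortTable) -> pd.Series:
    """Ordinal multimorbidity category from the disease count.

    Counts yes-responses across the disease columns and bins into
    ``<=1 | 2 | >=3`` conditions.  A row missing any disease cell gets a
    missing category — never imputed.
    """
    block = table.df[table.schema.disease_names()]
    counts = block.sum(axis=1, skipna=False)
    out = pd.Series(pd.Categorical([None] * len(table), categories=MULTIMORBIDITY_LEVELS, ordered=True), index=table.df.index)
    obs = counts.notna()
    binned = pd.cut(
        counts[obs].astype(float),
        bins=[-0.5, 1.5, 2.5, np.inf],
        labels=MULTIMORBIDITY_LEVELS,
    )
    out[obs] = binned.astype(out.dtype)
    return out


# ---------------------------------------------------------------------------
# design-based prevalence


def weighted_prevalence(
    table: CohortTable,
    var: str,
    extra_weight: pd.Series | None = None,
    single_psu: str = "error",
) -> PrevalenceEstimate:
    """Horvitz–Thompson weighted proportion with a design-based 95% CI.

    The variance is a stratified between-PSU Taylor linearisation of the
    ratio estimator; the interval is Wald on the logit scale and
    back-transformed.  ``extra_weight`` (e.g. IPW multipliers) is combined
    multiplicatively with the survey weight.

    ``single_psu='error'`` refuses strata with one PSU (variance undefined);
    ``'collapse'`` pools all such strata into one synthetic stratum.
    """
    v = table.schema[var]
    if v.vtype != "binary":
        raise ValueError(f"{var!r} is not binary")
    sub = table.df[table.df[var].notna()]
    y = sub[var].astype(float).to_numpy()
    w = sub[table.schema.weight].astype(float).to_numpy()
    if extra_weight is not None:
        w = w * np.asarray(extra_weight.loc[sub.index], float)
    strata = sub[table.schema.stratum].to_numpy()
    psus = sub[table.schema.psu].to_numpy()
    n = len(y)
    if n == 0:
        raise ValueError(f"no observed rows for {var!r}")

    wsum = w.sum()
    est = float(np.dot(w, y) / wsum)
    if est in (0.0, 1.0):
        return PrevalenceEstimate(est, est, est, n)

    # stratum -> psu -> totals of the linearised variable z_i = w_i (y_i - est)/wsum
    z = w * (y - est) / wsum
    psu_per_stratum: dict = {}
    for s, p in zip(strata, psus):
        psu_per_stratum.setdefault(s, set()).add(p)
    singles = [s for s, ps in psu_per_stratum.items() if len(ps) < 2]
    if singles:
        if single_psu == "error":
            raise ValueError(
                f"strata with a single PSU (variance undefined): {sorted(map(str, singles))}; "
                "pass single_psu='collapse' to pool them"
            )
        if single_psu != "collapse":
            raise ValueError("single_psu must be 'error' or 'collapse'")
        strata = np.array(
            ["__collapsed__" if s in set(singles) else s for s in strata], dtype=object
        )

    var_hat = 0.0
    for s in pd.unique(strata):
        mask = strata == s
        psu_tot = pd.Series(z[mask]).groupby(pd.Series(psus[mask])).sum().to_numpy()
        n_h = len(psu_tot)
        if n_h < 2:
            continue  # collapsed stratum that still ended up alone
        zbar = psu_tot.mean()
        var_hat += n_h / (n_h - 1) * float(((psu_tot - zbar) ** 2).sum())

    se = float(np.sqrt(var_hat))
    logit = np.log(est / (1 - est))
    se_logit = se / (est * (1 - est))
    lo = 1.0 / (1.0 + np.exp(-(logit - Z95 * se_logit)))
    hi = 1.0 / (1.0 + np.exp(-(logit + Z95 * se_logit)))
    return PrevalenceEstimate(est, float(lo), float(hi), n)
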