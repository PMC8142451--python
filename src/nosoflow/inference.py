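"""Logistic modelling, descriptive tables, and the clustering check.

The primary analysis is an ordinary maximum-likelihood logistic
regression of case status on the number of pre-index intrahospital
transfers plus banded covariates; effect sizes are reported as odds
ratios with Wald 95% confidence intervals on the log-odds scale
(z = 1.959964).  A univariable screen (likelihood-ratio test at
alpha = 0.05, with gender kept a priori) selects candidate covariates.
Cluster-level heterogeneity is summarised by the intraclass correlation
of a random-intercept logistic model on the latent-threshold scale,
ICC = sigma^2 / (sigma^2 + pi^2/3); the random-intercept model is fit
by adaptive-free Gauss-Hermite quadrature maximum likelihood (no
frequentist mixed-logit fitter exists in the scientific Python stack).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from scipy.special import expit, log_expit, logsumexp

from .types import IccResult, ModelResult

WALD_Z = 1.959964


class SeparationError(RuntimeError):
    """Perfect (or quasi-perfect) separation: the MLE does not exist."""


def _design_matrix(records: pd.DataFrame, terms: Sequence[str]):
    """Expand terms into a patsy-free design matrix with an intercept.

    Categorical and object columns are dummy-coded against their first
    (reference) level; numeric and boolean columns enter linearly.
    """
    cols: dict[str, np.ndarray] = {"const": np.ones(len(records))}
    for term in terms:
        if term not in records.columns:
            raise KeyError(f"term {term!r} not in records")
        col = records[term]
        if isinstance(col.dtype, pd.CategoricalDtype) or col.dtype == object:
            cat = col.astype("category")
            levels = list(cat.cat.categories)
            if len(levels) < 2:
                raise ValueError(f"term {term!r} has a single level ({levels})")
            for level in levels[1:]:
                cols[f"{term}[{level}]"] = (cat == level).to_numpy(dtype=float)
        else:
            vals = col.to_numpy(dtype=float)
            if np.all(vals == vals[0]):
                raise ValueError(f"term {term!r} is constant")
            cols[term] = vals
    return pd.DataFrame(cols, index=records.index)


def _separation_suspects(y: np.ndarray, X: pd.DataFrame) -> list[str]:
    suspects = []
    for name in X.columns:
        if name == "const":
            continue
        x = X[name].to_numpy()
        if set(np.unique(x)) <= {0.0, 1.0}:
            for level in (0.0, 1.0):
                ys = y[x == level]
                if ys.size and (ys.min() == ys.max()):
                    suspects.append(name)
                    break
    return suspects


def fit_logistic(
    records: pd.DataFrame, outcome: str = "case", terms: Sequence[str] = ("n_transfers",)
) -> ModelResult:
    """Maximum-likelihood logistic regression.

    Parameters
    ----------
    records
        One row per spell.  ``outcome`` must be binary (0/1 or
        case/control strings).
    terms
        Column names entering the linear predictor; categoricals are
        dummy-coded against their first level.

    Returns a :class:`ModelResult` whose table has one row per
    design-matrix column with the coefficient, its standard error, the
    odds ratio and Wald 95% CI, and the Wald p-value.
    """
    y = records[outcome]
    if y.dtype == object or isinstance(y.dtype, pd.CategoricalDtype):
        y = (y == "case").astype(int)
    y = y.to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must have both classes present")

    X = _design_matrix(records, terms)
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200, tol=1e-10)
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError) as exc:
        suspects = _separation_suspects(y, X)
        if suspects:
            raise SeparationError(
                f"perfect separation involving term(s) {suspects}"
            ) from exc
        raise ValueError(f"singular design matrix for terms {list(terms)}") from exc
    if np.any(~np.isfinite(fit.bse)) or np.any(np.abs(fit.params) > 30):
        suspects = _separation_suspects(y, X) or list(X.columns)
        raise SeparationError(f"separation or non-identified fit; suspect term(s) {suspects}")

    coef = np.asarray(fit.params)
    se = np.asarray(fit.bse)
    table = pd.DataFrame(
        {
            "term": X.columns,
            "coef": coef,
            "se": se,
            "odds_ratio": np.exp(coef),
            "ci_low": np.exp(coef - WALD_Z * se),
            "ci_high": np.exp(coef + WALD_Z * se),
            "p": 2 * stats.norm.sf(np.abs(coef / se)),
        }
    )
    return ModelResult(table=table, n=len(y), loglik=float(fit.llf), terms=list(terms))


def screen_covariates(
    records: pd.DataFrame,
    candidates: Sequence[str],
    alpha: float = 0.05,
    a_priori: Sequence[str] = ("gender",),
    outcome: str = "case",
) -> list[str]:
    """Univariable screen: keep candidates associated with the outcome.

    Each candidate is fitted alone against the outcome and retained
    when the likelihood-ratio p-value is below ``alpha``.  Terms in
    ``a_priori`` are retained regardless of significance.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    missing = [c for c in candidates if c not in records.columns]
    if missing:
        raise KeyError(f"candidates absent from records: {missing}")
    y = records[outcome]
    if y.dtype == object or isinstance(y.dtype, pd.CategoricalDtype):
        y = (y == "case").astype(int)
    y = y.to_numpy(dtype=float)
    ll_null = sm.Logit(y, np.ones((len(y), 1))).fit(disp=0).llf

    retained = []
    for cand in candidates:
        if cand in a_priori:
            retained.append(cand)
            continue
        X = _design_matrix(records, [cand])
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        lr = 2.0 * (fit.llf - ll_null)
        p = stats.chi2.sf(max(lr, 0.0), df=X.shape[1] - 1)
        if p < alpha:
            retained.append(cand)
    return retained


def chi_square_table(
    records: pd.DataFrame, covariate: str, outcome: str = "status"
) -> tuple[float, int, float]:
    """Pearson chi-square on the case/control-by-band contingency table.

    No continuity correction.  Returns ``(statistic, df, p)``; warns if
    any expected cell count drops below 1.
    """
    table = pd.crosstab(records[outcome], records[covariate])
    table = table.loc[:, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError(
            f"chi-square needs at least 2 outcome classes and 2 bands; got {table.shape}"
        )
    stat, p, df, expected = stats.chi2_contingency(table.to_numpy(), correction=False)
    if np.any(expected < 1):
        import warnings

        warnings.warn(
            f"chi-square for {covariate!r}: expected cell count below 1", stacklevel=2
        )
    return float(stat), int(df), float(p)


# ----------------------------------------------------------------------
@dataclass
class DescriptiveTable:
    """Cohort characteristics stratified by case status."""

    bands: pd.DataFrame  # per (covariate, level): n and % per stratum, chi-square p
    continuous: pd.DataFrame  # median / IQR / mean / sd per stratum

    def to_markdown(self) -> str:
        return _markdown_table(self.bands) + "\n\n" + _markdown_table(self.continuous)


def _markdown_table(frame: pd.DataFrame) -> str:
    """Minimal pipe-table rendering (no external table dependency)."""

    def fmt(v):
        return f"{v:.2f}" if isinstance(v, float) else str(v)

    header = "| " + " | ".join(frame.columns) + " |"
    rule = "| " + " | ".join("---" for _ in frame.columns) + " |"
    body = ["| " + " | ".join(fmt(v) for v in row) + " |" for row in frame.itertuples(index=False)]
    return "\n".join([header, rule, *body])


DEFAULT_TABLE_COVARIATES = (
    "gender",
    "age_band",
    "icu_before_index",
    "elix_band",
    "time_band",
    "proc_band",
    "hospital_site",
)

DEFAULT_CONTINUOUS = ("age", "time_at_risk", "elixhauser_count", "procedures")


def descriptive_table(
    records: pd.DataFrame,
    covariates: Sequence[str] = DEFAULT_TABLE_COVARIATES,
    continuous: Sequence[str] = DEFAULT_CONTINUOUS,
    outcome: str = "status",
) -> DescriptiveTable:
    """Counts and column percentages per covariate band, by case status.

    Percentages are within-column (all spells / controls / cases) and
    sum to 100 per covariate; a Pearson chi-square p-value compares the
    case and control distributions of each covariate.  Empty strata
    report 0%.
    """
    col = records[outcome]
    is_case = col.astype(bool) if col.dtype.kind in "biu" else (col == "case")
    mask = is_case.to_numpy(dtype=bool)
    strata = {"all": records, "controls": records[~mask], "cases": records[mask]}
    rows = []
    for cov in covariates:
        if cov not in records.columns:
            raise KeyError(f"covariate {cov!r} not in records")
        col = records[cov]
        if isinstance(col.dtype, pd.CategoricalDtype):
            levels = list(col.cat.categories)
        else:
            levels = sorted(col.dropna().unique(), key=str)
        try:
            _, _, p = chi_square_table(records, cov, outcome=outcome)
        except ValueError:
            p = np.nan
        for level in levels:
            row = {"covariate": cov, "level": level, "p": p}
            for name, part in strata.items():
                n = int((part[cov] == level).sum())
                row[f"{name}_n"] = n
                row[f"{name}_pct"] = 100.0 * n / len(part) if len(part) else 0.0
            rows.append(row)
    bands = pd.DataFrame(rows)

    cont_rows = []
    for field in continuous:
        for name, part in strata.items():
            vals = part[field].astype(float)
            cont_rows.append(
                {
                    "field": field,
                    "stratum": name,
                    "median": vals.median(),
                    "q1": vals.quantile(0.25),
                    "q3": vals.quantile(0.75),
                    "mean": vals.mean(),
                    "sd": vals.std(),
                }
            )
    return DescriptiveTable(bands=bands, continuous=pd.DataFrame(cont_rows))


# ----------------------------------------------------------------------
# Random-intercept logistic model and the intraclass correlation

LOGISTIC_RESIDUAL_VARIANCE = np.pi**2 / 3.0


def icc_from_variance(between_variance: float) -> float:
    """Latent-threshold ICC: var / (var + pi^2/3)."""
    if between_variance < 0:
        raise ValueError("between-cluster variance must be non-negative")
    return between_variance / (between_variance + LOGISTIC_RESIDUAL_VARIANCE)


def _gh_loglik(params, y, X, groups, nodes, weights):
    """Negative marginal log-likelihood via adaptive Gauss-Hermite.

    Quadrature nodes are recentred at each cluster's conditional mode
    and rescaled by the local curvature (the Laplace scale); plain GH
    is badly biased for large clusters, whose integrand is far more
    peaked than the N(0, sigma^2) prior.
    """
    beta, log_sigma = params[:-1], params[-1]
    sigma2 = np.exp(2.0 * log_sigma)
    eta = X @ beta
    log_norm = -0.5 * np.log(2.0 * np.pi * sigma2)
    log_w = np.log(weights)
    total = 0.0
    for idx in groups:
        e0 = eta[idx]
        yg = y[idx]
        u = 0.0  # Newton ascent to the conditional mode of the intercept
        for _ in range(30):
            p = expit(e0 + u)
            grad = np.sum(yg - p) - u / sigma2
            curv = -np.sum(p * (1.0 - p)) - 1.0 / sigma2
            step = grad / curv
            u -= step
            if abs(step) < 1e-10:
                break
        p = expit(e0 + u)
        h = np.sum(p * (1.0 - p)) + 1.0 / sigma2
        s = np.sqrt(2.0 / h)
        uq = u + s * nodes
        e = e0[:, None] + uq[None, :]
        ll = np.where(yg[:, None] > 0, log_expit(e), log_expit(-e)).sum(axis=0)
        f = ll - 0.5 * uq * uq / sigma2 + log_norm
        total += logsumexp(f + nodes**2 + log_w) + np.log(s)
    return -total


def icc_site(
    records: pd.DataFrame,
    cluster: str = "hospital_site",
    outcome: str = "case",
    terms: Sequence[str] = (),
    n_quad: int = 21,
) -> IccResult:
    """Random-intercept logistic model; ICC on the latent scale.

    Fits ``logit P(case) = X beta + u_g`` with ``u_g ~ N(0, sigma^2)``
    by Gauss-Hermite quadrature maximum likelihood and returns
    ``ICC = sigma^2 / (sigma^2 + pi^2/3)``.
    """
    y = records[outcome]
    if y.dtype == object or isinstance(y.dtype, pd.CategoricalDtype):
        y = (y == "case").astype(int)
    y = y.to_numpy(dtype=float)
    labels = records[cluster].to_numpy()
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters for a random-intercept model")
    groups = [np.flatnonzero(labels == g) for g in uniq]

    X = _design_matrix(records, terms).to_numpy() if terms else np.ones((len(y), 1))
    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)

    start = np.zeros(X.shape[1] + 1)
    start[0] = np.log(max(y.mean(), 1e-6) / max(1 - y.mean(), 1e-6))
    start[-1] = np.log(0.1)
    res = optimize.minimize(
        _gh_loglik,
        start,
        args=(y, X, groups, nodes, weights),
        method="L-BFGS-B",
        bounds=[(None, None)] * X.shape[1] + [(-8.0, 3.0)],
    )
    sigma2 = float(np.exp(2.0 * res.x[-1]))
    return IccResult(cluster=cluster, between_variance=sigma2, icc=icc_from_variance(sigma2))
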