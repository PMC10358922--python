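"""Broad-area participation rate-ratio models.

Negative-binomial (and Poisson) generalized linear models of the screened
count per area with the log expected count as offset, quantifying
participation differences by state/territory, remoteness and area
disadvantage as participation rate ratios (PRR = exponentiated
coefficients) with Wald 95% confidence intervals.  The negative binomial
uses the mean-dispersion (NB2) parameterisation Var = mu + alpha mu^2,
nesting Poisson at alpha = 0; a boundary-corrected likelihood-ratio test
compares the two.  Marginal, covariate-standardised rate ratios (SPRR) per
stratum are computed as predictive margins over the empirical distribution
of the other covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .standardization import ScreeningCounts

__all__ = [
    "GLMResult",
    "fit_rate_model",
    "lrt_nb_vs_poisson",
    "wald_tests",
    "marginal_sprr",
]

DEFAULT_COVARIATES = ("disadvantage", "remoteness", "state")
DEFAULT_REFERENCES = {
    "disadvantage": "most_advantaged",
    "remoteness": "major_cities",
}


@dataclass
class GLMResult:
    """Fitted rate model: coefficients on the log rate-ratio scale, their
    covariance, the NB dispersion alpha (0 for Poisson), and the PRR table."""

    family: str
    params: pd.Series
    cov: pd.DataFrame
    dispersion: float
    loglik: float
    prr: pd.DataFrame
    data: pd.DataFrame = field(repr=False)
    design: pd.DataFrame = field(repr=False)
    offset: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    covariates: tuple[str, ...] = ()
    references: Mapping[str, str] = field(default_factory=dict)
    levels: Mapping[str, Sequence[str]] = field(default_factory=dict)
    converged: bool = True
    fit_history: dict = field(default_factory=dict, repr=False)

    @property
    def coef_terms(self) -> list[str]:
        return [t for t in self.params.index if t != "alpha"]


def _reference_levels(data: pd.DataFrame, covariates: Sequence[str]) -> dict[str, str]:
    refs = {}
    for cov in covariates:
        if cov in DEFAULT_REFERENCES and DEFAULT_REFERENCES[cov] in set(data[cov]):
            refs[cov] = DEFAULT_REFERENCES[cov]
        elif cov == "state":
            # most populous state (by invitees) as reference
            refs[cov] = data.groupby(cov)["invitees"].sum().idxmax()
        else:
            refs[cov] = sorted(set(data[cov]))[0]
    return refs


def _build_design(
    data: pd.DataFrame,
    covariates: Sequence[str],
    references: Mapping[str, str],
    levels: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    X = pd.DataFrame({"Intercept": np.ones(len(data))}, index=data.index)
    for cov in covariates:
        non_ref = (levels[cov] if levels is not None
                   else [l for l in sorted(set(data[cov])) if l != references[cov]])
        for level in non_ref:
            X[f"{cov}[{level}]"] = (data[cov] == level).astype(float)
    return X


def fit_rate_model(
    counts: ScreeningCounts,
    expected: pd.DataFrame,
    areas: pd.DataFrame,
    family: str = "negative_binomial",
    covariates: Sequence[str] | None = None,
) -> GLMResult:
    """Fit screened ~ covariates with offset log(E) by maximum likelihood.

    ``family`` is ``"poisson"`` or ``"negative_binomial"`` (NB2, dispersion
    estimated jointly).  Covariates default to whichever of disadvantage,
    remoteness and state are present in the area table with more than one
    level; pass an empty list for the intercept-only (null) model.
    Reference levels: most advantaged quintile, major cities, most
    populous state.
    """
    data = (
        counts.area.merge(expected, on=["area_id", "period"], how="inner")
        .merge(areas, on="area_id", how="inner")
    )
    if (data["expected"] <= 0).any():
        raise ValueError("all modelled areas need a positive expected count")
    if covariates is None:
        covariates = tuple(
            c for c in DEFAULT_COVARIATES
            if c in data.columns and data[c].nunique() > 1
        )
    refs = _reference_levels(data, covariates)
    lvls = {cov: [l for l in sorted(set(data[cov])) if l != refs[cov]]
            for cov in covariates}
    X = _build_design(data, covariates, refs, lvls)
    y = data["screened"].to_numpy(float)
    offset = np.log(data["expected"].to_numpy(float))

    boundary_collapse = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pois_res = sm.Poisson(y, X.to_numpy(), offset=offset).fit(disp=0, maxiter=200)
        if family == "poisson":
            res = pois_res
            names = list(X.columns)
            dispersion = 0.0
            params = pd.Series(res.params, index=names)
            cov = pd.DataFrame(res.cov_params(), index=names, columns=names)
        elif family == "negative_binomial":
            model = sm.NegativeBinomial(y, X.to_numpy(), offset=offset,
                                        loglike_method="nb2")
            res = model.fit(start_params=np.append(pois_res.params, 0.05),
                            method="bfgs", maxiter=500, disp=0)
            names = list(X.columns) + ["alpha"]
            dispersion = max(float(res.params[-1]), 0.0)
            try:
                cov_arr = np.asarray(res.cov_params())
                if not np.all(np.isfinite(cov_arr)):
                    raise ValueError("non-finite covariance")
            except (ValueError, np.linalg.LinAlgError):
                cov_arr = None
            if cov_arr is None or res.llf <= pois_res.llf:
                # dispersion on its boundary: the NB collapses onto the
                # Poisson fit, whose coefficient covariance applies
                boundary_collapse = True
                params = pd.Series(np.append(pois_res.params, dispersion),
                                   index=names)
                cov_arr = np.zeros((len(names), len(names)))
                cov_arr[:-1, :-1] = pois_res.cov_params()
                cov_arr[-1, -1] = np.nan
                cov = pd.DataFrame(cov_arr, index=names, columns=names)
            else:
                params = pd.Series(res.params, index=names)
                cov = pd.DataFrame(cov_arr, index=names, columns=names)
        else:
            raise ValueError(f"unknown family {family!r}")

    converged = bool(res.mle_retvals.get("converged", True)) or boundary_collapse
    if not converged:
        warnings.warn(
            f"{family} fit did not converge; trace: {res.mle_retvals}"
        )

    terms = [t for t in names if t != "alpha"]
    est = params[terms]
    se = np.sqrt(np.diag(cov.loc[terms, terms]))
    z = est.to_numpy() / se
    prr = pd.DataFrame({
        "term": terms,
        "coef": est.to_numpy(),
        "se": se,
        "prr": np.exp(est.to_numpy()),
        "ci_low": np.exp(est.to_numpy() - 1.959963984540054 * se),
        "ci_high": np.exp(est.to_numpy() + 1.959963984540054 * se),
        "p": 2.0 * stats.norm.sf(np.abs(z)),
    })
    loglik = float(max(res.llf, pois_res.llf)) if family == "negative_binomial" \
        else float(res.llf)
    return GLMResult(
        family=family, params=params, cov=cov, dispersion=dispersion,
        loglik=loglik, prr=prr, data=data, design=X, offset=offset,
        y=y, covariates=tuple(covariates), references=refs, levels=lvls,
        converged=converged, fit_history=dict(res.mle_retvals),
    )


def lrt_nb_vs_poisson(nb: GLMResult, pois: GLMResult) -> tuple[float, float]:
    """Boundary-corrected likelihood-ratio test of NB against Poisson.

    The dispersion alpha sits on the boundary of its parameter space under
    the Poisson null, so the statistic's null distribution is the mixture
    0.5 chi2_0 + 0.5 chi2_1: p = 0.5 * P(chi2_1 > stat) for stat > 0 and
    p = 1 at stat = 0.
    """
    if nb.family != "negative_binomial" or pois.family != "poisson":
        raise ValueError("pass the NB fit first and the Poisson fit second")
    if not (np.array_equal(nb.y, pois.y) and np.allclose(nb.offset, pois.offset)
            and list(nb.design.columns) == list(pois.design.columns)):
        raise ValueError("fits are not on the same data and mean structure")
    stat = max(2.0 * (nb.loglik - pois.loglik), 0.0)
    p = 1.0 if stat == 0.0 else 0.5 * float(stats.chi2.sf(stat, 1))
    return stat, p


def wald_tests(
    fit: GLMResult, term_groups: Mapping[str, Sequence[str]] | None = None
) -> dict[str, float]:
    """Two-sided Wald tests: per-coefficient z tests plus chi-square tests
    for named groups of coefficients (e.g. all levels of one covariate).

    Groups default to one per covariate.  A group on a single term equals
    the square of its z test.
    """
    if term_groups is None:
        term_groups = {
            cov: [t for t in fit.coef_terms if t.startswith(f"{cov}[")]
            for cov in fit.covariates
        }
    out: dict[str, float] = {}
    for term in fit.coef_terms:
        se = float(np.sqrt(fit.cov.loc[term, term]))
        z = fit.params[term] / se
        out[term] = 2.0 * float(stats.norm.sf(abs(z)))
    for group, terms in term_groups.items():
        terms = list(terms)
        if not terms:
            continue
        b = fit.params[terms].to_numpy()
        V = fit.cov.loc[terms, terms].to_numpy()
        try:
            chi2 = float(b @ np.linalg.solve(V, b))
        except np.linalg.LinAlgError as err:
            raise ValueError(f"singular covariance for group {group!r}") from err
        out[group] = float(stats.chi2.sf(chi2, len(terms)))
    return out


def marginal_sprr(fit: GLMResult, factor: str) -> pd.DataFrame:
    """Marginal (covariate-standardised) participation rate ratios.

    Predictive margins: for each level l of ``factor`` the whole study
    population is assigned level l, expected screens are predicted from the
    fitted model, and the ratio of total predicted screens against the
    reference level is reported with a delta-method CI on the log scale.
    With a single covariate this reduces to the fitted PRR.
    """
    if factor not in fit.covariates:
        raise ValueError(f"{factor!r} was not a covariate of the fit")
    levels = sorted(set(fit.data[factor]))
    ref = fit.references[factor]
    terms = fit.coef_terms
    beta = fit.params[terms].to_numpy()
    V = fit.cov.loc[terms, terms].to_numpy()
    E = np.exp(fit.offset)

    def margin(level: str) -> tuple[float, np.ndarray]:
        data = fit.data.copy()
        if (fit.data[factor] == level).sum() == 0:
            raise ValueError(f"empty stratum {level!r} for factor {factor!r}")
        data[factor] = level
        X = _build_design(data, fit.covariates, fit.references,
                          fit.levels or None)[terms].to_numpy()
        mu = E * np.exp(X @ beta)
        m = mu.sum()
        grad = (mu[:, None] * X).sum(axis=0) / m  # d log m / d beta
        return m, grad

    m_ref, g_ref = margin(ref)
    rows = []
    for level in levels:
        m_l, g_l = margin(level)
        log_ratio = np.log(m_l / m_ref)
        g = g_l - g_ref
        se = float(np.sqrt(g @ V @ g))
        rows.append({
            "stratum": level,
            "sprr": float(np.exp(log_ratio)),
            "ci_low": float(np.exp(log_ratio - 1.959963984540054 * se)),
            "ci_high": float(np.exp(log_ratio + 1.959963984540054 * se)),
        })
    return pd.DataFrame(rows)
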