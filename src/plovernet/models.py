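"""Regression harness: GLM / mixed-model fits, likelihood ratios, VIFs.

Model specifications mirror the analysis suite: binomial (logit) for
binary and proportion responses, Poisson (log) for counts, gaussian
with identity or log link for continuous responses, with optional
(possibly crossed) random intercepts for repeated measures.  All fits
are by maximum likelihood so nested models can be compared by
likelihood-ratio test.  Gaussian responses with identity link support
random intercepts through ``MixedLM`` (crossed effects as variance
components); for other families the random terms are dropped and the
fit downgraded to a fixed-effects GLM, with the downgrade flagged —
the permutation tests compare like with like, so their inference does
not depend on the random-effect likelihood.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

logger = logging.getLogger(__name__)

_VALID_FAMILY_LINKS = {
    ("binomial", "logit"),
    ("poisson", "log"),
    ("gaussian", "identity"),
    ("gaussian", "log"),
}


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one regression model."""

    name: str
    response: str
    family: str
    link: str
    fixed_terms: tuple[str, ...]
    random_terms: tuple[str, ...] = ()
    focal_term: str | None = None
    data_filter: str = ""

    def __post_init__(self) -> None:
        if (self.family, self.link) not in _VALID_FAMILY_LINKS:
            raise ValueError(
                f"unsupported family/link: {self.family}/{self.link}"
            )
        if self.focal_term is not None and self.focal_term not in self.fixed_terms:
            raise ValueError(
                f"focal_term {self.focal_term!r} not among fixed terms"
            )

    @property
    def formula(self) -> str:
        rhs = " + ".join(self.fixed_terms) if self.fixed_terms else "1"
        return f"{self.response} ~ {rhs}"

    def drop_term(self, term: str) -> "ModelSpec":
        if term not in self.fixed_terms:
            raise ValueError(f"term {term!r} not in model")
        return replace(
            self,
            name=f"{self.name}_minus_{term}",
            fixed_terms=tuple(t for t in self.fixed_terms if t != term),
            focal_term=None,
        )


@dataclass
class ModelFit:
    spec: ModelSpec
    params: pd.Series
    bse: pd.Series
    llf: float
    n_obs: int
    k_params: int
    converged: bool
    degenerate: bool = False
    downgraded: bool = False
    method: str = "glm"

    @property
    def focal_estimate(self) -> float:
        """Coefficient of the spec's focal term (first matching column)."""
        term = self.spec.focal_term
        if term is None:
            raise ValueError("model spec has no focal term")
        if term in self.params.index:
            return float(self.params[term])
        matches = [ix for ix in self.params.index if ix.startswith(term)]
        if not matches:
            raise KeyError(f"focal term {term!r} not found in fit")
        return float(self.params[matches[0]])


@dataclass(frozen=True)
class LRTResult:
    chi_sq: float
    df: int
    p: float


def _family(spec: ModelSpec) -> sm.families.Family:
    if spec.family == "binomial":
        return sm.families.Binomial()
    if spec.family == "poisson":
        return sm.families.Poisson()
    link = sm.families.links.Log() if spec.link == "log" else sm.families.links.Identity()
    return sm.families.Gaussian(link=link)


def fit_model(spec: ModelSpec, data: pd.DataFrame) -> ModelFit:
    """Fit a model specification by maximum likelihood.

    Random grouping factors with fewer than two levels are dropped (a
    logged downgrade); gaussian-identity models with random terms use
    ``MixedLM`` (ML, crossed intercepts as variance components), other
    families fall back to a fixed-effects GLM with ``downgraded=True``.
    A constant response yields a degenerate fit with zero slopes.
    """
    data = data.reset_index(drop=True)
    if data.empty:
        raise ValueError(f"model {spec.name}: empty dataset")

    if data[spec.response].nunique(dropna=True) <= 1:
        names = ["Intercept"] + [t for t in spec.fixed_terms]
        params = pd.Series(0.0, index=names)
        logger.warning("model %s: constant response, degenerate fit", spec.name)
        return ModelFit(
            spec=spec,
            params=params,
            bse=pd.Series(np.nan, index=names),
            llf=np.nan,
            n_obs=len(data),
            k_params=len(names),
            converged=False,
            degenerate=True,
        )

    random_terms = tuple(
        t for t in spec.random_terms if data[t].nunique() >= 2
    )
    dropped = set(spec.random_terms) - set(random_terms)
    if dropped:
        logger.info(
            "model %s: random term(s) %s dropped (<2 levels)",
            spec.name,
            sorted(dropped),
        )

    if random_terms and spec.family == "gaussian" and spec.link == "identity":
        return _fit_mixed(spec, data, random_terms)

    downgraded = bool(random_terms)
    if downgraded:
        logger.info(
            "model %s: %s family with random terms fitted as fixed-effects GLM",
            spec.name,
            spec.family,
        )
    return _fit_glm(spec, data, downgraded=downgraded)


def _fit_glm(spec: ModelSpec, data: pd.DataFrame, downgraded: bool) -> ModelFit:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = smf.glm(spec.formula, data=data, family=_family(spec))
            res = model.fit()
            converged = bool(res.converged)
        except Exception as exc:
            raise RuntimeError(f"model {spec.name}: GLM fit failed: {exc}") from exc
    if not np.all(np.isfinite(res.params)):
        converged = False
        logger.warning(
            "model %s: non-finite coefficients (separation/singular fit)",
            spec.name,
        )
    return ModelFit(
        spec=spec,
        params=res.params,
        bse=res.bse,
        llf=float(res.llf),
        n_obs=int(res.nobs),
        k_params=len(res.params),
        converged=converged,
        downgraded=downgraded,
    )


def _fit_mixed(
    spec: ModelSpec, data: pd.DataFrame, random_terms: Sequence[str]
) -> ModelFit:
    df = data.copy()
    df["_const_group"] = 1
    vc = {t: f"0 + C({t})" for t in random_terms}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = smf.mixedlm(
                spec.formula,
                data=df,
                groups="_const_group",
                vc_formula=vc,
                re_formula="0",
            )
            res = model.fit(reml=False)
            converged = bool(res.converged)
        except Exception as exc:
            logger.warning(
                "model %s: mixed fit failed (%s); falling back to GLM",
                spec.name,
                exc,
            )
            return _fit_glm(spec, data, downgraded=True)
    fe = res.fe_params
    # parameter count: fixed effects + variance components + residual var
    k = len(fe) + len(random_terms) + 1
    return ModelFit(
        spec=spec,
        params=fe,
        bse=res.bse.loc[fe.index],
        llf=float(res.llf),
        n_obs=int(res.nobs),
        k_params=k,
        converged=converged,
        method="mixedlm",
    )


def lrt(full: ModelFit, reduced: ModelFit) -> LRTResult:
    """Likelihood-ratio test of nested maximum-likelihood fits."""
    if not set(reduced.spec.fixed_terms) <= set(full.spec.fixed_terms):
        raise ValueError("reduced model is not nested in full model")
    if full.n_obs != reduced.n_obs:
        raise ValueError("models fitted on different numbers of rows")
    df = full.k_params - reduced.k_params
    chi = max(0.0, 2.0 * (full.llf - reduced.llf))
    if df <= 0:
        return LRTResult(chi_sq=chi, df=max(df, 0), p=1.0)
    return LRTResult(chi_sq=chi, df=df, p=float(stats.chi2.sf(chi, df)))


def lrt_for_term(spec: ModelSpec, data: pd.DataFrame, term: str) -> LRTResult:
    """LRT for dropping a single fixed term from a specification."""
    full = fit_model(spec, data)
    reduced = fit_model(spec.drop_term(term), data)
    return lrt(full, reduced)


def compute_vif(data: pd.DataFrame, terms: Sequence[str]) -> pd.Series:
    """Variance inflation factor per model term.

    VIF_j = 1 / (1 - R²_j), where R²_j is from regressing the design
    column of term j on all other terms (with intercept).  Perfectly
    collinear terms report ``inf``.
    """
    if len(terms) < 2:
        raise ValueError("VIF needs at least two non-intercept terms")
    from patsy import dmatrix

    design = dmatrix(" + ".join(terms), data, return_type="dataframe")
    cols = [c for c in design.columns if c != "Intercept"]
    x = design.to_numpy(dtype=float)
    out = {}
    for name in cols:
        j = list(design.columns).index(name)
        others = np.delete(x, j, axis=1)
        yj = x[:, j]
        beta, _, _, _ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ beta
        ss_tot = np.sum((yj - yj.mean()) ** 2)
        ss_res = np.sum(resid**2)
        if ss_tot <= 0:
            out[name] = np.nan
            continue
        r2 = 1.0 - ss_res / ss_tot
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")
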