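"""Minimal-adequate-model workflow via generalized least squares.

The ecological and biomarker responses are modelled against the full
factorial of species and temperature treatment.  Because variances often
differ between factor levels (e.g. one species responds far more variably
than the other), the linear model is extended with a variance-covariate
structure: observations in stratum g have variance sigma^2 * delta_g^2,
with delta fixed to 1 in the first stratum.  The workflow is the standard
one for such models:

1. choose the variance structure by fitting the full fixed model under REML
   for each candidate structure and keeping the lowest AIC (ties go to the
   simpler structure);
2. simplify the fixed structure by backward selection: repeatedly drop the
   least significant droppable term judged by a maximum-likelihood (ML)
   ratio test against chi-square, never removing a main effect while its
   interaction is retained;
3. re-express the final model under REML for unbiased variance estimates.

The per-stratum SD ratios are estimated by profiling out the coefficients
and sigma^2 and maximizing the (restricted) log-likelihood over the
remaining log-ratios numerically.  AIC counts fixed coefficients, sigma^2
and the free variance ratios.  Likelihood-ratio degrees of freedom are
reported as the parameter-count difference between the compared models.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

VARIANCE_STRUCTURES = ("identity", "species", "treatment",
                       "species_treatment")

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class ModelSpec:
    """A GLS model: response ~ fixed terms, with a variance structure.

    ``fixed`` holds main-effect factor names and ``a:b`` interactions; an
    interaction requires both its main effects.  ``variance`` is
    ``"identity"`` or a stratification: a factor name, or two factor names
    joined by ``_`` for their crossing.
    """

    response: str
    fixed: tuple[str, ...] = ("species", "treatment", "species:treatment")
    variance: str = "identity"
    method: str = "REML"

    def __post_init__(self):
        if self.method not in ("ML", "REML"):
            raise ValueError("method must be 'ML' or 'REML'")
        mains = {t for t in self.fixed if ":" not in t}
        for t in self.fixed:
            if ":" in t:
                a, b = t.split(":")
                if a not in mains or b not in mains:
                    raise ValueError(
                        f"interaction {t!r} requires both main effects")

    def variance_factors(self) -> tuple[str, ...]:
        if self.variance == "identity":
            return ()
        return tuple(self.variance.split("_", 1)) \
            if "_" in self.variance and self.variance not in ("species",
                                                              "treatment") \
            else (self.variance,)


@dataclass(frozen=True)
class FitResult:
    """One fitted GLS model."""

    spec: ModelSpec
    params: pd.Series
    sigma: float
    weights: dict[str, float]  # per-stratum SD ratio, first stratum = 1
    loglik: float
    aic: float
    n_obs: int
    n_params: int  # fixed coefficients + sigma^2 + free variance ratios

    @property
    def method(self) -> str:
        return self.spec.method


@dataclass(frozen=True)
class LRTest:
    """A likelihood-ratio test between nested ML fits."""

    df: int
    L_ratio: float
    p: float
    term: str | None = None  # the term whose removal was tested
    removed: bool = False


@dataclass(frozen=True)
class SelectionResult:
    """Backward-selection outcome: the minimal adequate model."""

    spec: ModelSpec
    fit: FitResult  # final model re-expressed under REML
    trail: tuple[LRTest, ...]


# --------------------------------------------------------------------------
# Design matrix and likelihood machinery
# --------------------------------------------------------------------------

def _factor_dummies(data: pd.DataFrame, factor: str):
    levels = sorted(map(str, pd.unique(data[factor].astype(str))))
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} needs >= 2 observed levels")
    cols, names = [], []
    vals = data[factor].astype(str).to_numpy()
    for lev in levels[1:]:  # treatment coding, first level is the reference
        cols.append((vals == lev).astype(float))
        names.append(f"{factor}[{lev}]")
    return cols, names


def _design_matrix(data: pd.DataFrame, terms: tuple[str, ...]):
    n = len(data)
    cols, names = [np.ones(n)], ["(Intercept)"]
    cache = {}
    for t in terms:
        if ":" not in t:
            cache[t] = _factor_dummies(data, t)
            c, nm = cache[t]
            cols.extend(c)
            names.extend(nm)
    for t in terms:
        if ":" in t:
            a, b = t.split(":")
            ca, na = cache.get(a) or _factor_dummies(data, a)
            cb, nb = cache.get(b) or _factor_dummies(data, b)
            for (x, nx), (z, nz) in itertools.product(zip(ca, na),
                                                      zip(cb, nb)):
                cols.append(x * z)
                names.append(f"{nx}:{nz}")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design matrix")
    return X, names


def _strata(data: pd.DataFrame, spec: ModelSpec):
    factors = spec.variance_factors()
    if not factors:
        return np.zeros(len(data), dtype=int), ("all",)
    labels = data[list(factors)].astype(str).agg("*".join, axis=1)
    levels = tuple(sorted(labels.unique()))
    index = {lev: k for k, lev in enumerate(levels)}
    codes = labels.map(index).to_numpy()
    counts = np.bincount(codes, minlength=len(levels))
    if (counts < 2).any():
        bad = [levels[k] for k in np.flatnonzero(counts < 2)]
        raise ValueError(f"variance strata with <2 observations: {bad}")
    return codes, levels


def _profiled_loglik(y, X, sd_per_obs, method):
    """(beta_hat, rss, loglik) with sigma^2 profiled out."""
    n, p = X.shape
    yw = y / sd_per_obs
    Xw = X / sd_per_obs[:, None]
    beta, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    logdet_v = 2.0 * float(np.log(sd_per_obs).sum())
    if method == "ML":
        sigma2 = rss / n
        ll = -0.5 * (n * _LOG_2PI + n * np.log(sigma2) + logdet_v + n)
    else:
        sigma2 = rss / (n - p)
        sign, logdet_xx = np.linalg.slogdet(Xw.T @ Xw)
        ll = -0.5 * ((n - p) * _LOG_2PI + (n - p) * np.log(sigma2)
                     + logdet_v + logdet_xx + (n - p))
    return beta, np.sqrt(sigma2), ll


def fit_gls(data: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Fit one GLS model by ML or REML.

    With the identity variance structure this reduces exactly to ordinary
    least squares; otherwise the per-stratum SD ratios (first stratum fixed
    at 1) are estimated by maximizing the profiled (restricted) likelihood.
    Deterministic given the data.
    """
    if spec.response not in data.columns:
        raise ValueError(f"response {spec.response!r} not in data")
    y = pd.to_numeric(data[spec.response], errors="raise").to_numpy(float)
    if np.isnan(y).any():
        raise ValueError("response contains missing values")
    X, names = _design_matrix(data, spec.fixed)
    codes, levels = _strata(data, spec)
    G = len(levels)
    n, p = X.shape

    if G == 1:
        beta, sigma, ll = _profiled_loglik(y, X, np.ones(n), spec.method)
        deltas = np.array([1.0])
    else:
        def negll(log_d):
            deltas = np.concatenate([[1.0], np.exp(log_d)])
            return -_profiled_loglik(y, X, deltas[codes], spec.method)[2]

        res = optimize.minimize(negll, x0=np.zeros(G - 1),
                                method="L-BFGS-B")
        if not res.success:  # pragma: no cover - L-BFGS-B rarely fails here
            raise RuntimeError(f"variance estimation failed: {res.message}")
        deltas = np.concatenate([[1.0], np.exp(res.x)])
        beta, sigma, ll = _profiled_loglik(y, X, deltas[codes], spec.method)

    k = p + 1 + (G - 1)
    return FitResult(
        spec=spec,
        params=pd.Series(beta, index=names),
        sigma=float(sigma),
        weights=dict(zip(levels, map(float, deltas))),
        loglik=float(ll),
        aic=float(-2.0 * ll + 2.0 * k),
        n_obs=n,
        n_params=k,
    )


# --------------------------------------------------------------------------
# Selection workflow
# --------------------------------------------------------------------------

def select_variance_structure(
    data: pd.DataFrame,
    spec: ModelSpec,
    candidates: tuple[str, ...] = VARIANCE_STRUCTURES,
) -> ModelSpec:
    """Choose the variance structure by REML AIC on the full fixed model.

    Candidates must include ``"identity"`` (the no-structure reference).
    Ties in AIC are broken toward the structure with fewer parameters.
    """
    if len(candidates) < 1 or "identity" not in candidates:
        raise ValueError("candidates must include 'identity'")
    if len(candidates) == 1:
        return replace(spec, variance=candidates[0], method="REML")
    fits = [fit_gls(data, replace(spec, variance=v, method="REML"))
            for v in candidates]
    best = min(fits, key=lambda f: (f.aic, f.n_params))
    return best.spec


def lr_test(full: FitResult, reduced: FitResult) -> LRTest:
    """Likelihood-ratio test of two nested ML fits.

    df is the parameter-count difference; the statistic is referred to the
    chi-square distribution with that df.  REML fits are rejected because
    restricted likelihoods of models with different fixed structures are
    not comparable.
    """
    if full.method != "ML" or reduced.method != "ML":
        raise ValueError("lr_test requires ML fits on both sides")
    if not set(reduced.spec.fixed) <= set(full.spec.fixed) \
            or full.spec.variance != reduced.spec.variance \
            or full.spec.response != reduced.spec.response:
        raise ValueError("models are not nested")
    df = full.n_params - reduced.n_params
    if df <= 0:
        raise ValueError("full model must have more parameters")
    L = 2.0 * (full.loglik - reduced.loglik)
    p = float(stats.chi2.sf(max(L, 0.0), df)) if L > 0 else 1.0
    return LRTest(df=df, L_ratio=float(max(L, 0.0)), p=p)


def _droppable(terms: tuple[str, ...]) -> list[str]:
    blocked = set()
    for t in terms:
        if ":" in t:
            blocked.update(t.split(":"))
    return [t for t in terms if t not in blocked]


def backward_select(data: pd.DataFrame, spec: ModelSpec,
                    alpha: float = 0.05) -> SelectionResult:
    """Backward-eliminate fixed terms by ML ratio tests.

    At each step, every droppable term (interactions before their main
    effects) is tested by dropping it and comparing the ML likelihoods; the
    least significant term with p >= ``alpha`` is removed.  The surviving
    model is re-expressed under REML.  The trail records each accepted
    drop (and, last, the test that stopped the elimination, if any).
    """
    current = replace(spec, method="ML")
    trail: list[LRTest] = []
    while current.fixed:
        full_fit = fit_gls(data, current)
        tests = []
        for term in _droppable(current.fixed):
            reduced = replace(
                current, fixed=tuple(t for t in current.fixed if t != term))
            tests.append((term, lr_test(full_fit, fit_gls(data, reduced))))
        if not tests:
            break
        term, best = max(tests, key=lambda kv: kv[1].p)
        remove = best.p >= alpha
        trail.append(replace(best, term=term, removed=remove))
        if not remove:
            break
        current = replace(
            current, fixed=tuple(t for t in current.fixed if t != term))
    final = replace(current, method="REML")
    return SelectionResult(spec=final, fit=fit_gls(data, final),
                           trail=tuple(trail))
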