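"""Comparative-statistics pipeline relating morphology to swimming speed.

The observational counterpart of the mechanistic drag model: log U_max is
regressed on fineness ``f``, its quadratic ``f^2``, propulsive-fin aspect
ratio ``AR`` and log body mass ``logM``, separately per gait group, with

* all variables mean-centred and scaled to unit variance (``f^2`` squared
  after centring ``f`` but before scaling, so the linear coefficient keeps
  its interpretation at the mean fineness);
* every predictor subset fitted (16 candidates, no interactions), ranked by
  the small-sample AICc, retained at ``dAICc <= 2`` (with a small soft
  margin mirroring the near-miss models the analysis admits), and averaged
  with Akaike weights conditional on inclusion;
* phylogenetic generalised least squares with Pagel's lambda estimated per
  model by maximum likelihood (lambda = 0 collapses exactly to OLS);
* percentile bootstrap intervals over whole re-analysed pseudo-samples;
* Felsenstein's independent contrasts for phylogeny-corrected correlations;
* a permutation test of the variance in (mass- and fin-adjusted) U_max
  explained by the mechanistic model.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import solve_triangular
from scipy.optimize import minimize_scalar

from . import morphometrics, trees

__all__ = [
    "PREDICTORS",
    "DesignMatrix",
    "ModelFit",
    "ModelSet",
    "AveragedCoefficients",
    "build_design",
    "fit_pgls",
    "aicc",
    "enumerate_and_retain",
    "model_average",
    "bootstrap_cis",
    "adjusted_umax",
    "mechanistic_r2",
    "PermutationResult",
    "permutation_test",
    "PicCorrelations",
    "pic_correlations",
    "VertexResult",
    "quadratic_vertex",
]

#: Candidate predictors of log U_max, in canonical order.
PREDICTORS = ("f", "f2", "AR", "logM")


# ---------------------------------------------------------------------------
# design matrix


@dataclass
class DesignMatrix:
    """Standardised regression design for one gait group.

    ``response`` and every predictor column have mean 0 and SD 1 (ddof=1).
    ``meta`` keeps the centring/scale constants needed to map standardised
    coefficients back to the raw fineness scale (see
    :func:`quadratic_vertex`).
    """

    gait: str
    species: list[str]
    response: np.ndarray  # standardised log U_max
    columns: dict[str, np.ndarray]
    meta: dict[str, float]

    @property
    def n(self) -> int:
        return self.response.size

    def matrix(self, included: Sequence[str]) -> np.ndarray:
        """Design matrix with intercept column for a predictor subset."""
        cols = [np.ones(self.n)]
        for name in included:
            cols.append(self.columns[name])
        return np.column_stack(cols)


def _standardise(x: np.ndarray, label: str):
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if sd == 0.0 or not np.isfinite(sd):
        raise ValueError(f"predictor {label!r} has zero variance")
    return (x - mean) / sd, mean, sd


def build_design(
    records: Iterable[morphometrics.SpeciesRecord],
    gait: str,
    *,
    viscosity: float = 8.8e-7,
    elliptical: str = "quadratic",
) -> DesignMatrix:
    """Standardised design (log U_max ~ f + f^2 + AR + logM) for one gait."""
    recs = [r for r in records if r.gait == gait]
    if len(recs) < 6:
        raise ValueError(f"need at least 6 records of gait {gait!r}, got {len(recs)}")
    for r in recs:
        if r.mass <= 0 or r.umax <= 0:
            raise ValueError(f"{r.species}: mass and umax must be positive to take logs")
    f_raw = np.array(
        [morphometrics.derive(r, viscosity=viscosity, elliptical=elliptical).fineness for r in recs]
    )
    ar_raw = np.array([r.fin_aspect_ratio for r in recs])
    logm_raw = np.log([r.mass for r in recs])
    y_raw = np.log([r.umax for r in recs])

    f_std, f_mean, f_sd = _standardise(f_raw, "f")
    # quadratic built from the *centred but unscaled* fineness
    fsq_raw = (f_raw - f_mean) ** 2
    fsq_std, fsq_mean, fsq_sd = _standardise(fsq_raw, "f2")
    ar_std, ar_mean, ar_sd = _standardise(ar_raw, "AR")
    logm_std, logm_mean, logm_sd = _standardise(logm_raw, "logM")
    y_std, y_mean, y_sd = _standardise(y_raw, "logU")

    return DesignMatrix(
        gait=gait,
        species=[r.species for r in recs],
        response=y_std,
        columns={"f": f_std, "f2": fsq_std, "AR": ar_std, "logM": logm_std},
        meta={
            "f_mean": f_mean,
            "f_sd": f_sd,
            "f2_mean": fsq_mean,
            "f2_sd": fsq_sd,
            "AR_mean": ar_mean,
            "AR_sd": ar_sd,
            "logM_mean": logm_mean,
            "logM_sd": logm_sd,
            "logU_mean": y_mean,
            "logU_sd": y_sd,
            "f_min": float(f_raw.min()),
            "f_max": float(f_raw.max()),
        },
    )


# ---------------------------------------------------------------------------
# (phylogenetic) generalised least squares


@dataclass
class ModelFit:
    """One fitted candidate model (GLS under lambda-scaled covariance)."""

    predictors: tuple[str, ...]
    beta: pd.Series  # standardised coefficients, index: intercept + predictors
    se: pd.Series
    pvalues: pd.Series  # two-sided t tests, df = n - p
    lambda_: float | None  # None for a plain OLS fit (no tree supplied)
    loglik: float
    k: int  # parameters counted by AICc: coefficients + sigma^2 (+ lambda)
    n: int
    aicc: float
    r2: float
    adj_r2: float
    sigma2: float  # ML residual variance (of the whitened model)


def _gls_core(y: np.ndarray, X: np.ndarray, V: np.ndarray | None):
    """GLS estimates and ML log-likelihood under known covariance ``V``.

    Returns (beta, cov_unscaled, rss, logdet, yw, Xw) where ``cov_unscaled``
    is ``(X' V^-1 X)^-1`` and rss the whitened residual sum of squares.
    """
    n = y.size
    if V is None:
        yw, Xw = y, X
        logdet = 0.0
    else:
        L = np.linalg.cholesky(V)
        yw = solve_triangular(L, y, lower=True)
        Xw = solve_triangular(L, X, lower=True)
        logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    xtx = Xw.T @ Xw
    cov_unscaled = np.linalg.inv(xtx)
    return beta, cov_unscaled, rss, logdet, yw, Xw


def _ml_loglik(n: int, rss: float, logdet: float) -> float:
    sigma2 = rss / n
    if sigma2 <= 0:
        return math.inf
    return -0.5 * (n * math.log(2.0 * math.pi * sigma2) + n + logdet)


def _lambda_cov(V: np.ndarray, lam: float) -> np.ndarray:
    """Pagel transform: off-diagonal Brownian covariances scaled by lambda."""
    out = lam * V
    np.fill_diagonal(out, np.diag(V))
    return out


def fit_pgls(
    design: DesignMatrix,
    tree=None,
    included: Sequence[str] = PREDICTORS,
    *,
    vcv: np.ndarray | None = None,
    lambda_grid_tol: float = 1e-6,
) -> ModelFit:
    """Fit one candidate model, estimating Pagel's lambda by ML if a tree.

    With ``tree`` (or a precomputed ``vcv`` in design species order) the
    residual covariance is the Brownian VCV with off-diagonals scaled by
    lambda, and lambda is chosen on [0, 1] by maximising the ML profile
    likelihood.  Without a tree the fit is ordinary least squares.  At
    ``lambda = 0`` the GLS collapses to OLS exactly (for an ultrametric
    tree the diagonal is constant and is absorbed by sigma^2).
    """
    included = tuple(included)
    unknown = set(included) - set(PREDICTORS)
    if unknown:
        raise ValueError(f"unknown predictors: {sorted(unknown)}")
    y = design.response
    X = design.matrix(included)
    n, p = X.shape

    if tree is None and vcv is None:
        beta, cov_unscaled, rss, logdet, _, _ = _gls_core(y, X, None)
        lam_hat = None
        loglik = _ml_loglik(n, rss, logdet)
        V = None
    else:
        if vcv is None:
            _, V = trees.vcv_matrix(tree, labels=design.species)
        else:
            V = vcv

        def neg_ll(lam: float) -> float:
            try:
                _, _, rss_l, logdet_l, _, _ = _gls_core(y, X, _lambda_cov(V, lam))
            except np.linalg.LinAlgError:
                return math.inf
            return -_ml_loglik(n, rss_l, logdet_l)

        res = minimize_scalar(neg_ll, bounds=(0.0, 1.0), method="bounded",
                              options={"xatol": lambda_grid_tol})
        candidates = [(neg_ll(0.0), 0.0), (neg_ll(1.0), 1.0), (res.fun, float(res.x))]
        _, lam_hat = min(candidates, key=lambda t: t[0])
        beta, cov_unscaled, rss, logdet, _, _ = _gls_core(y, X, _lambda_cov(V, lam_hat))
        loglik = _ml_loglik(n, rss, logdet)

    sigma2_ml = rss / n
    dof = n - p
    if dof <= 0:
        raise ValueError("model has no residual degrees of freedom")
    sigma2_unbiased = rss / dof
    se = np.sqrt(np.diag(cov_unscaled) * sigma2_unbiased)
    tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df=dof)

    # generalised R^2 against the (same-covariance) intercept-only model
    Vlam = None if lam_hat is None or V is None else _lambda_cov(V, lam_hat)
    _, _, tss, _, _, _ = _gls_core(y, np.ones((n, 1)), Vlam)
    r2 = 1.0 - rss / tss if tss > 0 else math.nan
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / dof if dof > 0 else math.nan

    k = p + 1 + (1 if lam_hat is not None else 0)
    names = ["intercept", *included]
    return ModelFit(
        predictors=included,
        beta=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        pvalues=pd.Series(pvals, index=names),
        lambda_=lam_hat,
        loglik=loglik,
        k=k,
        n=n,
        aicc=aicc(loglik, k, n),
        r2=float(r2),
        adj_r2=float(adj_r2),
        sigma2=float(sigma2_ml),
    )


def aicc(loglik_or_fit, k: int | None = None, n: int | None = None) -> float:
    """Small-sample Akaike information criterion.

    ``AICc = -2 logL + 2k + 2k(k+1)/(n-k-1)``.  Accepts either a
    :class:`ModelFit` or an explicit ``(loglik, k, n)`` triple;
    requires ``n > k + 1``.
    """
    if isinstance(loglik_or_fit, ModelFit):
        fit = loglik_or_fit
        loglik, k, n = fit.loglik, fit.k, fit.n if n is None else n
    else:
        loglik = float(loglik_or_fit)
        if k is None or n is None:
            raise TypeError("aicc(loglik, k, n) requires k and n")
    if n <= k + 1:
        raise ValueError(f"AICc undefined: need n > k + 1 (n={n}, k={k})")
    aic = -2.0 * loglik + 2.0 * k
    return aic + 2.0 * k * (k + 1) / (n - k - 1)


# ---------------------------------------------------------------------------
# all-subsets enumeration, retention, model averaging


@dataclass
class ModelSet:
    """All candidate fits with dAICc, retention flags and Akaike weights."""

    fits: list[ModelFit]
    delta: np.ndarray
    retained: np.ndarray  # boolean
    weights: np.ndarray  # NaN for non-retained; sums to 1 over retained
    delta_max: float
    soft_margin: float

    @property
    def best(self) -> ModelFit:
        return self.fits[int(np.argmin(self.delta))]

    def retained_fits(self) -> list[ModelFit]:
        return [f for f, r in zip(self.fits, self.retained) if r]

    def to_frame(self) -> pd.DataFrame:
        """Model table: one row per candidate (AICc, betas, P values, fit)."""
        rows = []
        for fit, d, r, w in zip(self.fits, self.delta, self.retained, self.weights):
            row = {
                "model": "+".join(fit.predictors) or "intercept",
                "AICc": fit.aicc,
                "dAICc": d,
                "retained": bool(r),
                "weight": w,
                "lambda": fit.lambda_,
                "R2": fit.r2,
                "adjR2": fit.adj_r2,
            }
            for pred in PREDICTORS:
                row[f"beta_{pred}"] = fit.beta.get(pred, np.nan)
                row[f"P_{pred}"] = fit.pvalues.get(pred, np.nan)
            rows.append(row)
        return pd.DataFrame(rows).sort_values("AICc").reset_index(drop=True)


def enumerate_and_retain(
    design: DesignMatrix,
    tree=None,
    delta_max: float = 2.0,
    soft_margin: float = 0.2,
    *,
    vcv: np.ndarray | None = None,
) -> ModelSet:
    """Fit all 16 predictor subsets and retain the near-minimum-AICc set.

    Retention keeps every model with ``dAICc <= delta_max + soft_margin``;
    the default soft margin of 0.2 admits the just-over-the-line models
    (dAICc 2.01 and 2.14) that the analysis deliberately includes.  ``f^2``
    is allowed without ``f``.  Akaike weights are computed over the
    retained set only.
    """
    subsets = []
    for r in range(len(PREDICTORS) + 1):
        subsets.extend(itertools.combinations(PREDICTORS, r))
    fits = [fit_pgls(design, tree, included=sub, vcv=vcv) for sub in subsets]
    aiccs = np.array([f.aicc for f in fits])
    delta = aiccs - aiccs.min()
    retained = delta <= (delta_max + soft_margin)
    raw_w = np.exp(-0.5 * delta[retained])
    weights = np.full(len(fits), np.nan)
    weights[retained] = raw_w / raw_w.sum()
    return ModelSet(
        fits=fits,
        delta=delta,
        retained=retained,
        weights=weights,
        delta_max=delta_max,
        soft_margin=soft_margin,
    )


@dataclass
class AveragedCoefficients:
    """AICc-weight-averaged standardised coefficients.

    Averaging is conditional: for each predictor the Akaike weights are
    renormalised over the retained models that contain it.  A predictor in
    no retained model is *absent* (not zero).  ``se`` is the unconditional
    (model-selection-aware) standard error.  Bootstrap percentile intervals
    are attached by :func:`bootstrap_cis`.
    """

    coef: dict[str, float]
    se: dict[str, float]
    intervals: dict[str, dict[int, tuple[float, float]]] | None = None
    n_boot: int = 0
    n_absent: dict[str, int] = field(default_factory=dict)


def model_average(modelset: ModelSet) -> AveragedCoefficients:
    retained = modelset.retained_fits()
    if not retained:
        raise ValueError("no retained models to average")
    weights = modelset.weights[modelset.retained]
    coef: dict[str, float] = {}
    se: dict[str, float] = {}
    for pred in PREDICTORS:
        idx = [i for i, fit in enumerate(retained) if pred in fit.predictors]
        if not idx:
            continue  # absent, reported as missing rather than zero
        w = weights[idx] / weights[idx].sum()
        betas = np.array([retained[i].beta[pred] for i in idx])
        ses = np.array([retained[i].se[pred] for i in idx])
        b_bar = float(w @ betas)
        coef[pred] = b_bar
        se[pred] = float(np.sqrt(w @ (ses**2 + (betas - b_bar) ** 2)))
    return AveragedCoefficients(coef=coef, se=se)


_INTERVALS = {50: (25.0, 75.0), 75: (12.5, 87.5), 95: (2.5, 97.5)}


def bootstrap_cis(
    records: Iterable[morphometrics.SpeciesRecord],
    gait: str,
    tree=None,
    n_boot: int = 4999,
    seed: int | None = None,
    *,
    delta_max: float = 2.0,
    soft_margin: float = 0.2,
    refit_selection: bool = True,
    viscosity: float = 8.8e-7,
    elliptical: str = "quadratic",
) -> AveragedCoefficients:
    """Percentile bootstrap of the model-averaged coefficients.

    Species rows are resampled with replacement; each pseudo-sample is
    re-standardised and (by default) re-run through the full all-subsets
    enumeration before averaging, so the intervals reflect model-selection
    uncertainty as well as sampling noise.  ``refit_selection=False``
    instead freezes the model set retained on the original data.  Intervals
    are simple percentiles at the 50/75/95% levels.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    recs = [r for r in records if r.gait == gait]
    design = build_design(recs, gait, viscosity=viscosity, elliptical=elliptical)
    base_vcv = None
    if tree is not None:
        _, base_vcv = trees.vcv_matrix(tree, labels=design.species)
    full_set = enumerate_and_retain(design, tree, delta_max, soft_margin, vcv=base_vcv)
    result = model_average(full_set)
    frozen = [f.predictors for f in full_set.retained_fits()]

    rng = np.random.default_rng(seed)
    draws: dict[str, list[float]] = {p: [] for p in PREDICTORS}
    absent = {p: 0 for p in PREDICTORS}
    n = len(recs)
    for _ in range(n_boot):
        ix = rng.integers(0, n, size=n)
        sample = [recs[i] for i in ix]
        try:
            d = build_design(sample, gait, viscosity=viscosity, elliptical=elliptical)
        except ValueError:
            for p in PREDICTORS:
                absent[p] += 1
            continue
        v = base_vcv[np.ix_(ix, ix)] if base_vcv is not None else None
        if refit_selection:
            ms = enumerate_and_retain(d, None, delta_max, soft_margin, vcv=v)
            avg = model_average(ms)
        else:
            fits = [fit_pgls(d, None, included=sub, vcv=v) for sub in frozen]
            aiccs = np.array([f.aicc for f in fits])
            delta = aiccs - aiccs.min()
            w = np.exp(-0.5 * delta)
            ms = ModelSet(fits, delta, np.ones(len(fits), bool), w / w.sum(),
                          delta_max, soft_margin)
            avg = model_average(ms)
        for p in PREDICTORS:
            if p in avg.coef:
                draws[p].append(avg.coef[p])
            else:
                absent[p] += 1

    intervals: dict[str, dict[int, tuple[float, float]]] = {}
    for p in PREDICTORS:
        if not draws[p]:
            continue
        arr = np.asarray(draws[p])
        intervals[p] = {
            level: tuple(np.percentile(arr, q)) for level, q in _INTERVALS.items()
        }
    result.intervals = intervals
    result.n_boot = n_boot
    result.n_absent = absent
    return result


# ---------------------------------------------------------------------------
# mechanistic-model goodness of fit


def adjusted_umax(
    records: Iterable[morphometrics.SpeciesRecord], gait: str
) -> pd.Series:
    """U_max adjusted for body size and fin shape, on the raw speed scale.

    Residuals of the OLS regression of U_max on ``M^(1/3)`` and ``AR``,
    re-anchored at the grand mean of U_max.  This removes the allometric
    and fin contributions before the mechanistic fineness model is scored.
    """
    recs = [r for r in records if r.gait == gait]
    if len(recs) < 4:
        raise ValueError(f"need at least 4 records of gait {gait!r}")
    u = np.array([r.umax for r in recs])
    X = np.column_stack(
        [np.ones(len(recs)), np.array([r.mass for r in recs]) ** (1.0 / 3.0),
         np.array([r.fin_aspect_ratio for r in recs])]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("adjustment design is rank deficient (constant mass or AR?)")
    beta, *_ = np.linalg.lstsq(X, u, rcond=None)
    resid = u - X @ beta
    return pd.Series(resid + u.mean(), index=[r.species for r in recs], name="adjusted_umax")


def mechanistic_r2(adjusted: np.ndarray, modeled: np.ndarray) -> float:
    """Fraction of adjusted-U_max variance explained by model predictions.

    The model curve is re-centred to the mean of the adjusted speeds (only
    its shape is scored, not its elevation):
    ``R^2 = 1 - sum((adj - modeled_c)^2) / sum((adj - mean(adj))^2)``.
    Can be negative when the model fits worse than a constant.
    """
    a = np.asarray(adjusted, float)
    m = np.asarray(modeled, float)
    if a.shape != m.shape:
        raise ValueError("adjusted and modeled speeds must be paired")
    mc = m - m.mean() + a.mean()
    tss = float(np.sum((a - a.mean()) ** 2))
    if tss == 0.0:
        raise ValueError("adjusted speeds have zero variance")
    return 1.0 - float(np.sum((a - mc) ** 2)) / tss


@dataclass(frozen=True)
class PermutationResult:
    p_value: float
    observed_r2: float
    n_perm: int


def permutation_test(
    adjusted: np.ndarray,
    modeled: np.ndarray,
    n_perm: int = 4999,
    seed: int | None = None,
) -> PermutationResult:
    """Permutation P for the mechanistic R^2 under no fineness-speed link.

    Adjusted speeds are permuted across species ``n_perm`` times; with g
    the number of permuted R^2 at least as large as the observed one,
    ``P = (g + 1) / (n_perm + 1)`` (guaranteed positive).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    a = np.asarray(adjusted, float)
    observed = mechanistic_r2(a, modeled)
    g = 0
    for _ in range(n_perm):
        if mechanistic_r2(rng.permutation(a), modeled) >= observed:
            g += 1
    return PermutationResult(p_value=(g + 1) / (n_perm + 1), observed_r2=observed, n_perm=n_perm)


# ---------------------------------------------------------------------------
# independent contrasts


@dataclass
class PicCorrelations:
    """Raw and phylogenetically independent correlations among traits."""

    raw: pd.DataFrame
    pic: pd.DataFrame
    n_contrasts: int

    def combined(self) -> pd.DataFrame:
        """Raw correlations below the diagonal, PIC above (survey layout)."""
        out = self.raw.copy()
        vars_ = list(out.columns)
        for i, a in enumerate(vars_):
            for j, b in enumerate(vars_):
                if j > i:
                    out.iloc[i, j] = self.pic.iloc[i, j]
                elif i == j:
                    out.iloc[i, j] = np.nan
        return out


def pic_correlations(
    records: Iterable[morphometrics.SpeciesRecord],
    tree,
    variables: Sequence[str] = ("f", "AR", "logM", "logU"),
    *,
    viscosity: float = 8.8e-7,
    elliptical: str = "quadratic",
) -> PicCorrelations:
    """Trait correlations from raw data and from independent contrasts.

    PIC correlations are Pearson correlations through the origin of the
    standardised contrasts.  With fewer than two contrasts (n = 2 species)
    the PIC correlation is undefined and reported as NaN.
    """
    recs = list(records)
    table = morphometrics.derive_table(recs, viscosity=viscosity, elliptical=elliptical)
    table = table.rename(columns={"fineness": "f", "fin_ar": "AR"})
    missing = [v for v in variables if v not in table.columns]
    if missing:
        raise ValueError(f"unknown variables: {missing}")
    df = table[list(variables)]
    raw = df.corr()

    contrasts = {
        v: trees.pic_contrasts(tree, df[v].to_dict()) for v in variables
    }
    k = len(variables)
    pic = np.full((k, k), np.nan)
    n_con = len(next(iter(contrasts.values())))
    for i, a in enumerate(variables):
        pic[i, i] = 1.0
        for j in range(i + 1, k):
            b = variables[j]
            ca, cb = contrasts[a], contrasts[b]
            if len(ca) < 2:
                continue
            denom = math.sqrt(float(ca @ ca) * float(cb @ cb))
            if denom == 0.0:
                continue
            pic[i, j] = pic[j, i] = float(ca @ cb) / denom
    return PicCorrelations(
        raw=raw,
        pic=pd.DataFrame(pic, index=list(variables), columns=list(variables)),
        n_contrasts=n_con,
    )


# ---------------------------------------------------------------------------
# quadratic optimum on the raw fineness scale


@dataclass(frozen=True)
class VertexResult:
    f_vertex: float  # raw fineness at the stationary point
    is_maximum: bool  # quadratic coefficient < 0
    effect_at_fmin: float  # combined standardised linear effect of f at f_min
    effect_at_fmax: float


def quadratic_vertex(avg: AveragedCoefficients, meta: Mapping[str, float]) -> VertexResult:
    """Raw-scale fineness at the vertex of the averaged quadratic.

    With standardised coefficients ``b1`` (for ``(f - c)/s_f``) and ``b2``
    (for the standardised centred square), the fitted response is
    stationary at ``f = c - b1 s_q / (2 b2 s_f)``.  Also reports the
    combined standardised linear effect of fineness,
    ``b1 + 2 b2 (s_f / s_q)(f0 - c)``, at the sample's minimum and maximum
    fineness.  ``is_maximum`` is False when the quadratic opens upward (no
    interior maximum).
    """
    if "f" not in avg.coef or "f2" not in avg.coef:
        raise ValueError("vertex requires both the linear and quadratic fineness coefficients")
    b1, b2 = avg.coef["f"], avg.coef["f2"]
    if b2 == 0.0:
        raise ValueError("quadratic coefficient is zero; no vertex")
    c, s_f, s_q = meta["f_mean"], meta["f_sd"], meta["f2_sd"]

    f_vertex = c - b1 * s_q / (2.0 * b2 * s_f)

    def effect(f0: float) -> float:
        return b1 + 2.0 * b2 * (s_f / s_q) * (f0 - c)

    return VertexResult(
        f_vertex=float(f_vertex),
        is_maximum=b2 < 0.0,
        effect_at_fmin=float(effect(meta["f_min"])),
        effect_at_fmax=float(effect(meta["f_max"])),
    )
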