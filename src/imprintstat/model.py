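"""Batch standardization and the preference-score regression.

The design is hierarchical: chicks are nested in hatch batches, and batches
differ in overall protein level (rearing cohort, gel run). Two tools deal
with this structure:

* :class:`BatchStandardizer` removes the estimated batch effect
  (batch mean - overall mean) from each value, yielding the *standardized
  relative amount* used for summaries, variance tests and plots.

* :class:`PreferenceRegression` fits, by restricted maximum likelihood, a
  linear mixed model of protein amount on preference score with a random
  batch intercept:

      y_ij = a + b * score_ij + u_j + e_ij,   u_j ~ N(0, s_b^2), e ~ N(0, s^2)

  With one observation per chick, a chick-within-batch random term is not
  identifiable and is absorbed into the residual; replicate rows re-enable
  it as a variance component. Slope inference uses t with
  df = n_chicks - n_batches - 1.

The within-batch correlation between amount and score reported alongside
the fit is derived from the slope t-statistic, r = sign(b) * sqrt(t^2 /
(t^2 + df)), so the (r, df, p) triple is internally consistent with the
slope test. Predicted levels at chosen scores (50 = no learning, the
maximum attained score = strong learning) carry delta-method standard
errors from the fixed-effects covariance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin

from .exceptions import InsufficientDataError, UnidentifiableModelError

log = logging.getLogger(__name__)

# Sum of squared residuals below this fraction of total signal marks an
# exactly-deterministic (noiseless) relationship; variances are then pinned
# to zero rather than estimated.
_NOISELESS_RTOL = 1e-24


@dataclass(frozen=True)
class GroupSummary:
    """Mean, SEM, df (= n - 1), sample variance and n for one group."""

    mean: float
    sem: float
    df: int
    variance: float
    n: int


@dataclass(frozen=True)
class ModelFit:
    """Fixed effects, their covariance, and variance components of one fit."""

    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    cov_intercept_slope: float
    df_slope: int
    residual_variance: float
    df_residual: int
    var_batch: float
    var_chick: float
    n_obs: int
    n_batches: int


@dataclass(frozen=True)
class TermF:
    """Marginal F test for one fixed term (numerator df is always 1)."""

    name: str
    coef: float
    se: float
    f: float
    df_num: int
    df_den: int
    p: float


@dataclass(frozen=True)
class CovariateModelFit:
    """Preference regression with training/testing approach covariates."""

    fit: ModelFit
    terms: tuple[TermF, ...]

    def term(self, name: str) -> TermF:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)


@dataclass(frozen=True)
class Prediction:
    """A fitted level at one preference score, with its SE and df."""

    estimate: float
    se: float
    df: int


class BatchStandardizer(BaseEstimator, TransformerMixin):
    """Remove the estimated batch effect from per-chick values.

    ``fit`` learns one offset per batch, ``batch mean - overall mean``,
    from the values it is given (all chicks by default; pass a trained-only
    subset to change the scope). ``transform`` subtracts the offset of each
    value's batch, leaving the overall mean of the fitting set unchanged
    and the per-batch means of the fitting set all equal to it.
    """

    def fit(self, values, batch_ids, y=None):
        values = np.asarray(values, dtype=float)
        batch_ids = np.asarray(batch_ids)
        if values.size == 0:
            raise InsufficientDataError("no values to standardize")
        if values.shape != batch_ids.shape:
            raise ValueError("values and batch_ids must have the same length")
        self.overall_mean_ = float(values.mean())
        s = pd.Series(values).groupby(pd.Series(batch_ids)).mean()
        self.offsets_ = {b: float(m - self.overall_mean_) for b, m in s.items()}
        return self

    def transform(self, values, batch_ids):
        values = np.asarray(values, dtype=float)
        batch_ids = np.asarray(batch_ids)
        try:
            offs = np.array([self.offsets_[b] for b in batch_ids])
        except KeyError as e:
            raise KeyError(f"batch {e.args[0]!r} was not seen during fit") from None
        return values - offs

    def fit_transform(self, values, batch_ids, y=None):
        return self.fit(values, batch_ids).transform(values, batch_ids)


def standardize_by_batch(values, batch_ids):
    """One-shot batch standardization: value - (batch mean - overall mean)."""
    return BatchStandardizer().fit_transform(values, batch_ids)


def _profiled_variance_fit(y, X, groups, *, reml: bool = True):
    """REML (or ML) fit of y = X b + u_batch + e by profiling the likelihood.

    With V = sigma2 * (I + lam * Z Z'), both b and sigma2 have closed GLS
    forms given the variance ratio lam = var_batch / sigma2, so the fit
    reduces to a 1-d search in lam. Block structure makes every evaluation
    O(n p^2): within batch j of size m_j, W^-1 = I - lam/(1 + lam m_j) J.

    Returns (beta, cov_beta, sigma2, var_batch).
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, p = X.shape
    _, inv = np.unique(groups, return_inverse=True)
    m = np.bincount(inv).astype(float)

    def pieces(lam):
        shrink = (lam / (1.0 + lam * m))[inv]

        def w_inv(M):
            sums = np.zeros((len(m),) + M.shape[1:])
            np.add.at(sums, inv, M)
            sh = shrink[:, None] if M.ndim == 2 else shrink
            return M - sh * sums[inv]

        XtWX = X.T @ w_inv(X)
        beta = np.linalg.solve(XtWX, X.T @ w_inv(y))
        r = y - X @ beta
        q = float(r @ w_inv(r))
        logdet_w = float(np.sum(np.log1p(lam * m)))
        return beta, XtWX, q, logdet_w

    def neg2_profile(lam):
        _, XtWX, q, logdet_w = pieces(lam)
        q = max(q, 1e-300)
        if reml:
            sign, logdet_a = np.linalg.slogdet(XtWX)
            return (n - p) * np.log(q) + logdet_w + logdet_a
        return n * np.log(q) + logdet_w

    grid = np.concatenate([[0.0], np.logspace(-6, 4, 51)])
    vals = [neg2_profile(l) for l in grid]
    i = int(np.argmin(vals))
    if 0 < i < len(grid) - 1:
        from scipy.optimize import minimize_scalar

        res = minimize_scalar(
            neg2_profile, bounds=(grid[i - 1], grid[i + 1]), method="bounded",
            options={"xatol": 1e-8},
        )
        lam = float(res.x) if res.fun <= vals[i] else float(grid[i])
    else:
        lam = float(grid[i])
    beta, XtWX, q, _ = pieces(lam)
    sigma2 = q / (n - p) if reml else q / n
    cov = sigma2 * np.linalg.inv(XtWX)
    return beta, cov, float(sigma2), float(lam * sigma2)


def _gls_fe_cov(exog, groups, chick_ids, sigma2, var_batch, var_chick) -> np.ndarray:
    """Fixed-effects covariance (X' V^-1 X)^-1 for the nested random-intercept model.

    V = sigma2 * I + var_batch * [same batch] + var_chick * [same chick].
    """
    n = exog.shape[0]
    groups = np.asarray(groups)
    chick_ids = np.asarray(chick_ids)
    V = sigma2 * np.eye(n)
    V += var_batch * (groups[:, None] == groups[None, :])
    if var_chick > 0:
        V += var_chick * (chick_ids[:, None] == chick_ids[None, :])
    xtvx = exog.T @ np.linalg.solve(V, exog)
    return np.linalg.inv(xtvx)


def _as_scores(X) -> np.ndarray:
    x = np.asarray(X, dtype=float)
    if x.ndim == 2 and x.shape[1] == 1:
        x = x[:, 0]
    if x.ndim != 1:
        raise ValueError("X must be a 1-d array of preference scores (or a single column)")
    return x


class PreferenceRegression(BaseEstimator, RegressorMixin):
    """REML mixed-effects regression of protein amount on preference score.

    Parameters
    ----------
    reml : bool, default True
        Restricted maximum likelihood (the standard choice for variance
        components); ``False`` for plain maximum likelihood.

    Attributes (after ``fit``)
    --------------------------
    intercept_, slope_ : float
        Fixed effects (amount at score 0; amount per score unit).
    se_intercept_, se_slope_, cov_intercept_slope_ : float
        Fixed-effects standard errors and covariance.
    df_slope_ : int
        ``n_chicks - n_batches - 1``; reference df for slope inference.
    residual_variance_, var_batch_, var_chick_ : float
        Variance components (chick variance is 0 unless replicate rows
        re-enable the chick-within-batch term).
    result_ : ModelFit
        All of the above in one immutable record.
    """

    def __init__(self, reml: bool = True):
        self.reml = reml

    def fit(self, X, y, groups, chick_ids=None):
        """Fit amounts ``y`` on scores ``X`` with random batch intercepts ``groups``.

        ``chick_ids`` is only needed when chicks contribute replicate rows;
        with one row per chick the chick random term is dropped.
        """
        scores = _as_scores(X)
        y = np.asarray(y, dtype=float)
        groups = np.asarray(groups)
        n = y.size
        if not (scores.size == n == groups.size):
            raise ValueError("X, y and groups must have equal length")
        chick_ids = np.asarray(chick_ids) if chick_ids is not None else np.arange(n)
        n_chicks = len(np.unique(chick_ids))
        n_batches = len(np.unique(groups))
        if n_chicks < 3:
            raise InsufficientDataError(f"need >=3 trained chicks, got {n_chicks}")
        if np.unique(scores).size < 2:
            raise UnidentifiableModelError("all preference scores identical; slope unidentifiable")
        df_slope = n_chicks - n_batches - 1
        if df_slope < 1:
            raise InsufficientDataError(
                f"df = n_chicks - n_batches - 1 = {df_slope} < 1; design too sparse"
            )
        exog = np.column_stack([np.ones(n), scores])

        beta, cov, sigma2, var_batch, var_chick = self._estimate(
            y, exog, scores, groups, chick_ids, n_batches
        )
        self.intercept_, self.slope_ = float(beta[0]), float(beta[1])
        self.se_intercept_ = float(np.sqrt(max(cov[0, 0], 0.0)))
        self.se_slope_ = float(np.sqrt(max(cov[1, 1], 0.0)))
        self.cov_intercept_slope_ = float(cov[0, 1])
        self.df_slope_ = int(df_slope)
        self.residual_variance_ = float(max(sigma2, 0.0))
        self.var_batch_ = float(max(var_batch, 0.0))
        self.var_chick_ = float(max(var_chick, 0.0))
        self.n_obs_ = int(n)
        self.n_batches_ = int(n_batches)
        self.result_ = ModelFit(
            intercept=self.intercept_,
            slope=self.slope_,
            se_intercept=self.se_intercept_,
            se_slope=self.se_slope_,
            cov_intercept_slope=self.cov_intercept_slope_,
            df_slope=self.df_slope_,
            residual_variance=self.residual_variance_,
            df_residual=self.df_slope_,
            var_batch=self.var_batch_,
            var_chick=self.var_chick_,
            n_obs=self.n_obs_,
            n_batches=self.n_batches_,
        )
        return self

    def _estimate(self, y, exog, scores, groups, chick_ids, n_batches):
        # Pooled OLS first: it is the exact answer for a single batch and
        # detects noiseless data, where likelihood optimization is
        # ill-posed and every variance is genuinely zero.
        beta_ols, ssr, *_ = np.linalg.lstsq(exog, y, rcond=None)
        ssr = float(ssr[0]) if np.size(ssr) else float(np.sum((y - exog @ beta_ols) ** 2))
        scale_ref = max(float(np.mean(y**2)), 1.0)
        xtx_inv = np.linalg.inv(exog.T @ exog)
        n, k = exog.shape
        if ssr <= _NOISELESS_RTOL * scale_ref * n:
            log.info("residuals numerically zero; variance components pinned at 0")
            return beta_ols, np.zeros((k, k)), 0.0, 0.0, 0.0
        if n_batches == 1:
            # One batch: the random intercept is confounded with the fixed
            # intercept; the mixed fit degenerates to OLS with var_batch 0.
            sigma2 = ssr / (n - k)
            return beta_ols, sigma2 * xtx_inv, sigma2, 0.0, 0.0
        replicated = len(np.unique(chick_ids)) < len(chick_ids)
        if not replicated:
            beta, cov, sigma2, var_batch = _profiled_variance_fit(
                y, exog, groups, reml=self.reml
            )
            var_chick = 0.0
        else:
            # Replicate filter rows: chick-within-batch variance component,
            # delegated to the general mixed-model machinery.
            from statsmodels.regression.mixed_linear_model import MixedLM

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                df = pd.DataFrame(
                    {"y": y, "batch": groups, "chick": chick_ids}
                ).join(pd.DataFrame(exog[:, 1:], columns=[f"x{i}" for i in range(1, k)]))
                fixed = "y ~ " + " + ".join(f"x{i}" for i in range(1, k))
                model = MixedLM.from_formula(
                    fixed,
                    groups="batch",
                    re_formula="1",
                    vc_formula={"chick": "0 + C(chick)"},
                    data=df,
                )
                res = model.fit(reml=self.reml)
            var_chick = float(res.vcomp[0])
            beta = np.asarray(res.fe_params, dtype=float)
            sigma2 = float(res.scale)
            var_batch = float(np.asarray(res.cov_re)[0, 0])
            # GLS covariance at the fitted components; the optimizer's
            # inverse-Hessian loses positive-definiteness at the boundary.
            cov = _gls_fe_cov(exog, groups, chick_ids, sigma2, var_batch, var_chick)
        if var_batch <= 1e-12 or sigma2 <= 1e-12:
            log.info("variance component pinned at boundary (batch=%.3g, resid=%.3g)",
                     var_batch, sigma2)
        return beta, cov, sigma2, var_batch, var_chick

    def predict(self, X):
        """Fitted amount at the given preference scores."""
        return self.intercept_ + self.slope_ * _as_scores(X)

    def predict_at_score(self, score: float) -> Prediction:
        """Level at one score with delta-method SE; see :func:`predict_at_score`."""
        return predict_at_score(self.result_, score)


def fit_preference_regression(amounts, scores, batch_ids, *, reml: bool = True,
                              chick_ids=None) -> ModelFit:
    """Functional wrapper over :class:`PreferenceRegression`.

    Returns the :class:`ModelFit` record for ``amounts ~ score`` with a
    random batch intercept.
    """
    est = PreferenceRegression(reml=reml).fit(scores, amounts, groups=batch_ids,
                                              chick_ids=chick_ids)
    return est.result_


def correlation_from_fit(fit: ModelFit) -> tuple[float, int, float]:
    """Within-batch correlation implied by the mixed-model slope test.

    ``t = slope / se_slope``; ``r = sign(slope) * sqrt(t^2 / (t^2 + df))``;
    two-tailed p from t with ``df_slope`` degrees of freedom. The p-value
    is identical to the slope's t-test p-value by construction.
    """
    df = fit.df_slope
    if fit.se_slope == 0:
        log.warning("zero slope SE: correlation reported as +/-1 with p = 0")
        r = float(np.sign(fit.slope)) if fit.slope != 0 else 0.0
        return r, df, 0.0 if fit.slope != 0 else 1.0
    t = fit.slope / fit.se_slope
    r = float(np.sign(t) * np.sqrt(t**2 / (t**2 + df)))
    p = float(2 * stats.t.sf(abs(t), df))
    return r, df, p


def p_from_correlation(r: float, df: int) -> float:
    """Two-tailed p for a correlation r with the given df (t transform)."""
    if abs(r) >= 1:
        return 0.0
    t = abs(r) * np.sqrt(df / (1 - r**2))
    return float(2 * stats.t.sf(t, df))


def predict_at_score(fit: ModelFit, score: float) -> Prediction:
    """Regression level at a preference score, with delta-method SE.

    ``se^2 = se_a^2 + score^2 * se_b^2 + 2 * score * cov(a, b)`` — the
    quadratic form of the fixed-effects covariance in (1, score).
    """
    est = fit.intercept + fit.slope * score
    var = (
        fit.se_intercept**2
        + score**2 * fit.se_slope**2
        + 2 * score * fit.cov_intercept_slope
    )
    return Prediction(estimate=float(est), se=float(np.sqrt(max(var, 0.0))), df=fit.df_slope)


def untrained_summary(values) -> GroupSummary:
    """Mean / SEM / df / variance of the (standardized) untrained group."""
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise InsufficientDataError(f"need >=2 untrained chicks, got {n}")
    var = float(values.var(ddof=1))
    return GroupSummary(
        mean=float(values.mean()),
        sem=float(np.sqrt(var / n)),
        df=n - 1,
        variance=var,
        n=n,
    )


def fit_with_approach_covariates(
    amounts, scores, approach_training, approach_testing, batch_ids, *, reml: bool = True
) -> CovariateModelFit:
    """Preference regression with training and testing approach as covariates.

    Same random structure as the plain fit. Each fixed term gets a marginal
    Wald F (numerator df 1, denominator df = n_chicks - n_batches - 3).
    """
    scores = np.asarray(scores, dtype=float)
    a_tr = np.asarray(approach_training, dtype=float)
    a_te = np.asarray(approach_testing, dtype=float)
    y = np.asarray(amounts, dtype=float)
    groups = np.asarray(batch_ids)
    n = y.size
    if not (scores.size == a_tr.size == a_te.size == n == groups.size):
        raise ValueError("all inputs must have equal length")
    if np.any(np.isnan(a_tr)) or np.any(np.isnan(a_te)):
        raise InsufficientDataError("approach covariates missing for some chicks")
    n_batches = len(np.unique(groups))
    names = ("preference_score", "approach_training", "approach_testing")
    columns = {"preference_score": scores, "approach_training": a_tr,
               "approach_testing": a_te}
    # A constant covariate carries no information and would make the design
    # singular; it is dropped (F = 0) and the model reduces to the nested one.
    active = [nm for nm in names if np.ptp(columns[nm]) > 0]
    if "preference_score" not in active:
        raise UnidentifiableModelError("all preference scores identical; slope unidentifiable")
    df_den = n - n_batches - len(active)
    if df_den < 1:
        raise InsufficientDataError(
            f"denominator df {df_den} < 1 with {len(active)} fixed terms"
        )
    exog = np.column_stack([np.ones(n)] + [columns[nm] for nm in active])
    cond = np.linalg.cond(exog)
    if cond > 1e8:
        log.warning("covariate design nearly collinear (condition number %.3g)", cond)
    est = PreferenceRegression(reml=reml)
    beta, cov, sigma2, var_batch, var_chick = est._estimate(
        y, exog, scores, groups, np.arange(n), n_batches
    )
    terms = []
    for name in names:
        if name not in active:
            terms.append(TermF(name=name, coef=0.0, se=0.0, f=0.0,
                               df_num=1, df_den=df_den, p=1.0))
            continue
        j = 1 + active.index(name)
        se = float(np.sqrt(max(cov[j, j], 0.0)))
        f = (beta[j] / se) ** 2 if se > 0 else np.inf
        p = float(stats.f.sf(f, 1, df_den)) if np.isfinite(f) else 0.0
        terms.append(TermF(name=name, coef=float(beta[j]), se=se, f=float(f),
                           df_num=1, df_den=df_den, p=p))
    base = ModelFit(
        intercept=float(beta[0]),
        slope=float(beta[1]),
        se_intercept=float(np.sqrt(max(cov[0, 0], 0.0))),
        se_slope=float(np.sqrt(max(cov[1, 1], 0.0))),
        cov_intercept_slope=float(cov[0, 1]),
        df_slope=df_den,
        residual_variance=float(max(sigma2, 0.0)),
        df_residual=df_den,
        var_batch=float(max(var_batch, 0.0)),
        var_chick=float(max(var_chick, 0.0)),
        n_obs=n,
        n_batches=n_batches,
    )
    return CovariateModelFit(fit=base, terms=tuple(terms))
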