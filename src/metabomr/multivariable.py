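"""Multivariable two-sample MR: direct effects adjusting for a covariate.

The typical use here is re-estimating each metabolic exposure's effect on
disease while including waist circumference (an abdominal-adiposity proxy and
candidate confounder) as a second exposure.  Estimators: MVMR-IVW (weighted
multiple regression of outcome on exposure betas through the origin),
MVMR-Egger (adds an orientation-dependent intercept as a pleiotropy test),
the multivariable median (weighted L1 regression, robust to a minority of
invalid variants) and MVMR-Lasso (per-variant pleiotropy intercepts with an
L1 penalty and a heterogeneity stopping rule).  Conditional F-statistics
quantify instrument strength for each exposure given the others.

Cross-exposure GWAS error covariances are treated as zero throughout (the
conditional F machinery with full covariance is out of scope; a documented
limitation when exposures share one GWAS sample).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from scipy.optimize import linprog

from .exceptions import (
    CollinearityError,
    InputError,
    InsufficientInstrumentsError,
    NoValidSubsetError,
)
from .sumstats import HarmonizedSet
from .univariable import Z95


@dataclass
class MVHarmonizedSet:
    """Outcome effects with a k x p matrix of exposure effects, one shared
    effect-allele orientation per variant."""

    variant_ids: list[str]
    exposure_names: list[str]
    beta_x: np.ndarray   # (k, p)
    se_x: np.ndarray     # (k, p)
    beta_y: np.ndarray   # (k,)
    se_y: np.ndarray     # (k,)
    n_exposures: np.ndarray  # (p,)
    n_outcome: int
    outcome_name: str = "outcome"

    def __post_init__(self) -> None:
        self.beta_x = np.atleast_2d(np.asarray(self.beta_x, float))
        self.se_x = np.atleast_2d(np.asarray(self.se_x, float))
        self.beta_y = np.asarray(self.beta_y, float)
        self.se_y = np.asarray(self.se_y, float)
        self.n_exposures = np.asarray(self.n_exposures, int)
        k, p = self.beta_x.shape
        if len(self.variant_ids) != k or len(self.exposure_names) != p:
            raise InputError("shape mismatch in MVHarmonizedSet")

    @property
    def k(self) -> int:
        return self.beta_x.shape[0]

    @property
    def p(self) -> int:
        return self.beta_x.shape[1]

    def subset(self, idx) -> "MVHarmonizedSet":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return replace(
            self,
            variant_ids=[self.variant_ids[i] for i in idx],
            beta_x=self.beta_x[idx], se_x=self.se_x[idx],
            beta_y=self.beta_y[idx], se_y=self.se_y[idx])


def combine_harmonized(harmonized: list[HarmonizedSet]) -> MVHarmonizedSet:
    """Stack univariably harmonized sets (same outcome) into an MVMR input.

    Variants present in every set are kept, in the first set's order.  Each
    set was aligned to its own per-variant effect allele; the shared outcome
    effect identifies the orientation, so later sets whose outcome beta is
    the negation of the first set's are sign-flipped onto the reference
    orientation.
    """
    if len(harmonized) < 2:
        raise InputError("need at least two exposures to combine")
    ref = harmonized[0]
    common = [v for v in ref.variant_ids
              if all(v in h.variant_ids for h in harmonized[1:])]
    if len(common) == 0:
        raise InputError("no variants shared across all exposures")
    idx0 = [ref.variant_ids.index(v) for v in common]
    by = ref.beta_y[idx0]
    cols_b, cols_s = [ref.beta_x[idx0]], [ref.se_x[idx0]]
    for h in harmonized[1:]:
        idx = [h.variant_ids.index(v) for v in common]
        b, s = h.beta_x[idx], h.se_x[idx]
        by_h = h.beta_y[idx]
        agree = np.isclose(by_h, by)
        disagree = np.isclose(by_h, -by)
        if not np.all(agree | disagree):
            raise InputError("outcome effects inconsistent across exposures")
        b = np.where(agree, b, -b)
        cols_b.append(b)
        cols_s.append(s)
    return MVHarmonizedSet(
        variant_ids=common,
        exposure_names=[h.exposure_name for h in harmonized],
        beta_x=np.column_stack(cols_b), se_x=np.column_stack(cols_s),
        beta_y=by, se_y=ref.se_y[idx0],
        n_exposures=np.array([h.n_exposure for h in harmonized]),
        n_outcome=ref.n_outcome, outcome_name=ref.outcome_name)


@dataclass
class MVMREstimate:
    """Per-exposure direct-effect estimates from one MVMR method."""

    method: str
    exposure_names: list[str]
    estimates: np.ndarray
    ses: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    pvals: np.ndarray
    n_variants: int
    Q: float | None = None
    Q_pval: float | None = None
    conditional_F: np.ndarray | None = None
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_pval: float | None = None
    retained_variant_ids: list[str] | None = None

    def exposure(self, name: str) -> dict:
        i = self.exposure_names.index(name)
        return {"estimate": float(self.estimates[i]), "se": float(self.ses[i]),
                "ci_low": float(self.ci_low[i]), "ci_high": float(self.ci_high[i]),
                "pval": float(self.pvals[i])}


def _check_rank(X: np.ndarray) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise CollinearityError("rank-deficient exposure design matrix")


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray, df_resid: int):
    """Weighted least squares with SE scale floored at 1 (returns coef, se,
    weighted RSS)."""
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    rss = float(np.sum(w * (y - X @ coef) ** 2))
    scale = max(1.0, np.sqrt(rss / df_resid)) if df_resid > 0 else 1.0
    cov = np.linalg.inv(X.T @ (X * w[:, None]))
    se = np.sqrt(np.diag(cov)) * scale
    return coef, se, rss


def mvmr_ivw(h: MVHarmonizedSet) -> MVMREstimate:
    """MVMR-IVW: WLS of beta_y on the exposure beta matrix, no intercept,
    weights 1/se_y²; SEs scaled by max(1, sqrt(Q/(k-p)))."""
    k, p = h.k, h.p
    if k <= p:
        raise InsufficientInstrumentsError(f"MVMR-IVW needs k > p ({k} <= {p})")
    _check_rank(h.beta_x)
    w = 1.0 / h.se_y ** 2
    coef, se, Q = _wls(h.beta_x, h.beta_y, w, k - p)
    pv = 2 * stats.norm.sf(np.abs(coef) / se)
    return MVMREstimate(
        method="mvmr_ivw", exposure_names=list(h.exposure_names),
        estimates=coef, ses=se,
        ci_low=coef - Z95 * se, ci_high=coef + Z95 * se, pvals=pv,
        n_variants=k, Q=Q, Q_pval=float(stats.chi2.sf(Q, k - p)),
        conditional_F=conditional_f(h))


def mvmr_egger(h: MVHarmonizedSet, primary: int = 0) -> MVMREstimate:
    """MVMR-Egger: adds an intercept after orienting every variant to a
    positive beta on the designated primary exposure."""
    k, p = h.k, h.p
    if k <= p + 1:
        raise InsufficientInstrumentsError(f"MVMR-Egger needs k > p+1 ({k} <= {p + 1})")
    flip = np.where(h.beta_x[:, primary] < 0, -1.0, 1.0)
    bx = h.beta_x * flip[:, None]
    by = h.beta_y * flip
    X = np.column_stack([np.ones(k), bx])
    _check_rank(X)
    w = 1.0 / h.se_y ** 2
    coef, se, Q = _wls(X, by, w, k - p - 1)
    inter, slopes = float(coef[0]), coef[1:]
    se_i, se_s = float(se[0]), se[1:]
    pv = 2 * stats.norm.sf(np.abs(slopes) / se_s)
    return MVMREstimate(
        method="mvmr_egger", exposure_names=list(h.exposure_names),
        estimates=slopes, ses=se_s,
        ci_low=slopes - Z95 * se_s, ci_high=slopes + Z95 * se_s, pvals=pv,
        n_variants=k, Q=Q, Q_pval=float(stats.chi2.sf(Q, k - p - 1)),
        intercept=inter, intercept_se=se_i,
        intercept_pval=float(2 * stats.norm.sf(abs(inter) / se_i)))


def _weighted_l1_fit(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Minimize sum_j w_j |y_j - x_j . theta| over theta (LP formulation)."""
    k, p = X.shape
    # variables: theta+ (p), theta- (p), u (k) with u >= |resid|
    c = np.concatenate([np.zeros(2 * p), w])
    A_ub = np.block([
        [X, -X, -np.eye(k)],
        [-X, X, -np.eye(k)],
    ])
    b_ub = np.concatenate([y, -y])
    res = linprog(c, A_ub=A_ub, b_ub=b_ub,
                  bounds=[(0, None)] * (2 * p) + [(0, None)] * k,
                  method="highs")
    if not res.success:
        raise InputError(f"weighted L1 fit failed: {res.message}")
    return res.x[:p] - res.x[p:2 * p]


def mvmr_median(h: MVHarmonizedSet, n_boot: int = 200,
                seed: int | None = None) -> MVMREstimate:
    """Multivariable median: weighted L1 regression through the origin,
    weights 1/se_y²; SEs from a seeded parametric bootstrap."""
    k, p = h.k, h.p
    if k <= p:
        raise InsufficientInstrumentsError(f"MVMR-median needs k > p ({k} <= {p})")
    _check_rank(h.beta_x)
    w = 1.0 / h.se_y ** 2
    coef = _weighted_l1_fit(h.beta_x, h.beta_y, w)

    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, p))
    for b in range(n_boot):
        bx = rng.normal(h.beta_x, h.se_x)
        by = rng.normal(h.beta_y, h.se_y)
        boots[b] = _weighted_l1_fit(bx, by, 1.0 / h.se_y ** 2)
    se = boots.std(axis=0, ddof=1)
    se[se == 0] = np.finfo(float).tiny
    pv = 2 * stats.norm.sf(np.abs(coef) / se)
    return MVMREstimate(
        method="mvmr_median", exposure_names=list(h.exposure_names),
        estimates=coef, ses=se,
        ci_low=coef - Z95 * se, ci_high=coef + Z95 * se, pvals=pv,
        n_variants=k)


def _lasso_cd(X: np.ndarray, y: np.ndarray, w: np.ndarray, lam: float,
              theta0: np.ndarray, alpha0: np.ndarray,
              tol: float = 1e-8, max_iter: int = 10_000):
    """Coordinate descent for sum w_j (y_j - x_j.theta - alpha_j)^2
    + lam * sum |alpha_j|; alpha has a closed-form soft-threshold update."""
    theta, alpha = theta0.copy(), alpha0.copy()
    for _ in range(max_iter):
        # theta given alpha: plain WLS on the offset outcome
        sw = np.sqrt(w)
        theta_new, *_ = np.linalg.lstsq(X * sw[:, None], (y - alpha) * sw,
                                        rcond=None)
        r = y - X @ theta_new
        alpha_new = np.sign(r) * np.maximum(np.abs(r) - lam / (2 * w), 0.0)
        delta = max(np.max(np.abs(theta_new - theta)),
                    np.max(np.abs(alpha_new - alpha)))
        theta, alpha = theta_new, alpha_new
        if delta < tol:
            break
    return theta, alpha


def mvmr_lasso(h: MVHarmonizedSet, lambda_grid: np.ndarray | None = None
               ) -> MVMREstimate:
    """MVMR-Lasso: per-variant pleiotropy intercepts alpha_j with an L1
    penalty; the tuning parameter follows a heterogeneity stopping rule.

    Lambda values are visited in decreasing order and the first (largest)
    one whose zero-intercept ("valid") subset is homogeneous
    (Q <= chi2_{k_valid - p, 0.95}) is selected; the reported estimate is
    MVMR-IVW on that subset and ``retained_variant_ids`` lists it.
    """
    k, p = h.k, h.p
    if k <= p:
        raise InsufficientInstrumentsError(f"MVMR-Lasso needs k > p ({k} <= {p})")
    _check_rank(h.beta_x)
    w = 1.0 / h.se_y ** 2
    base = mvmr_ivw(h)
    resid = h.beta_y - h.beta_x @ base.estimates
    lam_max = 2 * float(np.max(w * np.abs(resid)))  # all alpha_j exactly 0
    if lambda_grid is None:
        if lam_max == 0:
            lambda_grid = np.array([1.0])
        else:
            lambda_grid = np.geomspace(1e-4, 1e2, 61) * (lam_max / 1e2)
    lambda_grid = np.sort(np.asarray(lambda_grid, float))[::-1]

    theta = base.estimates.copy()
    alpha = np.zeros(k)
    fallback = None  # (Q ratio, subset) among feasible grids
    for lam in lambda_grid:
        theta, alpha = _lasso_cd(h.beta_x, h.beta_y, w, lam, theta, alpha)
        valid = np.abs(alpha) < 1e-12
        kv = int(valid.sum())
        if kv < p + 1:
            continue
        sub = h.subset(valid)
        fit = mvmr_ivw(sub)
        if fit.Q <= stats.chi2.ppf(0.95, kv - p):
            fit = replace(fit, method="mvmr_lasso",
                          retained_variant_ids=list(sub.variant_ids))
            return fit
        ratio = fit.Q / max(kv - p, 1)
        if fallback is None or ratio < fallback[0]:
            fallback = (ratio, sub)
    if fallback is None:
        raise NoValidSubsetError("no lambda left a valid subset of size > p")
    fit = mvmr_ivw(fallback[1])
    return replace(fit, method="mvmr_lasso",
                   retained_variant_ids=list(fallback[1].variant_ids))


def conditional_f(h: MVHarmonizedSet) -> np.ndarray:
    """Conditional F-statistic per exposure: instrument strength left in one
    exposure's betas after projecting out the other exposures' betas.

    For exposure e, regress beta_x[:,e] on the remaining columns with weights
    1/se_x[:,e]²; F_e = Q_e/(k - p + 1) where Q_e is the weighted residual
    sum of squares.  Cross-exposure GWAS error covariances are taken as zero.
    """
    k, p = h.k, h.p
    if k <= p:
        raise InsufficientInstrumentsError(f"conditional F needs k > p ({k} <= {p})")
    out = np.empty(p)
    for e in range(p):
        y = h.beta_x[:, e]
        w = 1.0 / h.se_x[:, e] ** 2
        others = np.delete(h.beta_x, e, axis=1)
        if others.shape[1] == 0:
            rss = float(np.sum(w * y ** 2))
        else:
            sw = np.sqrt(w)
            coef, *_ = np.linalg.lstsq(others * sw[:, None], y * sw, rcond=None)
            rss = float(np.sum(w * (y - others @ coef) ** 2))
        out[e] = rss / (k - p + 1)
    return out
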