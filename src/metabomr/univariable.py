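"""Univariable two-sample Mendelian randomization estimators and diagnostics.

The primary analysis is inverse-variance-weighted (IVW) meta-analysis of
per-variant Wald ratios under a multiplicative random-effects model whose
dispersion is floored at 1 (a standard-error correction for under-dispersion).
Four robust estimators probe violations of the exclusion restriction:
MR-Egger regression (directional pleiotropy via its intercept), the weighted
median (valid-majority assumption), the contamination mixture (profile
likelihood over a causal-effect grid with a valid/invalid mixture per
variant), and MR-PRESSO (parametric residual-sum-of-squares global test plus
per-variant outlier flags).  Instrument strength (F, r²), Steiger
directionality filtering and a reverse-direction pipeline round out the
diagnostics.

For a binary outcome on the log-odds scale, ``exp(estimate)`` is the odds
ratio per SD of exposure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import (
    BoundaryError,
    CollinearityError,
    DegenerateInstrumentError,
    InputError,
    InsufficientInstrumentsError,
)
from .sumstats import HarmonizedSet, LDMatrix, SumStatTable, harmonize, select_instruments

Z95 = float(stats.norm.ppf(0.975))


@dataclass
class MREstimate:
    """A single MR method's causal-effect estimate with diagnostics."""

    method: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_variants: int
    Q: float | None = None
    Q_pval: float | None = None
    dispersion: float | None = None       # IVW multiplicative dispersion phi
    intercept: float | None = None        # Egger
    intercept_se: float | None = None
    intercept_pval: float | None = None
    valid_fraction: float | None = None   # contamination mixture
    ci_intervals: list[tuple[float, float]] | None = None  # conmix (may be disjoint)
    outlier_ids: list[str] | None = None  # MR-PRESSO
    global_pval: float | None = None      # MR-PRESSO global test

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.estimate))

    @property
    def or_ci(self) -> tuple[float, float]:
        return float(np.exp(self.ci_low)), float(np.exp(self.ci_high))


@dataclass
class SteigerResult:
    """Per-variant exposure-vs-outcome variance-explained comparison."""

    variant_ids: list[str]
    r2_exposure: np.ndarray
    r2_outcome: np.ndarray
    z: np.ndarray
    pval: np.ndarray
    flagged: np.ndarray
    n_flagged: int = 0

    def __post_init__(self) -> None:
        self.n_flagged = int(np.sum(self.flagged))


@dataclass
class StrengthSummary:
    """Instrument relevance: per-variant and overall F, variance explained."""

    variant_ids: list[str]
    F: np.ndarray
    r2: np.ndarray
    mean_F: float
    total_r2: float
    overall_F: float


# ---------------------------------------------------------------------------
# per-variant ratios
# ---------------------------------------------------------------------------

def wald_ratio(beta_x: float, se_x: float, beta_y: float, se_y: float
               ) -> tuple[float, float]:
    """Per-variant causal estimate beta_y/beta_x with first-order delta SE."""
    if beta_x == 0:
        raise DegenerateInstrumentError("exposure beta is zero")
    return beta_y / beta_x, se_y / abs(beta_x)


def _ratios(h: HarmonizedSet) -> tuple[np.ndarray, np.ndarray]:
    if np.any(h.beta_x == 0):
        raise DegenerateInstrumentError("exposure beta of zero in harmonized set")
    return h.beta_y / h.beta_x, h.se_y / np.abs(h.beta_x)


# ---------------------------------------------------------------------------
# IVW
# ---------------------------------------------------------------------------

def ivw(h: HarmonizedSet) -> MREstimate:
    """IVW with multiplicative random effects, dispersion floored at 1.

    Weights are the inverse squared delta-method ratio SEs,
    w_j = beta_x_j^2 / se_y_j^2; the point estimate equals weighted least
    squares of beta_y on beta_x through the origin.  Cochran's Q measures
    ratio heterogeneity; the reported SE is the fixed-effect SE times
    sqrt(phi) with phi = max(1, Q/(k-1)).
    """
    k = h.k
    if k < 2:
        raise InsufficientInstrumentsError(f"IVW needs k >= 2, got {k}")
    theta_j, _ = _ratios(h)
    w = h.beta_x ** 2 / h.se_y ** 2
    theta = float(np.sum(w * theta_j) / np.sum(w))
    se_fixed = float(np.sum(w)) ** -0.5
    Q = float(np.sum(w * (theta_j - theta) ** 2))
    phi = max(1.0, Q / (k - 1))
    se = se_fixed * np.sqrt(phi)
    p = 2 * stats.norm.sf(abs(theta) / se)
    return MREstimate(
        method="ivw", estimate=theta, se=se,
        ci_low=theta - Z95 * se, ci_high=theta + Z95 * se,
        pval=float(p), n_variants=k,
        Q=Q, Q_pval=float(stats.chi2.sf(Q, k - 1)), dispersion=phi)


# ---------------------------------------------------------------------------
# MR-Egger
# ---------------------------------------------------------------------------

def mr_egger(h: HarmonizedSet) -> MREstimate:
    """MR-Egger: weighted regression of beta_y on beta_x with an intercept.

    Variants are oriented so beta_x >= 0 (the intercept is only interpretable
    under a fixed exposure-increasing orientation).  SEs are scaled by
    max(1, sqrt(RSS_w/(k-2))).  The intercept estimates the average direct
    (pleiotropic) effect; its test is the standard pleiotropy diagnostic.
    """
    k = h.k
    if k < 3:
        raise InsufficientInstrumentsError(f"MR-Egger needs k >= 3, got {k}")
    flip = np.where(h.beta_x < 0, -1.0, 1.0)
    bx = h.beta_x * flip
    by = h.beta_y * flip
    if np.ptp(bx) == 0:
        raise CollinearityError("no spread in |beta_x|; Egger slope undefined")
    w = 1.0 / h.se_y ** 2
    X = np.column_stack([np.ones(k), bx])
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(X * sw[:, None], by * sw, rcond=None)
    resid = by - X @ coef
    rss_w = float(np.sum(w * resid ** 2))
    scale = max(1.0, np.sqrt(rss_w / (k - 2)))
    cov = np.linalg.inv(X.T @ (X * w[:, None]))
    se = np.sqrt(np.diag(cov)) * scale
    inter, slope = float(coef[0]), float(coef[1])
    se_i, se_s = float(se[0]), float(se[1])
    return MREstimate(
        method="egger", estimate=slope, se=se_s,
        ci_low=slope - Z95 * se_s, ci_high=slope + Z95 * se_s,
        pval=float(2 * stats.norm.sf(abs(slope) / se_s)), n_variants=k,
        Q=rss_w, Q_pval=float(stats.chi2.sf(rss_w, k - 2)),
        intercept=inter, intercept_se=se_i,
        intercept_pval=float(2 * stats.norm.sf(abs(inter) / se_i)))


# ---------------------------------------------------------------------------
# weighted median
# ---------------------------------------------------------------------------

def _weighted_median_point(theta_j: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(theta_j, kind="mergesort")
    t = theta_j[order]
    wn = w[order] / np.sum(w)
    s = np.cumsum(wn) - wn / 2  # cumulative midpoint positions
    if s[0] >= 0.5:
        return float(t[0])
    if s[-1] <= 0.5:
        return float(t[-1])
    j = int(np.searchsorted(s, 0.5))  # s[j-1] < 0.5 <= s[j]
    return float(t[j - 1] + (t[j] - t[j - 1]) * (0.5 - s[j - 1]) / (s[j] - s[j - 1]))


def weighted_median(h: HarmonizedSet, n_boot: int = 1000,
                    seed: int | None = None) -> MREstimate:
    """Weighted median of Wald ratios (consistent if >50% of weight is valid).

    The estimate interpolates the inverse-variance-weighted empirical
    distribution of ratios at probability 0.5.  The SE comes from a seeded
    parametric bootstrap resampling each beta from its sampling distribution.
    """
    k = h.k
    if k < 3:
        raise InsufficientInstrumentsError(f"weighted median needs k >= 3, got {k}")
    theta_j, ratio_se = _ratios(h)
    w = 1.0 / ratio_se ** 2
    est = _weighted_median_point(theta_j, w)

    rng = np.random.default_rng(seed)
    bx = rng.normal(h.beta_x, h.se_x, size=(n_boot, k))
    by = rng.normal(h.beta_y, h.se_y, size=(n_boot, k))
    bx[bx == 0] = np.finfo(float).tiny
    boots = np.empty(n_boot)
    for b in range(n_boot):
        tj = by[b] / bx[b]
        wj = bx[b] ** 2 / h.se_y ** 2
        boots[b] = _weighted_median_point(tj, wj)
    se = float(np.std(boots, ddof=1))
    p = 2 * stats.norm.sf(abs(est) / se) if se > 0 else np.nan
    return MREstimate(
        method="weighted_median", estimate=est, se=se,
        ci_low=est - Z95 * se, ci_high=est + Z95 * se,
        pval=float(p), n_variants=k)


# ---------------------------------------------------------------------------
# contamination mixture
# ---------------------------------------------------------------------------

def contamination_mixture(h: HarmonizedSet, psi: float | None = None,
                          grid: np.ndarray | None = None) -> MREstimate:
    """Contamination-mixture estimator via profile likelihood on a theta grid.

    Each variant contributes the larger of a "valid" log-likelihood
    (ratio_j ~ N(theta, ratio_se_j^2)) and an "invalid" one
    (ratio_j ~ N(0, ratio_se_j^2 + psi^2)).  The 95% confidence region is the
    set of grid values within chi2_1(0.95)/2 of the profile maximum and may
    be a union of disjoint intervals (reported in ``ci_intervals``).  By
    default psi = 1.5 * SD of the ratio estimates and the grid spans the IVW
    estimate +/- 6 SE at step SE/10, widened until the maximum is interior.
    """
    if h.k < 2:
        raise InsufficientInstrumentsError("contamination mixture needs k >= 2")
    theta_j, ratio_se = _ratios(h)
    if psi is None:
        psi = 1.5 * float(np.std(theta_j, ddof=1))
        if psi == 0:
            psi = float(np.mean(ratio_se))
    base = ivw(h)

    def _profile(g):
        valid = stats.norm.logpdf(theta_j[None, :], loc=g[:, None],
                                  scale=ratio_se[None, :])
        invalid = stats.norm.logpdf(theta_j, loc=0.0,
                                    scale=np.sqrt(ratio_se ** 2 + psi ** 2))
        both = np.maximum(valid, invalid[None, :])
        return both.sum(axis=1), valid >= invalid[None, :]

    if grid is not None:
        g = np.asarray(grid, dtype=float)
        ll, valid_mask = _profile(g)
        imax = int(np.argmax(ll))
        if imax in (0, len(g) - 1):
            raise BoundaryError("profile maximum on the supplied grid boundary")
    else:
        lo, hi = base.estimate - 6 * base.se, base.estimate + 6 * base.se
        step = base.se / 10
        for _ in range(12):
            g = np.arange(lo, hi + step / 2, step)
            ll, valid_mask = _profile(g)
            imax = int(np.argmax(ll))
            if 0 < imax < len(g) - 1:
                break
            width = hi - lo
            lo, hi = lo - width, hi + width
        else:
            raise BoundaryError("profile maximum still on boundary after widening")

    est = float(g[imax])
    cutoff = ll[imax] - stats.chi2.ppf(0.95, 1) / 2
    inside = ll >= cutoff
    # contiguous runs of grid points inside the likelihood region
    edges = np.flatnonzero(np.diff(np.concatenate(([0], inside.view(np.int8), [0]))))
    intervals = [(float(g[a]), float(g[b - 1]))
                 for a, b in zip(edges[::2], edges[1::2])]
    ci_low, ci_high = intervals[0][0], intervals[-1][1]
    se = (ci_high - ci_low) / (2 * Z95)
    ll0, _ = _profile(np.array([0.0]))
    lr = 2 * (ll[imax] - ll0[0])
    p = float(stats.chi2.sf(max(lr, 0.0), 1))
    return MREstimate(
        method="contamination_mixture", estimate=est, se=float(se),
        ci_low=ci_low, ci_high=ci_high, pval=p, n_variants=h.k,
        valid_fraction=float(np.mean(valid_mask[imax])),
        ci_intervals=intervals)


# ---------------------------------------------------------------------------
# MR-PRESSO
# ---------------------------------------------------------------------------

def _loo_ivw(bx: np.ndarray, by: np.ndarray, se_y: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW estimates, vectorized; rows broadcast over sims."""
    w = bx ** 2 / se_y ** 2
    wt = bx * by / se_y ** 2
    S0 = w.sum(axis=-1, keepdims=True)
    S1 = wt.sum(axis=-1, keepdims=True)
    return (S1 - wt) / (S0 - w)


def mr_presso(h: HarmonizedSet, n_sim: int = 1000, seed: int | None = None,
              outlier_alpha: float = 0.05) -> MREstimate:
    """MR-PRESSO global heterogeneity test and per-variant outlier flags.

    The observed statistic is the sum over variants of the squared residual
    of beta_y about its leave-one-out IVW prediction, standardized by
    se_y^2.  Its null distribution comes from ``n_sim`` parametric
    simulations (beta_x* ~ N(beta_x, se_x^2), beta_y* ~ N(theta_{-j} beta_x,
    se_y^2)); empirical p-values are floored at 1/(n_sim+1).  Per-variant
    outliers use the same simulations with Bonferroni correction across k;
    when outliers are flagged the reported estimate is IVW on the remaining
    variants (the distortion test is not implemented).
    """
    k = h.k
    if k < 4:
        raise InsufficientInstrumentsError(f"MR-PRESSO needs k >= 4, got {k}")
    theta_loo = _loo_ivw(h.beta_x, h.beta_y, h.se_y)
    resid_obs = (h.beta_y - theta_loo * h.beta_x) ** 2 / h.se_y ** 2
    rss_obs = float(resid_obs.sum())

    rng = np.random.default_rng(seed)
    bx_s = rng.normal(h.beta_x, h.se_x, size=(n_sim, k))
    by_s = rng.normal(theta_loo * h.beta_x, h.se_y, size=(n_sim, k))
    bx_s[bx_s == 0] = np.finfo(float).tiny
    theta_loo_s = _loo_ivw(bx_s, by_s, h.se_y)
    resid_s = (by_s - theta_loo_s * bx_s) ** 2 / h.se_y ** 2
    rss_s = resid_s.sum(axis=1)

    floor = 1.0 / (n_sim + 1)
    global_p = max(float(np.mean(rss_s >= rss_obs)), floor)
    p_var = np.maximum(np.mean(resid_s >= resid_obs, axis=0), floor)
    flagged = p_var * k < outlier_alpha
    outlier_ids = [h.variant_ids[i] for i in np.flatnonzero(flagged)]

    if outlier_ids and k - len(outlier_ids) >= 2:
        base = ivw(h.subset(~flagged, dropped_reason="presso_outlier"))
    else:
        base = ivw(h)
    return MREstimate(
        method="mr_presso", estimate=base.estimate, se=base.se,
        ci_low=base.ci_low, ci_high=base.ci_high, pval=base.pval,
        n_variants=base.n_variants, Q=base.Q, Q_pval=base.Q_pval,
        dispersion=base.dispersion,
        outlier_ids=outlier_ids, global_pval=global_p)


# ---------------------------------------------------------------------------
# instrument strength, Steiger, reverse MR
# ---------------------------------------------------------------------------

def instrument_strength(h: HarmonizedSet) -> StrengthSummary:
    """Per-variant F and r², total variance explained, and the overall F.

    F_j = (beta_x_j/se_x_j)^2, r²_j = t²/(t² + n - 2); the overall F is the
    multi-instrument statistic r²(n-k-1)/((1-r²)k).
    """
    k = h.k
    if k < 1:
        raise InsufficientInstrumentsError("need at least one instrument")
    n = h.n_exposure
    if n <= k + 1:
        raise InputError(f"n_exposure={n} too small for k={k} instruments")
    t2 = (h.beta_x / h.se_x) ** 2
    r2 = t2 / (t2 + n - 2)
    total = float(np.sum(r2))
    if total >= 1:
        raise InputError("total r^2 >= 1; instruments implausible")
    overall = total * (n - k - 1) / ((1 - total) * k)
    return StrengthSummary(
        variant_ids=list(h.variant_ids), F=t2, r2=r2,
        mean_F=float(np.mean(t2)), total_r2=total, overall_F=float(overall))


def steiger_filter(h: HarmonizedSet, alpha: float = 0.05
                   ) -> tuple[SteigerResult, HarmonizedSet]:
    """Flag and remove variants explaining more outcome than exposure variance.

    Per variant, |correlations| are recovered from t-statistics
    (r = t/sqrt(t² + n - 2)); the two-sample Fisher-z comparison
    z = (atanh r_x - atanh r_y)/sqrt(1/(n_x-3) + 1/(n_y-3)) is one-sided
    against the reverse orientation.  For a binary outcome the log-odds
    t-statistic is used directly (an approximation, noted in reports).
    """
    nx, ny = h.n_exposure, h.n_outcome
    if nx <= 3 or ny <= 3:
        raise InputError("sample sizes must exceed 3 for the Steiger test")
    tx = np.abs(h.beta_x / h.se_x)
    ty = np.abs(h.beta_y / h.se_y)
    rx = tx / np.sqrt(tx ** 2 + nx - 2)
    ry = ty / np.sqrt(ty ** 2 + ny - 2)
    denom = np.sqrt(1.0 / (nx - 3) + 1.0 / (ny - 3))
    z = (np.arctanh(rx) - np.arctanh(ry)) / denom
    # one-sided p for the reverse orientation (outcome r exceeding exposure r)
    p = stats.norm.cdf(z)
    flagged = (ry ** 2 > rx ** 2) & (p < alpha)
    res = SteigerResult(
        variant_ids=list(h.variant_ids),
        r2_exposure=rx ** 2, r2_outcome=ry ** 2, z=z, pval=p, flagged=flagged)
    kept = h.subset(~flagged, dropped_reason="steiger_flagged") if flagged.any() else h
    return res, kept


def reverse_mr(liver_fat: SumStatTable, metabolite: SumStatTable,
               ld: LDMatrix, p_threshold: float = 5e-8,
               clump_r2: float = 0.01, clump_window_bp: int = 1_000_000,
               palindrome_eaf_limit: float = 0.42) -> MREstimate:
    """Reverse-direction MR: liver fat (continuous) as exposure.

    The disease outcome is a dichotomization of underlying liver fat, so the
    reverse direction is estimated on the continuous trait: select liver-fat
    instruments, harmonize against the metabolite, and run IVW.
    """
    inst = select_instruments(liver_fat, ld, p_threshold=p_threshold,
                              clump_r2=clump_r2, clump_window_bp=clump_window_bp)
    h = harmonize(liver_fat, metabolite, inst,
                  palindrome_eaf_limit=palindrome_eaf_limit, ld=ld)
    est = ivw(h)
    est.method = "reverse_ivw"
    return est
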