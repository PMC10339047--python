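"""Multiplicity correction, exposure clustering, causal-call triage, reports.

Because the metabolic exposures are heavily correlated, a plain Bonferroni
correction over all of them would be far too strict; the effective number of
tests is instead the number of principal components of the exposure
correlation matrix needed to reach a cumulative variance threshold
(default 90%).  k-means on the rows of the same correlation matrix groups
exposures into phenotypic clusters.

The triage turns one exposure's full result set into a verdict: a causal
candidate must have a primary IVW p below the corrected threshold, a strict
majority of robust estimators significant at 0.05, all estimates
directionally consistent with IVW, a non-significant Egger intercept,
supporting multivariable MR (adiposity-adjusted) results, no reverse-MR
signal from liver fat, and Steiger filtering applied.  Note the intercept
condition: a *non*-significant Egger intercept (p > 0.05) passes — a
significant intercept is evidence of directional pleiotropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .exceptions import InputError
from .multivariable import MVHarmonizedSet, MVMREstimate, mvmr_egger, mvmr_ivw, mvmr_lasso, mvmr_median
from .simulate import StudySim
from .univariable import (
    MREstimate,
    SteigerResult,
    contamination_mixture,
    ivw,
    mr_egger,
    mr_presso,
    steiger_filter,
    weighted_median,
)

ROBUST_METHODS = ("egger", "weighted_median", "contamination_mixture", "mr_presso")


@dataclass
class MultiplicityResult:
    n_components: int
    cumulative_variance: np.ndarray
    alpha_corrected: float
    base_alpha: float = 0.05

    @property
    def alpha_display(self) -> float:
        """Threshold rounded to 4 decimals for report display."""
        return round(self.alpha_corrected, 4)


@dataclass
class ClusterAssignment:
    labels: dict[str, int]
    min_corr: dict[int, float]
    k: int
    seed: int


@dataclass
class TriageResult:
    exposure: str
    flags: dict[str, bool]
    verdict: str  # "causal-candidate" | "not-supported"


def pc_effective_tests(corr: np.ndarray | pd.DataFrame,
                       variance_threshold: float = 0.9,
                       base_alpha: float = 0.05) -> MultiplicityResult:
    """Effective number of tests = principal components reaching the
    cumulative variance threshold; corrected alpha = base_alpha / m."""
    C = np.asarray(corr, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise InputError("correlation matrix must be square")
    if not np.allclose(C, C.T, atol=1e-8):
        raise InputError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(C), 1.0, atol=1e-6):
        raise InputError("correlation matrix must have unit diagonal")
    vals = np.linalg.eigvalsh(C)[::-1]
    if vals[-1] < -1e-6:
        raise InputError("correlation matrix is not positive semi-definite")
    vals = np.clip(vals, 0, None)
    cum = np.cumsum(vals) / C.shape[0]
    m = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
    m = min(m, C.shape[0])
    return MultiplicityResult(
        n_components=m, cumulative_variance=cum,
        alpha_corrected=base_alpha / m, base_alpha=base_alpha)


def kmeans_correlation_clusters(corr: pd.DataFrame, k: int = 3,
                                n_restarts: int = 10, seed: int = 0
                                ) -> ClusterAssignment:
    """k-means on the rows of the phenotypic correlation matrix.

    Each exposure's feature vector is its correlation profile with every
    other exposure; the best of ``n_restarts`` initializations (by
    within-cluster sum of squares) is kept, and each cluster reports its
    minimum pairwise correlation.
    """
    names = list(corr.index)
    p = len(names)
    if not (1 <= k <= p):
        raise InputError(f"k must lie in [1, {p}]")
    X = corr.to_numpy(float)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(X)
    assignment = {name: int(lab) for name, lab in zip(names, labels)}
    min_corr: dict[int, float] = {}
    for lab in range(k):
        members = [i for i in range(p) if labels[i] == lab]
        if len(members) < 2:
            min_corr[lab] = float("nan")
        else:
            sub = X[np.ix_(members, members)]
            min_corr[lab] = float(np.min(sub[np.triu_indices(len(members), 1)]))
    return ClusterAssignment(labels=assignment, min_corr=min_corr, k=k,
                             seed=seed)


def _sign(x: float) -> int:
    return 1 if x > 0 else (-1 if x < 0 else 0)


def triage(exposure: str,
           primary: MREstimate,
           robust: dict[str, MREstimate],
           mvmr: dict[str, MVMREstimate] | None,
           steiger: SteigerResult | None,
           reverse: MREstimate | None,
           alpha_corrected: float,
           mvmr_exposure_index: int = 0) -> TriageResult:
    """Evaluate the causal-call criteria for one exposure.

    ``robust`` maps method name to estimate (missing methods count as
    unavailable, not as failures); ``mvmr`` should carry ``mvmr_ivw`` and,
    when computable, ``mvmr_egger``, ``mvmr_median``, ``mvmr_lasso``.
    The verdict is "causal-candidate" iff every flag passes.
    """
    if primary is None:
        raise InputError("primary IVW estimate is required")
    available = {k: v for k, v in robust.items() if v is not None}
    if len(available) < 2:
        raise InputError("need at least two robust methods for triage")

    flags: dict[str, bool] = {}
    flags["primary_significant"] = primary.pval < alpha_corrected

    n_sig = sum(1 for est in available.values() if est.pval < 0.05)
    flags["robust_majority"] = n_sig > len(available) / 2

    s = _sign(primary.estimate)
    flags["directionally_consistent"] = all(
        _sign(est.estimate) == s for est in available.values())

    egger = available.get("egger")
    flags["egger_intercept_ok"] = (egger is None
                                   or egger.intercept_pval > 0.05)

    if mvmr and "mvmr_ivw" in mvmr:
        i = mvmr_exposure_index
        mv = mvmr["mvmr_ivw"]
        ok = mv.pvals[i] < 0.05 and _sign(mv.estimates[i]) == s
        med = mvmr.get("mvmr_median")
        if med is not None:
            ok = ok and med.pvals[i] < 0.05 and _sign(med.estimates[i]) == s
        las = mvmr.get("mvmr_lasso")
        if las is not None:
            ok = ok and las.pvals[i] < 0.05 and _sign(las.estimates[i]) == s
        egg = mvmr.get("mvmr_egger")
        if egg is not None:
            ok = ok and egg.intercept_pval > 0.05
        flags["mvmr_robust"] = bool(ok)
    else:
        flags["mvmr_robust"] = False

    flags["no_reverse_causality"] = (reverse is not None
                                     and reverse.pval >= 0.05)
    flags["steiger_clean"] = steiger is not None

    verdict = "causal-candidate" if all(flags.values()) else "not-supported"
    return TriageResult(exposure=exposure, flags=flags, verdict=verdict)


REPORT_COLUMNS = [
    "exposure", "method", "estimate", "se", "ci_low", "ci_high", "pval",
    "odds_ratio", "n_variants", "Q", "Q_pval", "intercept", "intercept_pval",
    "cluster", "verdict",
]


def build_report(results: dict[str, dict],
                 clusters: ClusterAssignment | None = None,
                 triage_results: dict[str, TriageResult] | None = None
                 ) -> pd.DataFrame:
    """Consolidated forest-style table: one row per exposure per method.

    ``results`` maps exposure name to {method name: MREstimate}.  Columns
    come out in a fixed deterministic order; ``odds_ratio`` is
    exp(estimate).
    """
    if not results:
        raise InputError("no results to report")
    rows = []
    for exposure in results:
        for method, est in results[exposure].items():
            if est is None:
                continue
            rows.append({
                "exposure": exposure, "method": method,
                "estimate": est.estimate, "se": est.se,
                "ci_low": est.ci_low, "ci_high": est.ci_high,
                "pval": est.pval, "odds_ratio": float(np.exp(est.estimate)),
                "n_variants": est.n_variants,
                "Q": est.Q, "Q_pval": est.Q_pval,
                "intercept": est.intercept,
                "intercept_pval": est.intercept_pval,
                "cluster": (clusters.labels.get(exposure)
                            if clusters is not None else None),
                "verdict": (triage_results[exposure].verdict
                            if triage_results and exposure in triage_results
                            else None),
            })
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def volcano_table(report: pd.DataFrame, method: str = "ivw") -> pd.DataFrame:
    """Estimate vs -log10 p for one method across exposures (plot data)."""
    sub = report[report["method"] == method].copy()
    sub["neg_log10_p"] = -np.log10(np.maximum(sub["pval"], 1e-300))
    return sub[["exposure", "estimate", "odds_ratio", "neg_log10_p"]]


# ---------------------------------------------------------------------------
# end-to-end study analysis
# ---------------------------------------------------------------------------

@dataclass
class StudyAnalysis:
    multiplicity: MultiplicityResult
    clusters: ClusterAssignment
    triage: dict[str, TriageResult]
    report: pd.DataFrame
    estimates: dict[str, dict[str, MREstimate]]


def analyze_study(study: StudySim, seed: int = 0, n_presso_sim: int = 500,
                  n_boot: int = 300) -> StudyAnalysis:
    """Run the full univariable + MVMR + triage pipeline on a simulated study.

    Per exposure: Steiger filtering, IVW, the four robust estimators, MVMR
    against the shared waist covariate, and reverse MR from liver fat; then
    PC-based multiplicity correction from the phenotypic correlation of the
    panel, k-means clustering, triage, and the consolidated report.
    """
    mult = pc_effective_tests(study.panel_corr.to_numpy())
    clusters = kmeans_correlation_clusters(study.panel_corr, k=3, seed=seed)

    rng = np.random.default_rng(seed)
    all_results: dict[str, dict[str, MREstimate]] = {}
    triage_results: dict[str, TriageResult] = {}
    for sim in study.exposures:
        st_res, h = steiger_filter(sim.harmonized)
        keep = np.array([v in h.variant_ids for v in sim.harmonized.variant_ids])

        primary = ivw(h)
        robust = {
            "egger": mr_egger(h),
            "weighted_median": weighted_median(
                h, n_boot=n_boot, seed=int(rng.integers(2 ** 31))),
            "contamination_mixture": contamination_mixture(h),
            "mr_presso": mr_presso(
                h, n_sim=n_presso_sim, seed=int(rng.integers(2 ** 31))),
        }
        mv = MVHarmonizedSet(
            variant_ids=list(h.variant_ids),
            exposure_names=[sim.name, "waist"],
            beta_x=np.column_stack([h.beta_x, sim.waist_beta[keep]]),
            se_x=np.column_stack([h.se_x, sim.waist_se[keep]]),
            beta_y=h.beta_y, se_y=h.se_y,
            n_exposures=[h.n_exposure, h.n_exposure],
            n_outcome=h.n_outcome)
        mv_results = {
            "mvmr_ivw": mvmr_ivw(mv),
            "mvmr_egger": mvmr_egger(mv),
            "mvmr_median": mvmr_median(mv, n_boot=max(100, n_boot // 2),
                                       seed=int(rng.integers(2 ** 31))),
            "mvmr_lasso": mvmr_lasso(mv),
        }
        reverse = ivw(sim.reverse)
        reverse.method = "reverse_ivw"

        triage_results[sim.name] = triage(
            sim.name, primary, robust, mv_results, st_res, reverse,
            alpha_corrected=mult.alpha_corrected)
        all_results[sim.name] = {"ivw": primary, **robust,
                                 "reverse_ivw": reverse}

    rep = build_report(all_results, clusters=clusters,
                       triage_results=triage_results)
    return StudyAnalysis(multiplicity=mult, clusters=clusters,
                         triage=triage_results, report=rep,
                         estimates=all_results)
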