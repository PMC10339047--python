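"""Cohort arm: incident fatty-liver phenotype, Cox regression, Kaplan–Meier.

The phenotype is derived from ICD-10-style first-occurrence diagnosis codes:
a small set of codes defines a case (hepatic fibrosis K74.0/K74.2, NASH
K75.8, NAFLD K76.0, other specified liver disease K76.9); any other code in
the K74/K75/K76 families marks non-NAFLD liver disease and removes the
participant entirely; cases diagnosed before enrollment are excluded from the
incident analysis.  Hazard ratios per SD of each standardized metabolite come
from Cox proportional-hazards models (Efron tie handling, via lifelines) with
the recruitment covariates; Kaplan–Meier curves, quintile groups and the
NCEP-ATPIII high-TG/low-HDL dyslipidemia classification support the
group-level analyses, and baseline characteristic tables summarize strata.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError as _LLConvergence

from .exceptions import ConvergenceError, InputError

#: case-defining first-occurrence codes
NAFLD_INCLUDE_CODES = ("K74.0", "K74.2", "K75.8", "K76.0", "K76.9")
#: families whose *other* members mark non-NAFLD liver disease
NAFLD_EXCLUDE_FAMILIES = ("K74", "K75", "K76")

_CODE_RE = re.compile(r"^[A-Z]\d{2}(\.\d+)?$")

#: NCEP-ATPIII cutoffs, mmol/L
TG_CUTOFF = 1.7
HDL_CUTOFF = {"male": 1.0, "female": 1.3}


@dataclass
class CohortTable:
    """Individual-level records: covariates, metabolite panel, diagnoses.

    ``individuals`` is indexed by participant id and carries enrollment and
    censor dates (as floats, years); ``diagnoses`` has one row per diagnosis
    record (id, code, date).  ``truth`` optionally carries the simulator's
    configured log hazard ratios.
    """

    individuals: pd.DataFrame
    diagnoses: pd.DataFrame
    metabolite_cols: list[str] = field(default_factory=list)
    truth: dict | None = None

    def __post_init__(self) -> None:
        if not self.individuals.index.is_unique:
            raise InputError("participant ids must be unique")


@dataclass
class PhenotypeResult:
    """Incident-case derivation output."""

    event: pd.Series        # bool, indexed by retained participant id
    time: pd.Series         # follow-up years to event or censoring
    excluded_ids: list      # removed: non-NAFLD liver code carriers
    prevalent_ids: list     # removed: case before enrollment


@dataclass
class SurvivalFit:
    """Per-covariate Cox results (HR per SD for standardized columns)."""

    summary: pd.DataFrame   # coef, se, hr, hr_ci_low, hr_ci_high, pval
    n_events: int
    n_at_risk: int
    converged: bool = True

    def coef(self, name: str) -> float:
        return float(self.summary.loc[name, "coef"])

    def se(self, name: str) -> float:
        return float(self.summary.loc[name, "se"])

    def hr(self, name: str) -> float:
        return float(self.summary.loc[name, "hr"])


@dataclass
class KMCurve:
    """Product-limit survival curve for one group."""

    label: str
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray


def _validate_code(code: str) -> str:
    code = str(code).strip().upper()
    if not _CODE_RE.match(code):
        raise InputError(f"malformed diagnosis code {code!r}")
    return code


def derive_nafld_phenotype(cohort: CohortTable,
                           include_codes=NAFLD_INCLUDE_CODES,
                           exclude_families=NAFLD_EXCLUDE_FAMILIES
                           ) -> PhenotypeResult:
    """Derive the incident-case indicator and follow-up time.

    A participant is a case at the earliest date of any code in
    ``include_codes``.  Any code whose family prefix is in
    ``exclude_families`` but which is not itself an include code marks
    unrelated liver disease: the participant is removed entirely.  Cases
    whose earliest include-code date precedes enrollment are removed from the
    incident analysis.  Everyone else is censored at their censor date.
    """
    if not include_codes or not exclude_families:
        raise InputError("code lists must be nonempty")
    include = {_validate_code(c) for c in include_codes}
    fams = tuple(exclude_families)

    diag = cohort.diagnoses.copy()
    diag["code"] = diag["code"].map(_validate_code)
    ind = cohort.individuals

    is_excl = diag["code"].str.startswith(fams) & ~diag["code"].isin(include)
    excluded_ids = sorted(set(diag.loc[is_excl, "id"]))

    cases = diag[diag["code"].isin(include) & ~diag["id"].isin(excluded_ids)]
    first_dx = cases.groupby("id")["date"].min()
    enroll = ind["enrollment"]
    prevalent_ids = sorted(
        v for v in first_dx.index if first_dx[v] < enroll.get(v, np.inf))

    keep = ind.index.difference(excluded_ids).difference(prevalent_ids)
    event = pd.Series(False, index=keep)
    time = (ind.loc[keep, "censor"] - ind.loc[keep, "enrollment"]).astype(float)
    incident = first_dx.index.intersection(keep)
    event.loc[incident] = True
    time.loc[incident] = (first_dx[incident] - enroll[incident]).astype(float)
    if (time <= 0).any():
        time = time.clip(lower=1e-6)
    return PhenotypeResult(event=event, time=time,
                           excluded_ids=list(excluded_ids),
                           prevalent_ids=list(prevalent_ids))


_SEX_MAP = {"male": 1, "female": 0, 1: 1, 0: 0}
_SMOKE_MAP = {"ever": 1, "never": 0, 1: 1, 0: 0}


def _numeric_design(df: pd.DataFrame, covariates: list[str],
                    standardize: list[str]) -> pd.DataFrame:
    X = pd.DataFrame(index=df.index)
    for c in covariates:
        col = df[c]
        if c == "sex":
            col = col.map(_SEX_MAP)
        elif c == "smoking":
            col = col.map(_SMOKE_MAP)
        col = pd.to_numeric(col)
        if c in standardize:
            sd = col.std(ddof=1)
            if sd == 0:
                raise InputError(f"covariate {c} has zero variance")
            col = (col - col.mean()) / sd
        X[c] = col
    return X


def cox_fit(cohort: CohortTable, phenotype: PhenotypeResult,
            covariates: list[str], standardize: list[str] | None = None,
            ties: str = "efron") -> SurvivalFit:
    """Cox proportional-hazards fit on the derived incident phenotype.

    Standardized columns (typically the metabolites) report HR per SD of the
    analysis sample after exclusions.  Efron tie handling by default
    (Breslow by flag).  Partial-likelihood maximization and the observed
    information matrix come from lifelines' Newton–Raphson fitter.
    """
    if phenotype.event.sum() < 1:
        raise InputError("no events; Cox model undefined")
    standardize = standardize or []
    df = cohort.individuals.loc[phenotype.event.index]
    X = _numeric_design(df, covariates, standardize)
    if np.linalg.matrix_rank(X.to_numpy(float)) < X.shape[1]:
        raise InputError("design matrix not full rank")
    X = X.assign(_time=phenotype.time, _event=phenotype.event.astype(int))
    fitter = CoxPHFitter()
    try:
        fitter.fit(X, duration_col="_time", event_col="_event",
                   show_progress=False)
    except _LLConvergence as exc:
        raise ConvergenceError(str(exc)) from exc
    if ties == "breslow":
        # lifelines implements Efron; Breslow differs only at ties and is
        # approximated by jittering tied times by a negligible epsilon.
        rng = np.random.default_rng(0)
        X["_time"] = X["_time"] + rng.uniform(0, 1e-9, len(X))
        fitter = CoxPHFitter()
        fitter.fit(X, duration_col="_time", event_col="_event")
    s = fitter.summary
    out = pd.DataFrame({
        "coef": s["coef"],
        "se": s["se(coef)"],
        "hr": np.exp(s["coef"]),
        "hr_ci_low": np.exp(s["coef"] - 1.959963984540054 * s["se(coef)"]),
        "hr_ci_high": np.exp(s["coef"] + 1.959963984540054 * s["se(coef)"]),
        "pval": s["p"],
    })
    return SurvivalFit(summary=out, n_events=int(phenotype.event.sum()),
                       n_at_risk=len(X))


def km_curve(time: pd.Series, event: pd.Series,
             groups: pd.Series | None = None) -> dict[str, KMCurve]:
    """Product-limit survival curves, one per group label."""
    if groups is None:
        groups = pd.Series("all", index=time.index)
    out: dict[str, KMCurve] = {}
    for label, idx in groups.groupby(groups).groups.items():
        if len(idx) == 0:
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(time.loc[idx], event.loc[idx].astype(int))
        times = kmf.survival_function_.index.to_numpy(float)
        surv = kmf.survival_function_.iloc[:, 0].to_numpy(float)
        at_risk = np.array([kmf.event_table.loc[:t, "at_risk"].iloc[-1]
                            if t in kmf.event_table.index else np.nan
                            for t in times])
        out[str(label)] = KMCurve(label=str(label), times=times,
                                  survival=surv, at_risk=at_risk)
    return out


def quintile_groups(values) -> np.ndarray:
    """Quintile labels 1..5 at the 20/40/60/80 empirical percentiles; ties
    fall in the lower group."""
    v = np.asarray(values, dtype=float)
    if len(np.unique(v)) < 5:
        raise InputError("need at least 5 distinct values for quintiles")
    cuts = np.percentile(v, [20, 40, 60, 80])
    return np.searchsorted(cuts, v, side="left") + 1


def dyslipidemia_groups(tg, hdl, sex) -> np.ndarray:
    """NCEP-ATPIII metabolic-dyslipidemia categories.

    High TG means TG >= 1.7 mmol/L (both sexes); low HDL means
    HDL-C < 1.0 mmol/L for men and < 1.3 mmol/L for women.
    """
    tg = np.asarray(tg, dtype=float)
    hdl = np.asarray(hdl, dtype=float)
    sex = np.asarray(sex)
    if np.any(tg <= 0) or np.any(hdl <= 0):
        raise InputError("TG and HDL-C must be positive")
    labels = np.empty(len(tg), dtype=object)
    for i in range(len(tg)):
        s = sex[i] if sex[i] in HDL_CUTOFF else {1: "male", 0: "female"}.get(sex[i])
        if s is None:
            raise InputError(f"unknown sex code {sex[i]!r}")
        high_tg = tg[i] >= TG_CUTOFF
        low_hdl = hdl[i] < HDL_CUTOFF[s]
        labels[i] = (("highTG" if high_tg else "lowTG") + "+"
                     + ("lowHDL" if low_hdl else "highHDL"))
    return labels


def baseline_table(df: pd.DataFrame, case: pd.Series,
                   continuous: list[str], categorical: list[str]
                   ) -> pd.DataFrame:
    """Baseline characteristics by case/control stratum.

    Continuous variables as mean and SD; categorical as n and percentage of
    the stratum (one decimal).
    """
    if df.empty:
        raise InputError("empty cohort")
    rows = []
    for label, mask in (("cases", case.astype(bool)), ("controls", ~case.astype(bool))):
        sub = df.loc[mask.index[mask]]
        n_stratum = len(sub)
        rows.append({"variable": "N", "stratum": label, "value": n_stratum})
        for c in continuous:
            rows.append({"variable": c, "stratum": label,
                         "mean": float(sub[c].mean()),
                         "sd": float(sub[c].std(ddof=1)) if n_stratum > 1 else 0.0})
        for c in categorical:
            col = sub[c]
            if col.dtype == object:
                col = col.map({**_SEX_MAP, **_SMOKE_MAP}).fillna(col)
            n_sub = int(pd.to_numeric(col).sum())
            pct = round(100.0 * n_sub / n_stratum, 1) if n_stratum else np.nan
            rows.append({"variable": c, "stratum": label,
                         "count": n_sub, "pct": pct})
    return pd.DataFrame(rows)


def percentage(n_sub: int, n_total: int, decimals: int = 1) -> float:
    """Stratum percentage as displayed in baseline tables: 100*n/N rounded."""
    if n_total <= 0:
        raise InputError("total must be positive")
    return round(100.0 * n_sub / n_total, decimals)
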