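"""Ground-truth synthetic data: two-sample GWAS, cohorts, and a full study.

Everything downstream of this module is exercised on data whose causal
structure is known.  The GWAS generator draws per-variant true exposure
effects scaled to a target variance explained, adds optional directional
pleiotropy (direct variant-outcome effects alpha_j for a chosen fraction of
invalid instruments), and samples exposure and outcome association estimates
with independent noise — the defining feature of the two-sample design.
Standard errors use the standardized-trait approximation
se = 1/sqrt(2 p (1-p) n), appropriate for rank-inverse-normalized GWAS
traits; binary-outcome statistics are generated on the log-odds scale
directly.

The cohort generator draws a factor-correlated metabolite panel
(compound-symmetric blocks), covariates matching a middle-aged population
cohort, and Weibull proportional-hazards event times with administrative
censoring, emitting ICD-10-style diagnosis records (including configurable
pre-enrollment and non-NAFLD liver codes to exercise the phenotype filter).

``simulate_study`` assembles the 20-exposure benchmark: a handful of truly
causal exposures, nulls, nulls contaminated with directional pleiotropy, a
shared adiposity covariate (waist) for MVMR, and a liver-fat trait for
reverse MR — all with per-exposure ground truth.

Default sample sizes mirror the data sources this pipeline is designed for:
~115,000 participants for the metabolite GWAS, a disease GWAS of ~8.4k cases
/ 770k controls (total n 778,614), a liver-fat GWAS of 32,860, and
instrument counts/strengths in the range observed there (14-56 SNPs,
F > 54).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .exceptions import InputError
from .observational import CohortTable
from .sumstats import SUMSTAT_COLUMNS, HarmonizedSet, LDMatrix, SumStatTable
from scipy import stats

_ALLELE_PAIRS = [("A", "G"), ("G", "A"), ("A", "C"), ("C", "A"),
                 ("T", "G"), ("G", "T"), ("T", "C"), ("C", "T")]


# ---------------------------------------------------------------------------
# two-sample GWAS
# ---------------------------------------------------------------------------

@dataclass
class GwasSimConfig:
    """Configuration for one exposure/outcome two-sample GWAS pair.

    ``theta`` is the true causal effect (outcome per SD exposure; log-odds
    for a binary outcome).  ``pi_invalid`` of the variants receive a direct
    outcome effect alpha_j ~ N(pleio_mean, pleio_sd^2); a nonzero mean makes
    the pleiotropy directional.  ``hx2`` is the exposure variance jointly
    explained by the instruments.  ``ld_blocks`` optionally gives
    (block_size, r) pairs for compound-symmetric LD blocks (zero between
    blocks); variants within a block are placed 10 kb apart, blocks 5 Mb
    apart.
    """

    m_snps: int = 30
    theta: float = 0.0
    pi_invalid: float = 0.0
    pleio_mean: float = 0.0
    pleio_sd: float = 0.0
    hx2: float = 0.02
    n_exposure: int = 115_000
    n_outcome: int = 778_614
    ld_blocks: list[tuple[int, float]] | None = None
    effect_dist: str = "halfnormal"  # "uniform": bounded away from 0; "normal": signed
    seed: int = 0

    def validate(self) -> None:
        if self.effect_dist not in ("halfnormal", "uniform", "normal"):
            raise InputError("effect_dist must be halfnormal, uniform or normal")
        if not (0 <= self.pi_invalid <= 1):
            raise InputError("pi_invalid must lie in [0,1]")
        if not (0 < self.hx2 < 1):
            raise InputError("hx2 must lie in (0,1)")
        if self.n_exposure < 100 or self.n_outcome < 100:
            raise InputError("sample sizes must be >= 100")
        if self.m_snps < 1:
            raise InputError("m_snps must be >= 1")


class TwoSampleGwas(NamedTuple):
    exposure: SumStatTable
    outcome: SumStatTable
    truth: pd.DataFrame
    ld: LDMatrix


def _draw_effects(cfg: GwasSimConfig, rng: np.random.Generator):
    m = cfg.m_snps
    p = rng.uniform(0.05, 0.95, m)
    # effect alleles oriented exposure-increasing, so pleio_mean != 0 is
    # genuinely directional with respect to the exposure; the "uniform"
    # distribution keeps effects bounded away from zero (no orientation
    # flips even in the noisiest draws)
    if cfg.effect_dist == "uniform":
        b = rng.uniform(1.0, 2.0, m)
    elif cfg.effect_dist == "normal":
        b = rng.normal(size=m)  # signed: orientation deliberately mixed
    else:
        b = np.abs(rng.normal(size=m))
    b *= np.sqrt(cfg.hx2 / np.sum(2 * p * (1 - p) * b ** 2))
    alpha = np.zeros(m)
    n_invalid = int(np.ceil(cfg.pi_invalid * m))
    invalid = rng.choice(m, size=n_invalid, replace=False) if n_invalid else []
    alpha[invalid] = rng.normal(cfg.pleio_mean, cfg.pleio_sd, size=n_invalid)
    valid = np.ones(m, dtype=bool)
    valid[invalid] = False
    se_x = 1.0 / np.sqrt(2 * p * (1 - p) * cfg.n_exposure)
    se_y = 1.0 / np.sqrt(2 * p * (1 - p) * cfg.n_outcome)
    bx = rng.normal(b, se_x)
    by = rng.normal(cfg.theta * b + alpha, se_y)
    return p, b, alpha, valid, se_x, se_y, bx, by


def simulate_two_sample_gwas(cfg: GwasSimConfig) -> TwoSampleGwas:
    """Simulate matching exposure and outcome summary-statistic tables.

    Exposure and outcome sampling errors are independent draws (two-sample
    independence).  The returned truth table carries each variant's true
    exposure effect, direct effect alpha_j and validity flag; the LD matrix
    is identity unless ``ld_blocks`` is set.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    m = cfg.m_snps
    p, b, alpha, valid, se_x, se_y, bx, by = _draw_effects(cfg, rng)

    ids = [f"rs{i + 1:05d}" for i in range(m)]
    if cfg.ld_blocks:
        sizes = [s for s, _ in cfg.ld_blocks]
        if sum(sizes) != m:
            raise InputError("ld_blocks sizes must sum to m_snps")
        pos, r = [], np.eye(m)
        offset, start = 1_000_000, 0
        for size, rho in cfg.ld_blocks:
            pos.extend(offset + 10_000 * i for i in range(size))
            blk = slice(start, start + size)
            r[blk, blk] = rho
            r[np.arange(start, start + size), np.arange(start, start + size)] = 1.0
            offset += 5_000_000
            start += size
        pos = np.array(pos)
    else:
        pos = 1_000_000 + 2_000_000 * np.arange(m)
        r = np.eye(m)

    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), m)
    ea = [_ALLELE_PAIRS[i][0] for i in pair_idx]
    oa = [_ALLELE_PAIRS[i][1] for i in pair_idx]

    def _table(name, ttype, beta, se, n):
        pval = 2 * stats.norm.sf(np.abs(beta / se))
        df = pd.DataFrame({
            "variant_id": ids, "chrom": "1", "pos": pos,
            "effect_allele": ea, "other_allele": oa,
            "eaf": p, "beta": beta, "se": se,
            "pval": np.maximum(pval, 1e-300), "n": n,
        })[SUMSTAT_COLUMNS]
        df = df.set_index("variant_id", drop=False)
        df.index.name = None
        return SumStatTable(trait_name=name, trait_type=ttype, df=df)

    truth = pd.DataFrame({"variant_id": ids, "b_true": b, "alpha": alpha,
                          "valid": valid})
    return TwoSampleGwas(
        exposure=_table("exposure", "continuous", bx, se_x, cfg.n_exposure),
        outcome=_table("outcome", "binary", by, se_y, cfg.n_outcome),
        truth=truth,
        ld=LDMatrix(variant_ids=ids, r=r))


def simulate_harmonized(cfg: GwasSimConfig,
                        rng: np.random.Generator | None = None
                        ) -> tuple[HarmonizedSet, pd.DataFrame]:
    """Array-level fast path: the same generative model as
    :func:`simulate_two_sample_gwas`, already harmonized (shared effect
    alleles), for simulation loops that run thousands of replicates."""
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    p, b, alpha, valid, se_x, se_y, bx, by = _draw_effects(cfg, rng)
    ids = [f"rs{i + 1:05d}" for i in range(cfg.m_snps)]
    h = HarmonizedSet(
        variant_ids=ids, beta_x=bx, se_x=se_x, beta_y=by, se_y=se_y,
        eaf_x=p, eaf_y=p, n_exposure=cfg.n_exposure, n_outcome=cfg.n_outcome)
    truth = pd.DataFrame({"variant_id": ids, "b_true": b, "alpha": alpha,
                          "valid": valid})
    return h, truth


@dataclass
class MvmrSimConfig:
    """Two-or-more-exposure GWAS generator for multivariable MR.

    Every exposure shares the same instruments; exposure effects are drawn
    independently per exposure and scaled to ``hx2`` each.  ``thetas`` are
    the true direct outcome effects.  Invalid variants get a direct effect
    alpha_j ~ N(pleio_mean, pleio_sd^2) on top.
    """

    m_snps: int = 40
    thetas: tuple = (0.3, 0.1)
    hx2: float = 0.03
    pi_invalid: float = 0.0
    pleio_mean: float = 0.0
    pleio_sd: float = 0.0
    n_exposure: int = 115_000
    n_outcome: int = 778_614
    effect_dist: str = "halfnormal"
    seed: int = 0


def simulate_mvmr_harmonized(cfg: MvmrSimConfig,
                             rng: np.random.Generator | None = None):
    """Simulate an already-harmonized multi-exposure set with ground truth.

    Returns (MVHarmonizedSet, truth DataFrame).  Imported lazily to avoid a
    circular dependency with the estimator module.
    """
    from .multivariable import MVHarmonizedSet

    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    m, pdim = cfg.m_snps, len(cfg.thetas)
    p = rng.uniform(0.05, 0.95, m)
    if cfg.effect_dist == "uniform":
        b = rng.uniform(1.0, 2.0, size=(m, pdim))
    elif cfg.effect_dist == "normal":
        b = rng.normal(size=(m, pdim))
    else:
        b = np.abs(rng.normal(size=(m, pdim)))
    b *= np.sqrt(cfg.hx2 / np.sum(2 * p * (1 - p) * b.T ** 2, axis=1))
    alpha = np.zeros(m)
    n_inv = int(np.ceil(cfg.pi_invalid * m))
    if n_inv:
        inv = rng.choice(m, size=n_inv, replace=False)
        alpha[inv] = rng.normal(cfg.pleio_mean, cfg.pleio_sd, n_inv)
    se_x = np.tile(1.0 / np.sqrt(2 * p * (1 - p) * cfg.n_exposure)[:, None],
                   (1, pdim))
    se_y = 1.0 / np.sqrt(2 * p * (1 - p) * cfg.n_outcome)
    bx = rng.normal(b, se_x)
    by = rng.normal(b @ np.asarray(cfg.thetas) + alpha, se_y)
    ids = [f"rs{i + 1:05d}" for i in range(m)]
    mv = MVHarmonizedSet(
        variant_ids=ids,
        exposure_names=[f"exposure_{j}" for j in range(pdim)],
        beta_x=bx, se_x=se_x, beta_y=by, se_y=se_y,
        n_exposures=[cfg.n_exposure] * pdim, n_outcome=cfg.n_outcome)
    truth = pd.DataFrame({"variant_id": ids, "alpha": alpha,
                          "valid": alpha == 0})
    return mv, truth


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

@dataclass
class CohortSimConfig:
    """Survival-cohort generator settings.

    Metabolites are standardized latent-factor variables: within each
    ``cluster_spec`` block (size, rho) the pairwise correlation is rho;
    metabolites beyond the blocks are independent.  Event times follow a
    Weibull proportional-hazards model, S(t) = exp(-(t/scale)^shape *
    exp(lp)), with the linear predictor built from the (centered) covariates
    and standardized metabolites; administrative censoring applies at
    ``admin_censor_years``.  Default baseline parameters give roughly a 2%
    cumulative incidence over the 12.6-year default horizon, matching a
    first-occurrence liver-disease phenotype in a population cohort.
    """

    n: int = 5000
    k_metabolites: int = 20
    cluster_spec: tuple = ((7, 0.85), (7, 0.85), (6, 0.85))
    log_hr_per_sd: np.ndarray | None = None  # length k, default zeros
    weibull_shape: float = 1.5
    weibull_scale: float = 170.0
    admin_censor_years: float = 12.6
    covariate_log_hr: dict | None = None
    frac_prevalent: float = 0.005
    frac_other_liver: float = 0.005
    seed: int = 0

    def validate(self) -> None:
        if self.n < 10:
            raise InputError("cohort n must be >= 10")
        if sum(s for s, _ in self.cluster_spec) > self.k_metabolites:
            raise InputError("cluster blocks exceed k_metabolites")
        if self.weibull_shape <= 0 or self.weibull_scale <= 0:
            raise InputError("Weibull parameters must be positive")


_DEFAULT_COV_LOG_HR = {
    "age": 0.02, "sex": 0.15, "waist": 0.03, "smoking": 0.25,
    "alcohol": -0.08, "townsend": 0.03, "ethnicity": 0.0,
    "medication": 0.4, "tg": np.log(1.19), "hdl": np.log(0.63),
}


def simulate_cohort(cfg: CohortSimConfig) -> CohortTable:
    """Simulate the observational cohort with known hazard structure."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n, k = cfg.n, cfg.k_metabolites
    loghr = (np.zeros(k) if cfg.log_hr_per_sd is None
             else np.asarray(cfg.log_hr_per_sd, float))
    if loghr.shape != (k,):
        raise InputError("log_hr_per_sd must have length k_metabolites")
    cov_hr = dict(_DEFAULT_COV_LOG_HR)
    if cfg.covariate_log_hr:
        cov_hr.update(cfg.covariate_log_hr)

    # factor-correlated metabolite panel
    mets = np.empty((n, k))
    start = 0
    for size, rho in cfg.cluster_spec:
        f = rng.normal(size=(n, 1))
        eps = rng.normal(size=(n, size))
        mets[:, start:start + size] = np.sqrt(rho) * f + np.sqrt(1 - rho) * eps
        start += size
    if start < k:
        mets[:, start:] = rng.normal(size=(n, k - start))

    ind = pd.DataFrame(index=pd.RangeIndex(n, name="id"))
    ind["age"] = rng.normal(57.1, 8.1, n).clip(40, 70)
    ind["sex"] = np.where(rng.random(n) < 0.46, "male", "female")
    ind["ethnicity"] = (rng.random(n) < 0.94).astype(int)
    ind["smoking"] = np.where(rng.random(n) < 0.45, "ever", "never")
    ind["alcohol"] = rng.normal(3.1, 1.5, n).round().clip(1, 6)
    ind["townsend"] = rng.normal(-1.3, 3.1, n)
    ind["waist"] = rng.normal(90.1, 13.4, n).clip(55, 160)
    ind["medication"] = (rng.random(n) < 0.27).astype(int)
    ind["tg"] = np.exp(rng.normal(np.log(1.55), 0.45, n))
    ind["hdl"] = rng.normal(1.5, 0.4, n).clip(0.4, 4.0)
    met_cols = [f"met_{i + 1:02d}" for i in range(k)]
    for j, c in enumerate(met_cols):
        ind[c] = mets[:, j]

    # linear predictor with covariates centered at their sampled means
    lp = mets @ loghr
    num = {"sex": (ind["sex"] == "male").astype(float),
           "smoking": (ind["smoking"] == "ever").astype(float)}
    for c, beta in cov_hr.items():
        col = num.get(c, ind[c]).astype(float)
        lp += beta * (col - col.mean()).to_numpy()

    u = rng.uniform(size=n)
    t_event = cfg.weibull_scale * (-np.log(u) / np.exp(lp)) ** (1 / cfg.weibull_shape)
    horizon = cfg.admin_censor_years
    event = t_event <= horizon

    ind["enrollment"] = 2008.0 + rng.uniform(0, 2, n)
    ind["censor"] = ind["enrollment"] + horizon

    recs = []
    for i in np.flatnonzero(event):
        recs.append({"id": i, "code": "K76.0",
                     "date": ind["enrollment"].iloc[i] + t_event[i]})
    # pre-enrollment diagnoses and unrelated liver disease, to exercise
    # the phenotype filter
    n_prev = int(round(cfg.frac_prevalent * n))
    n_liver = int(round(cfg.frac_other_liver * n))
    special = rng.choice(n, size=n_prev + n_liver, replace=False)
    for i in special[:n_prev]:
        recs.append({"id": int(i), "code": "K76.0",
                     "date": ind["enrollment"].iloc[int(i)] - rng.uniform(0.5, 5)})
    for i in special[n_prev:]:
        recs.append({"id": int(i), "code": "K74.6",
                     "date": ind["enrollment"].iloc[int(i)] + rng.uniform(0, horizon)})
    diagnoses = pd.DataFrame(recs, columns=["id", "code", "date"])

    truth = {"log_hr_per_sd": loghr, "covariate_log_hr": cov_hr,
             "weibull_shape": cfg.weibull_shape,
             "weibull_scale": cfg.weibull_scale,
             "event_time": t_event}
    return CohortTable(individuals=ind, diagnoses=diagnoses,
                       metabolite_cols=met_cols, truth=truth)


# ---------------------------------------------------------------------------
# full multi-exposure study
# ---------------------------------------------------------------------------

@dataclass
class StudySimConfig:
    """The 20-exposure benchmark study.

    Exposures 0..4 are truly causal with effects ``causal_thetas``; the next
    ``n_pleiotropic_nulls`` are null but contaminated with directional
    pleiotropy (fraction ``pleio_pi`` invalid variants, direct effects
    N(pleio_mean, pleio_sd^2)); the rest are clean nulls.  Every exposure
    shares its instruments with a waist-circumference covariate (true outcome
    effect ``waist_theta``), providing both a realistic confound for
    univariable heterogeneity and the MVMR second exposure.  A separate
    liver-fat trait (its own instruments) supplies the reverse-MR check; the
    per-exposure reverse effect is zero unless listed in
    ``reverse_thetas``.
    """

    n_exposures: int = 20
    causal_thetas: tuple = (0.3, -0.3, 0.5, -0.5, 0.4)
    n_pleiotropic_nulls: int = 5
    m_snps: int = 40
    hx2: float = 0.03
    waist_hx2: float = 0.02
    waist_theta: float = 0.3
    pleio_pi: float = 0.4
    pleio_mean: float = 0.08
    pleio_sd: float = 0.04
    n_exposure: int = 115_000
    n_outcome: int = 778_614
    liver_fat_m: int = 30
    liver_fat_hx2: float = 0.05
    n_liver_fat: int = 32_860
    reverse_thetas: dict = field(default_factory=dict)  # exposure idx -> effect
    cluster_spec: tuple = ((7, 0.85), (7, 0.85), (6, 0.85))
    panel_n: int = 2000
    seed: int = 0


@dataclass
class ExposureSim:
    name: str
    theta_true: float
    pleiotropic: bool
    harmonized: HarmonizedSet          # exposure vs disease
    waist_beta: np.ndarray             # waist effects at the same variants
    waist_se: np.ndarray
    reverse: HarmonizedSet             # liver fat vs this exposure


@dataclass
class StudySim:
    config: StudySimConfig
    exposures: list[ExposureSim]
    panel_corr: pd.DataFrame
    theta_true: np.ndarray


def simulate_study(cfg: StudySimConfig) -> StudySim:
    """Generate the full benchmark study with per-exposure ground truth."""
    rng = np.random.default_rng(cfg.seed)
    thetas = np.zeros(cfg.n_exposures)
    thetas[:len(cfg.causal_thetas)] = cfg.causal_thetas
    pleio_idx = set(range(len(cfg.causal_thetas),
                          len(cfg.causal_thetas) + cfg.n_pleiotropic_nulls))

    exposures = []
    for e in range(cfg.n_exposures):
        m = cfg.m_snps
        p = rng.uniform(0.05, 0.95, m)
        b = np.abs(rng.normal(size=m))
        b *= np.sqrt(cfg.hx2 / np.sum(2 * p * (1 - p) * b ** 2))
        bw = rng.normal(size=m)
        bw *= np.sqrt(cfg.waist_hx2 / np.sum(2 * p * (1 - p) * bw ** 2))
        alpha = np.zeros(m)
        if e in pleio_idx:
            n_inv = int(np.ceil(cfg.pleio_pi * m))
            inv = rng.choice(m, size=n_inv, replace=False)
            alpha[inv] = rng.normal(cfg.pleio_mean, cfg.pleio_sd, n_inv)
        se_x = 1.0 / np.sqrt(2 * p * (1 - p) * cfg.n_exposure)
        se_w = se_x  # waist GWAS is of comparable size
        se_y = 1.0 / np.sqrt(2 * p * (1 - p) * cfg.n_outcome)
        bx = rng.normal(b, se_x)
        bw_hat = rng.normal(bw, se_w)
        by = rng.normal(thetas[e] * b + cfg.waist_theta * bw + alpha, se_y)
        ids = [f"e{e:02d}_rs{i + 1:04d}" for i in range(m)]
        h = HarmonizedSet(
            variant_ids=ids, beta_x=bx, se_x=se_x, beta_y=by, se_y=se_y,
            eaf_x=p, eaf_y=p, n_exposure=cfg.n_exposure,
            n_outcome=cfg.n_outcome, exposure_name=f"exposure_{e:02d}",
            outcome_name="nafld")

        # liver fat -> this metabolite (reverse direction)
        ml = cfg.liver_fat_m
        pl = rng.uniform(0.05, 0.95, ml)
        bl = rng.normal(size=ml)
        bl *= np.sqrt(cfg.liver_fat_hx2 / np.sum(2 * pl * (1 - pl) * bl ** 2))
        se_l = 1.0 / np.sqrt(2 * pl * (1 - pl) * cfg.n_liver_fat)
        se_m = 1.0 / np.sqrt(2 * pl * (1 - pl) * cfg.n_exposure)
        rev_theta = cfg.reverse_thetas.get(e, 0.0)
        bl_hat = rng.normal(bl, se_l)
        bm_hat = rng.normal(rev_theta * bl, se_m)
        rev = HarmonizedSet(
            variant_ids=[f"lf_rs{i + 1:04d}" for i in range(ml)],
            beta_x=bl_hat, se_x=se_l, beta_y=bm_hat, se_y=se_m,
            eaf_x=pl, eaf_y=pl, n_exposure=cfg.n_liver_fat,
            n_outcome=cfg.n_exposure, exposure_name="liver_fat",
            outcome_name=f"exposure_{e:02d}")

        exposures.append(ExposureSim(
            name=f"exposure_{e:02d}", theta_true=float(thetas[e]),
            pleiotropic=e in pleio_idx, harmonized=h,
            waist_beta=bw_hat, waist_se=se_w, reverse=rev))

    panel_cfg = CohortSimConfig(
        n=cfg.panel_n, k_metabolites=cfg.n_exposures,
        cluster_spec=cfg.cluster_spec,
        seed=int(rng.integers(2 ** 31)))
    panel = simulate_cohort(panel_cfg)
    corr = panel.individuals[panel.metabolite_cols].corr()
    corr.index = corr.columns = [x.name for x in exposures]
    return StudySim(config=cfg, exposures=exposures, panel_corr=corr,
                    theta_true=thetas)
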