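"""Univariable MR estimators against closed-form and brute-force oracles."""

import numpy as np
import pytest
from scipy import stats

import metabomr as m
from metabomr.exceptions import (
    BoundaryError,
    DegenerateInstrumentError,
    InsufficientInstrumentsError,
)
from metabomr.simulate import GwasSimConfig, simulate_harmonized, simulate_two_sample_gwas
from metabomr.univariable import _ratios, _weighted_median_point

from conftest import make_harmonized


class TestWaldRatio:
    def test_arithmetic(self):
        assert m.wald_ratio(0.4, 0.02, 0.2, 0.1) == (pytest.approx(0.5),
                                                     pytest.approx(0.25))

    def test_null_outcome(self):
        assert m.wald_ratio(1, 0.01, 0, 0.1) == (0, pytest.approx(0.1))

    def test_zero_exposure_beta_raises(self):
        with pytest.raises(DegenerateInstrumentError):
            m.wald_ratio(0.0, 0.02, 0.2, 0.1)

    def test_delta_se_matches_monte_carlo(self):
        """SD of the ratio over resamples matches the first-order SE ~3%."""
        rng = np.random.default_rng(0)
        bx = rng.normal(0.4, 0.02, 100_000)
        by = rng.normal(0.2, 0.1, 100_000)
        mc_sd = np.std(by / bx)
        assert mc_sd == pytest.approx(0.25, rel=0.03)


class TestIVW:
    def test_identical_ratios_degenerate(self):
        h = make_harmonized([0.1, 0.2], [0.01, 0.02], [0.05, 0.10])
        est = m.ivw(h)
        assert est.estimate == pytest.approx(0.5)
        assert est.Q == pytest.approx(0.0, abs=1e-20)
        assert est.dispersion == 1.0

    def test_matches_closed_form_wls(self, five_variant_set):
        """IVW equals WLS of beta_y on beta_x through the origin."""
        import statsmodels.api as sm
        h = five_variant_set
        w = 1.0 / h.se_y ** 2
        fit = sm.WLS(h.beta_y, h.beta_x[:, None], weights=w).fit()
        est = m.ivw(h)
        assert est.estimate == pytest.approx(fit.params[0], abs=1e-10)
        se_fixed = float(np.sum(h.beta_x ** 2 / h.se_y ** 2)) ** -0.5
        Q = float(np.sum(w * (h.beta_y - fit.params[0] * h.beta_x) ** 2))
        phi = max(1.0, Q / (h.k - 1))
        assert est.se == pytest.approx(se_fixed * np.sqrt(phi), abs=1e-10)

    def test_insufficient_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            m.ivw(make_harmonized([0.1], [0.01], [0.05]))

    def test_random_effects_se_never_below_fixed(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            k = rng.integers(2, 15)
            h = make_harmonized(rng.uniform(0.05, 0.3, k),
                                rng.uniform(0.01, 0.05, k),
                                rng.normal(0, 0.1, k))
            est = m.ivw(h)
            se_fixed = float(np.sum(h.beta_x ** 2 / h.se_y ** 2)) ** -0.5
            assert est.se >= se_fixed - 1e-15


class TestEgger:
    def test_exact_linear_data_recovered(self):
        bx = np.array([0.1, 0.15, 0.2, 0.25, 0.3])
        by = 0.1 + 0.5 * bx
        h = make_harmonized(bx, np.full(5, 0.02), by)
        est = m.mr_egger(h)
        assert est.intercept == pytest.approx(0.1, abs=1e-12)
        assert est.estimate == pytest.approx(0.5, abs=1e-12)
        assert est.Q == pytest.approx(0.0, abs=1e-18)

    def test_matches_statsmodels_wls(self):
        rng = np.random.default_rng(3)
        bx = rng.uniform(0.05, 0.3, 6)
        se_y = rng.uniform(0.01, 0.04, 6)
        by = 0.05 + 0.4 * bx + rng.normal(0, se_y)
        h = make_harmonized(bx, se_y, by)
        import statsmodels.api as sm
        X = sm.add_constant(bx)
        fit = sm.WLS(by, X, weights=1 / se_y ** 2).fit()
        est = m.mr_egger(h)
        assert est.intercept == pytest.approx(fit.params[0], abs=1e-10)
        assert est.estimate == pytest.approx(fit.params[1], abs=1e-10)

    def test_directional_pleiotropy_intercept_recovered(self):
        """Mean intercept over replicates matches the planted direct effect."""
        rng = np.random.default_rng(4)
        # instruments strong enough that regression dilution is negligible
        cfg = GwasSimConfig(theta=0.3, m_snps=30, hx2=0.05, pi_invalid=1.0,
                            pleio_mean=0.05, pleio_sd=0.02,
                            effect_dist="uniform", n_exposure=1_000_000)
        inters = [m.mr_egger(simulate_harmonized(cfg, rng)[0]).intercept
                  for _ in range(500)]
        inters = np.array(inters)
        mcse = inters.std(ddof=1) / np.sqrt(len(inters))
        assert abs(inters.mean() - 0.05) < 2 * mcse

    def test_needs_three_variants(self):
        with pytest.raises(InsufficientInstrumentsError):
            m.mr_egger(make_harmonized([0.1, 0.2], [0.01, 0.02], [0.0, 0.1]))


class TestWeightedMedian:
    def test_symmetric_three_ratios(self):
        h = make_harmonized([1.0, 1.0, 1.0], [0.1, 0.1, 0.1], [1.0, 2.0, 3.0])
        est = m.weighted_median(h, n_boot=50, seed=0)
        assert est.estimate == pytest.approx(2.0)

    def test_constant_ratios_invariant_to_weights(self):
        h = make_harmonized([0.1, 0.2, 0.4], [0.01, 0.05, 0.02],
                            [0.07, 0.14, 0.28])
        est = m.weighted_median(h, n_boot=50, seed=0)
        assert est.estimate == pytest.approx(0.7)

    def test_matches_breakpoint_oracle(self):
        """Estimate equals a plain-loop weighted-CDF breakpoint search."""
        rng = np.random.default_rng(5)
        bx = rng.uniform(0.05, 0.3, 7)
        se_y = rng.uniform(0.01, 0.04, 7)
        by = 0.4 * bx + rng.normal(0, se_y)
        ratios, ratio_se = by / bx, se_y / np.abs(bx)
        w = 1 / ratio_se ** 2

        order = np.argsort(ratios)
        t, wn = ratios[order], w[order] / w.sum()
        s, cum, expected = [], 0.0, None
        for i in range(7):
            s.append(cum + wn[i] / 2)
            cum += wn[i]
        for i in range(6):
            if s[i] < 0.5 <= s[i + 1]:
                expected = t[i] + (t[i + 1] - t[i]) * (0.5 - s[i]) / (s[i + 1] - s[i])
        h = make_harmonized(bx, se_y, by)
        est = m.weighted_median(h, n_boot=50, seed=0)
        assert est.estimate == pytest.approx(expected, abs=1e-12)

    def test_robust_to_forty_percent_invalid(self):
        """Recovers theta near 0.3 where IVW is grossly biased."""
        rng = np.random.default_rng(6)
        cfg = GwasSimConfig(theta=0.3, m_snps=40, hx2=0.1, pi_invalid=0.3,
                            pleio_mean=0.08, pleio_sd=0.016,
                            effect_dist="uniform")
        wm, iv = [], []
        for _ in range(300):
            h, _ = simulate_harmonized(cfg, rng)
            tj, _ = _ratios(h)
            wm.append(_weighted_median_point(tj, h.beta_x ** 2 / h.se_y ** 2))
            iv.append(m.ivw(h).estimate)
        wm, iv = np.array(wm), np.array(iv)
        # weighted median stays within twice its own sampling SD of truth
        assert abs(wm.mean() - 0.3) < 2 * wm.std(ddof=1)
        # while IVW is biased by many times that spread
        assert abs(iv.mean() - 0.3) > 5 * wm.std(ddof=1)


class TestContaminationMixture:
    def test_consensus_case(self):
        rng = np.random.default_rng(7)
        bx = rng.uniform(0.1, 0.3, 6)
        h = make_harmonized(bx, np.full(6, 0.002), 0.4 * bx)
        est = m.contamination_mixture(h)
        assert est.estimate == pytest.approx(0.4, abs=0.01)
        assert est.valid_fraction == 1.0
        assert len(est.ci_intervals) == 1

    def test_profile_matches_per_grid_recomputation(self, five_variant_set):
        h = five_variant_set
        ratios, ratio_se = _ratios(h)
        psi = 1.5 * np.std(ratios, ddof=1)
        grid = np.linspace(-1, 2, 301)
        ll_oracle = []
        for g in grid:
            total = 0.0
            for j in range(h.k):
                lv = stats.norm.logpdf(ratios[j], g, ratio_se[j])
                li = stats.norm.logpdf(ratios[j], 0,
                                       np.sqrt(ratio_se[j] ** 2 + psi ** 2))
                total += max(lv, li)
            ll_oracle.append(total)
        est = m.contamination_mixture(h, psi=psi, grid=grid)
        assert est.estimate == pytest.approx(grid[int(np.argmax(ll_oracle))])

    def test_two_clusters_give_disjoint_ci(self):
        bx = np.full(8, 0.2)
        by = np.concatenate([np.zeros(4), 0.2 * np.ones(4)])
        by += np.array([-1, 1, -1, 1, -1, 1, -1, 1]) * 1e-4
        h = make_harmonized(bx, np.full(8, 0.002), by)
        # psi wide enough that the invalid model is near-flat over both
        # clusters; otherwise the zero-centered invalid term breaks the tie
        est = m.contamination_mixture(h, psi=5.0,
                                      grid=np.linspace(-0.5, 1.5, 2001))
        assert len(est.ci_intervals) >= 2
        assert est.ci_intervals[0][1] < est.ci_intervals[-1][0]

    def test_boundary_maximum_raises(self):
        h = make_harmonized([0.2, 0.2, 0.2], [0.002, 0.002, 0.002],
                            [0.08, 0.081, 0.079])
        with pytest.raises(BoundaryError):
            m.contamination_mixture(h, grid=np.linspace(1.0, 2.0, 50))


class TestMRPresso:
    def test_global_test_calibrated_on_clean_data(self):
        """Clean simulations: global p > 0.05 in >= 90% of replicates."""
        rng = np.random.default_rng(8)
        cfg = GwasSimConfig(theta=0.3, m_snps=20, hx2=0.03)
        n_ok = 0
        for _ in range(200):
            h, _ = simulate_harmonized(cfg, rng)
            est = m.mr_presso(h, n_sim=200, seed=int(rng.integers(2 ** 31)))
            n_ok += est.global_pval > 0.05
        assert n_ok >= 180

    def test_planted_outlier_flagged_and_corrected(self):
        cfg = GwasSimConfig(theta=0.3, m_snps=50, hx2=0.03, seed=9)
        h, _ = simulate_harmonized(cfg)
        h.beta_y[4] = 10 * 0.3 * h.beta_x[4]  # gross ratio outlier, tiny SE
        est = m.mr_presso(h, n_sim=2000, seed=1)
        assert est.outlier_ids == [h.variant_ids[4]]
        assert est.n_variants == 49  # outlier-corrected IVW
        # all simulated RSS sit below the observed one: floor convention
        assert est.global_pval == pytest.approx(1 / 2001)

    def test_needs_four_variants(self):
        with pytest.raises(InsufficientInstrumentsError):
            m.mr_presso(make_harmonized([0.1, 0.2, 0.3], [0.01] * 3,
                                        [0.05, 0.1, 0.15]))


class TestInstrumentStrength:
    def test_arithmetic_single_variant(self):
        h = make_harmonized([0.02], [0.01], [0.0], se_x=[0.01],
                            n_exposure=1000)
        s = m.instrument_strength(h)
        assert s.F[0] == pytest.approx(4.0)
        assert s.r2[0] == pytest.approx(4 / (4 + 998))

    def test_single_variant_overall_f_consistent(self):
        h = make_harmonized([0.06], [0.01], [0.0], se_x=[0.01],
                            n_exposure=1000)
        s = m.instrument_strength(h)
        r2 = s.total_r2
        assert s.overall_F == pytest.approx(r2 * (1000 - 2) / (1 - r2))

    def test_totals_equal_brute_force(self):
        rng = np.random.default_rng(10)
        bx = rng.uniform(0.02, 0.1, 10)
        sx = rng.uniform(0.005, 0.02, 10)
        h = make_harmonized(bx, np.full(10, 0.01), np.zeros(10), se_x=sx,
                            n_exposure=50_000)
        s = m.instrument_strength(h)
        t2 = [(bx[j] / sx[j]) ** 2 for j in range(10)]
        r2 = [t / (t + 50_000 - 2) for t in t2]
        assert s.total_r2 == pytest.approx(sum(r2), abs=1e-14)
        assert s.mean_F == pytest.approx(np.mean(t2), abs=1e-10)


class TestSteiger:
    def test_equal_correlations_not_flagged(self):
        h = make_harmonized([0.1], [0.02], [0.1], se_x=[0.02],
                            n_exposure=10_000, n_outcome=10_000)
        res, kept = m.steiger_filter(h)
        assert res.z[0] == pytest.approx(0.0, abs=1e-12)
        assert not res.flagged[0]
        assert kept.k == 1

    def test_outcome_dominant_variant_flagged(self):
        # t_y >> t_x at n = 100k each
        h = make_harmonized([0.01], [0.02], [2.0], se_x=[0.02],
                            n_exposure=100_000, n_outcome=100_000)
        res, kept = m.steiger_filter(h)
        assert res.flagged[0]
        assert kept.k == 0 or kept.dropped  # variant removed

    def test_z_matches_direct_fisher_recomputation(self):
        rng = np.random.default_rng(11)
        bx = rng.uniform(0.02, 0.1, 5)
        by = rng.uniform(0.0, 0.05, 5)
        h = make_harmonized(bx, np.full(5, 0.01), by, se_x=np.full(5, 0.01),
                            n_exposure=40_000, n_outcome=90_000)
        res, _ = m.steiger_filter(h)
        for j in range(5):
            tx, ty = abs(bx[j]) / 0.01, abs(by[j]) / 0.01
            rx = tx / np.sqrt(tx ** 2 + 40_000 - 2)
            ry = ty / np.sqrt(ty ** 2 + 90_000 - 2)
            z = (np.arctanh(rx) - np.arctanh(ry)) / np.sqrt(
                1 / (40_000 - 3) + 1 / (90_000 - 3))
            assert res.z[j] == pytest.approx(z, abs=1e-12)


class TestReverseMR:
    def test_pipeline_identical_to_manual_chain(self):
        cfg = GwasSimConfig(theta=0.2, m_snps=25, hx2=0.05,
                            n_exposure=32_860, n_outcome=115_000, seed=12)
        sim = simulate_two_sample_gwas(cfg)
        est = m.reverse_mr(sim.exposure, sim.outcome, sim.ld)
        inst = m.select_instruments(sim.exposure, sim.ld)
        h = m.harmonize(sim.exposure, sim.outcome, inst, ld=sim.ld)
        manual = m.ivw(h)
        assert est.estimate == manual.estimate
        assert est.se == manual.se

    def test_recovers_forward_effect(self):
        """Liver fat -> metabolite effect of 0.2 recovered within 2 SE."""
        cfg = GwasSimConfig(theta=0.2, m_snps=25, hx2=0.05,
                            n_exposure=32_860, n_outcome=115_000, seed=13)
        sim = simulate_two_sample_gwas(cfg)
        est = m.reverse_mr(sim.exposure, sim.outcome, sim.ld)
        assert abs(est.estimate - 0.2) < 2 * est.se


class TestEquivariance:
    def test_scale_equivariance_of_outcome(self, five_variant_set):
        """Scaling beta_y, se_y by c scales every estimate and SE by c."""
        h = five_variant_set
        c = 3.7
        h2 = make_harmonized(h.beta_x, c * h.se_y, c * h.beta_y,
                             se_x=h.se_x)
        for f in (m.ivw, m.mr_egger):
            a, b = f(h), f(h2)
            assert b.estimate == pytest.approx(c * a.estimate)
            assert b.se == pytest.approx(c * a.se)
        a = m.weighted_median(h, n_boot=200, seed=3)
        b = m.weighted_median(h2, n_boot=200, seed=3)
        assert b.estimate == pytest.approx(c * a.estimate)
        assert b.se == pytest.approx(c * a.se)

    def test_sign_equivariance_of_exposure_alleles(self, five_variant_set):
        """Flipping every exposure effect allele leaves estimates unchanged."""
        h = five_variant_set
        h2 = make_harmonized(-h.beta_x, h.se_y, -h.beta_y, se_x=h.se_x)
        assert m.ivw(h2).estimate == pytest.approx(m.ivw(h).estimate)
        assert m.mr_egger(h2).estimate == pytest.approx(m.mr_egger(h).estimate)
        a = m.weighted_median(h, n_boot=100, seed=4)
        b = m.weighted_median(h2, n_boot=100, seed=4)
        assert b.estimate == pytest.approx(a.estimate)

    def test_estimators_agree_without_pleiotropy(self):
        """All estimators cover the truth on clean simulated data."""
        rng = np.random.default_rng(14)
        cfg = GwasSimConfig(theta=0.4, m_snps=30, hx2=0.05,
                            n_outcome=115_000)
        hits = {"ivw": 0, "egger": 0, "weighted_median": 0,
                "contamination_mixture": 0, "mr_presso": 0}
        n_rep = 150
        for _ in range(n_rep):
            h, _ = simulate_harmonized(cfg, rng)
            for name, est in (
                    ("ivw", m.ivw(h)),
                    ("egger", m.mr_egger(h)),
                    ("weighted_median", m.weighted_median(
                        h, n_boot=200, seed=int(rng.integers(2 ** 31)))),
                    ("contamination_mixture", m.contamination_mixture(h)),
                    ("mr_presso", m.mr_presso(
                        h, n_sim=200, seed=int(rng.integers(2 ** 31))))):
                hits[name] += est.ci_low <= 0.4 <= est.ci_high
        for name, n_hit in hits.items():
            assert n_hit / n_rep >= 0.90, name
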