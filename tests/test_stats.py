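"""Statistics tests: t-tests, Bayes factors, reliability, Deming, full report."""

import math

import numpy as np
import pingouin as pg
import pytest
from scipy import optimize, stats

from beltquest import (
    DegenerateDataError,
    DomainError,
    ParameterError,
    PopulationSpec,
    ProtocolConfig,
    QuestParams,
    StructureError,
    StudyResult,
    VirtualObserver,
    analyze_study,
    deming_fit,
    interval_bf,
    jzs_ttest_bf,
    paired_t,
    pearson_bf,
    pearson_with_bf,
    r_max,
    rmax_interval,
    run_block,
    run_study,
    sample_population,
)
from beltquest import test_r_vs_rmax as compare_r_to_ceiling
from beltquest.session import _summarize_block
from beltquest.stats import BF_MAX, _corr_loglike, _stretched_beta_logpdf


class TestPairedT:
    def test_identical_pairs(self):
        res = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_closed_form(self, rng):
        x = rng.normal(0.5, 1.0, 20)
        y = rng.normal(0.0, 1.0, 20)
        d = x - y
        expected_t = d.mean() * math.sqrt(20) / d.std(ddof=1)
        res = paired_t(x, y)
        assert res.statistic == pytest.approx(expected_t, rel=1e-12)
        assert res.df == 19
        # cross-check p against scipy's own paired test
        sp = stats.ttest_rel(x, y)
        assert res.p_value == pytest.approx(sp.pvalue, rel=1e-9)

    def test_too_few_pairs(self):
        with pytest.raises(DegenerateDataError):
            paired_t([1.0, 2.0], [0.0, 1.0])


class TestJZS:
    def test_null_favoured_at_t_zero(self):
        for n in (2, 5, 48):
            for scale in (0.707, 1.0):
                assert jzs_ttest_bf(0.0, n, scale) < 1.0

    def test_monotone_in_abs_t(self):
        bfs = [jzs_ttest_bf(t, 30) for t in (0.0, 0.5, 1.0, 2.0, 4.0)]
        assert all(b2 > b1 for b1, b2 in zip(bfs, bfs[1:]))

    def test_sign_invariance(self):
        assert jzs_ttest_bf(-1.3, 25) == pytest.approx(jzs_ttest_bf(1.3, 25), rel=1e-9)

    def test_against_riemann_grid_oracle(self):
        """Adaptive quadrature vs a plain fixed-grid Riemann sum."""
        rng = np.random.default_rng(2)
        for _ in range(10):
            t = float(rng.uniform(-3, 3))
            n = int(rng.integers(5, 80))
            d = np.linspace(-8, 8, 160_001)
            integrand = stats.nct.pdf(t, n - 1, d * math.sqrt(n)) * stats.cauchy.pdf(d, 0, 0.707)
            grid_bf = np.trapezoid(integrand, d) / stats.t.pdf(t, n - 1)
            assert jzs_ttest_bf(t, n) == pytest.approx(grid_bf, rel=1e-4)

    def test_against_pingouin(self):
        for t, n in [(0.34, 48), (1.96, 48), (-2.5, 20)]:
            assert jzs_ttest_bf(t, n) == pytest.approx(
                float(pg.bayesfactor_ttest(t, n, paired=True, r=0.707)), rel=1e-6
            )

    def test_invalid_inputs(self):
        with pytest.raises(ParameterError):
            jzs_ttest_bf(float("inf"), 10)
        with pytest.raises(ParameterError):
            jzs_ttest_bf(1.0, 1)


class TestPearsonBF:
    def test_against_pingouin_closed_form(self):
        """Quadrature vs the analytic hypergeometric solution."""
        for r, n in [(-0.28, 96), (-0.36, 48), (0.1, 20), (0.6, 15)]:
            assert pearson_bf(r, n, 0.333) == pytest.approx(
                float(pg.bayesfactor_pearson(r, n, method="ly", kappa=0.333)), rel=1e-6
            )

    def test_against_riemann_grid_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            r = float(rng.uniform(-0.7, 0.7))
            n = int(rng.integers(6, 100))
            rho = np.linspace(-0.9999, 0.9999, 200_001)
            f = np.exp(_corr_loglike(r, n, rho) + _stretched_beta_logpdf(rho, 1 / 0.333))
            grid_bf = np.trapezoid(f, rho) / math.exp(_corr_loglike(r, n, 0.0))
            assert pearson_bf(r, n) == pytest.approx(grid_bf, rel=1e-4)

    def test_from_data(self, rng):
        x = rng.normal(size=40)
        y = 0.5 * x + rng.normal(size=40)
        res = pearson_with_bf(x, y)
        assert res.r == pytest.approx(float(np.corrcoef(x, y)[0, 1]), rel=1e-12)
        expected_t = res.r * math.sqrt(38) / math.sqrt(1 - res.r**2)
        assert res.test.statistic == pytest.approx(expected_t, rel=1e-12)
        assert res.test.bf10 == pytest.approx(pearson_bf(res.r, 40), rel=1e-9)

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateDataError):
            pearson_with_bf([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = pearson_with_bf(x, 2 * x + 1)
        assert res.test.bf10 == BF_MAX  # perfect correlation, overflow-guarded


class TestAttenuation:
    def test_worked_example(self):
        assert round(r_max(0.48, 0.57), 2) == 0.52

    def test_limits(self):
        assert r_max(1.0, 1.0) == 1.0
        assert r_max(0.0, 0.73) == 0.0

    def test_negative_reliability_rejected(self):
        with pytest.raises(DomainError):
            r_max(-0.1, 0.5)

    def test_comparison_zero_when_equal(self):
        assert compare_r_to_ceiling(0.5, 0.5, 48).statistic == 0.0

    def test_comparison_matches_stated_formula(self):
        res = compare_r_to_ceiling(0.46, 0.52, 48)
        expected = (0.46 - 0.52) * math.sqrt(46) / math.sqrt(1 - 0.46**2)
        assert res.statistic == pytest.approx(expected, rel=1e-12)
        assert res.statistic == pytest.approx(-0.46, abs=0.005)
        assert res.df == 46

    def test_antisymmetry(self):
        a = compare_r_to_ceiling(0.4, 0.6, 30).statistic
        b = compare_r_to_ceiling(0.6, 0.4, 30).statistic
        # swapping which value is larger flips the sign (magnitudes differ
        # because the standard error follows r_obs)
        assert a < 0 < b

    def test_rmax_interval_brackets_point(self):
        lo, hi = rmax_interval(0.48, 0.57, 48)
        assert lo < r_max(0.48, 0.57) < hi


class TestIntervalBF:
    def test_prior_identity_without_data(self):
        a = 1 / 0.333
        edge = 2 * stats.beta.ppf(0.75, a, a) - 1  # central 50% prior mass
        assert interval_bf(0.0, 0, (-edge, edge)) == pytest.approx(1.0, rel=1e-9)

    def test_near_full_interval_is_conclusive(self):
        assert interval_bf(0.3, 40, (-0.9, 0.9)) > 1e3

    def test_against_grid_oracle(self):
        r_obs, n, interval = 0.46, 48, (0.35, 0.68)
        a = 1 / 0.333
        rho = np.linspace(-0.999999, 0.999999, 1_000_001)
        post = np.exp(_corr_loglike(r_obs, n, rho) + _stretched_beta_logpdf(rho, a))
        inside = (rho >= interval[0]) & (rho <= interval[1])
        p_in = np.trapezoid(post[inside], rho[inside]) / np.trapezoid(post, rho)
        m_in = stats.beta.cdf((interval[1] + 1) / 2, a, a) - stats.beta.cdf((interval[0] + 1) / 2, a, a)
        expected = (p_in / (1 - p_in)) / (m_in / (1 - m_in))
        got = interval_bf(r_obs, n, interval)
        assert got == pytest.approx(expected, rel=0.01)
        assert got > 1.0  # r_obs near the interval: evidence for "inside"

    def test_invalid_interval(self):
        with pytest.raises(ParameterError):
            interval_bf(0.2, 20, (0.5, 0.2))
        with pytest.raises(ParameterError):
            interval_bf(0.2, 20, (-2.0, 0.5))


class TestDeming:
    def test_collinear_exact(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        fit = deming_fit(x, 2.5 * x - 1.0)
        assert fit.slope == pytest.approx(2.5, rel=1e-12)
        assert fit.intercept == pytest.approx(-1.0, rel=1e-9)

    def test_equal_variance_cloud_gives_unit_slope(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = np.array([0.0, 2.0, 1.0, 3.0])  # var(x) == var(y), cov > 0
        assert deming_fit(x, y, lam=1.0).slope == pytest.approx(1.0, rel=1e-12)

    def test_lambda_to_infinity_recovers_ols(self, rng):
        x = rng.normal(size=50)
        y = 1.7 * x + rng.normal(scale=0.5, size=50)
        ols = float(np.polyfit(x, y, 1)[0])
        assert deming_fit(x, y, lam=1e9).slope == pytest.approx(ols, rel=1e-6)

    def test_matches_numerical_perpendicular_least_squares(self, rng):
        x = rng.normal(size=40)
        y = 0.8 * x + rng.normal(scale=0.7, size=40)
        lam = 1.3
        fit = deming_fit(x, y, lam=lam)

        def objective(p):
            a, b = p
            return np.sum((y - a - b * x) ** 2 / (lam + b**2))

        res = optimize.minimize(objective, [0.0, 1.0], method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-14})
        assert fit.slope == pytest.approx(res.x[1], abs=1e-6)
        assert fit.intercept == pytest.approx(res.x[0], abs=1e-6)

    def test_degenerate_cloud_rejected(self, rng):
        x = np.array([0.0, 1.0, 0.0, 1.0])
        y = np.array([0.0, 0.0, 1.0, 1.0])  # zero covariance, equal variances
        with pytest.raises(DegenerateDataError):
            deming_fit(x, y, lam=1.0)


def _study_with_replayed_blocks(n=8, trials=20):
    """Study whose two blocks per type are identical replicates: the second
    block re-runs with the same RNG state, so block noise is frozen."""
    import pandas as pd

    pop = sample_population(PopulationSpec(n=n, seed=42))
    params, protocol = QuestParams(), ProtocolConfig(trials_per_block=trials)
    rows, blocks = [], {}
    for pid, obs in enumerate(pop):
        bidx = 0
        for rep_pair, direction in enumerate(("increase", "decrease")):
            for rep in (1, 2):
                bidx += 1
                block = run_block(obs, direction, params, protocol,
                                  np.random.default_rng(1000 + pid * 2 + rep_pair),
                                  n_trials=trials)
                blocks[(pid, bidx)] = block
                rows.append(_summarize_block(pid, bidx, rep, block, protocol))
    return StudyResult(table=pd.DataFrame(rows), blocks=blocks)


class TestAnalyzeStudy:
    def test_frozen_noise_gives_perfect_reliability(self):
        report = analyze_study(_study_with_replayed_blocks())
        rel = report["stability"]["reliability"]
        assert rel["r11"] == pytest.approx(1.0, abs=1e-12)
        assert rel["r22"] == pytest.approx(1.0, abs=1e-12)
        assert rel["r_max"] == pytest.approx(1.0, abs=1e-12)
        for direction in ("increase", "decrease"):
            assert report["stability"]["block_difference"][direction]["statistic"] == 0.0

    def test_percentile_factor_matches_lognormal_quantiles(self, rng):
        sigma = 0.59
        col = np.exp(rng.normal(math.log(7.0), sigma, size=2000))
        p5, p95 = np.percentile(col, [5, 95])
        assert p95 / p5 == pytest.approx(math.exp(2 * 1.645 * sigma), rel=0.15)

    def test_observed_cross_correlation_tracks_attenuation_ceiling(self):
        """With near-perfect latent coupling between types, the observed
        cross-type correlation sits inside the Monte-Carlo band of
        sqrt(r11 * r22) over replications."""
        r12s, ceilings = [], []
        for rep in range(30):
            pop = sample_population(PopulationSpec(n=24, rho_types=0.98, seed=300 + rep))
            study = run_study(pop, QuestParams(), ProtocolConfig(trials_per_block=25),
                              rng=900 + rep)
            rel = analyze_study(study)["stability"]["reliability"]
            r12s.append(rel["r12"]["r"])
            ceilings.append(rel["r_max"])
        band = 2 * np.std(r12s, ddof=1)
        assert abs(np.mean(r12s) - np.mean(ceilings)) < band

    def test_missing_block_structure_rejected(self):
        study = _study_with_replayed_blocks(n=4)
        broken = StudyResult(table=study.table.iloc[:-1], blocks=study.blocks)
        with pytest.raises(StructureError):
            analyze_study(broken)

    def test_report_is_json_serializable(self):
        import json

        report = analyze_study(_study_with_replayed_blocks(n=6))
        json.dumps(report)
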