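"""Linear MR estimators against brute-force oracles and algebraic identities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vitdmr import linear_mr as mr

from conftest import make_harmonized

TOY = make_harmonized(
    bx=[1.0, 0.8, 1.2, 0.9, 1.1],
    sx=[0.05, 0.04, 0.06, 0.05, 0.05],
    by=[0.50, 0.44, 0.54, 0.40, 0.60],
    sy=[0.10, 0.08, 0.12, 0.09, 0.11],
)


class TestWaldRatios:
    def test_unit_and_scaled_divisor(self):
        h = make_harmonized([1.0, 2.0], [0.1, 0.1], [0.5, 1.0], [0.1, 0.2])
        r = mr.wald_ratios(h)
        np.testing.assert_allclose(r["ratio"], [0.5, 0.5])
        np.testing.assert_allclose(r["se"], [0.1, 0.1])

    def test_zero_exposure_beta_rejected(self):
        with pytest.raises(ValueError, match="zero exposure beta"):
            mr.wald_ratios(make_harmonized([0.0, 1.0], [0.1, 0.1],
                                           [0.1, 0.1], [0.1, 0.1]))

    def test_delta_se_matches_monte_carlo(self):
        """First-order SE agrees with the simulated ratio SD for strong
        instruments (|beta_x|/se_x = 20)."""
        rng = np.random.default_rng(0)
        bx, sx, by, sy = 1.0, 0.05, 0.5, 0.1
        draws = rng.normal(by, sy, 100_000) / rng.normal(bx, sx, 100_000)
        delta = sy / abs(bx)
        assert np.std(draws) == pytest.approx(delta, rel=0.10)


class TestEstimators:
    def test_degenerate_consensus(self):
        h = make_harmonized([1.0, 2.0, 0.5, 1.5], [0.01] * 4,
                            [0.5, 1.0, 0.25, 0.75], [0.1, 0.2, 0.05, 0.15])
        for method in ("ivw_re", "weighted_median", "weighted_mode"):
            res = mr.estimate(h, method, n_boot=100, seed=1)
            assert res.estimate == pytest.approx(0.5, abs=1e-6)
        assert mr.estimate(h, "ivw_re").cochran_q == pytest.approx(0.0, abs=1e-20)

    def test_single_variant_ivw_equals_wald(self):
        h = make_harmonized([2.0], [0.1], [1.0], [0.3])
        res = mr.estimate(h, "ivw_re")
        assert res.estimate == pytest.approx(0.5)
        assert res.se == pytest.approx(0.15)

    def test_ivw_equal_ses_is_plain_mean(self):
        h = make_harmonized([1.0, 1.0, 1.0], [0.0] * 3, [0.1, 0.5, 0.9], [0.2] * 3)
        res = mr.estimate(h, "ivw_re")
        assert res.estimate == pytest.approx(0.5)

    def test_ivw_matches_wls_oracle(self):
        res = mr.estimate(TOY, "ivw_re")
        r = TOY.beta_outcome / TOY.beta_exposure
        w = (TOY.beta_exposure / TOY.se_outcome) ** 2
        oracle = np.sum(w * r) / np.sum(w)
        assert res.estimate == pytest.approx(oracle, abs=1e-8)
        # identical to the no-intercept WLS of by on bx with weights 1/sy^2
        sw = 1.0 / TOY.se_outcome.to_numpy()
        slope = np.linalg.lstsq(
            (TOY.beta_exposure.to_numpy() * sw)[:, None],
            TOY.beta_outcome.to_numpy() * sw, rcond=None,
        )[0][0]
        assert res.estimate == pytest.approx(slope, abs=1e-8)

    def test_egger_matches_wls_oracle(self):
        res = mr.estimate(TOY, "egger")
        sw = 1.0 / TOY.se_outcome.to_numpy()
        X = np.column_stack([np.ones(5), TOY.beta_exposure]) * sw[:, None]
        coef, *_ = np.linalg.lstsq(X, TOY.beta_outcome.to_numpy() * sw, rcond=None)
        assert res.egger_intercept == pytest.approx(coef[0], abs=1e-8)
        assert res.estimate == pytest.approx(coef[1], abs=1e-8)

    def test_weighted_median_matches_grid_search(self):
        res = mr.estimate(TOY, "weighted_median", n_boot=100, seed=0)
        r = (TOY.beta_outcome / TOY.beta_exposure).to_numpy()
        w = (TOY.beta_exposure / TOY.se_outcome).to_numpy() ** 2
        order = np.argsort(r)
        rs, ws = r[order], w[order]
        pk = (np.cumsum(ws) - 0.5 * ws) / ws.sum()
        grid = np.linspace(rs[0], rs[-1], 2_000_001)
        crossing = grid[np.argmin(np.abs(np.interp(grid, rs, pk) - 0.5))]
        assert res.estimate == pytest.approx(crossing, abs=1e-5)

    def test_too_few_variants(self):
        h = TOY.iloc[:2]
        with pytest.raises(ValueError, match="too few"):
            mr.estimate(h, "egger")
        with pytest.raises(ValueError, match="unknown method"):
            mr.estimate(TOY, "magic")


class TestInvariances:
    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_median_within_ratio_range_and_order_invariant(self, seed):
        rng = np.random.default_rng(seed)
        j = rng.integers(3, 12)
        h = make_harmonized(rng.uniform(0.5, 2.0, j), rng.uniform(0.01, 0.1, j),
                            rng.normal(0.3, 0.4, j), rng.uniform(0.05, 0.3, j))
        res = mr.estimate(h, "weighted_median", n_boot=50, seed=0)
        r = h.beta_outcome / h.beta_exposure
        assert r.min() - 1e-12 <= res.estimate <= r.max() + 1e-12
        perm = h.sample(frac=1, random_state=1).reset_index(drop=True)
        res_p = mr.estimate(perm, "weighted_median", n_boot=50, seed=0)
        assert res_p.estimate == pytest.approx(res.estimate, abs=1e-10)

    def test_unit_rescaling_equivariance(self):
        """Rescaling the exposure from nmol/L to 10-nmol/L units divides all
        estimates by 10 (exact scaling law)."""
        scaled = TOY.copy()
        scaled["beta_exposure"] *= 10
        scaled["se_exposure"] *= 10
        for method in ("ivw_re", "egger", "weighted_median"):
            a = mr.estimate(TOY, method, n_boot=200, seed=3)
            b = mr.estimate(scaled, method, n_boot=200, seed=3)
            assert b.estimate == pytest.approx(a.estimate / 10, rel=1e-9)
            assert b.se == pytest.approx(a.se / 10, rel=1e-6)
        a = mr.estimate(TOY, "weighted_mode", n_boot=200, seed=3)
        b = mr.estimate(scaled, "weighted_mode", n_boot=200, seed=3)
        assert b.estimate == pytest.approx(a.estimate / 10, rel=1e-6)

    def test_egger_without_intercept_reduces_to_fixed_effect_ivw(self):
        """Algebraic identity: constraining the Egger intercept to zero gives
        the fixed-effect IVW estimate."""
        sw = 1.0 / TOY.se_outcome.to_numpy()
        slope = np.linalg.lstsq(
            (TOY.beta_exposure.to_numpy() * sw)[:, None],
            TOY.beta_outcome.to_numpy() * sw, rcond=None,
        )[0][0]
        r = TOY.beta_outcome / TOY.beta_exposure
        w = (TOY.beta_exposure / TOY.se_outcome) ** 2
        ivw_fixed = np.sum(w * r) / np.sum(w)
        assert slope == pytest.approx(ivw_fixed, abs=1e-10)


class TestPresso:
    def test_guards(self):
        with pytest.raises(ValueError, match="at least 4"):
            mr.mr_presso(TOY.iloc[:3])
        with pytest.raises(ValueError, match="n_sim"):
            mr.mr_presso(TOY, n_sim=10)

    def test_displaced_variant_flagged_and_corrected(self):
        rng = np.random.default_rng(5)
        j, beta = 20, -0.05
        bx = rng.uniform(0.5, 2.0, j)
        sx = np.full(j, 0.02)
        sy = np.full(j, 0.05)
        by = beta * bx + rng.normal(0, sy)
        by[0] += 10 * sy[0]
        h = make_harmonized(bx, sx, by, sy)
        res = mr.mr_presso(h, n_sim=500, seed=0)
        assert res.outlier_flags[0]
        assert res.global_p < 0.05
        # corrected estimate equals the IVW of the unflagged variants exactly
        clean = mr.estimate(h[~res.outlier_flags], "ivw_re")
        assert res.corrected.estimate == pytest.approx(clean.estimate, abs=1e-12)
        # removing the planted outlier cancels its pull on the estimate
        naive = mr.estimate(h, "ivw_re").estimate
        assert abs(res.corrected.estimate - clean.estimate) < abs(naive - clean.estimate)

    def test_null_not_flagged(self):
        rng = np.random.default_rng(6)
        j, beta = 20, -0.05
        bx = rng.uniform(0.5, 2.0, j)
        by = beta * bx + rng.normal(0, 0.05, j)
        h = make_harmonized(bx, np.full(j, 0.02), by, np.full(j, 0.05))
        res = mr.mr_presso(h, n_sim=500, seed=0)
        assert res.global_p > 0.05
        assert not res.outlier_flags.any()


class TestStratified:
    def test_guards(self, small_cohort):
        panel, cohort = small_cohort
        with pytest.raises(ValueError, match="empty|zero events"):
            mr.stratified_estimate(cohort, panel,
                                   strata_bounds=(300.0, 400.0),
                                   n_boot=50)
        with pytest.raises(ValueError, match="at least one stratum"):
            mr.stratified_estimate(cohort, panel, strata_bounds=(0.0,), n_boot=50)

    def test_null_world_covers_null(self):
        from vitdmr.simulate import SimParams
        from vitdmr import simulate as simmod

        params = SimParams(n_individuals=30_000, causal_slope_below_knot=0.0,
                           confounder_effect_outcome=0.0, baseline_hazard=5e-3,
                           seed=13)
        panel = simmod.simulate_panel(params)
        cohort = simmod.simulate_cohort(panel, params)
        strat = mr.stratified_estimate(cohort, panel, methods=("ivw_re",),
                                       strata_bounds=(0.0, 50.0, np.inf),
                                       n_boot=50, seed=0)
        for v in strat.values():
            res = v["results"]["ivw_re"]
            assert res.ci_low < 0.0 < res.ci_high
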