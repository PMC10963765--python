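"""Estimator suite: point estimates against independent oracles, dispatch
contract, sensitivity diagnostics, instrument strength and power."""

import numpy as np
import pytest
from scipy import stats

from mrphewas.estimators import (
    InsufficientInstrumentsError,
    cochran_q,
    dispatch_estimators,
    egger_regression,
    filter_weak_instruments,
    instrument_strength,
    ivw_random_effects,
    mode_based,
    mr_power,
    per_snp_diagnostics,
    steiger_direction,
    wald_ratio,
    weighted_median,
)
from mrphewas.io_summary import InputError

from conftest import make_hset


def wls_oracle(X, y, w):
    """Generic weighted-least-squares via the normal equations."""
    Xw = X * w[:, None]
    return np.linalg.solve(X.T @ Xw, Xw.T @ y)


class TestWaldRatio:
    def test_arithmetic(self):
        e = wald_ratio(0.2, 0.01, 0.1, 0.05)
        assert e.beta == pytest.approx(0.5)
        assert e.se == pytest.approx(0.25)

    def test_zero_outcome_effect(self):
        assert wald_ratio(0.2, 0.01, 0.0, 0.05).beta == 0.0

    def test_pvalue_is_two_sided_normal_tail(self):
        e = wald_ratio(0.1, 0.01, 0.05, 0.01)
        z = e.beta / e.se
        assert e.pvalue == pytest.approx(2 * (1 - stats.norm.cdf(abs(z))), rel=1e-12)

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(InputError):
            wald_ratio(0.0, 0.01, 0.1, 0.05)

    def test_or_sd_is_exp_beta(self):
        e = wald_ratio(0.2, 0.01, 0.1, 0.05)
        assert e.or_sd == pytest.approx(np.exp(e.beta))
        assert e.ci_low < e.beta < e.ci_high


class TestIVW:
    def test_exact_proportionality(self):
        h = make_hset([1, 1], [0.1, 0.1], [2, 2], [1, 1])
        assert ivw_random_effects(h).beta == pytest.approx(2.0)

    def test_three_instrument_closed_form(self, spec_triple_hset):
        # w = (100, 25, 100): beta = 79 / 141
        est = ivw_random_effects(spec_triple_hset)
        assert est.beta == pytest.approx(79 / 141, rel=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_wls_oracle(self, seed):
        rng = np.random.default_rng(seed)
        j = int(rng.integers(3, 21))
        b_x = rng.normal(0.1, 0.05, j)
        b_y = rng.normal(0.03, 0.05, j)
        s_y = rng.uniform(0.01, 0.1, j)
        h = make_hset(b_x, np.full(j, 0.01), b_y, s_y)
        oracle = wls_oracle(b_x[:, None], b_y, 1 / s_y**2)[0]
        assert ivw_random_effects(h).beta == pytest.approx(oracle, rel=1e-10)

    def test_fixed_effect_se_when_floor_binds(self):
        # exact proportionality: Q = 0 -> sigma floored at 1
        h = make_hset([0.5, 1.0, 1.5], [0.01] * 3,
                      [0.2, 0.4, 0.6], [0.1, 0.1, 0.1])
        est = ivw_random_effects(h)
        w = 1 / np.array([0.1] * 3) ** 2
        se_fixed = 1 / np.sqrt(np.sum(w * np.array([0.5, 1.0, 1.5]) ** 2))
        assert est.se == pytest.approx(se_fixed, rel=1e-12)

    def test_single_instrument_raises(self):
        with pytest.raises(InsufficientInstrumentsError):
            ivw_random_effects(make_hset([1], [0.1], [2], [1]))


class TestCochranQ:
    def test_exact_proportionality_gives_zero(self):
        h = make_hset([0.5, 1.0], [0.01] * 2, [0.15, 0.3], [0.1, 0.1])
        q, df, p = cochran_q(h, 0.3)
        assert q == pytest.approx(0.0, abs=1e-20)
        assert df == 1

    def test_spec_triple_value(self, spec_triple_hset):
        beta = ivw_random_effects(spec_triple_hset).beta
        q, df, _ = cochran_q(spec_triple_hset, beta)
        assert q == pytest.approx(1.7376, abs=2e-4)
        assert df == 2

    def test_scaling_law(self, spec_triple_hset):
        h2 = make_hset(
            spec_triple_hset.data["beta_x"], spec_triple_hset.data["se_x"],
            spec_triple_hset.data["beta_y"], 2 * spec_triple_hset.data["se_y"],
        )
        q1, _, _ = cochran_q(spec_triple_hset, 0.5)
        q2, _, _ = cochran_q(h2, 0.5)
        assert q2 == pytest.approx(q1 / 4, rel=1e-12)


class TestWeightedMedian:
    def test_equal_weights_reduce_to_simple_median(self):
        h = make_hset([1, 1, 1], [0.01] * 3, [0.1, 0.2, 0.3], [1, 1, 1])
        est = weighted_median(h, n_boot=50, seed=0)
        assert est.beta == pytest.approx(0.2)

    def test_degenerate_all_equal(self):
        h = make_hset([1, 1, 1], [1e-6] * 3, [0.4, 0.4, 0.4], [1e-6] * 3)
        est = weighted_median(h, n_boot=200, seed=0)
        assert est.beta == pytest.approx(0.4)
        assert est.se < 1e-4

    def test_matches_cumulative_weight_oracle(self):
        rng = np.random.default_rng(5)
        j = 10
        b_x = rng.uniform(0.05, 0.2, j)
        b_y = b_x * rng.choice([0.1, 0.1, 0.1, 0.8], j)
        s_y = rng.uniform(0.01, 0.05, j)
        h = make_hset(b_x, np.full(j, 0.01), b_y, s_y)
        est = weighted_median(h, n_boot=50, seed=1)
        # independent evaluation of the interpolation formula
        ratio = b_y / b_x
        w = b_x**2 / s_y**2
        order = np.argsort(ratio)
        r, wt = ratio[order], w[order]
        s = (np.cumsum(wt) - 0.5 * wt) / wt.sum()
        k = np.searchsorted(s, 0.5)
        expected = r[k - 1] + (r[k] - r[k - 1]) * (0.5 - s[k - 1]) / (s[k] - s[k - 1])
        assert est.beta == pytest.approx(expected, rel=1e-12)

    def test_bootstrap_reproducible(self, random_hset):
        a = weighted_median(random_hset, n_boot=100, seed=9)
        b = weighted_median(random_hset, n_boot=100, seed=9)
        assert a.se == b.se

    def test_requires_three_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            weighted_median(make_hset([1, 1], [0.1] * 2, [1, 1], [1, 1]),
                            n_boot=10, seed=0)


class TestModeBased:
    def test_point_mass(self):
        h = make_hset([1, 1, 1], [0.01] * 3, [0.4, 0.4, 0.4], [0.1] * 3)
        assert mode_based(h, n_boot=50, seed=0).beta == pytest.approx(0.4)

    def test_robust_to_single_outlier(self):
        rng = np.random.default_rng(2)
        b_x = np.full(10, 1.0)
        b_y = np.concatenate([rng.normal(0.2, 0.005, 9), [5.0]])
        h = make_hset(b_x, np.full(10, 0.01), b_y, np.full(10, 0.05))
        est = mode_based(h, n_boot=50, seed=0)
        mean = np.mean(b_y / b_x)
        assert abs(est.beta - 0.2) < abs(mean - 0.2)

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(11)
        j = 10
        b_x = rng.uniform(0.1, 0.3, j)
        b_y = 0.25 * b_x + rng.normal(0, 0.01, j)
        s_y = rng.uniform(0.02, 0.06, j)
        h = make_hset(b_x, np.full(j, 0.01), b_y, s_y)
        est = mode_based(h, n_boot=50, seed=0)
        # independent fine-grid maximisation of the weighted kernel density
        ratio = b_y / b_x
        w = b_x**2 / s_y**2
        n = len(ratio)
        sd = np.std(ratio, ddof=1)
        mad = stats.median_abs_deviation(ratio, scale="normal")
        bw = 0.9 * min(sd, mad) * n ** (-0.2)
        grid = np.linspace(ratio.min() - 3 * bw, ratio.max() + 3 * bw, 200_001)
        dens = np.zeros_like(grid)
        for r_i, w_i in zip(ratio, w):
            dens += w_i * np.exp(-0.5 * ((grid - r_i) / bw) ** 2)
        oracle = grid[np.argmax(dens)]
        assert est.beta == pytest.approx(oracle, abs=5 * (grid[1] - grid[0]) + 1e-4)

    def test_bootstrap_reproducible(self, random_hset):
        a = mode_based(random_hset, n_boot=100, seed=3)
        b = mode_based(random_hset, n_boot=100, seed=3)
        assert a.se == b.se


class TestEgger:
    def test_exact_line_through_origin(self):
        b_x = np.array([0.2, 0.5, 1.0])
        h = make_hset(b_x, [0.01] * 3, 0.3 * b_x, [0.1] * 3)
        res = egger_regression(h)
        assert res.slope.beta == pytest.approx(0.3, abs=1e-12)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)

    def test_exact_affine_fit(self):
        b_x = np.array([0.2, 0.5, 1.0, 1.5])
        h = make_hset(b_x, [0.01] * 4, 0.05 + 0.3 * b_x, [0.1] * 4)
        res = egger_regression(h)
        assert res.slope.beta == pytest.approx(0.3, abs=1e-10)
        assert res.intercept == pytest.approx(0.05, abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        j = 20
        b_x = np.abs(rng.normal(0.2, 0.1, j)) + 0.01
        b_y = 0.02 + 0.4 * b_x + rng.normal(0, 0.03, j)
        s_y = rng.uniform(0.02, 0.08, j)
        h = make_hset(b_x, np.full(j, 0.01), b_y, s_y)
        res = egger_regression(h)
        X = np.column_stack([np.ones(j), b_x])
        coef = wls_oracle(X, b_y, 1 / s_y**2)
        assert res.intercept == pytest.approx(coef[0], rel=1e-10)
        assert res.slope.beta == pytest.approx(coef[1], rel=1e-10)

    def test_orientation_invariance(self):
        rng = np.random.default_rng(8)
        j = 15
        b_x = rng.normal(0.2, 0.1, j)
        b_y = 0.02 + 0.4 * b_x + rng.normal(0, 0.03, j)
        h1 = make_hset(b_x, np.full(j, 0.01), b_y, np.full(j, 0.05))
        flip = rng.random(j) < 0.5
        sgn = np.where(flip, -1.0, 1.0)
        h2 = make_hset(b_x * sgn, np.full(j, 0.01), b_y * sgn, np.full(j, 0.05))
        r1, r2 = egger_regression(h1), egger_regression(h2)
        assert r1.slope.beta == pytest.approx(r2.slope.beta)
        assert r1.intercept == pytest.approx(r2.intercept)


class TestSteiger:
    def test_forced_ordering(self):
        h = make_hset([0.1] * 3, [0.01] * 3, [0.01] * 3, [0.01] * 3,
                      eaf=[0.5] * 3, outcome_type="continuous")
        res = steiger_direction(h, n_exp=10_000, n_out=10_000)
        assert res.direction_true
        assert res.r2_exposure > res.r2_outcome

    def test_symmetric_inputs_give_p_one(self):
        h = make_hset([0.1, 0.2], [0.01] * 2, [0.1, 0.2], [0.01] * 2,
                      eaf=[0.3, 0.4], outcome_type="continuous")
        res = steiger_direction(h, n_exp=5_000, n_out=5_000)
        assert not res.direction_true
        assert res.pvalue == pytest.approx(1.0)

    def test_continuous_per_variant_r2(self):
        h = make_hset([0.1], [0.01], [0.0001], [0.01], eaf=[0.5],
                      outcome_type="continuous")
        res = steiger_direction(h, n_exp=10_000, n_out=10_000)
        assert res.r2_exposure == pytest.approx(2 * 0.5 * 0.5 * 0.01)

    def test_binary_outcome_requires_lifetime_risk(self):
        h = make_hset([0.1], [0.01], [0.01], [0.01], outcome_type="binary")
        from mrphewas.io_summary import ConfigurationError

        with pytest.raises(ConfigurationError):
            steiger_direction(h, n_exp=1000, n_out=1000)
        res = steiger_direction(h, n_exp=1000, n_out=1000, lifetime_risk=0.05)
        # K(1-K) scales the outcome-side r2
        assert res.r2_outcome == pytest.approx(
            2 * 0.3 * 0.7 * 0.01**2 * 0.05 * 0.95)


class TestPerSnpDiagnostics:
    def test_counts(self, spec_triple_hset):
        d = per_snp_diagnostics(spec_triple_hset)
        assert (d["analysis"] == "loo").sum() == 3
        assert (d["analysis"] == "single").sum() == 3

    def test_homogeneous_instruments_stable(self):
        rng = np.random.default_rng(4)
        j = 12
        b_x = rng.uniform(0.1, 0.3, j)
        b_y = 0.3 * b_x + rng.normal(0, 0.002, j)
        h = make_hset(b_x, np.full(j, 0.01), b_y, np.full(j, 0.02))
        full = ivw_random_effects(h)
        d = per_snp_diagnostics(h)
        loo = d.loc[d["analysis"] == "loo", "beta"]
        assert ((loo > full.ci_low) & (loo < full.ci_high)).all()

    def test_planted_outlier_dominates_leave_one_out(self):
        rng = np.random.default_rng(6)
        j = 10
        b_x = np.full(j, 0.2)
        b_y = 0.3 * b_x + rng.normal(0, 0.001, j)
        s_y = np.full(j, 0.03)
        b_y[0] = 0.2 * 2.0   # deviant ratio
        s_y[0] = 0.003       # 10x weight
        h = make_hset(b_x, np.full(j, 0.01), b_y, s_y)
        full = ivw_random_effects(h).beta
        d = per_snp_diagnostics(h)
        loo = d.loc[d["analysis"] == "loo"].reset_index(drop=True)
        deltas = (loo["beta"] - full).abs()
        assert deltas.idxmax() == 0


class TestInstrumentStrength:
    def test_f_arithmetic(self):
        h = make_hset([0.1, 0.03], [0.01, 0.01], [0.1, 0.1], [0.1, 0.1])
        s = instrument_strength(h)
        assert s.f[0] == pytest.approx(100.0)
        assert s.f[1] == pytest.approx(9.0)

    def test_weak_instrument_filter(self):
        h = make_hset([0.1, 0.03], [0.01, 0.01], [0.1, 0.1], [0.1, 0.1])
        kept = filter_weak_instruments(h, f_min=10)
        assert kept.n_snp == 1
        assert kept.data.loc[0, "beta_x"] == pytest.approx(0.1)

    def test_f_equals_squared_wald_z(self):
        b, se = 0.07, 0.013
        h = make_hset([b], [se], [0.1], [0.1])
        assert instrument_strength(h).f[0] == pytest.approx((b / se) ** 2)


class TestPower:
    def test_null_effect_gives_alpha(self):
        p = mr_power(10_000, 10_000, pve=0.05, beta=0.0)
        assert p.power == pytest.approx(0.05, abs=1e-10)

    @pytest.mark.parametrize("knob", ["n", "pve", "beta"])
    def test_monotone(self, knob):
        base = dict(n_case=5_000, n_control=5_000, pve=0.02, beta=0.1)
        lo = mr_power(**base).power
        bumped = dict(base)
        if knob == "n":
            bumped["n_case"] = bumped["n_control"] = 20_000
        elif knob == "pve":
            bumped["pve"] = 0.08
        else:
            bumped["beta"] = 0.3
        assert mr_power(**bumped).power >= lo

    def test_saturates(self):
        assert mr_power(50_000, 50_000, pve=1.0, beta=2.0).power > 0.999


class TestDispatchAndEquivariance:
    def test_single_instrument_routes_to_wald(self):
        h = make_hset([0.2], [0.01], [0.1], [0.05])
        out = dispatch_estimators(h)
        assert out["primary"].method == "wald"
        w = wald_ratio(0.2, 0.01, 0.1, 0.05)
        assert out["primary"].beta == pytest.approx(w.beta)

    def test_two_instruments_ivw_only(self):
        h = make_hset([0.2, 0.3], [0.01] * 2, [0.1, 0.15], [0.05] * 2)
        out = dispatch_estimators(h)
        assert out["primary"].method == "ivw_re"
        assert "wme" not in out and "mbe" not in out and "egger" not in out

    def test_three_instruments_full_battery(self, spec_triple_hset):
        out = dispatch_estimators(spec_triple_hset, n_boot=50, seed=0)
        assert {"primary", "wme", "mbe", "egger", "q", "loo"} <= set(out)

    def test_estimators_equivariant_under_allele_relabelling(self, random_hset):
        rng = np.random.default_rng(13)
        d = random_hset.data
        flip = rng.random(len(d)) < 0.5
        sgn = np.where(flip, -1.0, 1.0)
        h2 = make_hset(d["beta_x"] * sgn, d["se_x"], d["beta_y"] * sgn,
                       d["se_y"])
        assert ivw_random_effects(random_hset).beta == pytest.approx(
            ivw_random_effects(h2).beta)
        assert weighted_median(random_hset, 10, seed=0).beta == pytest.approx(
            weighted_median(h2, 10, seed=0).beta)
        assert mode_based(random_hset, n_boot=10, seed=0).beta == pytest.approx(
            mode_based(h2, n_boot=10, seed=0).beta)
        assert egger_regression(random_hset).slope.beta == pytest.approx(
            egger_regression(h2).slope.beta)
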