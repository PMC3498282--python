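"""Diversification-model likelihoods, ML fits and AIC bookkeeping.

Independent oracles used here:

* a per-interval exponential log-density summation for the pure-birth
  kernel (separate code path from the closed form);
* numerical integration (``scipy.integrate.quad``) of the lineage-count
  weighted rate intensity for the rate-variable models;
* a re-typed term-by-term birth--death expression;
* dense grid searches for the 1-parameter MLEs.
"""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import minimize
from scipy.special import gammaln

from conftest import make_yule_bt
from divrate.models import (
    MODEL_NAMES,
    aic,
    fit_all_models,
    fit_birth_death,
    fit_ddl,
    fit_ddx,
    fit_yule2rate,
    loglik_birth_death,
    loglik_pure_birth,
    loglik_rate_per_interval,
    mle_pure_birth,
)
from divrate.simulate import TreeSimSpec, simulate_birth_death, simulate_ddl_tree, simulate_rate_shift
from divrate.tree import BranchingTimes, branching_times


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def pure_birth_oracle(lam, bt):
    """Sum of per-interval exponential log-densities: each interval with i
    lineages ending in a branching event contributes log(i lam) - i lam d;
    the final interval contributes only survival."""
    ages = list(bt.ages) + [0.0]
    total = 0.0
    for idx, i in enumerate(range(2, bt.n_tips + 1)):
        d = ages[idx] - ages[idx + 1]
        total -= i * lam * d
        if i <= bt.n_tips - 1:
            total += math.log(i * lam)
    return total


def rate_fn_oracle(rate_of_age, bt):
    """Brute force for any age-dependent pure-birth rate: event terms
    log(i * lam(x_{i+1})) plus numerically integrated survival."""
    ages = list(bt.ages) + [0.0]
    total = 0.0
    for idx, i in enumerate(range(2, bt.n_tips + 1)):
        hi, lo = ages[idx], ages[idx + 1]
        integral, err = quad(rate_of_age, lo, hi, limit=200)
        assert err < 1e-12
        total -= i * integral
        if i <= bt.n_tips - 1:
            total += math.log(i * rate_of_age(lo))
    return total


def bd_oracle(r, a, bt):
    """Term-by-term re-typed birth-death expression (incl. the shared
    orderings constant)."""
    n = bt.n_tips
    x = list(bt.ages)
    out = (n - 2) * math.log(r)
    out += r * sum(x[1:])
    out += n * math.log(1.0 - a)
    out -= 2.0 * sum(math.log(math.exp(r * xi) - a) for xi in x)
    out += sum(math.log(i) for i in range(2, n))
    return out


@pytest.fixture(params=[(5, 101), (6, 202), (6, 303)])
def small_bt(request):
    n, seed = request.param
    return make_yule_bt(n, 0.3, seed)


# ---------------------------------------------------------------------------
# likelihood kernels
# ---------------------------------------------------------------------------


class TestPureBirthLikelihood:
    def test_hand_value(self, bt_3):
        assert loglik_pure_birth(1.0, bt_3) == pytest.approx(np.log(2) - 5, abs=1e-12)

    def test_diverges_as_rate_vanishes(self, bt_3):
        assert loglik_pure_birth(1e-12, bt_3) < -20

    def test_rejects_nonpositive_rate(self, bt_3):
        with pytest.raises(ValueError):
            loglik_pure_birth(0.0, bt_3)

    def test_matches_interval_density_oracle(self):
        bt = make_yule_bt(20, 0.2, 44)
        for lam in (0.05, 0.2, 1.3):
            assert loglik_pure_birth(lam, bt) == pytest.approx(
                pure_birth_oracle(lam, bt), abs=1e-10
            )


class TestIntervalKernel:
    def test_hand_value(self, bt_3):
        got = loglik_rate_per_interval([0.1, 0.3], bt_3)
        assert got == pytest.approx(np.log(0.2) - 1.1, abs=1e-12)

    def test_constant_rates_reduce_to_pure_birth(self):
        bt = make_yule_bt(12, 0.2, 9)
        rates = np.full(bt.n_tips - 1, 0.17)
        assert loglik_rate_per_interval(rates, bt) == pytest.approx(
            loglik_pure_birth(0.17, bt), abs=1e-10
        )

    def test_rejects_nonpositive_rates(self, bt_3):
        with pytest.raises(ValueError):
            loglik_rate_per_interval([0.1, 0.0], bt_3)


class TestBirthDeathLikelihood:
    def test_reduces_to_pure_birth_at_zero_extinction(self):
        bt = make_yule_bt(15, 0.2, 10)
        for r in (0.05, 0.2, 0.8):
            assert loglik_birth_death(r, 0.0, bt) == pytest.approx(
                loglik_pure_birth(r, bt), abs=1e-10
            )

    def test_dual_implementation_oracle(self, bt_3):
        assert loglik_birth_death(0.2, 0.5, bt_3) == pytest.approx(
            bd_oracle(0.2, 0.5, bt_3), abs=1e-10
        )

    def test_diverges_as_extinction_fraction_to_one(self, bt_3):
        assert loglik_birth_death(0.2, 1 - 1e-12, bt_3) < -50

    def test_domain_errors(self, bt_3):
        with pytest.raises(ValueError):
            loglik_birth_death(-0.1, 0.0, bt_3)
        with pytest.raises(ValueError):
            loglik_birth_death(0.1, 1.0, bt_3)


class TestOracleEquivalenceSmallTrees:
    """All five model likelihoods against brute force on <= 6-tip trees."""

    def test_pure_birth(self, small_bt):
        assert loglik_pure_birth(0.31, small_bt) == pytest.approx(
            rate_fn_oracle(lambda a: 0.31, small_bt), abs=1e-10
        )

    def test_bd(self, small_bt):
        assert loglik_birth_death(0.4, 0.35, small_bt) == pytest.approx(
            bd_oracle(0.4, 0.35, small_bt), abs=1e-10
        )

    def test_ddl_rates(self, small_bt):
        r1, k = 0.5, 25.0
        i = small_bt.lineage_counts()
        got = loglik_rate_per_interval(r1 * (1 - i / k), small_bt)

        # oracle: piecewise-constant-in-stage intensity; integrate per stage
        ages = list(small_bt.ages) + [0.0]
        total = 0.0
        for idx, ii in enumerate(range(2, small_bt.n_tips + 1)):
            lam_i = r1 * (1 - ii / k)
            integral, _ = quad(lambda a: lam_i, ages[idx + 1], ages[idx])
            total -= ii * integral
            if ii <= small_bt.n_tips - 1:
                total += math.log(ii * lam_i)
        assert got == pytest.approx(total, abs=1e-10)

    def test_ddx_rates(self, small_bt):
        r1, x = 0.6, 0.5
        i = small_bt.lineage_counts()
        got = loglik_rate_per_interval(r1 * i ** (-x), small_bt)
        ages = list(small_bt.ages) + [0.0]
        total = 0.0
        for idx, ii in enumerate(range(2, small_bt.n_tips + 1)):
            lam_i = r1 * ii ** (-x)
            total -= ii * lam_i * (ages[idx] - ages[idx + 1])
            if ii <= small_bt.n_tips - 1:
                total += math.log(ii * lam_i)
        assert got == pytest.approx(total, abs=1e-10)

    def test_yule2rate_segment_split(self, small_bt):
        """Assembling per-interval rates for a shift inside an interval
        equals the direct two-segment evaluation split at the shift."""
        r1, r2 = 0.5, 0.1
        x = small_bt.ages
        st = (x[1] + x[2]) / 2.0  # inside the 3-lineage interval

        def rate(age):
            return r1 if age >= st else r2

        oracle = rate_fn_oracle(rate, small_bt)
        # direct evaluation: event terms + exact weighted durations
        ages = list(x) + [0.0]
        total = 0.0
        for idx, ii in enumerate(range(2, small_bt.n_tips + 1)):
            hi, lo = ages[idx], ages[idx + 1]
            t1 = max(0.0, hi - max(lo, st))
            t2 = max(0.0, min(hi, st) - lo)
            total -= ii * (r1 * t1 + r2 * t2)
            if ii <= small_bt.n_tips - 1:
                total += math.log(ii * rate(lo))
        assert total == pytest.approx(oracle, abs=1e-10)


# ---------------------------------------------------------------------------
# fits
# ---------------------------------------------------------------------------


class TestPureBirthMLE:
    def test_hand_value(self, bt_3):
        assert mle_pure_birth(bt_3).params["r1"] == pytest.approx(0.2, abs=1e-14)

    def test_scale_covariance(self):
        bt = make_yule_bt(20, 0.2, 3)
        lam = mle_pure_birth(bt).params["r1"]
        lam_scaled = mle_pure_birth(bt.rescaled(4.0)).params["r1"]
        assert lam_scaled == pytest.approx(lam / 4.0, rel=1e-12)

    def test_matches_grid_search(self):
        bt = make_yule_bt(30, 0.3, 77)
        lam_hat = mle_pure_birth(bt).params["r1"]
        grid = np.arange(1e-4, 5.0, 1e-5)
        n, S = bt.n_tips, float(np.sum(bt.lineage_counts() * bt.durations()))
        lnl = (n - 2) * np.log(grid) + gammaln(n) - grid * S
        assert abs(lam_hat - grid[np.argmax(lnl)]) <= 1.5e-5

    def test_needs_three_tips(self):
        with pytest.raises(ValueError):
            mle_pure_birth(BranchingTimes(2, np.array([2.0])))


class TestBirthDeathFit:
    def test_zero_extinction_boundary_matches_pure_birth_exactly(self):
        for seed in range(8):
            bt = make_yule_bt(25, 0.2, 500 + seed)
            fit = fit_birth_death(bt)
            if fit.params["a"] == 0.0:
                pb = mle_pure_birth(bt)
                assert fit.lnl == pb.lnl
                assert fit.params["r1"] == pb.params["r1"]
                break
        else:
            pytest.fail("no boundary case among seeds (unexpected for Yule trees)")

    def test_at_least_matches_quasi_newton_multistart(self):
        """The profile fit must recover (or beat) a 5-start bounded
        quasi-Newton optimization, and agree to 1e-6 on pure-birth data."""

        def multistart(bt):
            n, x = bt.n_tips, bt.ages

            def neg(th):
                r, a = np.exp(th[0]), th[1]
                rx = r * x
                em = np.exp(-rx)
                return -(
                    (n - 2) * th[0]
                    + r * np.sum(x[1:])
                    + n * np.log1p(-a)
                    - 2 * np.sum(rx + np.log(1 - a * em))
                    + gammaln(n)
                )

            lam0 = mle_pure_birth(bt).params["r1"]
            best = np.inf
            for s in [(np.log(lam0), 0.0), (np.log(lam0), 0.3), (np.log(lam0), 0.7),
                      (np.log(0.3 * lam0), 0.5), (np.log(3 * lam0), 0.2)]:
                res = minimize(neg, np.array(s), method="L-BFGS-B",
                               bounds=[(np.log(lam0) - 7, np.log(lam0) + 7), (0, 1 - 1e-9)])
                best = min(best, res.fun)
            return -best

        for seed in range(5):
            bt = make_yule_bt(20, 0.15, 900 + seed)
            fit = fit_birth_death(bt)
            oracle = multistart(bt)
            assert fit.lnl >= oracle - 1e-6
            if fit.params["a"] < 0.9:  # away from the r->0, a->1 ridge
                assert fit.lnl == pytest.approx(oracle, abs=1e-6)

    def test_recovers_extinction_signal(self):
        bts = [
            branching_times(
                simulate_birth_death(
                    TreeSimSpec("birth_death", 20, lam=0.3, mu=0.15, seed=s)
                )
            )
            for s in range(30)
        ]
        a_hats = [fit_birth_death(bt).params["a"] for bt in bts]
        assert np.median(a_hats) > 0.0


class TestDDLFit:
    def test_collapse_to_pure_birth_reports_limit(self):
        # a star-burst-free Yule tree often shows no density dependence;
        # force the pattern with rates that *increase* through time
        bt = make_yule_bt(20, 0.2, 4)
        fit = fit_ddl(bt)
        if fit.diagnostics.get("collapsed_to_pure_birth"):
            pb = mle_pure_birth(bt)
            assert fit.lnl == pb.lnl
            assert fit.params["k"] == 1e7

    def test_parameter_recovery_median_within_factor_two(self):
        k_hats = []
        for s in range(100):
            t = simulate_ddl_tree(TreeSimSpec("ddl", 20, r1=0.5, k=25.0, seed=4000 + s))
            fit = fit_ddl(branching_times(t))
            k_hats.append(fit.params["k"])
        med = np.median(k_hats)
        assert 12.5 <= med <= 50.0

    def test_k_domain(self):
        bt = make_yule_bt(15, 0.2, 8)
        fit = fit_ddl(bt)
        assert fit.params["k"] > bt.n_tips


class TestDDXFit:
    def test_x_zero_reduces_to_pure_birth(self):
        bt = make_yule_bt(15, 0.2, 21)
        i = bt.lineage_counts()
        lam = mle_pure_birth(bt).params["r1"]
        assert loglik_rate_per_interval(
            np.full(len(i), lam) * i**0.0, bt
        ) == pytest.approx(loglik_pure_birth(lam, bt), abs=1e-12)

    def test_nesting(self):
        for s in (31, 32, 33):
            bt = make_yule_bt(18, 0.25, s)
            assert fit_ddx(bt).lnl >= mle_pure_birth(bt).lnl - 1e-8

    def test_parameter_recovery(self):
        x_hats = []
        for s in range(100):
            i = np.arange(2, 31)
            from divrate.simulate import _stage_rate_ages

            rng = np.random.default_rng(6000 + s)
            bt = _stage_rate_ages(30, 0.6 * i ** (-0.5), rng)
            x_hats.append(fit_ddx(bt).params["x"])
        assert abs(np.median(x_hats) - 0.5) <= 0.25


class TestYule2RateFit:
    def test_needs_four_tips(self, bt_3):
        with pytest.raises(ValueError):
            fit_yule2rate(bt_3)

    def test_equal_rates_truth_keeps_small_nonneg_gain(self):
        gains = []
        for s in (41, 42, 43, 44):
            bt = make_yule_bt(20, 0.2, s)
            gain = fit_yule2rate(bt).lnl - mle_pure_birth(bt).lnl
            assert gain >= -1e-10
            gains.append(gain)
        assert np.median(gains) < 5.0  # no spurious huge improvement

    def test_shift_age_bracketing_recovery(self):
        hits = 0
        for s in range(100):
            t = simulate_rate_shift(
                TreeSimSpec("yule2rate", 20, r1=0.5, r2=0.05, shift_age=5.0, seed=7000 + s)
            )
            bt = branching_times(t)
            st = fit_yule2rate(bt).params["st"]
            ages = np.sort(np.append(bt.ages, 0.0))
            below = ages[ages <= 5.0].max() if np.any(ages <= 5.0) else 0.0
            above = ages[ages > 5.0].min() if np.any(ages > 5.0) else bt.crown_age
            if below <= st <= above:
                hits += 1
        assert hits >= 80

    def test_reports_full_triple(self):
        bt = make_yule_bt(15, 0.2, 55)
        fit = fit_yule2rate(bt)
        assert set(fit.params) == {"r1", "r2", "st"}
        assert 0 < fit.params["st"] < bt.crown_age


# ---------------------------------------------------------------------------
# AIC and the comparison table
# ---------------------------------------------------------------------------


class TestAIC:
    @pytest.mark.parametrize(
        "lnl,k,conv,expected",
        [
            (14.668, 3, "table5", -35.336),
            (10.201, 2, "table5", -24.402),
            (0.0, 1, "standard", 2.0),
        ],
    )
    def test_values(self, lnl, k, conv, expected):
        assert aic(lnl, k, conv) == pytest.approx(expected, abs=1e-9)

    def test_convention_identity(self):
        for lnl, k in [(-3.2, 1), (14.668, 3), (0.0, 2)]:
            assert aic(lnl, k, "standard") + aic(lnl, k, "table5") == pytest.approx(
                -4 * lnl, abs=1e-10
            )
            assert aic(lnl, k, "standard") - aic(lnl, k, "table5") == pytest.approx(
                4 * k, abs=1e-10
            )


class TestFitAllModels:
    def test_structure_and_nesting(self):
        bt = make_yule_bt(20, 0.2, 60)
        table = fit_all_models(bt, "demo")
        assert tuple(table.fits) == MODEL_NAMES
        pb = table.fits["pureBirth"].lnl
        for m in ("BD", "DDL", "DDX", "yule2rate"):
            assert table.fits[m].lnl >= pb - 1e-8
        assert table.delta_aic_vs_purebirth()["pureBirth"] == 0.0

    def test_aic_consistency_every_fit(self):
        table = fit_all_models(make_yule_bt(15, 0.25, 61))
        for f in table.fits.values():
            assert f.aic_standard - f.aic_table5 == pytest.approx(4 * f.n_params)

    def test_time_rescaling_covariance(self):
        """Rescaling ages by c: rates x 1/c, shape params unchanged,
        shift time x c, lnL shifted by (n-2) ln(1/c)."""
        bt = make_yule_bt(20, 0.2, 62)
        c = 3.0
        t1 = fit_all_models(bt)
        t2 = fit_all_models(bt.rescaled(c))
        n = bt.n_tips
        jac = (n - 2) * np.log(1.0 / c)
        for m in MODEL_NAMES:
            assert t2.fits[m].lnl == pytest.approx(t1.fits[m].lnl + jac, abs=1e-5)
        assert t2.fits["pureBirth"].params["r1"] == pytest.approx(
            t1.fits["pureBirth"].params["r1"] / c, rel=1e-9
        )
        assert t2.fits["BD"].params["a"] == pytest.approx(
            t1.fits["BD"].params["a"], abs=1e-5
        )
        assert t2.fits["DDX"].params["x"] == pytest.approx(
            t1.fits["DDX"].params["x"], abs=1e-4
        )
        assert t2.fits["yule2rate"].params["st"] == pytest.approx(
            t1.fits["yule2rate"].params["st"] * c, rel=1e-9
        )

    def test_tsv_layout(self):
        table = fit_all_models(make_yule_bt(12, 0.3, 63), "cladeX")
        tsv = table.to_tsv()
        header = tsv.splitlines()[0].split("\t")
        assert header[2:] == list(MODEL_NAMES)
        assert "Ln(L)" in tsv and "dAIC" in tsv

    def test_json_and_tsv_agree_after_rounding(self):
        table = fit_all_models(make_yule_bt(12, 0.3, 64), "c")
        d = table.to_dict()
        tsv = table.to_tsv(ndigits=3)
        lnl_row = [l for l in tsv.splitlines() if l.split("\t")[1] == "Ln(L)"][0]
        cells = lnl_row.split("\t")[2:]
        for cell, m in zip(cells, MODEL_NAMES):
            assert float(cell) == pytest.approx(round(d["fits"][m]["lnl"], 3), abs=5e-4)


class TestParameterRecoveryYule:
    def test_median_rate_estimate_within_ten_percent(self):
        lam = 0.2
        rng = np.random.default_rng(314)
        from divrate.simulate import sample_yule_branching_ages

        hats = [
            mle_pure_birth(sample_yule_branching_ages(50, lam, rng)).params["r1"]
            for _ in range(200)
        ]
        assert abs(np.median(hats) / lam - 1.0) <= 0.10
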