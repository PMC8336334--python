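import numpy as np
import pandas as pd
import pytest

from istmescore.containers import ClinicalTable
from istmescore.survival import (
    c_index,
    cox_multivariate,
    cox_univariate,
    km_fit,
    logrank_test,
)


def _clin(times, events, **covs):
    n = len(times)
    df = pd.DataFrame({"os_time": times, "os_event": events, **covs},
                      index=pd.Index([f"s{i}" for i in range(n)], name="sample_id"))
    return ClinicalTable(df)


class TestKM:
    def test_hand_product_limit(self):
        curve = km_fit([1.0, 2.0, 3.0], [1, 1, 0])
        np.testing.assert_allclose(curve.times, [1.0, 2.0])
        np.testing.assert_allclose(curve.survival, [2 / 3, 1 / 3])
        assert curve.survival_at(3.0) == pytest.approx(1 / 3)
        assert curve.survival_at(0.5) == 1.0

    def test_all_censored_flat(self):
        with pytest.warns(UserWarning, match="no events"):
            curve = km_fit([1, 2, 3], [0, 0, 0])
        assert curve.survival_at(10) == 1.0

    def test_time_scaling_leaves_survival_values(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(5, 30)
        e = rng.integers(0, 2, 30)
        e[0] = 1
        a = km_fit(t, e)
        b = km_fit(2 * t, e)
        np.testing.assert_allclose(b.times, 2 * a.times)
        np.testing.assert_allclose(b.survival, a.survival)

    def test_matches_brute_force_product(self):
        rng = np.random.default_rng(5)
        t = np.round(rng.exponential(3, 25), 1)  # rounded -> ties exercised
        e = rng.integers(0, 2, 25)
        e[:2] = 1
        curve = km_fit(t, e)
        s = 1.0
        for i, et in enumerate(curve.times):
            d = np.sum((t == et) & (e == 1))
            n = np.sum(t >= et)
            s *= 1 - d / n
            assert curve.survival[i] == pytest.approx(s, abs=1e-12)


class TestLogrank:
    def test_identical_groups_null(self):
        t = np.array([1, 2, 3, 1, 2, 3], dtype=float)
        e = np.array([1, 1, 0, 1, 1, 0])
        g = np.array([0, 0, 0, 1, 1, 1])
        chi2, df, p = logrank_test(t, e, g)
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)

    def test_df_is_groups_minus_one(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(3, 40)
        e = np.ones(40, dtype=int)
        g = np.repeat([0, 1, 2, 3], 10)
        _, df, _ = logrank_test(t, e, g)
        assert df == 3

    def test_single_group_raises(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [1, 1], [0, 0])

    def test_invariant_to_monotone_time_transform(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(3, 30)
        e = rng.integers(0, 2, 30); e[:3] = 1
        g = rng.integers(0, 2, 30)
        chi_a, _, _ = logrank_test(t, e, g)
        chi_b, _, _ = logrank_test(np.log1p(t), e, g)
        assert chi_a == pytest.approx(chi_b, abs=1e-10)

    def test_p_within_permutation_null(self):
        def direct_chi2(t, e, g):
            """Independent textbook O-E/V two-group log-rank statistic."""
            o_minus_e, var = 0.0, 0.0
            for et in np.unique(t[e == 1]):
                at_risk = t >= et
                n_r = at_risk.sum()
                n1 = (at_risk & (g == 1)).sum()
                d = ((t == et) & (e == 1)).sum()
                d1 = ((t == et) & (e == 1) & (g == 1)).sum()
                o_minus_e += d1 - d * n1 / n_r
                if n_r > 1:
                    var += d * (n1 / n_r) * (1 - n1 / n_r) * (n_r - d) / (n_r - 1)
            return o_minus_e**2 / var

        rng = np.random.default_rng(3)
        n = 30
        t = rng.exponential(3, n)
        e = rng.integers(0, 2, n); e[:5] = 1
        g = rng.integers(0, 2, n)
        chi_obs, _, p = logrank_test(t, e, g)
        assert direct_chi2(t, e, g) == pytest.approx(chi_obs, abs=1e-8)
        n_perm = 10_000
        count = 0
        for _ in range(n_perm):
            gp = rng.permutation(g)
            count += direct_chi2(t, e, gp) >= chi_obs - 1e-12
        p_mc = count / n_perm
        se = np.sqrt(max(p_mc * (1 - p_mc), 1e-6) / n_perm)
        assert abs(p - p_mc) <= max(3 * se, 0.02)


class TestCox:
    def test_constant_covariate_raises(self):
        c = _clin([1, 2, 3, 4], [1, 1, 1, 1])
        with pytest.raises(ValueError, match="constant"):
            cox_univariate(np.ones(4), c)

    def test_beta_matches_grid_search_of_partial_likelihood(self):
        # deaths alternate between groups so the MLE is finite/identifiable
        times = np.array([1.0, 2.0, 3.0, 4.0])
        events = np.array([1, 1, 1, 1])
        x = np.array([1.0, 0.0, 1.0, 0.0])
        fit = cox_univariate(x, _clin(times, events))
        grid = np.linspace(-5, 5, 200_001)
        lls = np.zeros_like(grid)
        for t in np.unique(times[events == 1]):  # vectorized over the beta grid
            d = (times == t) & (events == 1)
            risk = times >= t
            lls += grid * x[d].sum() - d.sum() * np.log(
                np.exp(np.outer(grid, x[risk])).sum(axis=1)
            )
        beta_grid = grid[int(np.argmax(lls))]
        assert fit.beta[0] == pytest.approx(beta_grid, abs=1e-3)

    def test_negating_covariate_negates_beta(self):
        rng = np.random.default_rng(4)
        t = rng.exponential(3, 40)
        e = rng.integers(0, 2, 40); e[:10] = 1
        x = rng.normal(size=40)
        c = _clin(t, e)
        a = cox_univariate(x, c)
        b = cox_univariate(-x, c)
        assert a.beta[0] == pytest.approx(-b.beta[0], abs=1e-8)

    def test_multivariate_single_binary_equals_univariate(self):
        rng = np.random.default_rng(6)
        t = rng.exponential(3, 50)
        e = rng.integers(0, 2, 50); e[:10] = 1
        x = rng.integers(0, 2, 50).astype(float)
        c = _clin(t, e, marker=x)
        uni = cox_univariate(x, c)
        multi = cox_multivariate(c, ["marker"])
        assert multi.beta[0] == pytest.approx(uni.beta[0], abs=1e-8)
        assert multi.p[0] == pytest.approx(uni.p[0], abs=1e-8)

    def test_categorical_reference_level(self):
        rng = np.random.default_rng(7)
        t = rng.exponential(3, 60)
        e = np.ones(60, dtype=int)
        g = np.where(rng.random(60) < 0.5, "high", "low")
        c = _clin(t, e, grade=g)
        fit = cox_multivariate(c, ["grade"], reference_levels={"grade": "low"})
        assert fit.names == ["grade[high vs low]"]

    def test_calibration_recovers_planted_coefficient(self):
        # ~90% coverage of beta within 2 SE across seeded replicates
        beta_true = 0.7
        hits = 0
        reps = 50
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            n = 120
            x = rng.normal(size=n)
            t = rng.exponential(np.exp(-beta_true * x))
            cens = rng.random(n) < 0.25
            obs = np.where(cens, t * rng.random(n), t)
            c = _clin(obs, (~cens).astype(int))
            fit = cox_univariate(x, c)
            hits += abs(fit.beta[0] - beta_true) <= 2 * fit.se[0]
        assert hits >= int(0.9 * reps)


class TestCIndex:
    def test_perfectly_anti_ordered_risk(self):
        times = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
        risk = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert c_index(risk, times, np.ones(5, int)) == pytest.approx(1.0)

    def test_constant_risk_is_half(self):
        assert c_index(np.ones(5), [1, 2, 3, 4, 5], np.ones(5, int)) == pytest.approx(0.5)

    def test_complementarity_without_ties(self):
        rng = np.random.default_rng(8)
        t = rng.exponential(3, 25)
        e = rng.integers(0, 2, 25); e[:5] = 1
        r = rng.normal(size=25)
        assert c_index(r, t, e) + c_index(-r, t, e) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_all_pairs_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 30))
        t = rng.exponential(3, n)  # continuous: no tied event times
        e = rng.integers(0, 2, n); e[0] = 1
        r = np.round(rng.normal(size=n), 1)  # rounding makes risk ties likely
        conc = disc = ties = 0
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                # pair usable if i has the earlier observed event
                if e[i] == 1 and t[i] < t[j]:
                    if r[i] > r[j]:
                        conc += 1
                    elif r[i] < r[j]:
                        disc += 1
                    else:
                        ties += 1
        expected = (conc + 0.5 * ties) / (conc + disc + ties)
        assert c_index(r, t, e) == pytest.approx(expected, abs=1e-12)
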