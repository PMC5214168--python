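import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln

from popgenscan._util import harmonic, rng_from
from popgenscan.hka import (
    PolyDivTable, fit_hka, fit_mlhka, hka_parametric_p, hka_statistic,
    hka_test, lrt, mlhka_loglik, mlhka_scan,
)
from popgenscan.synthdata import sample_poly_div_tables


def expectation_table(theta, T, n=(10, 20), L=(500, 800)):
    """Counts set exactly to the HKA forward expectations."""
    rows = []
    for i, th in enumerate(theta):
        a = harmonic(n[i])
        rows.append({"locus": f"l{i}", "S": th * a, "D": th * (T + 1),
                     "L": L[i], "n": n[i]})
    return PolyDivTable(pd.DataFrame(rows))


class TestMomentFit:
    def test_exact_recovery_from_expectations(self):
        tab = expectation_table((2.0, 4.0), T=5.0)
        theta, T = fit_hka(tab)
        assert T == pytest.approx(5.0, abs=1e-6)
        assert theta == pytest.approx([2.0, 4.0], abs=1e-6)
        res = hka_statistic(tab, theta, T)
        assert res.deviation_sum == pytest.approx(0.0, abs=1e-9)
        assert res.p_chi == pytest.approx(1.0)
        assert res.df == 1

    def test_single_locus_rejected(self):
        tab = PolyDivTable(pd.DataFrame(
            {"locus": ["x"], "S": [3], "D": [5], "L": [100], "n": [10]}))
        with pytest.raises(ValueError, match="2 loci"):
            fit_hka(tab)

    def test_all_divergence_zero_hits_boundary(self):
        tab = PolyDivTable(pd.DataFrame(
            {"locus": ["a", "b"], "S": [5, 8], "D": [0, 0],
             "L": [100, 100], "n": [10, 10]}))
        with pytest.warns(UserWarning, match="boundary"):
            res = hka_test(tab)
        assert res.boundary

    def test_chi2_tail_reference_values(self):
        from scipy.stats import chi2
        assert chi2.sf(16.2086, 9) == pytest.approx(0.06265, abs=5e-6)
        assert chi2.sf(0.0, 9) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            PolyDivTable(pd.DataFrame(
                {"locus": ["a", "b"], "S": [-1, 2], "D": [1, 1],
                 "L": [10, 10], "n": [5, 5]}))


class TestParametricBootstrap:
    def _null_table(self, seed):
        rng = rng_from(seed, "tab")
        theta = rng.uniform(3, 10, size=6)
        return sample_poly_div_tables(
            [f"l{i}" for i in range(6)], theta, np.ones(6),
            np.full(6, 1000.0), 20, 6.0, rng)

    def test_bounds_and_determinism(self):
        tab = self._null_table(1)
        p1 = hka_parametric_p(tab, reps=300, seed=7)
        p2 = hka_parametric_p(tab, reps=300, seed=7)
        assert p1 == p2
        assert 1 / 301 <= p1 <= 1.0

    def test_null_p_values_spread(self):
        """On null data the bootstrap p should not pile up near 0."""
        ps = [hka_parametric_p(self._null_table(s), reps=200, seed=s)
              for s in range(30)]
        assert np.mean(ps) > 0.25
        assert min(ps) > 1 / 201 - 1e-12


class TestMlhkaLikelihood:
    def test_hand_evaluated_toy(self):
        tab = PolyDivTable(pd.DataFrame(
            {"locus": ["a", "b"], "S": [4, 7], "D": [10, 20],
             "L": [100, 100], "n": [10, 10]}))
        theta = np.array([1.5, 2.5])
        k = np.array([1.0, 2.0])
        T = 15.0
        a = harmonic(10)

        def log_pois(x, mu):
            return x * np.log(mu) - mu - gammaln(x + 1)

        expected = (log_pois(4, 1.0 * 1.5 * a) + log_pois(10, 1.5 * 16.0)
                    + log_pois(7, 2.0 * 2.5 * a) + log_pois(20, 2.5 * 17.0))
        assert mlhka_loglik(tab, theta, k, T) == pytest.approx(float(expected))

    def test_k_one_matches_neutral_nesting(self):
        tab = expectation_table((3.0, 6.0), T=8.0)
        theta = np.array([3.0, 6.0])
        assert (mlhka_loglik(tab, theta, np.ones(2), 8.0)
                == pytest.approx(mlhka_loglik(tab, theta, np.array([1.0, 1.0]), 8.0)))

    def test_zero_counts_contribute_minus_mean(self):
        tab = PolyDivTable(pd.DataFrame(
            {"locus": ["a"], "S": [0], "D": [0], "L": [100], "n": [10]}))
        theta, k, T = np.array([2.0]), np.array([1.5]), 10.0
        expected = -(1.5 * 2.0 * harmonic(10)) - (2.0 * (10 + 1.5))
        assert mlhka_loglik(tab, theta, k, T) == pytest.approx(expected)

    def test_domain_errors(self):
        tab = expectation_table((3.0, 6.0), T=8.0)
        with pytest.raises(ValueError):
            mlhka_loglik(tab, np.array([0.0, 1.0]), np.ones(2), 8.0)


class TestMlhkaFit:
    def test_selection_nests_neutral(self):
        rng = rng_from(3, "nest")
        for _ in range(10):
            theta = rng.uniform(2, 10, size=8)
            tab = sample_poly_div_tables([f"l{i}" for i in range(8)], theta,
                                         np.ones(8), np.full(8, 500.0), 20,
                                         15.0, rng)
            res = fit_mlhka(tab, free_k_loci=("l0",))
            assert res.lnl >= res.lnl_neutral - 1e-9
            assert res.LR >= 0 and res.valid

    def test_neutral_data_yield_small_lr(self):
        rng = rng_from(4, "small_lr")
        lrs = []
        for _ in range(30):
            tab = sample_poly_div_tables([f"l{i}" for i in range(8)],
                                         np.full(8, 8.0), np.ones(8),
                                         np.full(8, 500.0), 30, 15.0, rng)
            lrs.append(fit_mlhka(tab, free_k_loci=("l0",)).LR)
        # LR ~ chi2(1)-ish under the null: median well under 2
        assert np.median(lrs) < 2.0

    def test_k_recovery_direction(self):
        rng = rng_from(5, "k3")
        khats = []
        for _ in range(20):
            kv = np.ones(10)
            kv[0] = 3.0
            tab = sample_poly_div_tables([f"l{i}" for i in range(10)],
                                         np.full(10, 8.0), kv,
                                         np.full(10, 500.0), 50, 15.0, rng)
            khats.append(fit_mlhka(tab, free_k_loci=("l0",)).k_hat["l0"])
        assert np.median(khats) > 1.5

    def test_unknown_locus_rejected(self):
        tab = expectation_table((3.0, 6.0), T=8.0)
        with pytest.raises(ValueError, match="free_k_loci"):
            fit_mlhka(tab, free_k_loci=("nope",))

    def test_scan_table_layout(self):
        tab = expectation_table((3.0, 6.0), T=8.0)
        out = mlhka_scan(tab, ["l0", "l1"], T=8.0)
        assert list(out.columns) == ["locus", "lnL_neutral", "lnL", "LR", "p",
                                     "k", "valid"]
        assert len(out) == 2


class TestLRT:
    @pytest.mark.parametrize("null,alt,lr,p", [
        (-90.5620, -87.9450, 5.2340, 0.022),
        (-90.5620, -88.5555, 4.0130, 0.045),
        (-90.5620, -87.7454, 5.6332, 0.018),
        (-90.5620, -87.8897, 5.3446, 0.021),
        (-83.8881, -79.5194, 8.7374, 0.003),
        (-83.8881, -82.1915, 3.3932, 0.065),
        (-83.8881, -83.6798, 0.4166, 0.519),
        (-83.8881, -82.6406, 2.4950, 0.114),
        (-90.5620, -90.3898, 0.3444, 0.557),
    ])
    def test_published_pairs(self, null, alt, lr, p):
        LR, pval, valid = lrt(null, alt)
        assert valid
        assert LR == pytest.approx(lr, abs=1e-4)
        assert pval == pytest.approx(p, abs=5e-4)

    def test_equal_likelihoods(self):
        LR, p, valid = lrt(-10.0, -10.0)
        assert (LR, p, valid) == (0.0, 1.0, True)

    def test_negative_lr_flagged_invalid(self):
        LR, p, valid = lrt(-90.5620, -90.6341)
        assert not valid
        assert np.isnan(p)
        assert LR == pytest.approx(-0.1442, abs=1e-4)
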