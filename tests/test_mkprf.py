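import numpy as np
import pytest
from scipy.special import gammaln

from popgenscan._util import harmonic, rng_from
from popgenscan.mkprf import (
    MKTable, build_mk_table, prf_fixation_factor, prf_loglik,
    prf_polymorphism_factor, run_mkprf,
)
from popgenscan.seqdata import exclude_indels, polarize
from popgenscan.synthdata import sample_mk_tables
from conftest import make_alignment


class TestFixationFactor:
    def test_neutral_limit(self):
        assert prf_fixation_factor(0.0) == 1.0

    def test_closed_form_value(self):
        assert prf_fixation_factor(5.0) == pytest.approx(10 / (1 - np.exp(-10)))

    def test_reflection_identity(self):
        rng = np.random.default_rng(0)
        for g in rng.uniform(-8, 8, size=20):
            assert prf_fixation_factor(g) == pytest.approx(
                np.exp(2 * g) * prf_fixation_factor(-g), rel=1e-12)

    def test_vectorized_and_stable(self):
        g = np.array([-50.0, -1.0, 0.0, 1.0, 50.0])
        h = prf_fixation_factor(g)
        assert np.isfinite(h).all()
        assert h[2] == 1.0
        assert h[-1] == pytest.approx(100.0)


class TestPolymorphismFactor:
    def test_neutral_limit(self):
        for n in (2, 10, 80):
            assert prf_polymorphism_factor(0.0, n) == pytest.approx(1.0, abs=1e-9)

    def test_against_bruteforce_integration(self):
        # Simpson oracle with analytic endpoint limits of the integrand
        gamma, n = 2.0, 10
        m = 200_001
        q = np.linspace(0.0, 1.0, m)
        with np.errstate(divide="ignore", invalid="ignore"):
            s = 1 - q**n - (1 - q) ** n
            r = np.expm1(-2 * gamma * (1 - q)) / np.expm1(-2 * gamma)
            f = s * r / (q * (1 - q))
        # endpoint limits: s*r/(q(1-q)) -> n at q=0 and -> 0 at q=1
        f[0] = n
        f[-1] = 0.0
        from scipy.integrate import simpson
        brute = simpson(f, x=q) / harmonic(n)
        assert prf_polymorphism_factor(gamma, n) == pytest.approx(brute, abs=1e-6)

    def test_monotone_in_gamma(self):
        """Positive selection depletes polymorphism relative to fixation:
        G/H decreases in gamma (G itself rises toward 2 with the flux)."""
        gs = np.linspace(0.1, 12.0, 25)
        G = np.array([prf_polymorphism_factor(g, 50) for g in gs])
        H = prf_fixation_factor(gs)
        assert (np.diff(G / H) < 0).all()
        assert (np.diff(G) > 0).all()


class TestLoglik:
    def _table(self, **kw):
        defaults = dict(locus_id="x", Ps=5, Pn=2, Ds=12, Dn=6, n=10)
        defaults.update(kw)
        return MKTable(**defaults)

    def test_hand_evaluated_single_locus(self):
        t = self._table()
        th_s, th_r, g, tau = 2.0, 1.0, 0.0, 15.0
        a = harmonic(10)

        def lp(x, mu):
            return x * np.log(mu) - mu - gammaln(x + 1)

        expected = (lp(5, th_s * a) + lp(12, th_s * 16.0)
                    + lp(2, th_r * a) + lp(6, th_r * 16.0))
        got = prf_loglik([t], [th_s], [th_r], [g], tau)
        assert got == pytest.approx(float(expected))

    def test_neutral_reduction(self):
        """gamma = 0 reduces replacement means to the silent functional form."""
        t1 = self._table(Ps=3, Ds=7, Pn=3, Dn=7)
        l_repl = prf_loglik([t1], [1.0], [2.0], [0.0], 10.0)
        t2 = self._table(Ps=3, Ds=7, Pn=3, Dn=7)
        l_sil = prf_loglik([t2], [2.0], [1.0], [0.0], 10.0)
        assert l_repl == pytest.approx(l_sil)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            prf_loglik([self._table()], [0.0], [1.0], [0.0], 10.0)
        with pytest.raises(ValueError):
            prf_loglik([self._table()], [1.0], [1.0], [np.inf], 10.0)

    def test_maximized_near_generating_values(self):
        """On expectation-valued counts the likelihood peaks at the truth."""
        a = harmonic(20)
        th_s, th_r, g, tau = 4.0, 2.0, 1.0, 15.0
        G = prf_polymorphism_factor(g, 20)
        H = prf_fixation_factor(g)
        t = MKTable("x", Ps=round(th_s * a), Pn=round(th_r * a * G),
                    Ds=round(th_s * (tau + 1)), Dn=round(th_r * (tau + 1) * H),
                    n=20)
        base = prf_loglik([t], [th_s], [th_r], [g], tau)
        for dg in (-1.5, 1.5):
            assert prf_loglik([t], [th_s], [th_r], [g + dg], tau) < base


class TestBuildMKTable:
    def test_no_variants(self):
        aln = make_alignment(["ACGTAC"] * 4, "ACGTAC", exons=[(0, 6)])
        pol = polarize(aln, exclude_indels(aln))
        t = build_mk_table(pol, "sp1", 4)
        assert (t.Ps, t.Pn, t.Ds, t.Dn) == (0, 0, 0, 0)

    def test_hand_classified_counts(self, toy_locus):
        aln, cls = toy_locus
        pol = polarize(aln, cls)
        t1 = build_mk_table(pol, "sp1", 3)
        # sp1: col 5 synonymous polymorphism; col 11 noncoding fixed difference
        assert (t1.Ps, t1.Pn, t1.Ds, t1.Dn) == (1, 0, 1, 0)
        t2 = build_mk_table(pol, "sp2", 2)
        # sp2: col 3 nonsyn poly, col 9 noncoding poly, col 11 fixed diff
        assert (t2.Ps, t2.Pn, t2.Ds, t2.Dn) == (1, 1, 1, 0)

    def test_mixed_classes_partition(self):
        aln = make_alignment(
            ["TTTAAACCC", "TTCAAACCC", "TTTAAACCC", "TTTAAACCC"],
            "TTTCAACCC", exons=[(0, 9)])
        pol = polarize(aln, exclude_indels(aln))
        t = build_mk_table(pol, "sp1", 4)
        # col 2 TTT->TTC synonymous polymorphism; col 3 AAA->CAA nonsyn fixed
        assert (t.Ps, t.Pn, t.Ds, t.Dn) == (1, 0, 0, 1)


class TestMCMC:
    def _tables(self, gamma_cand, seed=0):
        rng = rng_from(seed, "tables")
        names = [f"c{i}" for i in range(6)] + [f"r{i}" for i in range(10)]
        gam = np.array([gamma_cand] * 6 + [0.0] * 10)
        return sample_mk_tables(names, np.full(16, 6.0), np.full(16, 2.5),
                                gam, 15.0, 40,
                                ["candidate"] * 6 + ["reference"] * 10, rng)

    def test_seeded_chains_identical(self):
        tabs = self._tables(1.0)
        p1 = run_mkprf(tabs, cycles=3000, burn_in=500, thin=5, seed=11)
        p2 = run_mkprf(tabs, cycles=3000, burn_in=500, thin=5, seed=11)
        assert np.array_equal(p1.gamma_samples, p2.gamma_samples)
        assert p1.summary.equals(p2.summary)

    def test_interval_ordering_invariant(self):
        post = run_mkprf(self._tables(0.5), cycles=4000, burn_in=500,
                         thin=5, seed=3)
        s = post.summary
        assert (s["q2.5"] <= s["gamma_mean"]).all()
        assert (s["gamma_mean"] <= s["q97.5"]).all()

    def test_sign_recovery(self):
        post_pos = run_mkprf(self._tables(2.0, seed=5), cycles=12000,
                             burn_in=2000, thin=10, seed=21)
        cand = post_pos.summary[post_pos.summary["locus_class"] == "candidate"]
        assert cand["gamma_mean"].mean() > 0.5
        post_neg = run_mkprf(self._tables(-2.0, seed=6), cycles=12000,
                             burn_in=2000, thin=10, seed=22)
        cand = post_neg.summary[post_neg.summary["locus_class"] == "candidate"]
        assert cand["gamma_mean"].mean() < -0.5

    def test_hierarchical_shrinkage_toward_class_mean(self):
        """A locus with almost no replacement information is pulled toward its
        class mean: the same tiny-count locus gets a higher posterior mean
        among high-gamma classmates than among neutral classmates."""
        tiny = dict(Ps=4, Pn=0, Ds=8, Dn=1, n=40)
        rng = rng_from(9, "mates")
        strong = sample_mk_tables([f"s{i}" for i in range(8)],
                                  np.full(8, 8.0), np.full(8, 4.0),
                                  np.full(8, 3.0), 15.0, 40, "candidate", rng)
        neutralmates = sample_mk_tables([f"n{i}" for i in range(8)],
                                        np.full(8, 8.0), np.full(8, 4.0),
                                        np.zeros(8), 15.0, 40, "candidate", rng)
        t_hi = [MKTable("tiny", locus_class="candidate", **tiny)] + strong
        t_lo = [MKTable("tiny", locus_class="candidate", **tiny)] + neutralmates
        g_hi = run_mkprf(t_hi, cycles=12000, burn_in=2000, thin=10,
                         seed=31).summary.set_index("locus_id").loc["tiny", "gamma_mean"]
        g_lo = run_mkprf(t_lo, cycles=12000, burn_in=2000, thin=10,
                         seed=31).summary.set_index("locus_id").loc["tiny", "gamma_mean"]
        assert g_hi > g_lo + 0.3

    def test_class_mean_posteriors_separate(self):
        post = run_mkprf(self._tables(2.5, seed=12), cycles=12000,
                         burn_in=2000, thin=10, seed=41)
        mu = post.class_mean_samples
        assert mu["candidate"].mean() > mu["reference"].mean() + 0.5

    def test_validation(self):
        with pytest.raises(ValueError):
            run_mkprf([], cycles=100, burn_in=10)
        with pytest.raises(ValueError):
            run_mkprf(self._tables(0.0), cycles=100, burn_in=100)
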