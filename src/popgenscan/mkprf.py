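"""McDonald–Kreitman tables and Poisson-random-field selection estimation.

Per locus, silent and replacement variants are partitioned into the 2x2
(polymorphic / fixed) MK layout against the outgroup.  Counts are modelled as
independent Poisson fields:

    Ps ~ Poisson(theta_s * a_n)               Ds ~ Poisson(theta_s * (tau+1))
    Pn ~ Poisson(theta_r * a_n * G(gamma,n))  Dn ~ Poisson(theta_r * (tau+1) * H(gamma))

where gamma = 2*Ne*s is the scaled selection coefficient on replacement
mutations, H(gamma) = 2*gamma / (1 - exp(-2*gamma)) is the relative fixation
rate, and G(gamma, n) the relative expected number of polymorphisms seen in a
sample of n chromosomes, obtained by integrating the stationary frequency
density of selected mutations against the sampling factor 1 - q^n - (1-q)^n.
The silent class is the gamma = 0 anchor.

Locus-specific gamma_i are estimated by Metropolis-within-Gibbs MCMC under a
hierarchical prior gamma_i ~ Normal(mu_class, sigma^2) with a flat prior on
each class mean (candidate vs reference), so loci with few counts shrink
toward their class mean and the class-level posteriors contrast the two
groups of loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate
from scipy.interpolate import CubicSpline
from scipy.special import gammaln

from ._util import harmonic, rng_from
from .seqdata import PolarizedVariants

_SILENT = ("synonymous", "noncoding")


@dataclass
class MKTable:
    locus_id: str
    Ps: int
    Pn: int
    Ds: int
    Dn: int
    n: int
    locus_class: str = "reference"   # "candidate" | "reference"

    def __post_init__(self):
        for name in ("Ps", "Pn", "Ds", "Dn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n < 2:
            raise ValueError("n must be >= 2")


def mk_tables_to_frame(tables: list[MKTable]) -> pd.DataFrame:
    return pd.DataFrame([vars(t) for t in tables])


def mk_tables_from_tsv(path) -> list[MKTable]:
    df = pd.read_csv(path, sep="\t")
    cls = "locus_class" if "locus_class" in df.columns else "class"
    return [MKTable(locus_id=str(r["locus_id"] if "locus_id" in df.columns else r["locus"]),
                    Ps=int(r["Ps"]), Pn=int(r["Pn"]), Ds=int(r["Ds"]), Dn=int(r["Dn"]),
                    n=int(r["n"]), locus_class=str(r[cls]))
            for _, r in df.iterrows()]


def build_mk_table(polarized: PolarizedVariants, species: str, n: int,
                   locus_class: str = "reference") -> MKTable:
    """Count the 2x2 MK layout for one species from polarized variants.

    Silent = synonymous + noncoding.  A variant counts as polymorphic when
    the species segregates for it and as a fixed difference when the species
    is monomorphic for a non-outgroup allele.
    """
    ps = pn = ds = dn = 0
    for rec in polarized.records:
        state = rec.species_state.get(species)
        silent = rec.effect in _SILENT
        if state == "polymorphic":
            if silent:
                ps += 1
            else:
                pn += 1
        elif state == "fixed_difference":
            if silent:
                ds += 1
            else:
                dn += 1
    return MKTable(locus_id=polarized.locus_id, Ps=ps, Pn=pn, Ds=ds, Dn=dn,
                   n=n, locus_class=locus_class)


# ---------------------------------------------------------------------------
# PRF intensity functions


def prf_fixation_factor(gamma) -> np.ndarray | float:
    """H(gamma) = 2*gamma / (1 - exp(-2*gamma)), the fixation rate of a
    selected mutation relative to a neutral one; H(0) = 1."""
    g = np.asarray(gamma, dtype=float)
    out = np.empty_like(g)
    pos = g > 0
    neg = g < 0
    zero = g == 0
    with np.errstate(over="ignore"):
        out[pos] = 2.0 * g[pos] / (-np.expm1(-2.0 * g[pos]))
        # multiply through by exp(2g) for stability at strongly negative gamma
        out[neg] = 2.0 * g[neg] * np.exp(2.0 * g[neg]) / np.expm1(2.0 * g[neg])
    out[zero] = 1.0
    return out if out.ndim else float(out)


def _density_ratio(q: np.ndarray, gamma: float) -> np.ndarray:
    """(1 - exp(-2*gamma*(1-q))) / (1 - exp(-2*gamma)), -> (1-q) as gamma -> 0."""
    if gamma == 0.0:
        return 1.0 - q
    if gamma > 0:
        return np.expm1(-2.0 * gamma * (1.0 - q)) / np.expm1(-2.0 * gamma)
    # gamma < 0: scale numerator and denominator by exp(2*gamma) to avoid overflow
    return ((np.exp(2.0 * gamma * q) - np.exp(2.0 * gamma))
            / -np.expm1(2.0 * gamma))


def prf_polymorphism_factor(gamma: float, n: int, rtol: float = 1e-10) -> float:
    """G(gamma, n): expected sampled replacement polymorphism relative to a
    neutral site, from the stationary PRF frequency density.

    G = [integral of (1 - q^n - (1-q)^n) * f(q; gamma) dq] / a_n with
    f(q; gamma) = density_ratio / (q (1-q)); the neutral denominator is a_n
    exactly.  G(0, n) = 1.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    gamma = float(gamma)
    if gamma == 0.0:
        return 1.0

    def integrand(q):
        s = 1.0 - q**n - (1.0 - q) ** n
        return s * _density_ratio(np.asarray(q), gamma) / (q * (1.0 - q))

    val, err = integrate.quad(integrand, 0.0, 1.0, epsabs=0.0, epsrel=rtol,
                              limit=200, points=(1e-8, 1.0 - 1e-8))
    if not np.isfinite(val) or (val != 0 and err / abs(val) > 1e-6):
        raise RuntimeError(
            f"PRF quadrature did not converge at gamma={gamma}, n={n}: "
            f"value {val}, error estimate {err}")
    return float(val / harmonic(n))


class _GTable:
    """Cubic-spline interpolant of G(gamma, n) on a gamma grid, per n.

    The MCMC evaluates G millions of times; direct quadrature per proposal
    would dominate the runtime.  gamma outside the grid is clipped (the
    hierarchical prior makes such excursions vanishingly rare).
    """

    def __init__(self, gamma_range=(-30.0, 30.0), n_points=601):
        self.grid = np.linspace(*gamma_range, n_points)
        self._splines: dict[int, CubicSpline] = {}

    def spline(self, n: int) -> CubicSpline:
        if n not in self._splines:
            vals = [prf_polymorphism_factor(g, n, rtol=1e-10) for g in self.grid]
            self._splines[n] = CubicSpline(self.grid, np.log(vals))
        return self._splines[n]

    def __call__(self, gamma: np.ndarray, n_arr: np.ndarray) -> np.ndarray:
        out = np.empty_like(np.asarray(gamma, float))
        gclip = np.clip(gamma, self.grid[0], self.grid[-1])
        for n in np.unique(n_arr):
            m = n_arr == n
            out[m] = np.exp(self.spline(int(n))(gclip[m]))
        return out


_G_TABLE = _GTable()


# ---------------------------------------------------------------------------
# likelihood and MCMC


def _log_poisson(k, mu):
    with np.errstate(divide="ignore", invalid="ignore"):
        lp = k * np.log(mu) - mu - gammaln(k + 1.0)
    return np.where((mu == 0) & (k == 0), 0.0, lp)


def prf_loglik(tables: list[MKTable], theta_s: np.ndarray, theta_r: np.ndarray,
               gamma: np.ndarray, tau: float,
               g_of_gamma: np.ndarray | None = None) -> float:
    """Joint Poisson log-likelihood of all MK tables."""
    theta_s = np.asarray(theta_s, float)
    theta_r = np.asarray(theta_r, float)
    gamma = np.asarray(gamma, float)
    if (theta_s <= 0).any() or (theta_r <= 0).any() or tau <= 0:
        raise ValueError("prf_loglik requires positive theta_s, theta_r, tau")
    if not np.isfinite(gamma).all():
        raise ValueError("gamma must be finite")
    n_arr = np.array([t.n for t in tables])
    a = np.array([harmonic(int(n)) for n in n_arr])
    Ps = np.array([t.Ps for t in tables], float)
    Pn = np.array([t.Pn for t in tables], float)
    Ds = np.array([t.Ds for t in tables], float)
    Dn = np.array([t.Dn for t in tables], float)
    G = _G_TABLE(gamma, n_arr) if g_of_gamma is None else g_of_gamma
    H = prf_fixation_factor(gamma)
    lnl = (_log_poisson(Ps, theta_s * a)
           + _log_poisson(Ds, theta_s * (tau + 1.0))
           + _log_poisson(Pn, theta_r * a * G)
           + _log_poisson(Dn, theta_r * (tau + 1.0) * H))
    total = float(lnl.sum())
    if not np.isfinite(total):
        raise FloatingPointError(
            f"non-finite PRF likelihood: theta_s={theta_s}, theta_r={theta_r}, "
            f"gamma={gamma}, tau={tau}")
    return total


@dataclass
class PRFPosterior:
    summary: pd.DataFrame           # per locus: mean gamma, q2.5, q97.5, class
    gamma_samples: np.ndarray       # (n_samples, n_loci)
    class_mean_samples: pd.DataFrame  # columns = class labels (Fig-style curves)
    acceptance: dict
    settings: dict

    def class_flagged(self) -> pd.DataFrame:
        """Loci whose 95% interval excludes 0."""
        s = self.summary
        return s[(s["q2.5"] > 0) | (s["q97.5"] < 0)]


def run_mkprf(tables: list[MKTable], cycles: int = 100_000, burn_in: int = 1_000,
              thin: int = 10, seed=0, tau: float = 15.0,
              sigma2: float = 4.0,
              step_theta: float = 0.35, step_gamma: float = 0.6) -> PRFPosterior:
    """Hierarchical Bayesian MK-PRF sampler.

    Metropolis-within-Gibbs: log-normal random-walk proposals on theta_s and
    theta_r (Jeffreys-style flat prior on log theta), normal random walk on
    each gamma_i under the prior Normal(mu_class, sigma2), and an exact Gibbs
    draw for each class mean mu (flat hyperprior).  One cycle updates every
    parameter once, vectorized across loci.
    """
    if not tables:
        raise ValueError("run_mkprf needs at least one MK table")
    if cycles <= burn_in:
        raise ValueError("cycles must exceed burn_in")
    rng = rng_from(seed, "mkprf")
    n_loci = len(tables)
    n_arr = np.array([t.n for t in tables])
    a = np.array([harmonic(int(n)) for n in n_arr])
    Ps = np.array([t.Ps for t in tables], float)
    Pn = np.array([t.Pn for t in tables], float)
    Ds = np.array([t.Ds for t in tables], float)
    Dn = np.array([t.Dn for t in tables], float)
    classes = np.array([t.locus_class for t in tables])
    class_labels = list(dict.fromkeys(classes))
    class_idx = {c: np.nonzero(classes == c)[0] for c in class_labels}

    # moment-style initialization (pseudocount 0.5 avoids log 0)
    theta_s = ((Ps + 0.5) / a + (Ds + 0.5) / (tau + 1.0)) / 2.0
    theta_r = ((Pn + 0.5) / a + (Dn + 0.5) / (tau + 1.0)) / 2.0
    gamma = np.zeros(n_loci)
    mu = {c: 0.0 for c in class_labels}

    spline_by_n = {int(n): _G_TABLE.spline(int(n)) for n in np.unique(n_arr)}
    glo, ghi = _G_TABLE.grid[0], _G_TABLE.grid[-1]

    def G_of(g):
        out = np.empty_like(g)
        gc = np.clip(g, glo, ghi)
        for n, sp in spline_by_n.items():
            m = n_arr == n
            out[m] = np.exp(sp(gc[m]))
        return out

    def ll_silent(ts):
        return _log_poisson(Ps, ts * a) + _log_poisson(Ds, ts * (tau + 1.0))

    def ll_repl(tr, g, G=None):
        if G is None:
            G = G_of(g)
        return (_log_poisson(Pn, tr * a * G)
                + _log_poisson(Dn, tr * (tau + 1.0) * prf_fixation_factor(g)))

    lls = ll_silent(theta_s)
    G_cur = G_of(gamma)
    llr = ll_repl(theta_r, gamma, G_cur)

    keep = (cycles - burn_in) // thin
    gamma_out = np.empty((keep, n_loci))
    mu_out = np.empty((keep, len(class_labels)))
    acc = {"theta_s": 0, "theta_r": 0, "gamma": 0}
    kept = 0
    mu_vec = np.array([mu[c] for c in classes])

    for it in range(cycles):
        # --- theta_s (vectorized componentwise MH, log-scale walk)
        prop = theta_s * np.exp(step_theta * rng.standard_normal(n_loci))
        ll_p = ll_silent(prop)
        accept = np.log(rng.random(n_loci)) < ll_p - lls
        theta_s = np.where(accept, prop, theta_s)
        lls = np.where(accept, ll_p, lls)
        acc["theta_s"] += int(accept.sum())

        # --- theta_r
        prop = theta_r * np.exp(step_theta * rng.standard_normal(n_loci))
        ll_p = ll_repl(prop, gamma, G_cur)
        accept = np.log(rng.random(n_loci)) < ll_p - llr
        theta_r = np.where(accept, prop, theta_r)
        llr = np.where(accept, ll_p, llr)
        acc["theta_r"] += int(accept.sum())

        # --- gamma, with Normal(mu_class, sigma2) prior
        prop = gamma + step_gamma * rng.standard_normal(n_loci)
        G_p = G_of(prop)
        ll_p = ll_repl(theta_r, prop, G_p)
        dprior = ((gamma - mu_vec) ** 2 - (prop - mu_vec) ** 2) / (2.0 * sigma2)
        accept = np.log(rng.random(n_loci)) < ll_p - llr + dprior
        gamma = np.where(accept, prop, gamma)
        G_cur = np.where(accept, G_p, G_cur)
        llr = np.where(accept, ll_p, llr)
        acc["gamma"] += int(accept.sum())

        # --- class means: exact Gibbs (flat hyperprior)
        for ci, c in enumerate(class_labels):
            idx = class_idx[c]
            mu[c] = rng.normal(gamma[idx].mean(), np.sqrt(sigma2 / len(idx)))
        mu_vec = np.array([mu[c] for c in classes])

        if it >= burn_in and (it - burn_in) % thin == 0 and kept < keep:
            gamma_out[kept] = gamma
            mu_out[kept] = [mu[c] for c in class_labels]
            kept += 1

    rates = {k: v / (cycles * n_loci) for k, v in acc.items()}
    for name, rate in rates.items():
        if rate < 0.01 or rate > 0.99:
            import warnings
            warnings.warn(f"mkprf: pathological acceptance rate {rate:.3f} "
                          f"for {name}; consider retuning step sizes")

    gamma_out = gamma_out[:kept]
    mu_out = mu_out[:kept]
    summary = pd.DataFrame({
        "locus_id": [t.locus_id for t in tables],
        "locus_class": classes,
        "gamma_mean": gamma_out.mean(axis=0),
        "q2.5": np.quantile(gamma_out, 0.025, axis=0),
        "q97.5": np.quantile(gamma_out, 0.975, axis=0),
    })
    return PRFPosterior(
        summary=summary, gamma_samples=gamma_out,
        class_mean_samples=pd.DataFrame(mu_out, columns=class_labels),
        acceptance=rates,
        settings={"cycles": cycles, "burn_in": burn_in, "thin": thin,
                  "seed": seed, "tau": tau, "sigma2": sigma2})
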