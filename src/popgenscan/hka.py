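"""Multilocus HKA neutrality test and maximum-likelihood HKA (mlHKA).

The classical test fits, by the method of moments, per-locus population
mutation parameters theta_i and a shared divergence time T to the observed
silent segregating sites S_i and silent divergence counts D_i under

    E[S_i] = theta_i * a_{n_i}          (Watterson expectation)
    E[D_i] = theta_i * (T + 1)          (divergence + one ancestral unit)

and measures goodness of fit by the summed chi-square deviation with the
variance forms Var(S) = E[S] + b_n * theta^2 and Var(D) = E[D] + theta^2,
df = L - 1 for single-species polymorphism plus divergence data.

mlHKA places a per-locus selection factor k on the same counts:

    S_i ~ Poisson(k_i * theta_i * a_{n_i})
    D_i ~ Poisson(theta_i * (T + k_i))

so k scales polymorphism and the ancestral-polymorphism component of
divergence; k = 1 is neutrality, k > 1 suggests balancing selection, k < 1 a
sweep.  With T fixed, the likelihood separates by locus and the per-locus
theta given k has the closed form theta_i = (S_i + D_i)/(k_i a_i + T + k_i),
so the profile likelihood over each free k is maximized exactly by a bounded
one-dimensional search — deterministic, and guaranteeing LR >= 0 between
nested fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar
from scipy.special import gammaln
from scipy.stats import chi2

from ._util import harmonic, harmonic2, rng_from

_T_MIN = -1.0 + 1e-9
_T_MAX = 1e8


@dataclass
class PolyDivTable:
    """Per-locus (S, D, L, n) counts consumed by HKA and mlHKA.

    S: silent segregating sites within the focal species; D: silent
    divergence count vs the outgroup; L: silent sites; n: chromosomes.
    """

    data: pd.DataFrame

    REQUIRED = ("locus", "S", "D", "L", "n")

    def __post_init__(self):
        df = pd.DataFrame(self.data)
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ValueError(f"PolyDivTable missing column {col!r}")
        if (df["S"] < 0).any() or (df["D"] < 0).any():
            raise ValueError("S and D must be non-negative")
        if (df["n"] < 2).any():
            raise ValueError("n must be >= 2 at every locus")
        if (df["L"] <= 0).any():
            raise ValueError("L must be positive")
        self.data = df.reset_index(drop=True)

    @classmethod
    def from_tsv(cls, path) -> "PolyDivTable":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @property
    def n_loci(self) -> int:
        return len(self.data)

    @property
    def a_n(self) -> np.ndarray:
        return np.array([harmonic(int(n)) for n in self.data["n"]])

    @property
    def b_n(self) -> np.ndarray:
        return np.array([harmonic2(int(n)) for n in self.data["n"]])


@dataclass
class HKAResult:
    theta_hat: np.ndarray
    T_hat: float
    deviation_sum: float          # X^2
    df: int
    p_chi: float
    per_locus: pd.DataFrame
    p_sim: float | None = None
    boundary: bool = False        # T at its lower boundary (e.g. all D = 0)


@dataclass
class MLHKAResult:
    free_k_loci: tuple[str, ...]
    lnl: float
    lnl_neutral: float
    k_hat: dict
    theta_hat: np.ndarray
    T: float
    LR: float
    p: float
    valid: bool = True


# ---------------------------------------------------------------------------
# classical HKA


def _solve_T(S: np.ndarray, D: np.ndarray, a: np.ndarray) -> tuple[float, bool]:
    """Root of sum_i a_i (S_i+D_i)/(a_i+T+1) = sum_i S_i; monotone in T."""
    tot = S + D

    def g(T):
        return float(np.sum(a * tot / (a + T + 1.0)) - S.sum())

    if g(_T_MIN) <= 0:          # all D == 0 (or degenerate): boundary
        return _T_MIN, True
    if g(_T_MAX) > 0:
        raise RuntimeError(f"HKA moment fit failed to bracket T; residual {g(_T_MAX)}")
    return brentq(g, _T_MIN, _T_MAX, xtol=1e-10, rtol=1e-12), False


def fit_hka(table: PolyDivTable) -> tuple[np.ndarray, float]:
    """Method-of-moments HKA fit: per-locus theta and shared T.

    Uses the per-locus constraint S_i + D_i = theta_i (a_i + T + 1) together
    with the total-polymorphism constraint sum S_i = sum theta_i a_i.
    """
    if table.n_loci < 2:
        raise ValueError(">=2 loci required for the HKA fit")
    S = table.data["S"].to_numpy(float)
    D = table.data["D"].to_numpy(float)
    a = table.a_n
    T, boundary = _solve_T(S, D, a)
    theta = (S + D) / (a + T + 1.0)
    if boundary:
        import warnings
        warnings.warn("HKA: T at lower boundary (total divergence ~ 0)")
    return theta, float(T)


def hka_statistic(table: PolyDivTable, theta_hat: np.ndarray,
                  T_hat: float) -> HKAResult:
    """Summed chi-square deviation, df = L - 1, and its upper-tail p."""
    S = table.data["S"].to_numpy(float)
    D = table.data["D"].to_numpy(float)
    a, b = table.a_n, table.b_n
    exp_S = theta_hat * a
    exp_D = theta_hat * (T_hat + 1.0)
    var_S = exp_S + b * theta_hat**2
    var_D = exp_D + theta_hat**2
    dev_S = np.where(var_S > 0, (S - exp_S) ** 2 / np.where(var_S > 0, var_S, 1), 0.0)
    dev_D = np.where(var_D > 0, (D - exp_D) ** 2 / np.where(var_D > 0, var_D, 1), 0.0)
    x2 = float(dev_S.sum() + dev_D.sum())
    df = table.n_loci - 1
    per_locus = pd.DataFrame({
        "locus": table.data["locus"], "S": S, "D": D,
        "exp_S": exp_S, "exp_D": exp_D, "dev_S": dev_S, "dev_D": dev_D,
    })
    return HKAResult(theta_hat=theta_hat, T_hat=T_hat, deviation_sum=x2,
                     df=df, p_chi=float(chi2.sf(x2, df)), per_locus=per_locus,
                     boundary=T_hat <= _T_MIN + 1e-12)


def hka_test(table: PolyDivTable) -> HKAResult:
    theta, T = fit_hka(table)
    return hka_statistic(table, theta, T)


def _simulate_total_lengths(n: int, reps: int, rng) -> np.ndarray:
    """Total coalescent tree lengths for `reps` replicates (vectorized)."""
    k = np.arange(n, 1, -1)
    waits = rng.exponential(size=(reps, n - 1)) * (2.0 / (k * (k - 1)))
    return waits @ k.astype(float)


def _solve_T_many(S: np.ndarray, D: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Vectorized bisection of the HKA T equation, one root per row of S/D."""
    tot = S + D
    target = S.sum(axis=1)

    def g(T):
        return (a * tot / (a + T[:, None] + 1.0)).sum(axis=1) - target

    lo = np.full(len(S), _T_MIN)
    hi = np.full(len(S), 1e6)
    boundary = g(lo) <= 0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        pos = g(mid) > 0
        lo = np.where(pos, mid, lo)
        hi = np.where(pos, hi, mid)
    T = 0.5 * (lo + hi)
    T[boundary] = _T_MIN
    return T


def hka_parametric_p(table: PolyDivTable, reps: int = 10000, seed=0,
                     result: HKAResult | None = None) -> float:
    """Parametric-bootstrap p for the HKA deviation.

    Simulates `reps` datasets from the fitted null (coalescent-distributed
    S: Poisson mutations on simulated tree lengths; Poisson divergence),
    refits each, and returns the add-one fraction of simulated deviations at
    least as large as the observed one.
    """
    if result is None:
        result = hka_test(table)
    rng = rng_from(seed, "hka_parametric")
    L = table.n_loci
    a, b = table.a_n, table.b_n
    theta, T = result.theta_hat, result.T_hat
    S_sim = np.empty((reps, L))
    D_sim = np.empty((reps, L))
    for i in range(L):
        n_i = int(table.data["n"].iloc[i])
        lengths = _simulate_total_lengths(n_i, reps, rng)
        S_sim[:, i] = rng.poisson(theta[i] / 2.0 * lengths)
        D_sim[:, i] = rng.poisson(theta[i] * (T + 1.0), size=reps)
    T_hat = _solve_T_many(S_sim, D_sim, a)
    theta_hat = (S_sim + D_sim) / (a + T_hat[:, None] + 1.0)
    exp_S = theta_hat * a
    exp_D = theta_hat * (T_hat[:, None] + 1.0)
    var_S = exp_S + b * theta_hat**2
    var_D = exp_D + theta_hat**2
    with np.errstate(invalid="ignore", divide="ignore"):
        dev = (np.where(var_S > 0, (S_sim - exp_S) ** 2 / var_S, 0.0).sum(axis=1)
               + np.where(var_D > 0, (D_sim - exp_D) ** 2 / var_D, 0.0).sum(axis=1))
    return float((1 + np.sum(dev >= result.deviation_sum)) / (reps + 1))


# ---------------------------------------------------------------------------
# mlHKA


def _log_poisson(k: np.ndarray, mu: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        lp = k * np.log(mu) - mu - gammaln(k + 1.0)
    return np.where((mu == 0) & (k == 0), 0.0, lp)


def mlhka_loglik(table: PolyDivTable, theta: np.ndarray, k: np.ndarray,
                 T: float) -> float:
    """Poisson log-likelihood of (S, D) under the mlHKA model."""
    theta = np.asarray(theta, float)
    k = np.asarray(k, float)
    if (theta <= 0).any() or (k <= 0).any() or T <= 0:
        raise ValueError("mlhka_loglik requires theta > 0, k > 0, T > 0")
    S = table.data["S"].to_numpy(float)
    D = table.data["D"].to_numpy(float)
    a = table.a_n
    return float(_log_poisson(S, k * theta * a).sum()
                 + _log_poisson(D, theta * (T + k)).sum())


def _profile_lnl_locus(S: float, D: float, a: float, k: float, T: float) -> float:
    """Per-locus profile log-likelihood at selection factor k (theta profiled
    out in closed form)."""
    theta = (S + D) / (k * a + T + k)
    if theta <= 0:  # S = D = 0: likelihood is maximized at theta -> 0
        return 0.0
    mu_s, mu_d = k * theta * a, theta * (T + k)
    return float(_log_poisson(np.array([S]), np.array([mu_s]))[0]
                 + _log_poisson(np.array([D]), np.array([mu_d]))[0])


def fit_mlhka(table: PolyDivTable, free_k_loci: tuple[str, ...] = (),
              T: float = 15.0, chain_length: int = 200, seed=0,
              k_bounds: tuple[float, float] = (1e-3, 1e3)) -> MLHKAResult:
    """Maximize the mlHKA likelihood with free selection factors at the given
    loci (all other k pinned at 1).

    Because T is fixed the likelihood separates by locus: each free k is
    found by a deterministic coarse grid scan (``chain_length`` points on a
    log scale) refined by bounded scalar minimization; theta at each locus is
    profiled out exactly.  ``seed`` is accepted for interface stability but
    the optimization is deterministic.
    """
    loci = list(table.data["locus"])
    unknown = set(free_k_loci) - set(loci)
    if unknown:
        raise ValueError(f"free_k_loci not in table: {sorted(unknown)}")
    S = table.data["S"].to_numpy(float)
    D = table.data["D"].to_numpy(float)
    a = table.a_n

    k_hat = {}
    lnl = 0.0
    lnl_neutral = 0.0
    theta_hat = np.empty(table.n_loci)
    grid = np.exp(np.linspace(np.log(k_bounds[0]), np.log(k_bounds[1]),
                              max(int(chain_length), 25)))
    for i, locus in enumerate(loci):
        lnl_i_neutral = _profile_lnl_locus(S[i], D[i], a[i], 1.0, T)
        lnl_neutral += lnl_i_neutral
        if locus in free_k_loci:
            vals = [_profile_lnl_locus(S[i], D[i], a[i], g, T) for g in grid]
            j = int(np.argmax(vals))
            lo = grid[max(j - 1, 0)]
            hi = grid[min(j + 1, len(grid) - 1)]
            res = minimize_scalar(
                lambda lk: -_profile_lnl_locus(S[i], D[i], a[i], np.exp(lk), T),
                bounds=(np.log(lo), np.log(hi)), method="bounded",
                options={"xatol": 1e-10})
            k_i = float(np.exp(res.x))
            lnl_i = -float(res.fun)
            if lnl_i < lnl_i_neutral:  # never below the nested neutral value
                k_i, lnl_i = 1.0, lnl_i_neutral
            k_hat[locus] = k_i
            lnl += lnl_i
            theta_hat[i] = (S[i] + D[i]) / (k_i * a[i] + T + k_i)
        else:
            lnl += lnl_i_neutral
            theta_hat[i] = (S[i] + D[i]) / (a[i] + T + 1.0)

    LR, p, valid = lrt(lnl_neutral, lnl, df=max(len(free_k_loci), 1))
    return MLHKAResult(free_k_loci=tuple(free_k_loci), lnl=lnl,
                       lnl_neutral=lnl_neutral, k_hat=k_hat,
                       theta_hat=theta_hat, T=T, LR=LR, p=p, valid=valid)


def lrt(lnl_null: float, lnl_alt: float, df: int = 1,
        tol: float = 1e-8) -> tuple[float, float, bool]:
    """Likelihood-ratio test for nested models.

    Returns (LR, p, valid).  A negative LR beyond tolerance — an optimizer
    failure in whichever program produced the likelihoods — is flagged
    invalid with p = NaN rather than reported as a number.
    """
    LR = 2.0 * (lnl_alt - lnl_null)
    if LR < -tol:
        return float(LR), float("nan"), False
    LR = max(LR, 0.0)
    return float(LR), float(chi2.sf(LR, df)), True


def mlhka_scan(table: PolyDivTable, candidate_loci: list[str],
               T: float = 15.0, **kw) -> pd.DataFrame:
    """One-free-k mlHKA fit per candidate locus, Table-style output."""
    rows = []
    for locus in candidate_loci:
        res = fit_mlhka(table, free_k_loci=(locus,), T=T, **kw)
        rows.append({"locus": locus, "lnL_neutral": res.lnl_neutral,
                     "lnL": res.lnl, "LR": res.LR, "p": res.p,
                     "k": res.k_hat[locus], "valid": res.valid})
    return pd.DataFrame(rows)
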