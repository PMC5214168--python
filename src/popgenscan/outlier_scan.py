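"""Simulation-based outlier scans.

Two scans are provided:

* a genomewide neutral null for (pi_sil, Tajima's D_sil), calibrated from the
  reference loci's per-locus Watterson estimates, against which candidate
  loci are flagged as outliers of the simulated 2-D cloud;
* the per-locus pi_T-S differentiation test: observed pooled-minus-within
  diversity compared with the 95% interval of neutral coalescent replicates
  conditioned on the observed number of segregating sites, with the pooled
  sample treated as one panmictic population and split into pseudo-species
  of the observed sizes by fixed block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import UNDEFINED, is_defined, rng_from
from .coalsim import drop_mutations_fixed_s, drop_mutations_theta, simulate_genealogy
from .popstats import tajimas_d


@dataclass
class NullDistribution:
    """Simulated neutral cloud of (pi_sil per site, Tajima's D)."""

    species: str
    n_chrom: int
    reps: int
    points: pd.DataFrame          # columns pi_sil, tajima_d (NaN rows dropped)
    calibration: pd.DataFrame     # the (theta per site, L) pairs resampled


@dataclass
class PiTSResult:
    locus_id: str
    pi_t: float
    pi_s: float
    pi_ts: float
    ci_low: float
    ci_high: float
    significant: bool
    reps: int
    skipped: str | None = None    # reason when the test could not run


def calibrate_null(reference_summaries: pd.DataFrame, n_chrom: int,
                   reps: int = 10_000, seed=0,
                   species: str = "") -> NullDistribution:
    """Simulate the reference-calibrated genomewide neutral null.

    ``reference_summaries`` needs columns ``theta_w`` (per silent site) and
    ``sites`` (silent length); each replicate draws one reference locus
    uniformly (theta and length matched) and simulates a fixed-theta
    neutral coalescent sample of ``n_chrom`` chromosomes.
    """
    ref = pd.DataFrame(reference_summaries)
    for col in ("theta_w", "sites"):
        if col not in ref.columns:
            raise ValueError(f"reference summaries need column {col!r}")
    ref = ref[np.isfinite(ref["theta_w"])]
    if len(ref) < 1 or (ref["theta_w"] <= 0).all():
        raise ValueError("no reference locus with positive theta estimate")
    rng = rng_from(seed, "outlier_null")
    thetas = ref["theta_w"].to_numpy(float)
    lengths = ref["sites"].to_numpy(float)
    picks = rng.integers(0, len(ref), size=reps)
    pi_vals = np.empty(reps)
    d_vals = np.empty(reps)
    n = n_chrom
    for r in range(reps):
        i = picks[r]
        tree = simulate_genealogy(n, rng)
        counts = _mutation_counts_theta(tree, thetas[i] * lengths[i], rng)
        S = len(counts)
        pi_locus = float(np.sum(2.0 * counts * (n - counts)) / (n * (n - 1)))
        pi_vals[r] = pi_locus / lengths[i]
        d_vals[r] = tajimas_d(S, n, pi_locus)
    points = pd.DataFrame({"pi_sil": pi_vals, "tajima_d": d_vals})
    return NullDistribution(species=species, n_chrom=n_chrom, reps=reps,
                            points=points,
                            calibration=ref[["theta_w", "sites"]].reset_index(drop=True))


def _mutation_counts_theta(tree, theta_locus, rng) -> np.ndarray:
    """Derived counts per segregating site, without building the matrix."""
    n_mut = rng.poisson(theta_locus / 2.0 * tree.total_length)
    if n_mut == 0:
        return np.zeros(0, dtype=int)
    p = tree.branch_length / tree.total_length
    branches = rng.choice(len(p), size=int(n_mut), p=p)
    return tree.leaf_counts[branches]


def flag_outliers(candidate_summaries: pd.DataFrame, null: NullDistribution,
                  alpha: float = 0.05, bins: int = 50) -> pd.DataFrame:
    """Flag candidates outside the empirical (1-alpha) highest-density region.

    The null cloud is binned on a ``bins`` x ``bins`` grid; a candidate's
    density rank is the fraction of null mass lying in bins no denser than
    the candidate's bin, and it is flagged when that rank is <= alpha.
    Marginal percentile positions are reported per axis.  Candidates with an
    undefined D (S = 0) are reported unassessable, not flagged.
    """
    pts = null.points.dropna()
    if len(pts) < 1000:
        raise ValueError("null distribution needs >= 1000 usable points")
    cand = pd.DataFrame(candidate_summaries)
    x = pts["pi_sil"].to_numpy()
    y = pts["tajima_d"].to_numpy()
    cx = cand["pi_sil"].to_numpy(float)
    cy = cand["tajima_d"].to_numpy(float)
    fx = cx[np.isfinite(cx)]
    fy = cy[np.isfinite(cy)]
    x_edges = np.linspace(min(x.min(), *fx, x.min()) - 1e-12,
                          max(x.max(), *fx, x.max()) + 1e-12, bins + 1)
    y_edges = np.linspace(min(y.min(), *fy, y.min()) - 1e-12,
                          max(y.max(), *fy, y.max()) + 1e-12, bins + 1)
    hist, _, _ = np.histogram2d(x, y, bins=[x_edges, y_edges])
    total = hist.sum()

    def density_rank(px, py):
        ix = min(np.searchsorted(x_edges, px, side="right") - 1, bins - 1)
        iy = min(np.searchsorted(y_edges, py, side="right") - 1, bins - 1)
        d = hist[max(ix, 0), max(iy, 0)]
        return float(hist[hist <= d].sum() / total)

    rows = []
    for i in range(len(cand)):
        row = {"locus_id": cand["locus_id"].iloc[i] if "locus_id" in cand else i,
               "pi_sil": cx[i], "tajima_d": cy[i]}
        if not np.isfinite(cy[i]) or not np.isfinite(cx[i]):
            row.update(density_rank=UNDEFINED, pi_percentile=UNDEFINED,
                       d_percentile=UNDEFINED, flagged=False, assessable=False)
        else:
            rank = density_rank(cx[i], cy[i])
            row.update(
                density_rank=rank,
                pi_percentile=float(np.mean(x <= cx[i])),
                d_percentile=float(np.mean(y <= cy[i])),
                flagged=bool(rank <= alpha),
                assessable=True)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pi_T-S


def pi_ts_observed(pi_pooled: float, pi_within: list[float]) -> float:
    """pi_T-S = pooled two-species diversity minus mean within-species diversity."""
    return float(pi_pooled - np.mean(pi_within))


def _pi_ts_from_counts(counts: np.ndarray, counts_sp1: np.ndarray,
                       n1: int, n2: int) -> float:
    """pi_T-S (per locus, unnormalized by length) from per-column derived
    counts in the pooled sample and within pseudo-species 1."""
    n = n1 + n2
    c = counts.astype(float)
    c1 = counts_sp1.astype(float)
    c2 = c - c1
    pi_t = np.sum(2.0 * c * (n - c)) / (n * (n - 1))
    pi_1 = np.sum(2.0 * c1 * (n1 - c1)) / (n1 * (n1 - 1))
    pi_2 = np.sum(2.0 * c2 * (n2 - c2)) / (n2 * (n2 - 1))
    return float(pi_t - 0.5 * (pi_1 + pi_2))


def pi_ts_null_quantiles(n1: int, n2: int, S: int, L: float,
                         reps: int = 10_000, seed=0,
                         alpha: float = 0.05) -> tuple[float, float]:
    """95% interval of pi_T-S per site under the panmictic S-conditioned null.

    Each replicate simulates one neutral genealogy of n1+n2 chromosomes with
    exactly S segregating sites and splits the sample into fixed blocks of
    n1 and n2 pseudo-species.
    """
    rng = rng_from(seed, "pi_ts")
    n = n1 + n2
    vals = np.empty(reps)
    for r in range(reps):
        tree = simulate_genealogy(n, rng)
        if S == 0:
            vals[r] = 0.0
            continue
        p = tree.branch_length / tree.total_length
        branches = rng.choice(len(p), size=S, p=p)
        counts = tree.leaf_counts[branches]
        counts_sp1 = tree.leaf_sets[branches][:, :n1].sum(axis=1)
        vals[r] = _pi_ts_from_counts(counts, counts_sp1, n1, n2) / L
    return (float(np.quantile(vals, alpha / 2.0)),
            float(np.quantile(vals, 1.0 - alpha / 2.0)))


def pi_ts_test(aln, classes, reps: int = 10_000, seed=0,
               class_filter: str = "all", alpha: float = 0.05) -> PiTSResult:
    """pi_T-S differentiation test for one two-species locus alignment."""
    from .popstats import pi, segregating_sites

    species = aln.species_labels
    if len(species) != 2:
        raise ValueError("pi_ts_test needs both species at the locus")
    sites = classes.effective_sites(class_filter)
    S = segregating_sites(aln, classes, class_filter)
    if S == 0:
        return PiTSResult(locus_id=aln.locus_id, pi_t=0.0, pi_s=0.0, pi_ts=0.0,
                          ci_low=UNDEFINED, ci_high=UNDEFINED,
                          significant=False, reps=reps,
                          skipped="no segregating sites")
    pi_t = pi(aln, classes, class_filter)
    pi_within = [pi(aln, classes, class_filter, rows=aln.species_rows(sp))
                 for sp in species]
    obs = pi_ts_observed(pi_t, pi_within)
    n1 = int(aln.species_rows(species[0]).sum())
    n2 = int(aln.species_rows(species[1]).sum())
    lo, hi = pi_ts_null_quantiles(n1, n2, S, sites, reps=reps, seed=seed,
                                  alpha=alpha)
    eps = 1e-9 * max(abs(lo), abs(hi), abs(obs), 1e-12)  # guard quantile atoms
    return PiTSResult(locus_id=aln.locus_id, pi_t=pi_t,
                      pi_s=float(np.mean(pi_within)), pi_ts=obs,
                      ci_low=lo, ci_high=hi,
                      significant=bool(obs < lo - eps or obs > hi + eps),
                      reps=reps)


def plot_null_cloud(null: NullDistribution, report: pd.DataFrame, path) -> None:
    """Scatter the simulated (pi_sil, D) cloud with candidates overlaid."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    pts = null.points.dropna()
    ax.scatter(pts["pi_sil"], pts["tajima_d"], s=2, alpha=0.15,
               color="grey", label="neutral simulations")
    ok = report[report["assessable"]]
    ax.scatter(ok["pi_sil"], ok["tajima_d"],
               c=["red" if f else "black" for f in ok["flagged"]],
               s=30, zorder=3, label="candidates")
    ax.set_xlabel(r"$\pi_{sil}$")
    ax.set_ylabel("Tajima's D")
    ax.set_title(f"{null.species} (n={null.n_chrom})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
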