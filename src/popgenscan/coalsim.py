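"""Standard-neutral-model coalescent simulation without recombination.

Implements the single-population constant-size coalescent used for every null
distribution in the scan: genealogy simulation, mutation dropping in fixed-S
and fixed-theta modes, and per-replicate summary statistics.

Conventions (pinned by tests, the single most error-prone choice here):

* time is measured in units of 2N generations, so the coalescence rate for k
  lineages is k(k-1)/2 and the expected height of a 2-leaf tree is 1;
* theta = 4*N*mu per locus, and mutations fall on the tree as a Poisson
  process of rate theta/2 per unit branch length, giving E[S] = theta * a_n
  with a_n = sum_{i<n} 1/i.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from ._util import harmonic, rng_from


@dataclass
class Genealogy:
    """A realized coalescent tree for n sampled chromosomes.

    Nodes 0..n-1 are leaves; nodes n..2n-2 are internal, in coalescence
    order; node 2n-2 is the root.  ``leaf_sets[b]`` is the boolean set of
    leaves subtended by the branch above node b (the root row is all True but
    the root carries no branch).
    """

    n: int
    parent: np.ndarray          # (2n-1,) int, -1 at root
    node_time: np.ndarray       # (2n-1,) float, 0 at leaves
    branch_length: np.ndarray   # (2n-1,) float, 0 at root
    leaf_sets: np.ndarray       # (2n-1, n) bool

    @property
    def total_length(self) -> float:
        return float(self.branch_length.sum())

    @property
    def leaf_counts(self) -> np.ndarray:
        """Number of leaves below each branch (the derived-allele count a
        mutation on that branch would produce)."""
        return self.leaf_sets.sum(axis=1)


@dataclass
class SimulatedSample:
    """0/1 haplotype matrix from one coalescent replicate.

    Rows are chromosomes, columns are segregating sites (1 = derived).  Every
    column is polymorphic in the sample by construction.
    """

    matrix: np.ndarray
    mode: Literal["fixed_theta", "fixed_S"]
    seed: int | None = None
    derived_counts: np.ndarray = field(init=False)

    def __post_init__(self):
        self.derived_counts = self.matrix.sum(axis=0)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def S(self) -> int:
        return self.matrix.shape[1]


def simulate_genealogy(n: int, rng) -> Genealogy:
    """Draw one standard-coalescent genealogy for ``n`` chromosomes.

    While k lineages remain the waiting time to the next coalescence is
    exponential with rate k(k-1)/2; the merging pair is uniform among pairs.
    """
    if n < 2:
        raise ValueError("need at least 2 chromosomes")
    rng = _as_rng(rng)
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    node_time = np.zeros(n_nodes)
    leaf_sets = np.zeros((n_nodes, n), dtype=bool)
    leaf_sets[np.arange(n), np.arange(n)] = True

    active = list(range(n))
    t = 0.0
    # pre-drawn randomness keeps the per-merge cost to simple arithmetic
    expo = rng.exponential(size=n - 1)
    unif = rng.random((n - 1, 2))
    for step, new in enumerate(range(n, n_nodes)):
        k = len(active)
        t += expo[step] * 2.0 / (k * (k - 1))
        i = int(unif[step, 0] * k)
        j = int(unif[step, 1] * (k - 1))
        if j >= i:
            j += 1
        a, b = active[i], active[j]
        parent[a] = parent[b] = new
        node_time[new] = t
        leaf_sets[new] = leaf_sets[a] | leaf_sets[b]
        # replace the two children by their parent in the active set
        lo, hi = (i, j) if i < j else (j, i)
        active.pop(hi)
        active.pop(lo)
        active.append(new)

    branch_length = np.where(parent >= 0, node_time[parent] - node_time, 0.0)
    return Genealogy(n=n, parent=parent, node_time=node_time,
                     branch_length=branch_length, leaf_sets=leaf_sets)


def _place(tree: Genealogy, n_mut: int, rng) -> np.ndarray:
    """Assign ``n_mut`` mutations to branches with probability proportional to
    branch length; returns the haplotype matrix (n x n_mut)."""
    if n_mut == 0:
        return np.zeros((tree.n, 0), dtype=np.int8)
    p = tree.branch_length / tree.total_length
    branches = rng.choice(len(p), size=n_mut, p=p)
    return tree.leaf_sets[branches].T.astype(np.int8)


def drop_mutations_fixed_s(tree: Genealogy, S: int, rng,
                           seed: int | None = None) -> SimulatedSample:
    """Place exactly S mutations on the genealogy (multinomial over branches,
    conditional on the tree), one segregating column each."""
    if S < 0:
        raise ValueError("S must be >= 0")
    rng = _as_rng(rng)
    return SimulatedSample(matrix=_place(tree, S, rng), mode="fixed_S", seed=seed)


def drop_mutations_theta(tree: Genealogy, theta_locus: float, rng,
                         seed: int | None = None) -> SimulatedSample:
    """Poisson mutation dropping: S ~ Poisson(theta/2 * total tree length)."""
    if theta_locus < 0:
        raise ValueError("theta must be >= 0")
    rng = _as_rng(rng)
    n_mut = rng.poisson(theta_locus / 2.0 * tree.total_length)
    return SimulatedSample(matrix=_place(tree, int(n_mut), rng),
                           mode="fixed_theta", seed=seed)


def pairwise_pi_from_counts(derived_counts: np.ndarray, n: int) -> float:
    """Mean pairwise differences per locus from per-column derived counts."""
    c = np.asarray(derived_counts, dtype=float)
    return float(np.sum(2.0 * c * (n - c)) / (n * (n - 1)))


def simulate_summaries(n: int, mode: str, param: float, reps: int, seed,
                       L: float | None = None) -> pd.DataFrame:
    """Simulate ``reps`` neutral replicates and summarize each.

    Returns a DataFrame with columns S, pi (mean pairwise differences per
    locus), tajima_d, and — when a locus length ``L`` is given — per-site
    rates pi_site and theta_w_site.
    """
    from .popstats import tajimas_d, watterson_theta

    if reps < 1:
        raise ValueError("reps must be >= 1")
    if mode not in ("fixed_theta", "fixed_S"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = rng_from(seed, "coalsim")
    rows = []
    for _ in range(reps):
        tree = simulate_genealogy(n, rng)
        if mode == "fixed_theta":
            sample = drop_mutations_theta(tree, param, rng)
        else:
            sample = drop_mutations_fixed_s(tree, int(param), rng)
        S = sample.S
        pi = pairwise_pi_from_counts(sample.derived_counts, n)
        row = {"S": S, "pi": pi, "tajima_d": tajimas_d(S, n, pi)}
        if L is not None:
            row["pi_site"] = pi / L
            row["theta_w_site"] = watterson_theta(S, n, L)
        rows.append(row)
    return pd.DataFrame(rows)


def write_ms(samples: list[SimulatedSample], path, command: str = "popgenscan coalsim") -> None:
    """Write replicates in ms-compatible text (segsites/positions blocks)."""
    with open(path, "w") as fh:
        fh.write(f"{command}\n\n")
        for s in samples:
            fh.write("//\n")
            fh.write(f"segsites: {s.S}\n")
            if s.S:
                pos = (np.arange(s.S) + 0.5) / s.S
                fh.write("positions: " + " ".join(f"{p:.5f}" for p in pos) + "\n")
                for row in s.matrix:
                    fh.write("".join(map(str, row)) + "\n")
            fh.write("\n")


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)
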