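"""Per-locus diversity and differentiation statistics.

Watterson's theta, nucleotide diversity pi (total and per site class),
Tajima's D, raw divergence to the outgroup, and an FST with permutation
significance.  All statistics treat undefined results (S = 0 for Tajima's D,
zero total diversity for FST) as explicit NaN markers, never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import UNDEFINED, harmonic, harmonic2, is_defined
from .seqdata import LocusAlignment, SiteClassification, CLASS_FILTERS


@dataclass
class DiversitySummary:
    """Diversity statistics for one locus x one species."""

    locus_id: str
    species: str
    n: int
    sites: float              # analyzable sites in the class filter
    S: int
    theta_w: float            # per site
    pi: float                 # per site
    pi_sil: float             # per silent site (synonymous + noncoding)
    tajima_d: float           # NaN when undefined (S = 0)
    divergence_k: float       # raw per-site distance to outgroup


@dataclass
class FstResult:
    locus_id: str
    species: str
    fst: float
    permutation_p: float
    n_permutations: int


def watterson_theta(S: int, n: int, L: float) -> float:
    """Watterson's estimator S / (a_n * L), per site."""
    if n < 2:
        raise ValueError("watterson_theta requires n >= 2")
    if L <= 0:
        raise ValueError("L must be positive")
    return S / (harmonic(n) * L)


def tajimas_d(S: int, n: int, pi_total: float) -> float:
    """Tajima's D from S, sample size and mean pairwise differences per locus.

    Returns NaN (undefined) when S = 0.  Uses the canonical variance
    constants a1, a2, b1, b2, c1, c2, e1, e2 of the original test.
    """
    if S == 0:
        return UNDEFINED
    a1 = harmonic(n)
    a2 = harmonic2(n)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return UNDEFINED
    return (pi_total - S / a1) / np.sqrt(var)


# ---------------------------------------------------------------------------
# alignment-column machinery


def _column_filter(classes: SiteClassification, class_filter: str) -> np.ndarray:
    """Boolean mask of analyzable columns belonging to the class filter."""
    try:
        return CLASS_FILTERS[class_filter](classes)
    except KeyError:
        raise ValueError(f"unknown class filter {class_filter!r}") from None


def _pairwise_pi_columns(seqs: np.ndarray) -> np.ndarray:
    """Per-column mean pairwise difference for an (n x L) byte matrix."""
    n, L = seqs.shape
    diffs = np.zeros(L)
    # sum over unordered base pairs of c_a * c_b == (n^2 - sum c_a^2) / 2
    sq = np.zeros(L)
    for base in (b"A", b"C", b"G", b"T"):
        c = (seqs == base).sum(axis=0)
        sq += c.astype(float) ** 2
    diffs = (n * n - sq) / 2.0
    return diffs / (n * (n - 1) / 2.0)


def pi(aln: LocusAlignment, classes: SiteClassification,
       class_filter: str = "all", rows: np.ndarray | None = None) -> float:
    """Per-site nucleotide diversity over analyzable class-filtered columns.

    ``rows`` selects a subset of ingroup haplotypes (e.g. one species).
    """
    mask, sites = _effective_sites(classes, class_filter)
    if sites <= 0:
        raise ValueError(f"class filter {class_filter!r} selects no sites")
    seqs = aln.seqs if rows is None else aln.seqs[rows]
    if seqs.shape[0] < 2:
        raise ValueError("pi requires at least 2 sequences")
    per_col = _pairwise_pi_columns(seqs[:, mask])
    return float(per_col.sum() / sites)


def _effective_sites(classes: SiteClassification, class_filter: str):
    """(column mask, effective fractional site count) for a class filter.

    Coding columns count fractionally toward synonymous / nonsynonymous site
    totals (Nei–Gojobori weights); the mask selects every column on which a
    variant of the class could segregate.
    """
    mask = _column_filter(classes, class_filter)
    sites = classes.effective_sites(class_filter)
    return mask, sites


def segregating_sites(aln: LocusAlignment, classes: SiteClassification,
                      class_filter: str = "all",
                      rows: np.ndarray | None = None) -> int:
    """Number of class-filtered analyzable columns with >1 allele among the
    selected ingroup rows (variant columns are assigned to a class by their
    observed effect, matching the per-variant classification)."""
    mask = _column_filter(classes, class_filter)
    seqs = aln.seqs if rows is None else aln.seqs[rows]
    sub = seqs[:, mask]
    return int(np.sum((sub != sub[0]).any(axis=0)))


def divergence_to_outgroup(aln: LocusAlignment, classes: SiteClassification,
                           class_filter: str = "all",
                           rows: np.ndarray | None = None) -> float:
    """Mean raw per-site distance from ingroup haplotypes to the outgroup."""
    mask, sites = _effective_sites(classes, class_filter)
    if sites <= 0:
        raise ValueError(f"class filter {class_filter!r} selects no sites")
    seqs = aln.seqs if rows is None else aln.seqs[rows]
    out = aln.outgroup_seq[mask]
    per_hap = (seqs[:, mask] != out).sum(axis=1)
    return float(per_hap.mean() / sites)


def diversity_summary(aln: LocusAlignment, classes: SiteClassification,
                      species: str) -> DiversitySummary:
    """Assemble the per-locus, per-species summary row (Table-style)."""
    rows = aln.species_rows(species)
    n = int(rows.sum())
    if n < 2:
        raise ValueError(f"species {species!r} has fewer than 2 haplotypes")
    _, sites_all = _effective_sites(classes, "all")
    _, sites_sil = _effective_sites(classes, "silent")
    S = segregating_sites(aln, classes, "all", rows)
    pi_all = pi(aln, classes, "all", rows)
    pi_sil_v = pi(aln, classes, "silent", rows) if sites_sil > 0 else UNDEFINED
    theta = watterson_theta(S, n, sites_all)
    # Tajima's D needs pi as mean pairwise differences per locus, not per site
    d = tajimas_d(S, n, pi_all * sites_all)
    k = divergence_to_outgroup(aln, classes, "all", rows)
    return DiversitySummary(locus_id=aln.locus_id, species=species, n=n,
                            sites=sites_all, S=S, theta_w=theta, pi=pi_all,
                            pi_sil=pi_sil_v, tajima_d=d, divergence_k=k)


def summary_table(summaries: list[DiversitySummary]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in summaries])


# ---------------------------------------------------------------------------
# FST


def _onehot_variant_columns(seqs: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """One-hot (n x m x 4) base indicators restricted to the masked columns
    that are actually variable among the selected rows."""
    sub = seqs[:, mask]
    variable = (sub != sub[0]).any(axis=0)
    sub = sub[:, variable]
    onehot = np.zeros(sub.shape + (4,), dtype=np.float64)
    for bi, base in enumerate((b"A", b"C", b"G", b"T")):
        onehot[..., bi] = sub == base
    return onehot


def _fst_from_onehot(onehot: np.ndarray, order: np.ndarray,
                     offsets: np.ndarray, sizes: np.ndarray) -> float:
    """FST = 1 - Hw/Ht with per-column 2p(1-p) heterozygosities summed over
    columns; Hw averages the groups.  Frequency-based (no n/(n-1) correction)
    so merging identical groups gives exactly 0.  ``order`` assigns rows to
    contiguous group blocks delimited by ``offsets``."""
    n, m, _ = onehot.shape
    if m == 0:
        return UNDEFINED
    counts = np.add.reduceat(onehot[order], offsets, axis=0)  # (G, m, 4)
    freqs = counts / sizes[:, None, None]
    hw = float((1.0 - (freqs ** 2).sum(axis=2)).sum(axis=1).mean())
    p_tot = counts.sum(axis=0) / n
    ht = float((1.0 - (p_tot ** 2).sum(axis=1)).sum())
    if ht == 0:
        return UNDEFINED
    return 1.0 - hw / ht


def hudson_fst(aln: LocusAlignment, classes: SiteClassification,
               species: str | None = None, grouping: str = "population",
               n_perm: int = 10000, seed=0) -> FstResult:
    """FST among populations with a permutation p-value.

    p = (1 + #{permuted FST >= observed}) / (n_perm + 1), permuting sequence
    labels among populations.
    """
    rows = (aln.species_rows(species) if species is not None
            else np.ones(len(aln.ids), dtype=bool))
    groups = np.asarray(aln.populations)[rows]
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2 or (counts < 2).any():
        raise ValueError("FST requires >=2 groups with >=2 sequences each")
    mask = _column_filter(classes, "all")
    onehot = _onehot_variant_columns(aln.seqs[rows], mask)
    order = np.argsort(groups, kind="stable")
    sizes = counts  # np.unique returns labels sorted, counts aligned
    offsets = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    fst = _fst_from_onehot(onehot, order, offsets, sizes)
    p = fst_permutation_test(onehot, offsets, sizes, fst, n_perm, seed)
    return FstResult(locus_id=aln.locus_id,
                     species=species if species is not None else "all",
                     fst=fst, permutation_p=p, n_permutations=n_perm)


def fst_permutation_test(onehot: np.ndarray, offsets: np.ndarray,
                         sizes: np.ndarray, observed: float,
                         n_perm: int, seed) -> float:
    """Add-one permutation p-value for an observed FST (shuffling sequences
    among the population blocks)."""
    if not is_defined(observed):
        return UNDEFINED
    rng = np.random.default_rng(int(seed) % (2**31))
    n = onehot.shape[0]
    ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if _fst_from_onehot(onehot, perm, offsets, sizes) >= observed:
            ge += 1
    return (1 + ge) / (n_perm + 1)
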