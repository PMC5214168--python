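"""Synthetic two-species + outgroup multilocus datasets with known truth.

The generator emulates the statistical structure the scan assumes: a set of
candidate loci and a larger set of reference loci, sampled as phased
chromosomes from two sister species subdivided into island-model populations,
plus one outgroup sequence at deep scaled divergence.  Selection is emulated
at the level of summary intensities rather than forward simulation:

* a per-locus diversity scaling k multiplies every ingroup coalescent
  intensity (deeper genealogies for k > 1, shallower for k < 1), mirroring
  the mlHKA selection factor (E[S] ~ k*theta*a_n, E[D] ~ theta*(T+k));
* replacement-class mutation intensities are multiplied by the PRF factors
  G(gamma, n) on polymorphism-generating branches and H(gamma) on divergence
  (stalk) branches, mirroring the MK-PRF model.

Mutations are threaded onto a random ancestral sequence honoring the exon
layout: silent changes at noncoding positions or as synonymous codon changes,
replacement changes as nonsynonymous codon changes, one mutation per position
(infinite sites).  Emitted data use exactly the formats the alignment reader
consumes, and every locus carries a truth row with its generating parameters
and realized counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import harmonic, rng_from
from .mkprf import MKTable, prf_fixation_factor, prf_polymorphism_factor, _G_TABLE
from .seqdata import LocusAlignment, write_locus
from .hka import PolyDivTable

_DNA = np.frombuffer(b"ACGT", dtype="S1")

# codon -> amino acid, shared with seqdata's table
from .seqdata import _CODON_TO_AA


@dataclass
class GeneratorConfig:
    """Generating conditions for one synthetic dataset.

    Defaults emulate the study design the scan targets: 10 candidate and 16
    reference loci; 80 and 50 sampled chromosomes from the two species spread
    over 11 and 6 populations; per-site silent diversity near 0.0034 / 0.0053;
    locus lengths 0.4-9 kb with ~35% coding; outgroup at scaled divergence
    T = 15; island-model migration tuned to put FST in the observed ranges.
    """

    n_candidate_loci: int = 10
    n_reference_loci: int = 16
    species: tuple[str, str] = ("sp1", "sp2")
    n_chrom: tuple[int, int] = (80, 50)
    n_pops: tuple[int, int] = (11, 6)
    theta_site: tuple[float, float] = (0.0027, 0.0072)
    migration: tuple[float, float] = (28.0, 23.0)  # per-lineage island rate
    interspecies_migration: tuple[float, float] = (0.0, 0.0)  # generation-only
    tau: float = 1.0           # species split, units of 2*Ne1 generations
    T: float = 15.0            # outgroup divergence, same units
    ancestral_size: float = 1.5
    length_range: tuple[int, int] = (400, 9000)
    exon_fraction: float = 0.35
    # per-candidate-locus selection effects (cycled if shorter than the list)
    candidate_k: tuple[float, ...] = (0.4, 1.0, 1.0, 1.8, 1.0, 1.0, 0.4, 1.0, 1.0, 2.0)
    candidate_gamma: tuple[float, ...] = (1.2,) * 10
    reference_k: float = 1.0
    reference_gamma: float = 0.0

    @classmethod
    def neutral(cls, **kw) -> "GeneratorConfig":
        """Fully neutral conditions (k = 1, gamma = 0 everywhere)."""
        n_cand = kw.pop("n_candidate_loci", 10)
        return cls(n_candidate_loci=n_cand,
                   candidate_k=(1.0,) * n_cand,
                   candidate_gamma=(0.0,) * n_cand, **kw)


@dataclass
class SyntheticDataset:
    config: GeneratorConfig
    seed: int
    alignments: list
    truth: pd.DataFrame
    paths: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# structured two-species coalescent


def simulate_two_species_tree(n1: int, n2: int, d1: int, d2: int,
                              mig1: float, mig2: float, tau: float, T: float,
                              size2: float, k: float, rng,
                              anc_size: float = 1.0,
                              mig12: float = 0.0, mig21: float = 0.0):
    """Coalescent genealogy for n1 + n2 ingroup chromosomes plus one outgroup.

    Time is in units of 2*Ne1 generations.  Each species is an island model
    of d demes of equal size (species totals 1 and ``size2``); lineages
    migrate among demes of their species at per-lineage rate mig; at ``tau``
    all ingroup lineages enter one ancestral population of relative size
    ``anc_size``; the outgroup lineage joins at ``T``.  All coalescence
    intensities are divided by the locus diversity scaling ``k``.

    Returns (parent, node_time, branch_length, leaf_sets) with leaves
    0..n1-1 = species 1, n1..n1+n2-1 = species 2, and leaf n1+n2 = outgroup.
    """
    n_leaves = n1 + n2 + 1
    n_nodes = 2 * n_leaves - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    node_time = np.zeros(n_nodes)
    leaf_sets = np.zeros((n_nodes, n_leaves), dtype=bool)
    leaf_sets[np.arange(n_leaves), np.arange(n_leaves)] = True
    out_leaf = n1 + n2

    # deme ids: (0, j) for species-1 islands, (1, j) for species-2 islands,
    # "anc" after the split, "out" for the outgroup stalk
    demes: dict = {}

    def put(lin, deme):
        demes.setdefault(deme, []).append(lin)

    pops1 = np.array_split(np.arange(n1), d1)
    for j, block in enumerate(pops1):
        for lin in block:
            put(int(lin), (0, j))
    pops2 = np.array_split(np.arange(n1, n1 + n2), d2)
    for j, block in enumerate(pops2):
        for lin in block:
            put(int(lin), (1, j))
    put(out_leaf, "out")

    # pair-coalescence rate per deme type (deme size = species size / d)
    def coal_rate(deme, m):
        if m < 2:
            return 0.0
        pairs = m * (m - 1) / 2.0
        if deme == "anc":
            return pairs / (anc_size * k)
        if deme == "out":
            return 0.0
        sp = deme[0]
        d = d1 if sp == 0 else d2
        size = 1.0 if sp == 0 else size2
        return pairs * d / (size * k)

    mig_rate = {0: mig1, 1: mig2}
    between = {0: mig12, 1: mig21}
    t = 0.0
    next_node = n_leaves
    n_active = n_leaves

    while n_active > 1:
        entries = [(deme, lins) for deme, lins in demes.items() if lins]
        rates = []
        events = []
        for deme, lins in entries:
            m = len(lins)
            r = coal_rate(deme, m)
            if r > 0:
                rates.append(r)
                events.append(("coal", deme))
            if deme not in ("anc", "out") and t < tau:
                sp = deme[0]
                if mig_rate[sp] > 0 and (d1 if sp == 0 else d2) > 1:
                    rates.append(mig_rate[sp] * m)
                    events.append(("mig", deme))
                if between[sp] > 0:
                    rates.append(between[sp] * m)
                    events.append(("mig_x", deme))
        total = float(sum(rates))
        # next structural boundary
        if t < tau:
            boundary = tau
        elif t < T:
            boundary = T
        else:
            boundary = math.inf
        dt = rng.exponential(1.0 / total) if total > 0 else math.inf
        if t + dt >= boundary:
            t = boundary
            if boundary == tau:
                merged = []
                for deme in list(demes):
                    if deme not in ("anc", "out"):
                        merged.extend(demes.pop(deme))
                demes.setdefault("anc", []).extend(merged)
            else:  # boundary == T: outgroup joins the ancestral population
                demes.setdefault("anc", []).extend(demes.pop("out", []))
            continue
        t += dt
        u = rng.random() * total
        acc = 0.0
        for r, ev in zip(rates, events):
            acc += r
            if u < acc:
                kind, deme = ev
                break
        lins = demes[deme]
        if kind == "coal":
            i, j = rng.choice(len(lins), size=2, replace=False)
            a, b = lins[i], lins[j]
            for idx in sorted((i, j), reverse=True):
                lins.pop(idx)
            parent[a] = parent[b] = next_node
            node_time[next_node] = t
            leaf_sets[next_node] = leaf_sets[a] | leaf_sets[b]
            lins.append(next_node)
            next_node += 1
            n_active -= 1
        elif kind == "mig":
            sp = deme[0]
            d = d1 if sp == 0 else d2
            i = int(rng.integers(len(lins)))
            lin = lins.pop(i)
            j = int(rng.integers(d - 1))
            if j >= deme[1]:
                j += 1
            put(lin, (sp, j))
        else:  # interspecies migration (generation-only color)
            sp = deme[0]
            other = 1 - sp
            d = d1 if other == 0 else d2
            i = int(rng.integers(len(lins)))
            lin = lins.pop(i)
            put(lin, (other, int(rng.integers(d))))

    branch_length = np.where(parent >= 0, node_time[parent] - node_time, 0.0)
    return parent, node_time, branch_length, leaf_sets


# ---------------------------------------------------------------------------
# sequence threading


def _make_exons(L: int, exon_fraction: float, rng) -> list[tuple[int, int]]:
    """2-3 exons totalling ~exon_fraction of the locus, length divisible by 3."""
    coding = int(round(exon_fraction * L / 3.0)) * 3
    coding = max(coding, 0)
    if coding == 0:
        return []
    n_exons = 2 if L < 2000 else 3
    n_exons = min(n_exons, max(coding // 3, 1))
    cuts = np.sort(rng.choice(np.arange(1, coding // 3), size=n_exons - 1,
                              replace=False)) * 3 if n_exons > 1 else np.array([], int)
    pieces = np.diff(np.concatenate([[0], cuts, [coding]])).astype(int)
    intron_total = L - coding
    gaps = rng.multinomial(intron_total, np.ones(n_exons + 1) / (n_exons + 1))
    exons = []
    pos = 0
    for piece, gap in zip(pieces, gaps[:-1]):
        pos += int(gap)
        exons.append((pos, pos + int(piece)))
        pos += int(piece)
    return exons


def _purge_stop_codons(ancestral: np.ndarray, exons: list[tuple[int, int]],
                       rng) -> None:
    """Resample any stop codon in the ancestral reading frame (in place)."""
    coding_cols = (np.concatenate([np.arange(s, e) for s, e in exons])
                   if exons else np.array([], dtype=int))
    for ci in range(len(coding_cols) // 3):
        cods = coding_cols[3 * ci: 3 * ci + 3]
        while _CODON_TO_AA.get(b"".join(ancestral[cods]).decode()) == "*":
            ancestral[cods] = _DNA[rng.integers(0, 4, size=3)]


def _site_targets(ancestral: np.ndarray, exons: list[tuple[int, int]]):
    """Per-position mutation targets by class on the ancestral sequence.

    Returns (silent_positions, silent_alts, repl_positions, repl_alts,
    silent_sites, nonsyn_sites): positions where a silent / replacement
    change is possible, the allowed alternative bases per position, and the
    fractional (Nei-Gojobori style) site counts used as intensities.
    """
    L = len(ancestral)
    coding_cols = (np.concatenate([np.arange(s, e) for s, e in exons])
                   if exons else np.array([], dtype=int))
    is_coding = np.zeros(L, dtype=bool)
    is_coding[coding_cols] = True

    silent_pos, silent_alts = [], []
    repl_pos, repl_alts = [], []
    syn_sites = 0.0
    nonsyn_sites = 0.0
    for p in range(L):
        if not is_coding[p]:
            silent_pos.append(p)
            silent_alts.append([b for b in _DNA if b != ancestral[p]])
    for ci in range(len(coding_cols) // 3):
        cods = coding_cols[3 * ci: 3 * ci + 3]
        codon = b"".join(ancestral[cods]).decode()
        aa = _CODON_TO_AA.get(codon)
        if aa is None or aa == "*":
            continue
        for pos in range(3):
            syn_b, non_b = [], []
            for alt in "ACGT":
                if alt == codon[pos]:
                    continue
                mut = codon[:pos] + alt + codon[pos + 1:]
                if _CODON_TO_AA.get(mut) == aa:
                    syn_b.append(alt.encode())
                else:
                    non_b.append(alt.encode())
            col = int(cods[pos])
            syn_sites += len(syn_b) / 3.0
            nonsyn_sites += len(non_b) / 3.0
            if syn_b:
                silent_pos.append(col)
                silent_alts.append(syn_b)
            if non_b:
                repl_pos.append(col)
                repl_alts.append(non_b)
    n_noncoding = int((~is_coding).sum())
    return (np.array(silent_pos), silent_alts, np.array(repl_pos), repl_alts,
            n_noncoding + syn_sites, nonsyn_sites)


def _generate_locus(locus_id: str, locus_class: str, L: int, k: float,
                    gamma: float, cfg: GeneratorConfig, rng):
    """Simulate one locus: genealogy, mutations, sequences, truth row."""
    n1, n2 = cfg.n_chrom
    d1, d2 = cfg.n_pops
    size2 = (cfg.theta_site[1] / cfg.theta_site[0]
             if cfg.theta_site[0] > 0 else 1.0)
    parent, node_time, branch_length, leaf_sets = simulate_two_species_tree(
        n1, n2, d1, d2, cfg.migration[0], cfg.migration[1], cfg.tau, cfg.T,
        size2, k, rng, anc_size=cfg.ancestral_size,
        mig12=cfg.interspecies_migration[0], mig21=cfg.interspecies_migration[1])

    exons = _make_exons(L, cfg.exon_fraction, rng)
    ancestral = _DNA[rng.integers(0, 4, size=L)]
    _purge_stop_codons(ancestral, exons, rng)
    (sil_pos, sil_alts, rep_pos, rep_alts,
     sil_sites, nonsyn_sites) = _site_targets(ancestral, exons)

    theta = cfg.theta_site[0]  # per site, species-1 scale (time unit 2*Ne1)
    n_ing = n1 + n2
    ingroup_all = np.zeros(leaf_sets.shape[1], dtype=bool)
    ingroup_all[:n_ing] = True
    carriers_n_ing = leaf_sets[:, :n_ing].sum(axis=1)
    # divergence (stalk) branches separate the whole ingroup from the outgroup
    is_stalk = (carriers_n_ing == n_ing) | (
        (carriers_n_ing == 0) & leaf_sets[:, n_ing])
    G = prf_polymorphism_factor(gamma, n_ing) if gamma else 1.0
    H = prf_fixation_factor(gamma) if gamma else 1.0

    sil_rate = theta / 2.0 * sil_sites * branch_length
    rep_rate = theta / 2.0 * nonsyn_sites * branch_length * np.where(is_stalk, H, G)
    n_sil = rng.poisson(sil_rate.sum())
    n_rep = rng.poisson(rep_rate.sum())
    if n_sil > len(sil_pos) or n_rep > len(rep_pos):
        raise ValueError(
            f"locus {locus_id}: exon layout incompatible with requested "
            f"mutation counts ({n_sil} silent / {n_rep} replacement vs "
            f"{len(sil_pos)} / {len(rep_pos)} available positions)")

    seqs = np.tile(ancestral, (n_ing + 1, 1))
    truth_counts = {sp: {"S": 0, "D": 0, "Ps": 0, "Pn": 0, "Ds": 0, "Dn": 0}
                    for sp in cfg.species}
    sp_slices = {cfg.species[0]: (0, n1), cfg.species[1]: (n1, n1 + n2)}

    def apply_mutations(n_mut, rates, positions, alts, silent: bool):
        if n_mut == 0:
            return
        branches = rng.choice(len(rates), size=n_mut, p=rates / rates.sum())
        which = rng.choice(len(positions), size=n_mut, replace=False)
        for b, w in zip(branches, which):
            pos = int(positions[w])
            options = alts[w]
            alt = options[int(rng.integers(len(options)))]
            carriers = leaf_sets[b]
            seqs[carriers, pos] = alt
            out_c = bool(carriers[n_ing])
            for sp, (lo, hi) in sp_slices.items():
                c = int(carriers[lo:hi].sum())
                nsp = hi - lo
                if 0 < c < nsp:
                    truth_counts[sp]["S"] += 1
                    truth_counts[sp]["Ps" if silent else "Pn"] += 1
                elif (c == nsp) != out_c:
                    truth_counts[sp]["D"] += 1
                    truth_counts[sp]["Ds" if silent else "Dn"] += 1

    apply_mutations(int(n_sil), sil_rate, sil_pos, sil_alts, True)
    apply_mutations(int(n_rep), rep_rate, rep_pos, rep_alts, False)

    ids, species, pops = [], [], []
    for si, (sp, (lo, hi)) in enumerate(sp_slices.items()):
        blocks = np.array_split(np.arange(lo, hi), cfg.n_pops[si])
        for pj, block in enumerate(blocks):
            for h in block:
                ids.append(f"{sp}_p{pj:02d}_h{h:03d}")
                species.append(sp)
                pops.append(f"{sp}_pop{pj:02d}")
    aln = LocusAlignment(locus_id=locus_id, ids=ids, species=species,
                         populations=pops, seqs=seqs[:n_ing],
                         outgroup_id="outgroup", outgroup_seq=seqs[n_ing],
                         exons=exons)
    truth = {"locus_id": locus_id, "locus_class": locus_class, "length": L,
             "theta_site": theta, "k": k, "gamma": gamma,
             "silent_sites": sil_sites, "nonsyn_sites": nonsyn_sites,
             "n_silent_mut": int(n_sil), "n_repl_mut": int(n_rep)}
    for sp in cfg.species:
        for key, val in truth_counts[sp].items():
            truth[f"{key}_{sp}"] = val
    return aln, truth


def generate_dataset(config: GeneratorConfig, seed: int,
                     outdir=None) -> SyntheticDataset:
    """Generate a full synthetic dataset (optionally written to disk).

    The emitted formats are exactly what ``seqdata.read_locus`` consumes:
    one FASTA per locus plus shared-per-locus metadata and exon annotation
    TSVs, and one truth TSV for the whole dataset.
    """
    rng = rng_from(seed, "synthdata")
    alignments, truth_rows = [], []
    lo, hi = config.length_range
    cand_k = list(config.candidate_k)
    cand_g = list(config.candidate_gamma)
    for i in range(config.n_candidate_loci):
        L = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        aln, truth = _generate_locus(
            f"cand{i:02d}", "candidate", L,
            cand_k[i % len(cand_k)], cand_g[i % len(cand_g)], config, rng)
        alignments.append(aln)
        truth_rows.append(truth)
    for i in range(config.n_reference_loci):
        L = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        aln, truth = _generate_locus(
            f"ref{i:02d}", "reference", L,
            config.reference_k, config.reference_gamma, config, rng)
        alignments.append(aln)
        truth_rows.append(truth)
    truth = pd.DataFrame(truth_rows)
    ds = SyntheticDataset(config=config, seed=seed, alignments=alignments,
                          truth=truth)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for aln in alignments:
            write_locus(aln, outdir / f"{aln.locus_id}.fasta",
                        outdir / f"{aln.locus_id}.meta.tsv",
                        outdir / f"{aln.locus_id}.exons.tsv")
            ds.paths[aln.locus_id] = str(outdir / f"{aln.locus_id}.fasta")
        truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        ds.paths["truth"] = str(outdir / "truth.tsv")
    return ds


# ---------------------------------------------------------------------------
# model-level table generators (estimator-recovery oracles)


def sample_poly_div_tables(locus_names: list[str], theta: np.ndarray,
                           k: np.ndarray, L: np.ndarray, n: int, T: float,
                           rng) -> PolyDivTable:
    """Draw an (S, D) table from the mlHKA sampling model.

    S_i is Poisson on a simulated coalescent tree length scaled by k_i (so S
    has the model's coalescent overdispersion); D_i ~ Poisson(theta_i*(T+k_i)).
    theta is on the per-locus (count) scale.
    """
    from .coalsim import simulate_genealogy

    rows = []
    for i, name in enumerate(locus_names):
        tree = simulate_genealogy(n, rng)
        S = rng.poisson(k[i] * theta[i] / 2.0 * tree.total_length)
        D = rng.poisson(theta[i] * (T + k[i]))
        rows.append({"locus": name, "S": int(S), "D": int(D),
                     "L": float(L[i]), "n": n})
    return PolyDivTable(pd.DataFrame(rows))


def sample_mk_tables(locus_names: list[str], theta_s: np.ndarray,
                     theta_r: np.ndarray, gamma: np.ndarray, tau: float,
                     n: int, locus_class, rng) -> list[MKTable]:
    """Draw MK tables directly from the PRF Poisson model."""
    a = harmonic(n)
    classes = ([locus_class] * len(locus_names)
               if isinstance(locus_class, str) else list(locus_class))
    tables = []
    for i, name in enumerate(locus_names):
        G = prf_polymorphism_factor(float(gamma[i]), n)
        H = prf_fixation_factor(float(gamma[i]))
        tables.append(MKTable(
            locus_id=name,
            Ps=int(rng.poisson(theta_s[i] * a)),
            Ds=int(rng.poisson(theta_s[i] * (tau + 1.0))),
            Pn=int(rng.poisson(theta_r[i] * a * G)),
            Dn=int(rng.poisson(theta_r[i] * (tau + 1.0) * H)),
            n=n, locus_class=classes[i]))
    return tables


def truth_vs_estimates_report(truth: pd.DataFrame,
                              estimates: pd.DataFrame) -> pd.DataFrame:
    """Join generating truth with pipeline estimates and add error columns.

    ``estimates`` must carry ``locus_id`` plus any of ``k_hat``,
    ``gamma_mean``, ``flagged``; bias / RMSE summary rows are attached as a
    DataFrame attribute ``.attrs['summary']``.
    """
    merged = pd.merge(truth, estimates, on="locus_id", how="inner",
                      validate="one_to_one")
    if len(merged) != len(estimates):
        missing = set(estimates["locus_id"]) - set(truth["locus_id"])
        raise ValueError(f"loci in estimates without truth rows: {sorted(missing)}")
    summary = {}
    if "k_hat" in merged:
        err = merged["k_hat"] - merged["k"]
        summary["k_bias"] = float(err.mean())
        summary["k_rmse"] = float(np.sqrt((err ** 2).mean()))
    if "gamma_mean" in merged:
        err = merged["gamma_mean"] - merged["gamma"]
        summary["gamma_bias"] = float(err.mean())
        summary["gamma_rmse"] = float(np.sqrt((err ** 2).mean()))
    merged.attrs["summary"] = summary
    return merged
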