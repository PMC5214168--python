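# popgenscan

Multilocus scans for natural selection from population sequence data:
diversity statistics, neutral coalescent null distributions, the π_T−S
differentiation test, classical and maximum-likelihood HKA, and hierarchical
Bayesian McDonald–Kreitman / Poisson-random-field estimation of scaled
selection coefficients — plus a synthetic two-species data generator with
known truth so the whole pipeline is testable end to end without any
downloads.

## Who this is for

Population geneticists contrasting a set of **candidate genes** (the
motivating case: Na+/H+ antiporter salt-tolerance genes in two desert poplar
sister species) against a panel of **reference loci**, using per-locus FASTA
alignments of phased haplotypes from one or two ingroup species plus one
outgroup sequence, a sample-metadata TSV, and a minimal exon annotation.

## What it computes

Per locus and species, after column-wise exclusion of indel/ambiguous sites
and Nei–Gojobori fractional site counting:

* **Diversity**: S, Watterson's θ_W = S/(a_n L) with a_n = Σ_{i<n} 1/i,
  nucleotide diversity π (total and silent = synonymous + noncoding),
  Tajima's D, raw divergence to the outgroup, and F_ST among populations
  with a 10,000-shuffle permutation p-value.
* **Outlier scan**: a genomewide neutral null for (π_sil, D_sil) simulated
  from the reference loci's per-locus θ̂ estimates; candidates outside the
  empirical 95% highest-density region of the simulated cloud are flagged.
* **π_T−S**: pooled two-species diversity minus mean within-species
  diversity, tested against coalescent replicates conditioned on the
  observed number of segregating sites (no recombination).
* **HKA**: the multilocus goodness-of-fit test of proportionality between
  within-species polymorphism and divergence, E[S_i] = θ_i a_{n_i},
  E[D_i] = θ_i(T+1), with the classical chi-square deviation (df = L−1) and
  a parametric-bootstrap p.
* **mlHKA**: per-locus selection factor k with S_i ~ Poisson(k θ_i a_{n_i}),
  D_i ~ Poisson(θ_i(T+k)); likelihood-ratio tests against the neutral model
  (all k = 1), divergence time T = 15 by default.
* **MK–PRF**: per-locus γ = 2N_e s estimated from the 2×2 MK counts via
  Poisson intensities scaled by the fixation factor H(γ) = 2γ/(1−e^{−2γ})
  and the sampled-polymorphism factor G(γ, n), under a hierarchical prior
  γ_i ~ Normal(μ_class, σ²) that contrasts the candidate and reference
  classes (posterior means, 95% intervals, class-mean posteriors).

See `docs/methods.md` for the models, conventions, and design decisions.

## Worked example

Generate a synthetic dataset under the default study-like conditions (10
candidate + 16 reference loci, 80 + 50 chromosomes in two species, outgroup
at scaled divergence T = 15, candidate loci carrying diversity-scaling
effects k ∈ {0.4, 1, 1.8, 2} and replacement-site selection γ = 1.2), then
run the HKA family on species 1's silent counts:

```python
import pandas as pd
from popgenscan.synthdata import GeneratorConfig, generate_dataset
from popgenscan.seqdata import exclude_indels
from popgenscan.popstats import segregating_sites, divergence_to_outgroup
from popgenscan.hka import PolyDivTable, hka_test, mlhka_scan

ds = generate_dataset(GeneratorConfig(), seed=7)
rows = []
for aln in ds.alignments:
    cls = exclude_indels(aln)
    sp1 = aln.species_rows("sp1")
    L = cls.effective_sites("silent")
    rows.append({"locus": aln.locus_id, "n": 80, "L": L,
                 "S": segregating_sites(aln, cls, "silent", sp1),
                 "D": round(divergence_to_outgroup(aln, cls, "silent", sp1) * L)})
table = PolyDivTable(pd.DataFrame(rows))

cand = PolyDivTable(table.data[table.data.locus.str.startswith("cand")])
res = hka_test(cand)
print(f"HKA: deviation = {res.deviation_sum:.4f}, df = {res.df}, p = {res.p_chi:.5f}")

scan = mlhka_scan(table, [f"cand{i:02d}" for i in range(4)], T=15.0)
print(scan[["locus", "LR", "p", "k"]].round(4).to_string(index=False))
```

which prints:

```
HKA: deviation = 21.6212, df = 9, p = 0.01016
 locus      LR      p      k
cand00  8.3346 0.0039 0.3499
cand01  6.2035 0.0128 1.6843
cand02  0.0388 0.8438 0.9386
cand03 18.3918 0.0000 2.1661
```

The ten candidate loci jointly reject the neutral proportionality of
polymorphism and divergence (deviation 21.62 on 9 df, p ≈ 0.01). Per locus,
`cand00` was generated with a diversity deficit (k = 0.4, a sweep-like
signal) and is recovered at k̂ = 0.35 with LR = 8.33 (p = .004); `cand03`
was generated at k = 1.8 (balancing-selection-like diversity excess) and is
recovered at k̂ = 2.17. `cand02` (k = 1) is correctly quiet. `cand01`
(k = 1) shows a modest LR: the generator's island-model substructure
inflates within-species diversity relative to the panmictic mlHKA null, a
caveat that applies to real structured populations too. The dataset's
`ds.truth` table carries every generating parameter for exactly this kind of
comparison.

The same pipeline runs from the command line:

```bash
popgenscan generate --out data/ --seed 7
popgenscan run-all --out reports/ --seed 7
```

emitting TSV reports (diversity, FST, outlier flags, π_T−S, HKA, mlHKA,
MK-PRF posteriors) and a plain-text run manifest.

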