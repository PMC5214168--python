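# Methods

`popgenscan` implements a multilocus scan for natural selection of the kind
used to contrast a set of *candidate* genes (here, the motivating use case is
Na+/H+ antiporter salt-tolerance genes in two sister poplar species) against a
panel of putatively neutral *reference* loci, using per-locus alignments of
phased haplotypes from one or two ingroup species plus a single outgroup
sequence. This note records the models, the conventions, the tunable
parameters, and the design choices made where the design was genuinely open.

## Sequence handling and site classification

Coordinates are 0-based, half-open, on the alignment. Minus-strand
annotations are reverse-complemented at load time, so all downstream code
sees the coding strand. Columns containing a gap (`-`) **or** an ambiguous
base (anything outside `ACGT`) in any row — ingroup or outgroup — are
excluded from every statistic; gap handling is column-wise, which keeps the
analyzed length identical for every haplotype and across species subsets of
one locus.

Synonymous/nonsynonymous site counts are fractional, computed per intact
codon of the *first ingroup haplotype* by enumerating the three alternative
bases at each codon position under the standard genetic code (Nei–Gojobori
counting), so `syn + nonsyn = 3 × (intact codons)` exactly. A codon is intact
when its three columns are analyzable; reference codons that are stop codons
are skipped with a warning. The observed change at a variable column is
classified by substituting the most frequent non-reference allele into the
reference codon; variants inside non-intact codons are conservatively classed
with the silent (noncoding) pool — they carry no usable codon context.
Tri-allelic columns are retained as single segregating sites (the downstream
tests are infinite-sites based) and logged. "Silent" everywhere means
synonymous + noncoding; class filters for synonymous-only or
noncoding-only variants are exposed.

## Diversity and differentiation statistics

θ_W = S/(a_n·L) with a_n = Σ_{i<n} 1/i; π is the unbiased mean pairwise
difference per site; divergence to the outgroup is the raw (uncorrected) mean
per-haplotype distance, matching common practice for closely related taxa
(a Jukes–Cantor option is deliberately *not* the default). Tajima's D uses
the canonical 1989 constants; S = 0 yields an explicit undefined marker
(NaN), never 0. Note that D's exact finite-sample expectation under
neutrality is slightly negative (≈ −0.07 at n = 50 and θ = 5; its denominator
is an estimated SD and the statistic is skewed); the test suite asserts the
mean lies in that known range rather than at 0.

F_ST is `1 − Hw/Ht` with per-column `2p(1−p)` heterozygosities summed over
variant columns, Hw averaging populations (a Nei/Hudson G_ST-style,
frequency-based form). The frequency-based form is chosen over the unbiased
pairwise form so that merging two identical population samples gives exactly
0; it carries a small positive finite-sample bias (~1/(2·n_pop)), which the
permutation test — 10,000 label shuffles by default, add-one p-value —
calibrates away. This is a deliberate estimator substitution for the AMOVA
Φ_ST of the original workflow, whose exact weighting is not reproducible
from the published description.

## Neutral coalescent simulator

Single-population, no recombination (a modeling commitment of the scan, not
a convenience). Time is in units of 2N generations (k lineages coalesce at
rate k(k−1)/2; a 2-leaf tree has mean height 1); θ = 4Nμ per locus, and
mutations fall at rate θ/2 per unit branch length, so E[S] = θ·a_n. This
convention pair is pinned by Monte-Carlo tests and a distributional
cross-check against msprime. Fixed-S mode places exactly S mutations
multinomially, proportional to branch lengths, conditional on the genealogy
(the approach long used for confidence-interval simulation in DnaSP); it is
not rejection sampling. All randomness flows from one seed through named
substreams, so replicates are reproducible and independently re-runnable.

## Outlier scan and π_T−S

The genomewide neutral null for (π_sil, D_sil) is calibrated by resampling
the *per-locus* (θ̂ per silent site, silent length) pairs of the reference
loci — resampling loci rather than their mean propagates genomewide
heterogeneity into the null. Each replicate simulates one neutral sample at
the species' chromosome count. A candidate is flagged when its (π_sil, D_sil)
point falls outside the empirical 95% highest-density region of the simulated
cloud, estimated on a 50×50 histogram: the candidate's density rank is the
fraction of null mass in bins no denser than its own bin, flagged when
≤ α. Marginal percentiles per axis are reported alongside so users can apply
the simpler rule. Default 10⁴ replicates (configurable; desk-scale default
chosen for runtime, the original-scale 10⁵ is a flag away).

π_T−S = π_T − π_S, pooled two-species diversity minus the mean within-species
diversity. Its null conditions on the observed number of segregating sites:
each replicate simulates one *panmictic* genealogy of n₁+n₂ chromosomes,
places exactly S mutations, splits the sample into fixed blocks of n₁ and n₂
pseudo-species, and recomputes π_T−S; significance is falling outside the
[2.5%, 97.5%] replicate quantiles. The panmictic pooled sample is the
no-differentiation null; block (not random) assignment keeps the test
deterministic — leaves are exchangeable, so the choice is immaterial in
distribution. With the unbiased π estimator, identical species samples give a
small negative π_T−S of order π/n (exactly 0 only for the biased,
frequency-based estimator); the null simulation uses the same estimator, so
the test is calibrated regardless.

## HKA and mlHKA

The classical multilocus HKA test uses the single-species layout: per-locus
silent polymorphism S_i and silent divergence D_i to the outgroup, with
E[S_i] = θ_i·a_{n_i} and E[D_i] = θ_i(T+1) — one ancestral coalescent unit
added to the divergence time; the relative-ancestral-size parameter f of the
original formulation is fixed at 1 because no second-ingroup polymorphism is
used. The method-of-moments fit solves the per-locus constraints
S_i + D_i = θ_i(a_i + T + 1) together with ΣS_i = Σθ_i·a_i, a monotone 1-D
root-find in T. The deviation statistic sums
(S−Ŝ)²/Var(S) + (D−D̂)²/Var(D) with Var(S) = Ŝ + b_n θ², Var(D) = D̂ + θ²
(b_n = Σ 1/i²), df = L−1, upper-tail chi-square p. A parametric bootstrap p
re-simulates S (Poisson on coalescent tree lengths) and D (Poisson), refits
every replicate, and reports the add-one exceedance fraction. T at its lower
boundary (all D = 0) is flagged, not silently reported.

mlHKA places a selection factor k per locus: S_i ~ Poisson(k_i θ_i a_i),
D_i ~ Poisson(θ_i(T + k_i)) — k scales polymorphism and the
ancestral-polymorphism component of divergence (the Wright–Charlesworth
parameterization). With the divergence time fixed (default T = 15,
overridable) the likelihood separates by locus and θ_i given k_i has the
closed form (S_i+D_i)/(k_i a_i + T + k_i), so each free k is an exact 1-D
profile-likelihood problem, solved by a deterministic log-grid scan plus
bounded scalar refinement. This replaces the stochastic (MCMC) search of the
original tool: it is deterministic, exact at the optimum, and guarantees
LR ≥ 0 for nested fits — the original tool's occasional negative LRs
("#NUM" rows) are thereby impossible here; `lrt` still flags any negative LR
it is handed as an invalid result rather than a number.

## MK tables and Poisson-random-field selection estimation

Per species, variants polarized against the outgroup fill the 2×2 MK layout
(silent/replacement × polymorphic/fixed). Counts are modelled as independent
Poisson fields: Ps ~ θ_s·a_n, Ds ~ θ_s(τ+1), Pn ~ θ_r·a_n·G(γ,n),
Dn ~ θ_r(τ+1)·H(γ), with the silent class the γ = 0 anchor and the
divergence-lineage weighting fixed to 1 (lineage-specific fixations are not
separable with a single outgroup). H(γ) = 2γ/(1−e^{−2γ}) is the relative
fixation rate (removable singularity H(0) = 1 handled explicitly; the
reflection identity H(γ) = e^{2γ}H(−γ) is tested). G(γ,n) integrates the
stationary frequency density (1−e^{−2γ(1−q)})/((1−e^{−2γ})q(1−q)) against
the sampling factor 1−qⁿ−(1−q)ⁿ, normalized by the neutral value — which is
a_n exactly. The integrand's endpoint singularities are removable (limits n
at q=0, 0 at q=1); adaptive quadrature is verified against brute-force
Simpson integration to 1e-6. Note G itself *increases* with γ (toward 2 as
γ→∞, with the fixation flux); what selection depletes is polymorphism
*relative to divergence*, G/H, which is monotone decreasing — the test suite
asserts both facts.

Estimation is Metropolis-within-Gibbs: log-normal random-walk proposals on
each θ_s and θ_r (flat prior on log θ), a normal random walk on each γ_i
under the hierarchical prior γ_i ~ Normal(μ_class, σ²) with σ² = 4 by
default, and an exact Gibbs draw for each class mean μ (flat hyperprior).
One cycle updates every parameter once, vectorized across loci. Because the
chain evaluates G millions of times, G is tabulated on a γ ∈ [−30, 30] grid
(601 points, cubic spline in log G) per sample size; proposals outside the
grid are clipped — the prior makes such excursions vanishingly rare. The
desk-scale default chain is 10⁵ cycles, 10³ burn-in, thinning 10 (the
original-scale 10⁷ cycles is configuration); step sizes 0.35 (log θ) and 0.6
(γ) give acceptance rates near 0.3 at the default data scale, and rates
outside [1%, 99%] raise a warning. Loci with all-zero replacement counts are
retained — the hierarchical prior handles them; no pseudo-counts are added.
Hierarchical shrinkage is verified behaviorally: a locus with almost no
replacement information receives a posterior pulled toward its class mean.

## Synthetic data generator

The generator is the package's test bed: it emulates the *statistical
structure* the estimators assume rather than the full biology. Selection is
injected at the level of summary intensities — a per-locus diversity scaling
k divides every ingroup coalescent intensity (mirroring mlHKA's
E[S] ∝ kθ, E[D] ∝ θ(T+k): the clock-scaled outgroup stalk is *not*
rescaled), and replacement-class mutation intensities are multiplied by
G(γ,n) on polymorphism-generating branches and H(γ) on the stalk branches
that separate the whole ingroup from the outgroup. No forward simulation is
attempted; this is orders of magnitude faster and sufficient to test the
estimators' recovery behavior.

The genealogy is a two-species structured coalescent written in-package:
each species is an island model (11 and 6 demes by default, matching the
sampled population counts) with per-lineage migration; at the split time τ
all ingroup lineages enter one ancestral population; the outgroup lineage
joins at T. Mutations are threaded onto a random ancestral sequence honoring
a 2–3-exon layout (~35% coding, the study's coding fraction): silent changes
at noncoding positions or as synonymous codon changes, replacement changes
as nonsynonymous codon changes, one mutation per position per class
(infinite sites; a position offering both synonymous and nonsynonymous
alternatives can rarely be hit once by each class, producing a logged
tri-allelic column — the truth bookkeeping counts mutations, so realized
column counts can differ by a few per dataset). Stop codons are purged from
the ancestral reading frame.

Default conditions reproduce the study design: 10 candidate + 16 reference
loci; 80 and 50 chromosomes; locus lengths 0.4–9 kb (log-uniform); outgroup
at T = 15; candidate selection effects cycling k ∈ {0.4, 1, 1.8, 2} and
γ = 1.2 (bracketing the study's estimated per-species means). The free
quantities the study does not state were fixed once by calibrating to its
printed data summaries: per-site θ = (0.0027, 0.0072) and ancestral size 1.5
put realized reference-locus π_sil near the printed means (0.0034 / 0.0053)
given τ = 1.0, and island migration rates (28, 23) per lineage put mean
within-species F_ST near the printed means (0.257 / 0.149); island structure
and the recent split make realized diversity differ from the raw θ inputs,
which is why θ is not simply set to the printed π values.
Interspecies migration parameters exist for data generation only; no
isolation-with-migration inference exists anywhere in the package.

What the generator does *not* emulate: recombination, gene conversion,
indels, sequencing error, ascertainment, or realistic codon usage. Passing
tests therefore demonstrate correctness of the estimators under the scan's
own model assumptions, not robustness to their violation on real data.

## Problem sizes and numerical choices

Simulation-based defaults are desk-scale choices: 10⁴ replicates for the
outlier null and π_T−S (original workflow: 10⁵ and 10⁴), 10⁴ for the HKA
bootstrap, 10⁵ MCMC cycles. The validation suite uses smaller, stated sizes
(e.g. 500 null tables × 200 bootstrap replicates for size control; 50
datasets per recovery setting; 2×10⁴-cycle chains), all seeded. Quantile CIs
use a 1e-9 relative tolerance when comparing an observed statistic to its
simulated bounds, guarding against ties at distribution atoms. Undefined
statistics propagate as NaN and are reported as unassessable, never coerced.

## Known limitations

* The HKA variance forms are the classical moment approximations; at very
  small counts the chi-square reference distribution is rough — the
  parametric bootstrap p is the better-calibrated alternative and is always
  reported alongside.
* The MK-PRF model assumes free recombination between sites and independence
  across loci; linked selection violates both.
* G(γ,n) clipping at |γ| = 30 bounds the sampler's support; data favoring
  |γ| > 30 would saturate (not observed at realistic counts).
* The 2-D highest-density-region rule depends mildly on the 50×50 binning;
  marginal percentiles are reported so users can apply a binning-free rule.
* Tajima's D centring: see above — its neutral expectation is not exactly 0,
  and the package does not pretend otherwise.
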