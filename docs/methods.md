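# Methods

This note records the models implemented by `whalepop`, the assumptions
they make, the defaults and why, and the choices taken where the design
was genuinely open. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Synthetic data

**Independent-loci mode.** Each locus is a non-recombining genealogy drawn
backward in time: with k lineages in a deme of diploid size N(t) the
coalescence rate is C(k,2) / (2N(t)), integrated exactly across
piecewise-constant epochs (time in generations before present; an epoch
boundary belongs to the older epoch). For two populations, population 1's
lineages merge into population 0 at the split time and population 0's
trajectory continues as the ancestral population. An outgroup is a single
lineage held apart until its divergence time, then dropped into the
ancestral deme; it is written as a homozygous diploid (haploid-equivalent),
mirroring the use of a single outgroup genome purely for polarization.
Mutations are Poisson on branches with infinite sites within a locus
(collisions redrawn), which keeps SFS theory exact — this mode is the
default for diversity/SFS tests. Defaults mirror the study design the
package emulates: 9 diploids per population, mutation rate
0.9664 × 10⁻⁸ /bp/generation, generation time 32 years, uniform map of
1 cM/Mb.

**Linked mode.** Whole chromosomes with recombination are generated by
msprime (Hudson sequential coalescent; a binary mutation model on a
discrete genome), giving realistic ROH/IBD/LD structure. True IBD tracts
(MRCA segments up to a configurable age and above a minimum genetic
length) are extracted from the tree sequence into the dataset's truth
tables.

**Pedigree overlays.** Duplicates, parent–offspring and full-sib pairs are
built by Mendelian transmission with Poisson crossovers at the map rate.
Every overlay haplotype carries an exact founder-ancestry track (founder
haplotype per interval), so realized kinship, sib-sharing and
autozygosity have closed-form truth values; offspring of full sibs, for
example, are ~¼ autozygous.

**Quality metadata.** Per-genotype depth is negative-binomial (default
mean 40, overdispersion 8 — deep-WGS-like), GQ a clipped normal (mean 80),
site MQ ~ N(60, 1.5). These feed the filtering ladder with realistic
variation; they do not perturb the genotypes themselves, so simulated
genotypes are error-free unless filtered.

**What the generator does not emulate:** sequencing reads and genotyping
error processes, variable recombination/mutation maps, gene conversion,
selection, overlapping generations. Tests passing on these simulations
therefore validate the estimators under their own model assumptions, not
robustness to real-data artefacts.

## Filtering

Stage order: repeat mask → genotype DP/GQ masking (set missing, site kept)
→ site MQ → missingness (> 25% removed, evaluated *after* masking) →
summed-depth cap (strictly greater than multiplier × median of per-site
summed depth over post-mask sites, even-length medians averaged) →
scaffold length / sex-scaffold exclusion. Thresholds are compared as exact
floats; any stage can be disabled with `None`. The report records
(in, out, removed) per stage plus the per-genotype masked count. Because
the depth cap is data-derived, idempotence is a property of realistic
depth distributions rather than a theorem; it is tested on simulated data.

## Relatedness and structure

KING-robust is used because its first-degree cutoff 0.177 (= 2^(−5/2), the
geometric midpoint between first- and second-degree expectations) is the
conventional exclusion rule; a zero denominator yields a flagged NaN, not
an error. Exclusion is greedy by over-threshold degree with ties broken by
lower call rate then smaller ID — the outcome (no retained pair above
threshold) is what matters; the rule makes it deterministic.

LD r² is the squared Pearson correlation of unphased dosages (composite
LD); pruning windows default to 50 SNPs advancing by 5 (the cited tools'
common practice — not a value taken from any dataset). F_ST is
Weir–Cockerham (1984) with unequal sample sizes, weighted as
Σa / Σ(a+b+c). PCA imputes missing dosages to the site mean, centers, and
scales by √(p(1−p)); the largest-magnitude coordinate of each component
is made positive so output is deterministic.

## Diversity

Per-site π uses the unbiased pairwise estimator over called haplotypes;
window π and θ_W are divided by the full window length (10 kb default),
matching the behaviour of the standard windowed-statistics tooling, while
H_obs is the mean heterozygote fraction over variant sites only — the only
reading consistent with per-variant-site magnitudes. Windows without
variants are excluded (and counted) rather than zero-filled in genome-wide
means for H_obs. Tajima's D uses the 1989 constants and drops sites with
any missing call so the haplotype count is constant.

## Runs of homozygosity

The HMM emits heterozygotes inside a run only through genotyping error,
fixed at ε = 10⁻³ (the phred-30 analogue of the cited tool's `-G 30`,
applied uniformly rather than per-genotype); outside a run the
heterozygote probability is 2p̂(1−p̂) from sample allele frequencies.
Transitions between adjacent sites d bp apart switch state with
probability 1 − exp(−dτ), τ = 5 × 10⁻⁸ /bp by default (exposed in config;
the scale makes megabase segments plausible switches). `strict_hmm` sets
ε = 0; `rule` reports maximal segments with ≤ 2 heterozygous calls
(the "fewer than two mismatches" reading is ambiguous; the budget is a
parameter, default ≤ 2), selected longest-first without overlap. All
methods filter to ≥ 10 kb. F_ROH merges overlapping calls by union before
dividing by autosomal length. Dating uses T_gen = 50 / (L_Mb · r): only
the genetic length matters, and the presentation layer (not the function)
rounds.

## SFS demography

E[ξ_i] = μL Σ_k k E[T_k] p(i|k) with p(i|k) = C(n−i−1, k−2)/C(n−1, k−1).
E[T_k] comes from per-epoch occupation times of the pure-death lineage
chain in rescaled time, computed by spectral decomposition of its fixed
lower-bidiagonal generator (eigenvalues −C(k,2)); the final epoch is
integrated to infinity through the inverse generator. This is exact for
piecewise-constant trajectories (constant N reduces to 4NμL/i; the test
suite checks < 10⁻⁶ relative error to n = 20 and cross-checks a bottleneck
against vectorized Monte-Carlo genealogy timings).

The fit maximizes the composite Poisson likelihood over log₁₀ Ne with
bounded L-BFGS-B multi-starts. Epoch breakpoints are added stepwise from a
fixed log-spaced candidate set: each candidate is scored on a random 60%
of sites and the step is accepted only if the held-out 40% improves —
candidate choice by training likelihood, acceptance by validation, which
proved markedly more stable than selecting on the held-out score itself.
Singletons are kept by default (a flag masks ξ₁ when polarization error
is a worry). The bootstrap resamples sites (multinomial), refits Ne on the
chosen breakpoints, and reports 2.5/97.5 percentiles on a 64-point
log-time grid (10–10⁶ generations); the reported envelope is widened to
include the point estimate so it always brackets it. Identifiability is
the usual θ-scaling: doubling μ halves every Ne and every time.

## IBD and recent Ne

Detection is seed-and-extend: any qualifying segment (≥ 2 cM with at most
`tol` mismatches per cM) must contain a mismatch-free gap of ≥ ~0.3 cM,
so only such gaps seed a bounded two-pointer that finds maximal segments;
overlapping candidates are resolved greedily by length so one region
yields one call. With tol = 0 the segments are simply the inter-mismatch
gaps. Mismatch tolerance exists because even error-free genotypes carry
mutations (μ ≈ r per bp), which interrupt exact identity on true IBD
tracts roughly once per 2 cM of age-25 segment; 1 mismatch/cM is the
default in the pipeline. Within-individual haplotype pairs are detected
and flagged (they are ROH) but excluded from the spectrum used for
fitting.

The spectrum model: P(g) = (1/2N_g)·Π_{h<g}(1 − 1/2N_h); given coalescence
at g, segment count 2gL per pair with lengths Exp(2g) per Morgan, so the
expected count in [l₁, l₂) is n_pairs Σ_g 2gLP(g)(e^{−2gl₁} − e^{−2gl₂}).
Beyond the last modelled generation the trajectory is continued constant
for a long tail that absorbs the remaining mass. This approximation is
exact against the continuous coalescent (checked by simulation) but
ignores finite-N discrete-generation corrections, which amount to a few
percent of extra short segments at N = 500 against a literal
Wright–Fisher oracle — the acceptance suite measures exactly this, and
the shortest bin exceeds a 3-SE band at 200 replicates. Interpret the
shortest bin accordingly on very small populations.

The fit interpolates log Ne linearly between knots (default: every
generation 4–50, then log-spaced to 200), maximizing the Poisson
likelihood of binned counts plus a smoothness penalty
λ·S·Σ(Δlog N)² (scaled by the total count S so inference depends only on
per-pair rates); λ is chosen by a two-fold chromosome split and the
envelope by a chromosome bootstrap, again widened to include the point
estimate. Estimates within the last ~3 generations have little data and
should be read with caution.

## Pipeline

Stages run in dependency order (simulate/load → filter → kinship
exclusion → diversity, ROH, PCA/F_ST per population → polarize → SFS →
stairway per population → IBD → recent Ne per population); a manifest
records the seed and a stable hash of all parameters, and the global seed
fans out to stages by hashing stage names, so toggling one stage does not
perturb another's randomness. Any stage failure aborts with the stage
name and keeps partial outputs.

## Problem sizes

Test and demo scenarios are deliberately desk-scale: 300–2000 independent
10 kb loci, linked genomes of 2–20 chromosomes at 2–150 Mb, 4–9 diploids
per population, 10 seeded replicates for parameter-recovery checks, and
100–200 replicates for Monte-Carlo oracles. These sizes resolve the
expectations being tested while keeping a full run on one CPU within
minutes.

## Known limitations

Uniform genetic and mutation maps; no genotyping-error model in the
generator (the filtering ladder is exercised through metadata, not through
miscalled genotypes); the stairway-style fit uses a small fixed candidate
grid of breakpoints rather than per-bin epochs; the IBD spectrum model's
short-bin finite-N bias noted above; two populations at most, one split,
symmetric migration only.
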