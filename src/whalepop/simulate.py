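"""Coalescent simulation of phased diploid genotype datasets with known truth.

Two modes are provided:

* ``independent`` -- every locus is an independent non-recombining genealogy
  sampled backward in time under a piecewise-constant Ne trajectory (with an
  optional second population joined at a split time, and an optional outgroup
  lineage).  Mutations are dropped as a Poisson process on branches under an
  infinite-sites model, which keeps site-frequency-spectrum theory exact.
* ``linked`` -- whole chromosomes with recombination, simulated with msprime
  (sequential-coalescent approximation), yielding realistic ROH/IBD/LD
  structure and, on request, true IBD tracts extracted from the tree
  sequence.

Pedigree overlays (duplicate, parent-offspring, full sibs) are built by
Mendelian transmission with crossovers at the model's genetic-map rate and
carry exact founder-haplotype ancestry tracks, so realized kinship,
IBD-sharing and autozygosity have closed-form truth values.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from bisect import bisect_right

import numpy as np

__all__ = [
    "DemographicModel",
    "SimulationConfig",
    "GenotypeDataset",
    "simulate_dataset",
    "overlay_pedigree",
    "truth_kinship",
    "truth_autozygosity",
    "simulate_coalescent_durations",
]

# An Ne trajectory is a sequence of (epoch start in generations before present,
# diploid Ne); the first epoch must start at 0 and the boundary belongs to the
# older epoch.
Trajectory = tuple[tuple[float, float], ...]


def _as_trajectory(epochs) -> Trajectory:
    traj = tuple((float(t), float(n)) for t, n in epochs)
    if not traj:
        raise ValueError("trajectory must have at least one epoch")
    if traj[0][0] != 0.0:
        raise ValueError("first epoch must start at time 0")
    starts = [t for t, _ in traj]
    if any(b <= a for a, b in zip(starts, starts[1:])):
        raise ValueError("epoch start times must be strictly increasing")
    if any(n < 1 for _, n in traj):
        raise ValueError("all Ne must be >= 1")
    return traj


def ne_at(trajectory: Trajectory, t: float) -> float:
    """Diploid Ne at time ``t`` generations before present.

    The epoch boundary belongs to the older epoch.
    """
    starts = [s for s, _ in trajectory]
    return trajectory[bisect_right(starts, t) - 1][1]


@dataclass(frozen=True)
class DemographicModel:
    """Piecewise-constant Ne per population plus global rate parameters.

    ``populations`` holds one trajectory per population.  For a two-population
    model the lineages of population 1 merge into population 0 at
    ``split_time_generations``; population 0's trajectory continues backward
    in time as the ancestral population.
    """

    populations: tuple[Trajectory, ...]
    split_time_generations: float = 0.0
    migration_rate: float = 0.0
    mutation_rate: float = 0.9664e-8
    recombination_rate_cM_per_Mb: float = 1.0
    generation_time_years: float = 32.0

    def __post_init__(self):
        pops = tuple(_as_trajectory(p) for p in self.populations)
        object.__setattr__(self, "populations", pops)
        if len(pops) not in (1, 2):
            raise ValueError("one or two populations are supported")
        if self.split_time_generations < 0:
            raise ValueError("split_time_generations must be >= 0")
        if len(pops) == 2:
            if self.split_time_generations <= 0:
                raise ValueError("two populations require split_time_generations > 0")
            # Epoch boundaries of the non-ancestral population after the split
            # are inconsistent with the merge and rejected.
            if any(s > self.split_time_generations for s, _ in pops[1][1:]):
                raise ValueError(
                    "population 1 has an epoch boundary older than the split time"
                )
        for name in ("migration_rate", "mutation_rate", "recombination_rate_cM_per_Mb"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.generation_time_years <= 0:
            raise ValueError("generation_time_years must be > 0")

    @property
    def n_populations(self) -> int:
        return len(self.populations)

    @property
    def recombination_rate_per_bp(self) -> float:
        """Recombination probability per bp per generation (Morgans/bp)."""
        return self.recombination_rate_cM_per_Mb * 1e-8

    @classmethod
    def constant(cls, ne: float, **kwargs) -> "DemographicModel":
        return cls(populations=(((0.0, ne),),), **kwargs)


@dataclass(frozen=True)
class SimulationConfig:
    n_diploids: tuple[int, ...] = (9,)
    n_chromosomes: int = 1
    chromosome_length_bp: int = 10_000_000
    n_independent_loci: int = 1000
    locus_length_bp: int = 10_000
    seed: int = 1
    include_outgroup: bool = False
    outgroup_divergence_generations: float = 0.0
    mode: str = "independent"  # or "linked"
    track_ibd: bool = False
    ibd_max_time: float = 200.0
    ibd_min_cM: float = 2.0
    depth_mean: float = 40.0
    depth_overdispersion: float = 8.0
    gq_mean: float = 80.0
    gq_sd: float = 10.0

    def __post_init__(self):
        object.__setattr__(self, "n_diploids", tuple(int(n) for n in self.n_diploids))
        if any(n < 1 for n in self.n_diploids):
            raise ValueError("n_diploids entries must be >= 1")
        for name in ("n_chromosomes", "chromosome_length_bp", "n_independent_loci",
                     "locus_length_bp"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.mode not in ("independent", "linked"):
            raise ValueError("mode must be 'independent' or 'linked'")
        if self.include_outgroup and self.outgroup_divergence_generations <= 0:
            raise ValueError("outgroup requires outgroup_divergence_generations > 0")


@dataclass
class GenotypeDataset:
    """Sites x samples phased genotypes with quality metadata and truth.

    Haplotypes are stored as an ``(n_sites, 2 * n_samples)`` int8 matrix with
    columns ``2i, 2i+1`` forming diploid sample ``i``; values are 0 (ref),
    1 (alt) or -1 (missing).  Positions are 1-based as in VCF and strictly
    increasing within a scaffold.
    """

    scaffold_ids: list[str]
    scaffold_lengths: np.ndarray  # int64, per scaffold
    site_scaffold: np.ndarray  # int32 index into scaffold_ids, per site
    positions: np.ndarray  # int64, 1-based
    ref: np.ndarray  # <U1
    alt: np.ndarray  # <U1
    haplotypes: np.ndarray  # int8 (S, 2N)
    dp: np.ndarray  # int32 (S, N)
    gq: np.ndarray  # int32 (S, N)
    mq: np.ndarray  # float64 (S,)
    ancestral: np.ndarray  # int8 (S,): 0 ref, 1 alt, -1 unknown
    sample_ids: list[str]
    sample_population: list[str]
    phased: bool = True
    truth: dict = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    # ---------------------------------------------------------------- views
    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def genotypes(self) -> np.ndarray:
        """Dosage matrix (S, N): 0/1/2 alt-allele count, -1 missing."""
        h = self.haplotypes
        a = h[:, 0::2]
        b = h[:, 1::2]
        g = a + b
        g[(a < 0) | (b < 0)] = -1
        return g.astype(np.int8)

    def is_het(self) -> np.ndarray:
        a = self.haplotypes[:, 0::2]
        b = self.haplotypes[:, 1::2]
        return (a >= 0) & (b >= 0) & (a != b)

    def validate(self):
        s = self.n_sites
        for arr, name in ((self.site_scaffold, "site_scaffold"),
                          (self.ref, "ref"), (self.alt, "alt"),
                          (self.ancestral, "ancestral"), (self.mq, "mq")):
            if len(arr) != s:
                raise ValueError(f"{name} length mismatch")
        if self.haplotypes.shape != (s, 2 * self.n_samples):
            raise ValueError("haplotype matrix shape mismatch")
        if not set(np.unique(self.haplotypes)).issubset({-1, 0, 1}):
            raise ValueError("haplotype values must be in {0, 1, -1}")
        for sc in np.unique(self.site_scaffold):
            pos = self.positions[self.site_scaffold == sc]
            if np.any(np.diff(pos) <= 0):
                raise ValueError("positions must be strictly increasing per scaffold")

    def subset_sites(self, mask: np.ndarray) -> "GenotypeDataset":
        mask = np.asarray(mask)
        return dataclasses.replace(
            self,
            site_scaffold=self.site_scaffold[mask],
            positions=self.positions[mask],
            ref=self.ref[mask],
            alt=self.alt[mask],
            haplotypes=self.haplotypes[mask],
            dp=self.dp[mask],
            gq=self.gq[mask],
            mq=self.mq[mask],
            ancestral=self.ancestral[mask],
            truth=dict(self.truth),
        )

    def subset_samples(self, keep: list[int]) -> "GenotypeDataset":
        keep = list(keep)
        cols = np.array([c for i in keep for c in (2 * i, 2 * i + 1)])
        return dataclasses.replace(
            self,
            haplotypes=self.haplotypes[:, cols],
            dp=self.dp[:, keep],
            gq=self.gq[:, keep],
            sample_ids=[self.sample_ids[i] for i in keep],
            sample_population=[self.sample_population[i] for i in keep],
            truth=dict(self.truth),
        )

    def genetic_length_cM(self, rate_cM_per_Mb: float = 1.0) -> float:
        return float(self.scaffold_lengths.sum()) / 1e6 * rate_cM_per_Mb


# ======================================================================
# backward-in-time genealogy without recombination
# ======================================================================

def _simulate_tree(model: DemographicModel, k_per_pop, og_time, rng):
    """Sample one genealogy under the structured piecewise coalescent.

    Returns (times, children, n_leaves, og_leaf) where ``children`` maps an
    internal node to its two children.  Leaves are numbered per population in
    order; the outgroup leaf (if any) is the last leaf.
    """
    n_pops = model.n_populations
    split = model.split_time_generations if n_pops == 2 else 0.0
    og = og_time is not None
    if og and n_pops == 2 and og_time < split:
        raise ValueError("outgroup divergence must predate the population split")

    leaves = []
    demes: dict[object, list[int]] = {}
    nid = 0
    for p in range(n_pops):
        demes[p] = list(range(nid, nid + k_per_pop[p]))
        nid += k_per_pop[p]
    og_leaf = None
    if og:
        og_leaf = nid
        demes["og"] = [nid]
        nid += 1
    n_leaves = nid
    times = [0.0] * n_leaves
    children: dict[int, tuple[int, int]] = {}

    bounds = sorted({s for traj in model.populations for s, _ in traj}
                    | ({split} if n_pops == 2 else set())
                    | ({og_time} if og else set()))
    mig = model.migration_rate

    t = 0.0
    merged_split = n_pops == 1
    merged_og = not og
    while True:
        active = sum(len(v) for k, v in demes.items())
        if active <= 1 and merged_split and merged_og:
            break
        seg_end = next((b for b in bounds if b > t), np.inf)
        # per-deme coalescence rates (outgroup deme holds one lineage: rate 0)
        rates = {}
        for d, lin in demes.items():
            k = len(lin)
            if d == "og" or k < 2:
                continue
            traj = model.populations[d] if isinstance(d, int) else None
            rates[d] = k * (k - 1) / 2.0 / (2.0 * ne_at(traj, t))
        mig_rate = 0.0
        if mig > 0 and not merged_split:
            mig_rate = mig * (len(demes[0]) + len(demes[1]))
        total = sum(rates.values()) + mig_rate
        if total > 0:
            w = rng.exponential(1.0 / total)
            if t + w < seg_end:
                t += w
                u = rng.uniform(0, total)
                if u < mig_rate:
                    # move one random lineage to the other deme
                    k0 = len(demes[0])
                    src = 0 if u < mig * k0 else 1
                    dst = 1 - src
                    i = rng.integers(len(demes[src]))
                    demes[dst].append(demes[src].pop(i))
                    continue
                u -= mig_rate
                for d, r in rates.items():
                    if u < r:
                        lin = demes[d]
                        i, j = rng.choice(len(lin), size=2, replace=False)
                        c1, c2 = lin[i], lin[j]
                        for idx in sorted((i, j), reverse=True):
                            lin.pop(idx)
                        times.append(t)
                        children[nid] = (c1, c2)
                        lin.append(nid)
                        nid += 1
                        break
                    u -= r
                continue
        if not np.isfinite(seg_end):  # pragma: no cover - defensive
            raise RuntimeError("coalescent failed to terminate")
        t = seg_end
        if not merged_split and t >= split:
            demes[0].extend(demes.pop(1))
            merged_split = True
        if not merged_og and t >= og_time:
            demes[0].extend(demes.pop("og"))
            merged_og = True

    return np.array(times), children, n_leaves, og_leaf


def _leaf_sets(times, children, n_leaves):
    n_nodes = len(times)
    desc = np.zeros((n_nodes, n_leaves), dtype=bool)
    desc[np.arange(n_leaves), np.arange(n_leaves)] = True
    for node in range(n_leaves, n_nodes):  # children always have smaller ids
        c1, c2 = children[node]
        desc[node] = desc[c1] | desc[c2]
    return desc


def _drop_mutations(times, children, n_leaves, mu, length_bp, rng):
    """Poisson mutations on branches; infinite sites within the locus.

    Returns (positions 1-based sorted, carriers boolean (S, n_leaves)).
    """
    n_nodes = len(times)
    parent = np.full(n_nodes, -1)
    for node, (c1, c2) in children.items():
        parent[c1] = node
        parent[c2] = node
    has_parent = parent >= 0
    blen = np.zeros(n_nodes)
    blen[has_parent] = times[parent[has_parent]] - times[np.where(has_parent)[0]]
    total = blen.sum()
    n_mut = rng.poisson(mu * length_bp * total) if total > 0 else 0
    n_mut = min(n_mut, length_bp)  # infinite-sites cap
    if n_mut == 0:
        return np.empty(0, dtype=np.int64), np.zeros((0, n_leaves), dtype=bool)
    nodes = rng.choice(n_nodes, size=n_mut, p=blen / total)
    pos = rng.choice(length_bp, size=n_mut, replace=False) + 1
    order = np.argsort(pos)
    pos, nodes = pos[order], nodes[order]
    desc = _leaf_sets(times, children, n_leaves)
    return pos.astype(np.int64), desc[nodes]


def _ingroup_tmrca(times, children, n_leaves, og_leaf):
    """Time of the MRCA of the non-outgroup leaves."""
    desc = _leaf_sets(times, children, n_leaves)
    ingroup = np.ones(n_leaves, dtype=bool)
    if og_leaf is not None:
        ingroup[og_leaf] = False
    covers = desc[:, ingroup].all(axis=1)
    return float(times[np.where(covers)[0].min()])


# ======================================================================
# dataset assembly
# ======================================================================

_BASES = np.array(list("ACGT"))


def _quality_arrays(n_sites, n_samples, config, rng):
    m, k = config.depth_mean, config.depth_overdispersion
    if k <= 0:
        dp = rng.poisson(m, size=(n_sites, n_samples))
    else:
        dp = rng.negative_binomial(k, k / (k + m), size=(n_sites, n_samples))
    gq = np.clip(np.rint(rng.normal(config.gq_mean, config.gq_sd,
                                    size=(n_sites, n_samples))), 0, 99)
    mq = np.round(np.clip(rng.normal(60.0, 1.5, size=n_sites), 0, 70), 2)
    return dp.astype(np.int32), gq.astype(np.int32), mq


def _alleles(n_sites, rng):
    ref_idx = rng.integers(0, 4, size=n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4
    return _BASES[ref_idx], _BASES[alt_idx]


def _sample_names(config):
    names, pops = [], []
    for p, n in enumerate(config.n_diploids):
        pop = f"pop{p}"
        for i in range(n):
            names.append(f"{pop}_s{i:02d}")
            pops.append(pop)
    if config.include_outgroup:
        names.append("outgroup")
        pops.append("outgroup")
    return names, pops


def simulate_dataset(model: DemographicModel,
                     config: SimulationConfig) -> GenotypeDataset:
    """Generate a phased dataset with demographic truth.

    ``independent`` mode simulates ``n_independent_loci`` non-recombining loci
    of ``locus_length_bp`` each (one scaffold per locus); ``linked`` mode
    simulates ``n_chromosomes`` chromosomes of ``chromosome_length_bp`` with
    recombination via msprime.
    """
    if len(config.n_diploids) != model.n_populations:
        raise ValueError("n_diploids must list one count per population")
    rng = np.random.default_rng(config.seed)
    if config.mode == "independent":
        return _simulate_independent(model, config, rng)
    return _simulate_linked(model, config, rng)


def _simulate_independent(model, config, rng):
    k_per_pop = [2 * n for n in config.n_diploids]
    og_time = (config.outgroup_divergence_generations
               if config.include_outgroup else None)
    n_ingroup_hap = sum(k_per_pop)
    L = config.locus_length_bp

    scaffold_ids, scaffold_lengths = [], []
    site_scaffold, positions, hap_cols = [], [], []
    tmrcas = np.zeros(config.n_independent_loci)
    for locus in range(config.n_independent_loci):
        times, children, n_leaves, og_leaf = _simulate_tree(
            model, k_per_pop, og_time, rng)
        tmrcas[locus] = _ingroup_tmrca(times, children, n_leaves, og_leaf)
        pos, carriers = _drop_mutations(
            times, children, n_leaves, model.mutation_rate, L, rng)
        scaffold_ids.append(f"locus_{locus:06d}")
        scaffold_lengths.append(L)
        if len(pos):
            site_scaffold.append(np.full(len(pos), locus, dtype=np.int32))
            positions.append(pos)
            hap_cols.append(carriers.astype(np.int8))

    if positions:
        site_scaffold = np.concatenate(site_scaffold)
        positions = np.concatenate(positions)
        haps = np.concatenate(hap_cols, axis=0)
    else:
        site_scaffold = np.empty(0, dtype=np.int32)
        positions = np.empty(0, dtype=np.int64)
        haps = np.zeros((0, n_ingroup_hap + (1 if og_time else 0)), dtype=np.int8)

    if og_time is not None:
        # outgroup written as a haploid-equivalent homozygous diploid
        og = haps[:, -1:]
        haps = np.concatenate([haps[:, :-1], og, og], axis=1)

    names, pops = _sample_names(config)
    n_sites = len(positions)
    dp, gq, mq = _quality_arrays(n_sites, len(names), config, rng)
    ref, alt = _alleles(n_sites, rng)
    return GenotypeDataset(
        scaffold_ids=scaffold_ids,
        scaffold_lengths=np.array(scaffold_lengths, dtype=np.int64),
        site_scaffold=site_scaffold,
        positions=positions,
        ref=ref, alt=alt,
        haplotypes=haps,
        dp=dp, gq=gq, mq=mq,
        ancestral=np.zeros(n_sites, dtype=np.int8),
        sample_ids=names,
        sample_population=pops,
        phased=True,
        truth={"mode": "independent", "tmrca": tmrcas, "seed": config.seed,
               "model": model},
    )


def _msprime_demography(model, config):
    import msprime

    dem = msprime.Demography()
    traj0 = model.populations[0]
    split = model.split_time_generations
    dem.add_population(name="pop0", initial_size=traj0[0][1])
    for s, n in traj0[1:]:
        if model.n_populations == 2 and s > split:
            continue
        dem.add_population_parameters_change(time=s, initial_size=n,
                                             population="pop0")
    root_pop = "pop0"
    if model.n_populations == 2:
        traj1 = model.populations[1]
        dem.add_population(name="pop1", initial_size=traj1[0][1])
        for s, n in traj1[1:]:
            dem.add_population_parameters_change(time=s, initial_size=n,
                                                 population="pop1")
        dem.add_population(name="anc", initial_size=ne_at(traj0, split))
        dem.add_population_split(time=split, derived=["pop0", "pop1"],
                                 ancestral="anc")
        for s, n in traj0:
            if s > split:
                dem.add_population_parameters_change(time=s, initial_size=n,
                                                     population="anc")
        if model.migration_rate > 0:
            dem.set_symmetric_migration_rate(["pop0", "pop1"],
                                             model.migration_rate)
        root_pop = "anc"
    if config.include_outgroup:
        og_t = config.outgroup_divergence_generations
        dem.add_population(name="outg", initial_size=traj0[0][1])
        dem.add_population(name="root", initial_size=ne_at(traj0, og_t))
        dem.add_population_split(time=og_t, derived=[root_pop, "outg"],
                                 ancestral="root")
    dem.sort_events()
    return dem


def _simulate_linked(model, config, rng):
    import msprime

    dem = _msprime_demography(model, config)
    samples = {f"pop{p}": n for p, n in enumerate(config.n_diploids)}
    if config.include_outgroup:
        samples["outg"] = 1
    names, pops = _sample_names(config)
    n_samples = len(names)
    L = config.chromosome_length_bp

    scaffold_ids = [f"chr{c + 1:02d}" for c in range(config.n_chromosomes)]
    site_scaffold, positions, hap_cols = [], [], []
    ibd_rows = []
    for c in range(config.n_chromosomes):
        anc_seed, mut_seed = rng.integers(1, 2**31 - 1, size=2)
        ts = msprime.sim_ancestry(
            samples=samples, demography=dem, sequence_length=L,
            recombination_rate=model.recombination_rate_per_bp,
            random_seed=int(anc_seed))
        ts = msprime.sim_mutations(
            ts, rate=model.mutation_rate, random_seed=int(mut_seed),
            model=msprime.BinaryMutationModel(), discrete_genome=True)
        gm = ts.genotype_matrix().astype(np.int8)
        pos = np.array([int(s.position) + 1 for s in ts.sites()], dtype=np.int64)
        seg = (gm.max(axis=1) != gm.min(axis=1))
        site_scaffold.append(np.full(seg.sum(), c, dtype=np.int32))
        positions.append(pos[seg])
        hap_cols.append(gm[seg])
        if config.track_ibd:
            ibd_rows.extend(_true_ibd(ts, c, config, model))

    site_scaffold = np.concatenate(site_scaffold)
    positions = np.concatenate(positions)
    haps = np.concatenate(hap_cols, axis=0)
    if config.include_outgroup:
        haps[:, -1] = haps[:, -2]  # homozygous haploid-equivalent outgroup

    n_sites = len(positions)
    dp, gq, mq = _quality_arrays(n_sites, n_samples, config, rng)
    ref, alt = _alleles(n_sites, rng)
    truth = {"mode": "linked", "seed": config.seed, "model": model}
    if config.track_ibd:
        import pandas as pd

        truth["ibd_tracts"] = pd.DataFrame(
            ibd_rows, columns=["hap_a", "hap_b", "scaffold", "start",
                               "end", "tmrca"])
    return GenotypeDataset(
        scaffold_ids=scaffold_ids,
        scaffold_lengths=np.full(config.n_chromosomes, L, dtype=np.int64),
        site_scaffold=site_scaffold,
        positions=positions,
        ref=ref, alt=alt,
        haplotypes=haps,
        dp=dp, gq=gq, mq=mq,
        ancestral=np.zeros(n_sites, dtype=np.int8),
        sample_ids=names,
        sample_population=pops,
        phased=True,
        truth=truth,
    )


def _true_ibd(ts, chrom, config, model):
    """Extract true IBD tracts (recent MRCA segments) from a tree sequence."""
    min_bp = config.ibd_min_cM / model.recombination_rate_cM_per_Mb * 1e6
    res = ts.ibd_segments(max_time=config.ibd_max_time, min_span=min_bp,
                          store_pairs=True, store_segments=True)
    rows = []
    node_time = ts.tables.nodes.time
    for pair in res.pairs:
        segs = res[pair]
        for left, right, node in zip(segs.left, segs.right, segs.node):
            rows.append((int(pair[0]), int(pair[1]), chrom,
                         int(left), int(right), float(node_time[node])))
    return rows


# ======================================================================
# pedigree overlay with founder-ancestry truth
# ======================================================================

def _founder_track(dataset, hap):
    """Default ancestry of an original haplotype: itself, genome-wide."""
    return {sc: (np.array([0, int(L)]), np.array([hap]))
            for sc, L in enumerate(dataset.scaffold_lengths)}


def _get_track(dataset, hap):
    anc = dataset.truth.get("hap_ancestry", {})
    return anc.get(hap) or _founder_track(dataset, hap)


def _gamete(dataset, parent_idx, rng, rate_cM_per_Mb):
    """One meiosis: returns (allele column, ancestry track)."""
    h0, h1 = 2 * parent_idx, 2 * parent_idx + 1
    t0, t1 = _get_track(dataset, h0), _get_track(dataset, h1)
    alleles = np.empty(dataset.n_sites, dtype=np.int8)
    track = {}
    for sc, L in enumerate(dataset.scaffold_lengths):
        L = int(L)
        morgans = L / 1e6 * rate_cM_per_Mb / 100.0
        n_x = rng.poisson(morgans)
        cuts = np.sort(rng.integers(1, L, size=n_x)) if n_x else np.empty(0, int)
        start_hap = int(rng.integers(2))
        bounds = np.concatenate([[0], cuts, [L]])
        which = (start_hap + np.arange(len(bounds) - 1)) % 2

        site_mask = dataset.site_scaffold == sc
        pos0 = dataset.positions[site_mask] - 1  # 0-based
        seg_of_site = np.searchsorted(bounds, pos0, side="right") - 1
        use_h1 = which[seg_of_site] == 1
        col = np.where(use_h1,
                       dataset.haplotypes[site_mask, h1],
                       dataset.haplotypes[site_mask, h0])
        alleles[site_mask] = col

        # compose ancestry: pick from parent's track per transmitted segment
        bks, ids = [], []
        for k in range(len(bounds) - 1):
            a, b = int(bounds[k]), int(bounds[k + 1])
            if a == b:
                continue
            pb, pi = (t0, t1)[which[k]][sc]
            lo = np.searchsorted(pb, a, side="right") - 1
            hi = np.searchsorted(pb, b, side="left")
            for m in range(lo, hi):
                s = max(a, int(pb[m]))
                e = min(b, int(pb[m + 1]))
                if s < e:
                    bks.append(s)
                    ids.append(int(pi[m]))
        # merge adjacent segments with the same founder id
        mb, mi = [], []
        for start, fid in zip(bks, ids):
            if mi and fid == mi[-1]:
                continue
            mb.append(start)
            mi.append(fid)
        mb.append(L)
        track[sc] = (np.array(mb), np.array(mi))
    return alleles, track


def overlay_pedigree(dataset: GenotypeDataset, relationship: str,
                     parents: tuple[int, int] | None = None,
                     seed: int = 0) -> GenotypeDataset:
    """Append synthetic relatives built by Mendelian transmission.

    ``duplicate`` copies ``parents[0]``; ``parent_offspring`` appends one
    offspring of the two parents; ``full_sib`` appends two offspring of the
    same parents.  Crossovers are Poisson at the model's genetic map rate.
    Truth ancestry tracks (founder haplotype per genomic interval) are stored
    under ``truth['hap_ancestry']`` and the relationship under
    ``truth['pedigree']``.
    """
    if relationship not in ("duplicate", "parent_offspring", "full_sib"):
        raise ValueError(f"unknown relationship: {relationship}")
    if not dataset.phased:
        raise ValueError("pedigree overlay requires phased genotypes")
    model = dataset.truth.get("model")
    rate = (model.recombination_rate_cM_per_Mb if model is not None else 1.0)
    rng = np.random.default_rng(seed)
    if parents is None:
        parents = (0, 1 % dataset.n_samples)
    pa, pb = parents

    new_cols, new_tracks, new_names, ped = [], [], [], []
    if relationship == "duplicate":
        name = f"{dataset.sample_ids[pa]}_dup"
        new_cols.append((dataset.haplotypes[:, 2 * pa].copy(),
                         dataset.haplotypes[:, 2 * pa + 1].copy()))
        new_tracks.append((_get_track(dataset, 2 * pa),
                           _get_track(dataset, 2 * pa + 1)))
        new_names.append(name)
        ped.append({"child": name, "parents": (dataset.sample_ids[pa],),
                    "relationship": "duplicate"})
    else:
        n_children = 2 if relationship == "full_sib" else 1
        for c in range(n_children):
            ga, ta = _gamete(dataset, pa, rng, rate)
            gb, tb = _gamete(dataset, pb, rng, rate)
            name = f"child{len(dataset.sample_ids) + c}"
            new_cols.append((ga, gb))
            new_tracks.append((ta, tb))
            new_names.append(name)
            ped.append({"child": name,
                        "parents": (dataset.sample_ids[pa],
                                    dataset.sample_ids[pb]),
                        "relationship": relationship})

    n_new = len(new_names)
    haps = np.concatenate(
        [dataset.haplotypes] + [np.column_stack(c) for c in new_cols], axis=1)
    rng_q = np.random.default_rng(seed + 1)
    dp_new = rng_q.negative_binomial(8, 8 / 48.0,
                                     size=(dataset.n_sites, n_new)).astype(np.int32)
    gq_new = np.clip(np.rint(rng_q.normal(80, 10, size=(dataset.n_sites, n_new))),
                     0, 99).astype(np.int32)

    truth = dict(dataset.truth)
    anc = dict(truth.get("hap_ancestry", {}))
    base = 2 * dataset.n_samples
    for k, (ta, tb) in enumerate(new_tracks):
        anc[base + 2 * k] = ta
        anc[base + 2 * k + 1] = tb
    truth["hap_ancestry"] = anc
    truth["pedigree"] = truth.get("pedigree", []) + ped

    return dataclasses.replace(
        dataset,
        haplotypes=haps,
        dp=np.concatenate([dataset.dp, dp_new], axis=1),
        gq=np.concatenate([dataset.gq, gq_new], axis=1),
        sample_ids=dataset.sample_ids + new_names,
        sample_population=dataset.sample_population + ["pedigree"] * n_new,
        truth=truth,
    )


def _equal_fraction(dataset, hap_a, hap_b):
    """Genome fraction where two haplotypes carry the same founder segment."""
    ta, tb = _get_track(dataset, hap_a), _get_track(dataset, hap_b)
    total = float(dataset.scaffold_lengths.sum())
    same = 0.0
    for sc in range(len(dataset.scaffold_ids)):
        ba, ia = ta[sc]
        bb, ib = tb[sc]
        cuts = np.union1d(ba, bb)
        for k in range(len(cuts) - 1):
            s, e = cuts[k], cuts[k + 1]
            ja = np.searchsorted(ba, s, side="right") - 1
            jb = np.searchsorted(bb, s, side="right") - 1
            if ia[min(ja, len(ia) - 1)] == ib[min(jb, len(ib) - 1)]:
                same += e - s
    return same / total


def truth_kinship(dataset: GenotypeDataset, i: int, j: int) -> float:
    """Realized kinship phi from founder-ancestry truth tracks."""
    return sum(_equal_fraction(dataset, a, b)
               for a in (2 * i, 2 * i + 1)
               for b in (2 * j, 2 * j + 1)) / 4.0


def truth_autozygosity(dataset: GenotypeDataset, i: int) -> float:
    """Realized genome fraction where sample i's haplotypes are IBD."""
    return _equal_fraction(dataset, 2 * i, 2 * i + 1)


def simulate_mendelian_pair(n_sites: int = 10_000, seed: int = 0,
                            freq_low: float = 0.05, freq_high: float = 0.95
                            ) -> np.ndarray:
    """Unlinked parent-offspring dosages for kinship validation.

    Site allele frequencies are drawn uniform(freq_low, freq_high); the
    parent and an unrelated co-parent are Hardy-Weinberg draws and the
    offspring receives one Mendelian allele from each.  Returns an
    (n_sites, 3) dosage matrix: columns parent, co-parent, offspring.
    """
    rng = np.random.default_rng(seed)
    p = rng.uniform(freq_low, freq_high, size=n_sites)
    par = rng.binomial(1, p[:, None], size=(n_sites, 2))  # two haplotypes
    cop = rng.binomial(1, p[:, None], size=(n_sites, 2))
    from_par = par[np.arange(n_sites), rng.integers(2, size=n_sites)]
    from_cop = cop[np.arange(n_sites), rng.integers(2, size=n_sites)]
    return np.column_stack([par.sum(axis=1), cop.sum(axis=1),
                            from_par + from_cop]).astype(np.int8)


# ======================================================================
# vectorized Monte-Carlo of coalescent stage durations (oracle)
# ======================================================================

def simulate_coalescent_durations(trajectory, n: int, reps: int, rng):
    """Monte-Carlo durations T_k (k = n..2) under a piecewise trajectory.

    Returns an array of shape (reps, n - 1) with column k-index 0 holding the
    duration with n lineages and the last column the duration with 2.  Used as
    the independent oracle for the analytic expected-SFS machinery.
    """
    trajectory = _as_trajectory(trajectory)
    starts = np.array([s for s, _ in trajectory])
    sizes = np.array([s for _, s in trajectory])
    t = np.zeros(reps)
    out = np.empty((reps, n - 1))
    for ki, k in enumerate(range(n, 1, -1)):
        rate_scale = k * (k - 1) / 2.0
        target = rng.exponential(1.0, size=reps) / rate_scale  # scaled time
        t_new = np.empty(reps)
        remaining = target.copy()
        cur = t.copy()
        done = np.zeros(reps, dtype=bool)
        while not done.all():
            idx = np.minimum(np.searchsorted(starts, cur[~done], side="right") - 1,
                             len(starts) - 1)
            ne = sizes[idx]
            nxt = np.where(idx + 1 < len(starts), starts[np.minimum(idx + 1,
                                                                    len(starts) - 1)],
                           np.inf)
            # scaled time available in this epoch
            avail = (nxt - cur[~done]) / (2.0 * ne)
            use = np.minimum(avail, remaining[~done])
            cur_ = cur[~done] + use * 2.0 * ne
            rem_ = remaining[~done] - use
            fin = rem_ <= 1e-15
            sub = np.where(~done)[0]
            cur[sub] = cur_
            remaining[sub] = rem_
            done[sub[fin]] = True
        t_new = cur
        out[:, ki] = t_new - t
        t = t_new
    return out
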