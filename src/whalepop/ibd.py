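"""IBD segments between phased haplotypes and recent-Ne estimation.

Detection is seed-and-extend exact matching with an optional per-cM mismatch
allowance; segments shorter than 2 cM (constant-map conversion) are not
reported.  The length-spectrum model assumes that a haplotype pair
coalescing g generations ago leaves segments whose lengths are Exponential
with rate 2g per Morgan and whose expected number is 2 g L P(g) per pair,

    P(g) = (1 / 2N_g) * prod_{h<g} (1 - 1 / 2N_h),

so the expected count in a length bin [l1, l2) Morgans is
n_pairs * sum_g 2 g L P(g) (exp(-2 g l1) - exp(-2 g l2)).  The recent-Ne
fit maximizes the Poisson likelihood of binned counts over log-Ne at knots
with a squared-difference smoothness penalty; the penalty weight is chosen
by a two-fold chromosome split and the envelope by a chromosome bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln

from .simulate import GenotypeDataset

__all__ = ["IBDSegment", "IBDSpectrum", "RecentNeConfig",
           "detect_ibd", "ibd_spectrum", "expected_ibd_spectrum",
           "fit_recent_ne", "segments_frame"]


@dataclass(frozen=True)
class IBDSegment:
    sample_a: str
    hap_a: int  # 0 or 1 within sample
    sample_b: str
    hap_b: int
    scaffold: str
    start: int  # 0-based half-open physical span
    end: int
    cM: float
    n_mismatches: int
    within_individual: bool = False


def detect_ibd(dataset: GenotypeDataset, min_cM: float = 2.0,
               rate_cM_per_Mb: float = 1.0,
               max_mismatches_per_cM: float = 0.0,
               include_within_individual: bool = True) -> list[IBDSegment]:
    """Maximal (near-)identical tracts between all haplotype pairs.

    Within-individual pairs correspond to ROH and are flagged.  Mismatching
    sites up to floor(max_mismatches_per_cM * length_cM) are tolerated.
    """
    if not dataset.phased:
        raise ValueError("IBD detection requires phased haplotypes; use the "
                         "linked simulation mode or phase externally")
    h = dataset.haplotypes
    n_hap = h.shape[1]
    segs: list[IBDSegment] = []
    for sci, sc in enumerate(dataset.scaffold_ids):
        sel = dataset.site_scaffold == sci
        pos = dataset.positions[sel]
        hs = h[sel]
        L = int(dataset.scaffold_lengths[sci])
        for a in range(n_hap):
            for b in range(a + 1, n_hap):
                within = (a // 2) == (b // 2)
                if within and not include_within_individual:
                    continue
                for s0, s1, nmm in _pair_segments(
                        hs[:, a], hs[:, b], pos, L, min_cM, rate_cM_per_Mb,
                        max_mismatches_per_cM):
                    segs.append(IBDSegment(
                        sample_a=dataset.sample_ids[a // 2], hap_a=a % 2,
                        sample_b=dataset.sample_ids[b // 2], hap_b=b % 2,
                        scaffold=sc, start=s0, end=s1,
                        cM=(s1 - s0) / 1e6 * rate_cM_per_Mb,
                        n_mismatches=nmm, within_individual=within))
    return segs


def _pair_segments(ha, hb, pos, length_bp, min_cM, rate, tol_per_cM):
    """Candidate maximal segments for one haplotype pair on one scaffold."""
    ok = (ha >= 0) & (hb >= 0)
    mism_pos = pos[ok & (ha != hb)].astype(np.int64)
    bp_per_cM = 1e6 / rate
    min_bp = min_cM * bp_per_cM
    # segments run between consecutive mismatches (0-based half-open)
    bounds = np.concatenate([[0], mism_pos, [length_bp + 1]])
    m = len(mism_pos)
    out = []
    if tol_per_cM <= 0:
        for i in range(m + 1):
            s = int(bounds[i])  # position of previous mismatch (1-based) or 0
            e = int(bounds[i + 1]) - 1  # bp before the next mismatch
            if e - s >= min_bp:
                out.append((s, e, 0))
        return out
    # with tolerance: seed-and-extend.  Any qualifying segment (>= min_bp
    # with <= tol * span mismatches) must contain a mismatch-free gap of at
    # least ~1/(tol + 1/min_cM) cM, so only gaps above a seed length need
    # to be explored; a bounded two-pointer around each seed then finds the
    # maximal segments containing it.
    gap_sizes = np.diff(bounds)
    seed_bp = 0.3 * bp_per_cM
    seeds = np.where(gap_sizes >= max(seed_bp, 1.0))[0]
    K = 64  # mismatch-extension window; budgets beyond this are unreachable
    raw = set()
    for sd in seeds:
        for a in range(max(0, sd - K), sd + 1):
            best = None
            for j in range(sd, min(m, a + K) + 1):
                s = int(bounds[a])
                e = int(bounds[j + 1]) - 1
                n_mm = j - a
                span_cM = (e - s) / bp_per_cM
                if n_mm == 0 or n_mm <= np.floor(tol_per_cM * span_cM):
                    best = (s, e, n_mm)
                elif span_cM > 0 and n_mm > tol_per_cM * span_cM + 2:
                    break
            if best and best[1] - best[0] >= min_bp:
                raw.add(best)
    # one region, one call: greedy longest non-overlapping selection
    out = []
    for s, e, nm in sorted(raw, key=lambda c: c[1] - c[0], reverse=True):
        if all(e <= cs or s >= ce for cs, ce, _ in out):
            out.append((s, e, nm))
    out.sort()
    return out


@dataclass
class IBDSpectrum:
    bin_edges_cM: np.ndarray  # ascending, last bin open-ended
    counts: np.ndarray
    n_haplotype_pairs: int
    genome_morgans: float
    chromosome_counts: dict = field(default_factory=dict)

    def __post_init__(self):
        self.bin_edges_cM = np.asarray(self.bin_edges_cM, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(self.counts < 0):
            raise ValueError("counts must be >= 0")


def ibd_spectrum(segments: list[IBDSegment], n_haplotype_pairs: int,
                 genome_morgans: float,
                 bin_edges_cM=(2, 3, 4, 6, 8, 12, 16, 24, 32)) -> IBDSpectrum:
    """Bin between-individual segments by genetic length.

    Within-individual segments (ROH) are excluded from the spectrum used for
    the Ne fit.  The last edge opens an unbounded final bin.
    """
    edges = np.asarray(bin_edges_cM, dtype=float)
    lengths = np.array([s.cM for s in segments if not s.within_individual])
    scaffs = [s.scaffold for s in segments if not s.within_individual]
    counts = np.zeros(len(edges))
    chrom: dict[str, np.ndarray] = {}
    if len(lengths):
        idx = np.clip(np.digitize(lengths, edges) - 1, 0, len(edges) - 1)
        np.add.at(counts, idx, 1)
        for sc in sorted(set(scaffs)):
            c = np.zeros(len(edges))
            sel = [i for i, s in enumerate(scaffs) if s == sc]
            np.add.at(c, idx[sel], 1)
            chrom[sc] = c
    return IBDSpectrum(bin_edges_cM=edges, counts=counts,
                       n_haplotype_pairs=n_haplotype_pairs,
                       genome_morgans=genome_morgans,
                       chromosome_counts=chrom)


def _coalescence_mass(ne_per_gen: np.ndarray) -> np.ndarray:
    """P(g) for g = 1..len(ne): coalesce at g having escaped 1..g-1."""
    rate = 1.0 / (2.0 * ne_per_gen)
    log_surv = np.concatenate([[0.0], np.cumsum(np.log1p(-np.minimum(rate,
                                                                     0.999)))])
    return rate * np.exp(log_surv[:-1])


def expected_ibd_spectrum(ne_per_gen: np.ndarray, n_haplotype_pairs: int,
                          genome_morgans: float, bin_edges_cM,
                          min_cM: float = 2.0,
                          tail_generations: int = 5000) -> np.ndarray:
    """Expected counts per length bin under a recent-Ne trajectory.

    ``ne_per_gen[g-1]`` is Ne at generation g; beyond the array the
    trajectory is continued at its last value for ``tail_generations`` (the
    single "older" class absorbing the remaining coalescence mass).
    """
    edges = np.asarray(bin_edges_cM, dtype=float)
    if np.any(edges < min_cM):
        raise ValueError("bins must not extend below the detection threshold")
    ne = np.asarray(ne_per_gen, dtype=float)
    if tail_generations > len(ne):
        ne = np.concatenate([ne, np.full(tail_generations - len(ne), ne[-1])])
    g = np.arange(1, len(ne) + 1, dtype=float)
    pg = _coalescence_mass(ne)
    intensity = 2.0 * g * genome_morgans * pg  # segments per pair, age g
    lo = edges / 100.0  # Morgans
    hi = np.concatenate([edges[1:] / 100.0, [np.inf]])
    surv_lo = np.exp(-2.0 * np.outer(g, lo))
    surv_hi = np.where(np.isinf(hi), 0.0, np.exp(-2.0 * np.outer(g, hi)))
    return n_haplotype_pairs * (intensity[:, None]
                                * (surv_lo - surv_hi)).sum(axis=0)


@dataclass(frozen=True)
class RecentNeConfig:
    g_min: int = 4
    g_max: int = 200
    knots: tuple[int, ...] = ()
    lambda_grid: tuple[float, ...] = (0.003, 0.03, 0.3)
    n_boot: int = 80
    n_restarts: int = 2
    seed: int = 0

    def knot_vector(self) -> np.ndarray:
        if self.knots:
            return np.asarray(self.knots, dtype=float)
        dense = np.arange(self.g_min, min(51, self.g_max + 1))
        if self.g_max > 50:
            sparse = np.unique(np.rint(np.geomspace(50, self.g_max, 8)
                                       ).astype(int))[1:]
            return np.concatenate([dense, sparse]).astype(float)
        return dense.astype(float)


@dataclass
class RecentNeTrajectory:
    generations: np.ndarray
    ne: np.ndarray
    log_likelihood: float
    smoothing_lambda: float
    envelope: pd.DataFrame | None = None

    def ne_at(self, g: float) -> float:
        return float(np.interp(g, self.generations, self.ne))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"generation": self.generations, "ne": self.ne})
        if self.envelope is not None:
            df = df.merge(self.envelope, on="generation", how="left")
        return df


def _interp_log_ne(knots, log_ne, g_axis):
    return np.interp(g_axis, knots, log_ne)


def _poisson_ll(obs, lam):
    lam = np.clip(lam, 1e-300, None)
    return float(np.sum(obs * np.log(lam) - lam - gammaln(obs + 1.0)))


def _fit_knots(counts, n_pairs, genome_morgans, edges, min_cM, knots, lam_s,
               rng, n_restarts, g_max):
    g_axis = np.arange(1, g_max + 1, dtype=float)

    def expand(x):
        log_ne = _interp_log_ne(knots, x, g_axis)
        # below g_min the trajectory is held at its first knot value
        return 10.0 ** log_ne

    total = float(np.sum(counts))

    def nll(x):
        lam = expected_ibd_spectrum(expand(x), n_pairs, genome_morgans,
                                    edges, min_cM)
        # penalty scales with the observed count so the fit depends only on
        # per-pair rates (doubling counts and pairs leaves the argmax fixed)
        pen = lam_s * total * float(np.sum(np.diff(x) ** 2))
        return -_poisson_ll(counts, lam) + pen

    # moment start: total expected count under constant N matches observed
    best = None
    x0_base = np.full(len(knots), 3.0)
    for r in range(n_restarts):
        x0 = x0_base if r == 0 else x0_base + rng.normal(0, 0.4, len(knots))
        res = minimize(nll, x0, method="L-BFGS-B",
                       bounds=[(0.5, 8.0)] * len(knots))
        if best is None or res.fun < best.fun:
            best = res
    return best.x, -best.fun


def fit_recent_ne(spectrum: IBDSpectrum, config: RecentNeConfig = RecentNeConfig()
                  ) -> RecentNeTrajectory:
    """Recent-Ne trajectory from the binned IBD length spectrum."""
    if spectrum.counts.sum() <= 0:
        raise ValueError("empty IBD spectrum")
    knots = config.knot_vector()
    rng = np.random.default_rng(config.seed)
    edges = spectrum.bin_edges_cM
    min_cM = float(edges[0])
    np_pairs = spectrum.n_haplotype_pairs
    gm = spectrum.genome_morgans

    # smoothing weight by two-fold chromosome split (when per-chromosome
    # counts are available and more than one chromosome exists)
    lam_s = config.lambda_grid[len(config.lambda_grid) // 2]
    chroms = sorted(spectrum.chromosome_counts)
    if len(chroms) >= 2 and len(config.lambda_grid) > 1:
        half_a = chroms[::2]
        half_b = chroms[1::2]
        ca = np.sum([spectrum.chromosome_counts[c] for c in half_a], axis=0)
        cb = np.sum([spectrum.chromosome_counts[c] for c in half_b], axis=0)
        fa = len(half_a) / len(chroms)
        best_score = -np.inf
        for lam in config.lambda_grid:
            xa, _ = _fit_knots(ca, np_pairs, gm * fa, edges, min_cM, knots,
                               lam, rng, 1, config.g_max)
            xb, _ = _fit_knots(cb, np_pairs, gm * (1 - fa), edges, min_cM,
                               knots, lam, rng, 1, config.g_max)
            g_axis = np.arange(1, config.g_max + 1, dtype=float)
            la = expected_ibd_spectrum(10 ** _interp_log_ne(knots, xa, g_axis),
                                       np_pairs, gm * (1 - fa), edges, min_cM)
            lb = expected_ibd_spectrum(10 ** _interp_log_ne(knots, xb, g_axis),
                                       np_pairs, gm * fa, edges, min_cM)
            score = _poisson_ll(cb, la) + _poisson_ll(ca, lb)
            if score > best_score:
                best_score, lam_s = score, lam

    x, ll = _fit_knots(spectrum.counts, np_pairs, gm, edges, min_cM, knots,
                       lam_s, rng, config.n_restarts, config.g_max)
    gens = np.arange(config.g_min, config.g_max + 1, dtype=float)
    ne_fit = 10.0 ** _interp_log_ne(knots, x, gens)

    envelope = None
    if config.n_boot > 0 and len(chroms) >= 2:
        boots = [ne_fit]
        for _ in range(config.n_boot):
            pick = rng.choice(chroms, size=len(chroms), replace=True)
            cb = np.sum([spectrum.chromosome_counts[c] for c in pick], axis=0)
            xb, _ = _fit_knots(cb, np_pairs, gm, edges, min_cM, knots, lam_s,
                               rng, 1, config.g_max)
            boots.append(10.0 ** _interp_log_ne(knots, xb, gens))
        arr = np.vstack(boots)
        envelope = pd.DataFrame({
            "generation": gens,
            "q2.5": np.minimum(np.percentile(arr, 2.5, axis=0), ne_fit),
            "q97.5": np.maximum(np.percentile(arr, 97.5, axis=0), ne_fit)})

    return RecentNeTrajectory(generations=gens, ne=ne_fit,
                              log_likelihood=ll, smoothing_lambda=lam_s,
                              envelope=envelope)


def segments_frame(segments: list[IBDSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.sample_a, s.hap_a, s.sample_b, s.hap_b, s.scaffold, s.start,
          s.end, s.cM, s.n_mismatches, s.within_individual)
         for s in segments],
        columns=["sample1", "hap1", "sample2", "hap2", "scaffold", "start",
                 "end", "cM", "n_mismatches", "within_individual"])
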