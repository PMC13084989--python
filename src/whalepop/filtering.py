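"""Post-calling variant filtration ladder with stage-by-stage reporting.

Stages, applied in this order:

1. ``repeat_mask``      -- drop sites inside masked (BED, 0-based half-open)
                           intervals.
2. ``genotype_dp_gq``   -- set individual genotypes missing when DP < 10 or
                           GQ < 30 (site retained; removal count is 0, the
                           per-genotype masked count is reported separately).
3. ``mapping_quality``  -- drop sites with MQ < 30.
4. ``missingness``      -- drop sites missing more than 25% of genotype
                           calls, evaluated after genotype-level masking.
5. ``max_depth``        -- drop sites whose summed depth exceeds
                           multiplier x median summed depth; the median is
                           taken over sites surviving the repeat mask.
6. ``scaffold``         -- drop sites on scaffolds shorter than 1 Mbp or on
                           listed sex scaffolds (autosomes only).

Setting a threshold to ``None`` disables its stage (the stage still appears
in the report with zero removals).  Thresholds are compared as exact floats;
the depth cap is strict (> threshold removes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import GenotypeDataset

__all__ = ["FilterConfig", "FilterReport", "compute_max_depth_threshold",
           "apply_filters", "load_bed_mask"]

STAGE_ORDER = ("repeat_mask", "genotype_dp_gq", "mapping_quality",
               "missingness", "max_depth", "scaffold")


@dataclass(frozen=True)
class FilterConfig:
    min_genotype_dp: float | None = 10
    min_gq: float | None = 30
    max_missing_fraction: float | None = 0.25
    min_mq: float | None = 30
    max_depth_multiplier: float | None = 2.0
    min_scaffold_length_bp: int | None = 1_000_000
    repeat_mask: str | dict | None = None  # BED path or {scaffold: [(s,e)]}
    sex_scaffolds: tuple[str, ...] = ()

    def __post_init__(self):
        for name in ("min_genotype_dp", "min_gq", "min_mq",
                     "max_depth_multiplier", "min_scaffold_length_bp"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")
        f = self.max_missing_fraction
        if f is not None and not (0 <= f <= 1):
            raise ValueError("max_missing_fraction must be in [0, 1]")
        object.__setattr__(self, "sex_scaffolds", tuple(self.sex_scaffolds))


@dataclass
class FilterReport:
    stages: list[tuple[str, int, int, int]] = field(default_factory=list)
    genotypes_masked: int = 0
    max_depth_threshold: float | None = None

    def add(self, name: str, n_in: int, n_out: int):
        if n_out > n_in:
            raise ValueError("stage cannot add sites")
        self.stages.append((name, n_in, n_out, n_in - n_out))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages,
                            columns=["stage", "in", "out", "removed"])

    def site_counts(self) -> list[int]:
        """Site count trajectory: input count then count after each stage."""
        if not self.stages:
            return []
        return [self.stages[0][1]] + [s[2] for s in self.stages]


def compute_max_depth_threshold(site_summed_dp, multiplier: float) -> float:
    """multiplier x median of per-site summed depth.

    The median of an even-length sequence is the mean of the two central
    order statistics.
    """
    arr = np.asarray(site_summed_dp, dtype=float)
    if arr.size == 0:
        raise ValueError("site_summed_dp must be nonempty")
    return float(multiplier) * float(np.median(arr))


def load_bed_mask(bed) -> dict[str, list[tuple[int, int]]]:
    """Read a BED file (0-based half-open) into per-scaffold interval lists."""
    if isinstance(bed, dict):
        return {str(k): [(int(a), int(b)) for a, b in v] for k, v in bed.items()}
    try:
        df = pd.read_csv(bed, sep="\t", header=None, comment="#",
                         usecols=[0, 1, 2], names=["chrom", "start", "end"])
    except Exception as exc:
        raise ValueError(f"malformed BED file {bed!r}: {exc}") from exc
    if df.empty:
        return {}
    if (df["end"] < df["start"]).any():
        raise ValueError(f"malformed BED file {bed!r}: end < start")
    out: dict[str, list[tuple[int, int]]] = {}
    for chrom, grp in df.groupby("chrom"):
        out[str(chrom)] = list(zip(grp["start"].astype(int),
                                   grp["end"].astype(int)))
    return out


def _mask_hits(dataset, intervals):
    from intervaltree import IntervalTree

    trees = {}
    for chrom, ivs in intervals.items():
        t = IntervalTree()
        for s, e in ivs:
            if e > s:
                t.addi(s, e)
        trees[chrom] = t
    hit = np.zeros(dataset.n_sites, dtype=bool)
    for s in range(dataset.n_sites):
        tree = trees.get(dataset.scaffold_ids[dataset.site_scaffold[s]])
        if tree is not None and tree.overlaps_point(int(dataset.positions[s]) - 1):
            hit[s] = True
    return hit


def apply_filters(dataset: GenotypeDataset, config: FilterConfig,
                  scaffold_lengths: dict[str, int] | None = None
                  ) -> tuple[GenotypeDataset, FilterReport]:
    """Run the filtering ladder; returns the filtered dataset and report."""
    report = FilterReport()
    ds = dataset

    # 1. repeat mask ----------------------------------------------------
    n_in = ds.n_sites
    if config.repeat_mask is not None:
        hit = _mask_hits(ds, load_bed_mask(config.repeat_mask))
        ds = ds.subset_sites(~hit)
    report.add("repeat_mask", n_in, ds.n_sites)

    # summed depth for the max-depth cap is computed after repeat masking,
    # before genotype-level masking (raw INFO/DP semantics)
    site_dp_sum = ds.dp.sum(axis=1) if ds.n_sites else np.empty(0)

    # 2. genotype-level DP/GQ masking ----------------------------------
    n_in = ds.n_sites
    if (config.min_genotype_dp is not None or config.min_gq is not None) \
            and ds.n_sites:
        if config.min_genotype_dp is not None and ds.dp.size == 0:
            raise ValueError("DP annotation required for the genotype depth filter")
        if config.min_gq is not None and ds.gq.size == 0:
            raise ValueError("GQ annotation required for the genotype quality filter")
        bad = np.zeros((ds.n_sites, ds.n_samples), dtype=bool)
        if config.min_genotype_dp is not None:
            bad |= ds.dp < config.min_genotype_dp
        if config.min_gq is not None:
            bad |= ds.gq < config.min_gq
        already = (ds.haplotypes[:, 0::2] < 0) & (ds.haplotypes[:, 1::2] < 0)
        report.genotypes_masked = int((bad & ~already).sum())
        haps = ds.haplotypes.copy()
        haps[:, 0::2][bad] = -1
        haps[:, 1::2][bad] = -1
        import dataclasses as _dc

        ds = _dc.replace(ds, haplotypes=haps)
    report.add("genotype_dp_gq", n_in, ds.n_sites)

    # 3. mapping quality ------------------------------------------------
    n_in = ds.n_sites
    if config.min_mq is not None and ds.n_sites:
        if np.all(np.isnan(ds.mq)):
            raise ValueError("MQ annotation required for the mapping-quality filter")
        keep = ~(ds.mq < config.min_mq)  # NaN MQ passes
        site_dp_sum = site_dp_sum[keep]
        ds = ds.subset_sites(keep)
    report.add("mapping_quality", n_in, ds.n_sites)

    # 4. missingness (after genotype masking) ---------------------------
    n_in = ds.n_sites
    if config.max_missing_fraction is not None and ds.n_sites:
        g = ds.genotypes()
        frac = (g < 0).mean(axis=1)
        keep = frac <= config.max_missing_fraction
        site_dp_sum = site_dp_sum[keep]
        ds = ds.subset_sites(keep)
    report.add("missingness", n_in, ds.n_sites)

    # 5. maximum summed depth ------------------------------------------
    n_in = ds.n_sites
    if config.max_depth_multiplier is not None and ds.n_sites:
        # threshold from the post-mask site set (computed above)
        thresh = compute_max_depth_threshold(
            _post_mask_dp(dataset, config), config.max_depth_multiplier)
        report.max_depth_threshold = thresh
        keep = ~(site_dp_sum > thresh)
        ds = ds.subset_sites(keep)
    report.add("max_depth", n_in, ds.n_sites)

    # 6. scaffold length / sex scaffolds --------------------------------
    n_in = ds.n_sites
    lengths = scaffold_lengths or dict(zip(ds.scaffold_ids,
                                           (int(x) for x in ds.scaffold_lengths)))
    drop_scaffs = set(config.sex_scaffolds)
    if config.min_scaffold_length_bp is not None:
        for sc in ds.scaffold_ids:
            if lengths.get(sc, 0) < config.min_scaffold_length_bp:
                drop_scaffs.add(sc)
    if drop_scaffs and ds.n_sites:
        keep = np.array([ds.scaffold_ids[i] not in drop_scaffs
                         for i in ds.site_scaffold])
        ds = ds.subset_sites(keep)
    report.add("scaffold", n_in, ds.n_sites)
    return ds, report


def _post_mask_dp(dataset, config):
    """Per-site summed DP over the sites surviving the repeat mask."""
    if config.repeat_mask is None:
        return dataset.dp.sum(axis=1)
    hit = _mask_hits(dataset, load_bed_mask(config.repeat_mask))
    return dataset.dp[~hit].sum(axis=1)
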