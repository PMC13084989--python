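"""IBD detection, the segment length-spectrum model and its WF oracle."""

import numpy as np
import pytest

from whalepop.ibd import (IBDSpectrum, RecentNeConfig, detect_ibd,
                          expected_ibd_spectrum, fit_recent_ne, ibd_spectrum)
from whalepop.simulate import DemographicModel, SimulationConfig, \
    simulate_dataset

from conftest import make_dataset


class TestDetectIbd:
    def test_duplicate_haplotypes_full_chromosome(self):
        h = np.zeros((50, 4), dtype=np.int8)
        h[:, 0] = h[:, 2] = np.arange(50) % 2  # haplotypes 0 and 2 identical
        rng = np.random.default_rng(1)
        h[:, 1] = rng.integers(0, 2, 50)
        h[:, 3] = 1 - h[:, 1]
        pos = np.linspace(1, 99_999_999, 50).astype(np.int64)
        ds = make_dataset(h, positions=pos, scaffold_lengths=[100_000_000])
        segs = detect_ibd(ds, min_cM=2.0)
        full = [s for s in segs
                if {(s.sample_a, s.hap_a), (s.sample_b, s.hap_b)}
                == {("s0", 0), ("s1", 0)}]
        assert len(full) == 1
        assert full[0].cM == pytest.approx(100.0, rel=0.01)

    def test_everywhere_different_no_segments(self):
        h = np.zeros((30, 4), dtype=np.int8)
        h[:, 0] = 0
        h[:, 2] = 1
        pos = np.linspace(1, 9_999_999, 30).astype(np.int64)
        ds = make_dataset(h, positions=pos, scaffold_lengths=[10_000_000])
        segs = [s for s in detect_ibd(ds, min_cM=2.0)
                if (s.sample_a, s.hap_a) == ("s0", 0)
                and (s.sample_b, s.hap_b) == ("s1", 0)]
        # every inter-marker gap is < 2 cM except none: 30 mismatches over
        # 10 Mb leave max clean gaps ~0.33 Mb = 0.33 cM < 2 cM
        assert segs == []

    def test_unphased_rejected(self):
        ds = make_dataset(np.zeros((2, 4), dtype=np.int8), phased=False)
        with pytest.raises(ValueError, match="phased"):
            detect_ibd(ds)

    def test_within_individual_flagged_as_roh(self):
        h = np.zeros((20, 2), dtype=np.int8)  # one sample, both haps ref
        pos = np.linspace(1, 49_999_999, 20).astype(np.int64)
        ds = make_dataset(h, positions=pos, scaffold_lengths=[50_000_000])
        segs = detect_ibd(ds, min_cM=2.0)
        assert len(segs) == 1 and segs[0].within_individual

    def test_truth_tract_recovery(self, linked_bottleneck_dataset):
        """Detected segments cover >= 95% of true recent-IBD length with
        <= 5% spurious length (1 mismatch/cM tolerance for mutations)."""
        ds = linked_bottleneck_dataset
        truth = ds.truth["ibd_tracts"]
        truth = truth[(truth.end - truth.start) >= 2e6]
        segs = detect_ibd(ds, min_cM=2.0, max_mismatches_per_cM=1.0)
        det = {}
        for s in segs:
            a = 2 * ds.sample_ids.index(s.sample_a) + s.hap_a
            b = 2 * ds.sample_ids.index(s.sample_b) + s.hap_b
            det.setdefault((min(a, b), max(a, b), s.scaffold),
                           []).append((s.start, s.end))
        covered = total = 0
        for r in truth.itertuples():
            key = (min(r.hap_a, r.hap_b), max(r.hap_a, r.hap_b),
                   f"chr{r.scaffold + 1:02d}")
            total += r.end - r.start
            iv = _union(det.get(key, []))
            covered += sum(max(0, min(e, r.end) - max(s, r.start))
                           for s, e in iv)
        assert total > 0
        assert covered / total >= 0.95

    def test_symmetric_and_relabel_invariant(self):
        rng = np.random.default_rng(9)
        h = rng.integers(0, 2, size=(200, 4)).astype(np.int8)
        h[50:150, 2] = h[50:150, 0]  # shared middle tract
        pos = np.linspace(1, 19_999_999, 200).astype(np.int64)
        ds = make_dataset(h, positions=pos, scaffold_lengths=[20_000_000])
        segs1 = {(s.start, s.end) for s in detect_ibd(ds, min_cM=2.0)
                 if not s.within_individual}
        ds_flip = make_dataset(1 - h, positions=pos,
                               scaffold_lengths=[20_000_000])
        segs2 = {(s.start, s.end) for s in detect_ibd(ds_flip, min_cM=2.0)
                 if not s.within_individual}
        assert segs1 == segs2


def _union(intervals):
    out = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


class TestExpectedSpectrum:
    BINS = (2.0, 4.0, 8.0)

    def test_huge_n_no_recent_segments(self):
        ne = np.full(200, 1e8)
        c = expected_ibd_spectrum(ne, 1, 30.0, self.BINS,
                                  tail_generations=200)
        assert c.sum() < 1e-3

    def test_bin_partition_consistency(self):
        ne = np.full(200, 800.0)
        fine = expected_ibd_spectrum(ne, 153, 30.0,
                                     (2, 3, 4, 5, 6, 8, 10, 14),
                                     tail_generations=1000)
        coarse = expected_ibd_spectrum(ne, 153, 30.0, (2.0,),
                                       tail_generations=1000)
        assert fine.sum() == pytest.approx(coarse.sum(), rel=1e-12)

    def test_total_count_monotone_in_every_ne(self):
        """Raising Ne at any single generation lowers the total expected
        count above threshold (fewer coalescences => fewer long segments).
        Individual bins are not monotone: mass shifted to older ancestors
        re-enters the shortest bin, so only the total is tested."""
        base = np.full(60, 500.0)
        c0 = expected_ibd_spectrum(base, 10, 30.0, (2.0,),
                                   tail_generations=60).sum()
        for g in (0, 10, 40):
            up = base.copy()
            up[g] *= 3
            c1 = expected_ibd_spectrum(up, 10, 30.0, (2.0,),
                                       tail_generations=60).sum()
            assert c1 <= c0 + 1e-12

    def test_bins_below_threshold_rejected(self):
        with pytest.raises(ValueError):
            expected_ibd_spectrum(np.full(10, 100.0), 1, 1.0, (1.0, 2.0),
                                  min_cM=2.0)

    def test_matches_coalescent_simulation(self):
        """Mean per-pair counts from coalescent-with-recombination ancestry
        simulation within 3 SE of the 2g-rate exponential model, constant
        N = 500, 30 Morgans.  (The discrete-WF comparison at full scale
        lives in the acceptance suite; finite-N WF corrections of a few
        percent affect the shortest bin there.)"""
        import msprime

        n_rep = 60
        g_max = 200
        L = 3_000_000_000  # 30 Morgans at 1e-8/bp
        counts = np.zeros((n_rep, len(self.BINS)))
        for rep in range(n_rep):
            ts = msprime.sim_ancestry(
                samples=1, population_size=500,
                sequence_length=L, recombination_rate=1e-8,
                random_seed=1000 + rep, end_time=g_max + 1)
            res = ts.ibd_segments(max_time=g_max, min_span=2_000_000,
                                  store_pairs=True, store_segments=True)
            lengths = []
            for pair in res.pairs:
                seg = res[pair]
                lengths.extend((np.array(seg.right) - np.array(seg.left))
                               / 1e6)  # bp -> cM at 1 cM/Mb
            if lengths:
                idx = np.clip(np.digitize(lengths, self.BINS) - 1, 0,
                              len(self.BINS) - 1)
                np.add.at(counts[rep], idx, 1)
        expect = expected_ibd_spectrum(np.full(g_max, 500.0), 1, 30.0,
                                       self.BINS, tail_generations=g_max)
        mean = counts.mean(axis=0)
        se = counts.std(axis=0, ddof=1) / np.sqrt(n_rep)
        assert np.all(np.abs(mean - expect) < 3 * se + 1e-9)


class TestFitRecentNe:
    def _spectrum(self, ne_val=1000.0, seed=0, n_pairs=153, gm=30.0):
        rng = np.random.default_rng(seed)
        lam_chrom = []
        edges = (2, 3, 4, 6, 8, 12, 16, 24)
        expect = expected_ibd_spectrum(np.full(200, ne_val), n_pairs,
                                       gm / 20, edges)
        chrom = {f"c{i}": rng.poisson(expect) for i in range(20)}
        counts = np.sum(list(chrom.values()), axis=0)
        return IBDSpectrum(bin_edges_cM=np.array(edges, dtype=float),
                           counts=counts, n_haplotype_pairs=n_pairs,
                           genome_morgans=gm, chromosome_counts=chrom)

    CFG = RecentNeConfig(knots=(4, 8, 16, 32, 64, 128, 200), n_boot=0,
                         n_restarts=2, lambda_grid=(0.03,))

    def test_empty_spectrum_rejected(self):
        s = IBDSpectrum(bin_edges_cM=np.array([2.0]), counts=np.array([0.0]),
                        n_haplotype_pairs=1, genome_morgans=1.0)
        with pytest.raises(ValueError):
            fit_recent_ne(s, self.CFG)

    def test_constant_n_recovery_from_model_draws(self):
        s = self._spectrum(ne_val=1000.0, seed=3)
        traj = fit_recent_ne(s, self.CFG)
        mid = [(g, traj.ne_at(g)) for g in (10, 20, 50, 100)]
        for g, v in mid:
            assert abs(v / 1000.0 - 1) < 0.3, (g, v)

    def test_count_scaling_invariance(self):
        """Doubling counts with doubled pairs leaves the argmax unchanged."""
        s = self._spectrum(ne_val=800.0, seed=5)
        t1 = fit_recent_ne(s, self.CFG)
        s2 = IBDSpectrum(bin_edges_cM=s.bin_edges_cM, counts=2 * s.counts,
                         n_haplotype_pairs=2 * s.n_haplotype_pairs,
                         genome_morgans=s.genome_morgans,
                         chromosome_counts={k: 2 * v for k, v in
                                            s.chromosome_counts.items()})
        t2 = fit_recent_ne(s2, self.CFG)
        assert np.allclose(t1.ne, t2.ne, rtol=0.05)

    def test_deterministic_given_seed(self):
        s = self._spectrum(seed=7)
        t1 = fit_recent_ne(s, self.CFG)
        t2 = fit_recent_ne(s, self.CFG)
        assert np.array_equal(t1.ne, t2.ne)
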