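"""Simulator correctness: coalescent expectations, pedigree truth, VCF I/O."""

import numpy as np
import pytest

from whalepop import vcfio
from whalepop.simulate import (DemographicModel, SimulationConfig,
                               overlay_pedigree, simulate_dataset,
                               simulate_coalescent_durations, truth_kinship,
                               truth_autozygosity)
from whalepop.structure import weighted_fst


class TestModelValidation:
    def test_epoch_times_must_increase(self):
        with pytest.raises(ValueError):
            DemographicModel(populations=(((0.0, 100.0), (0.0, 200.0)),))

    def test_first_epoch_starts_at_zero(self):
        with pytest.raises(ValueError):
            DemographicModel(populations=(((10.0, 100.0),),))

    def test_ne_below_one_rejected(self):
        with pytest.raises(ValueError):
            DemographicModel.constant(0.5)

    def test_pop1_epoch_after_split_rejected(self):
        with pytest.raises(ValueError):
            DemographicModel(
                populations=(((0.0, 1000.0),),
                             ((0.0, 1000.0), (5000.0, 2000.0))),
                split_time_generations=100.0)


class TestCoalescentExpectations:
    def test_mean_pairwise_tmrca_constant_n(self):
        """Sample-of-two loci coalesce on average at 2N generations."""
        model = DemographicModel.constant(5000.0)
        cfg = SimulationConfig(n_diploids=(1,), n_independent_loci=2000,
                               seed=7)
        ds = simulate_dataset(model, cfg)
        t = ds.truth["tmrca"]
        se = t.std(ddof=1) / np.sqrt(len(t))
        assert abs(t.mean() - 10_000) < 3 * se

    def test_sfs_proportional_to_inverse_frequency(self):
        """Neutral constant-N spectrum: E[xi_i] = theta/i."""
        model = DemographicModel.constant(5000.0)
        cfg = SimulationConfig(n_diploids=(9,), n_independent_loci=2000,
                               seed=13)
        ds = simulate_dataset(model, cfg)
        n = 18
        counts = (ds.haplotypes > 0).sum(axis=1)
        xi = np.bincount(counts, minlength=n + 1)[1:n]
        theta_sites = (4 * 5000 * model.mutation_rate
                       * cfg.locus_length_bp * cfg.n_independent_loci)
        expect = theta_sites / np.arange(1, n)
        # Poisson counts: compare each class within ~4 sigma
        z = (xi - expect) / np.sqrt(expect)
        assert np.all(np.abs(z) < 4.5)

    def test_watterson_segregating_sites(self):
        """Mean S per locus matches theta * a_n at constant size."""
        model = DemographicModel.constant(2000.0)
        cfg = SimulationConfig(n_diploids=(5,), n_independent_loci=1500,
                               seed=5)
        ds = simulate_dataset(model, cfg)
        s_per_locus = np.bincount(ds.site_scaffold,
                                  minlength=cfg.n_independent_loci)
        theta = 4 * 2000 * model.mutation_rate * cfg.locus_length_bp
        a_n = np.sum(1.0 / np.arange(1, 10))
        se = s_per_locus.std(ddof=1) / np.sqrt(len(s_per_locus))
        assert abs(s_per_locus.mean() - theta * a_n) < 3 * se

    def test_split_increases_fst_over_panmixia(self):
        """Deep split yields larger WC F_ST than one panmictic population."""
        cfg_kw = dict(n_independent_loci=400, seed=21)
        split = DemographicModel(
            populations=(((0.0, 2000.0),), ((0.0, 2000.0),)),
            split_time_generations=20_000.0)
        ds_split = simulate_dataset(
            split, SimulationConfig(n_diploids=(5, 5), **cfg_kw))
        pan = DemographicModel.constant(2000.0)
        ds_pan = simulate_dataset(
            pan, SimulationConfig(n_diploids=(10,), **cfg_kw))
        labels = ["a"] * 5 + ["b"] * 5
        fst_split, _ = weighted_fst(ds_split.genotypes(), labels)
        fst_pan, _ = weighted_fst(ds_pan.genotypes(), labels)
        assert fst_split > fst_pan
        assert fst_split > 0.5  # deep split: near-complete sorting

    def test_mc_durations_match_constant_n_theory(self):
        """E[T_k] = 2N / C(k,2) from the vectorized Monte-Carlo."""
        rng = np.random.default_rng(3)
        out = simulate_coalescent_durations(((0.0, 1000.0),), 6, 20_000, rng)
        ks = np.arange(6, 1, -1)
        expect = 2 * 1000.0 / (ks * (ks - 1) / 2.0)
        se = out.std(axis=0, ddof=1) / np.sqrt(out.shape[0])
        assert np.all(np.abs(out.mean(axis=0) - expect) < 3.5 * se)


class TestDeterminism:
    def test_fixed_seed_byte_identical_vcf(self, tmp_path):
        model = DemographicModel.constant(800.0)
        cfg = SimulationConfig(n_diploids=(3,), n_independent_loci=40, seed=9)
        p1, p2 = tmp_path / "a.vcf", tmp_path / "b.vcf"
        vcfio.write_vcf(simulate_dataset(model, cfg), str(p1))
        vcfio.write_vcf(simulate_dataset(model, cfg), str(p2))
        assert p1.read_bytes() == p2.read_bytes()

    def test_linked_mode_deterministic(self):
        model = DemographicModel.constant(500.0)
        cfg = SimulationConfig(n_diploids=(3,), mode="linked",
                               n_chromosomes=1,
                               chromosome_length_bp=1_000_000, seed=17)
        a = simulate_dataset(model, cfg)
        b = simulate_dataset(model, cfg)
        assert np.array_equal(a.haplotypes, b.haplotypes)
        assert np.array_equal(a.positions, b.positions)


class TestPedigreeOverlay:
    def test_duplicate_is_identical(self, small_dataset):
        ds = overlay_pedigree(small_dataset, "duplicate", parents=(2, 0),
                              seed=1)
        n = small_dataset.n_samples
        assert np.array_equal(ds.haplotypes[:, [2 * n, 2 * n + 1]],
                              ds.haplotypes[:, [4, 5]])
        assert truth_kinship(ds, 2, n) == pytest.approx(0.5)

    def test_offspring_shares_an_allele_everywhere(self, small_dataset):
        ds = overlay_pedigree(small_dataset, "parent_offspring",
                              parents=(0, 1), seed=3)
        child = ds.n_samples - 1
        hp = ds.haplotypes[:, [0, 1]]
        hc = ds.haplotypes[:, [2 * child, 2 * child + 1]]
        # the transmitted haplotype equals one parental allele at every site
        share = ((hc[:, 0:1] == hp).any(axis=1)
                 | (hc[:, 1:2] == hp).any(axis=1))
        assert share.all()
        assert truth_kinship(ds, 0, child) == pytest.approx(0.25)

    def test_full_sib_sharing_near_half(self):
        """Realized sib IBD sharing ~ 1/2 over 20 x 100 cM chromosomes."""
        model = DemographicModel.constant(100.0)
        base = simulate_dataset(model, SimulationConfig(
            n_diploids=(2,), mode="linked", n_chromosomes=20,
            chromosome_length_bp=100_000_000, seed=23))
        fracs = []
        for rep in range(30):
            ds = overlay_pedigree(base, "full_sib", parents=(0, 1), seed=rep)
            i, j = ds.n_samples - 2, ds.n_samples - 1
            fracs.append(2.0 * truth_kinship(ds, i, j))
        fracs = np.array(fracs)
        se = fracs.std(ddof=1) / np.sqrt(len(fracs))
        assert abs(fracs.mean() - 0.5) < 3 * se

    def test_selfed_duplicate_haplotypes_fully_autozygous(self, small_dataset):
        ds = overlay_pedigree(small_dataset, "duplicate", parents=(1, 0),
                              seed=2)
        dup = ds.n_samples - 1
        # offspring of sample x duplicate built from the same haplotype pair
        assert truth_autozygosity(ds, dup) == truth_autozygosity(ds, 1)
        hap_pair_same = np.array_equal(ds.haplotypes[:, 2 * dup],
                                       ds.haplotypes[:, 2])
        assert hap_pair_same


class TestVcfRoundTrip:
    def test_round_trip_restores_genotypes(self, small_dataset, tmp_path):
        path = str(tmp_path / "rt.vcf")
        vcfio.write_vcf(small_dataset, path)
        back = vcfio.read_vcf(path)
        assert np.array_equal(back.haplotypes, small_dataset.haplotypes)
        assert np.array_equal(back.dp, small_dataset.dp)
        assert np.array_equal(back.gq, small_dataset.gq)
        assert np.array_equal(back.ancestral, small_dataset.ancestral)
        assert back.sample_ids == small_dataset.sample_ids

    def test_depth_model_mean(self, small_dataset, tmp_path):
        path = str(tmp_path / "dp.vcf")
        vcfio.write_vcf(small_dataset, path, depth_model=(40.0, 8.0), seed=2)
        back = vcfio.read_vcf(path)
        dp = back.dp.astype(float).ravel()
        se = dp.std(ddof=1) / np.sqrt(len(dp))
        assert abs(dp.mean() - 40.0) < 3 * se

    def test_empty_dataset_header_only(self, tmp_path):
        model = DemographicModel.constant(1.0)  # tiny N: often monomorphic
        cfg = SimulationConfig(n_diploids=(2,), n_independent_loci=1,
                               locus_length_bp=10, seed=1)
        ds = simulate_dataset(model, cfg)
        ds = ds.subset_sites(np.zeros(ds.n_sites, dtype=bool))
        path = str(tmp_path / "empty.vcf")
        vcfio.write_vcf(ds, path)
        body = [l for l in open(path) if not l.startswith("#")]
        assert body == []
        back = vcfio.read_vcf(path)
        assert back.n_sites == 0
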