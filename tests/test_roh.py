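"""ROH detection (three methods), F_ROH summaries and TMRCA dating."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from whalepop.roh import (DEFAULT_EPSILON, DEFAULT_TAU, ROHSegment,
                          detect_roh, detect_roh_dataset, froh, roh_age)
from whalepop.simulate import (DemographicModel, SimulationConfig,
                               overlay_pedigree, simulate_dataset,
                               truth_autozygosity)


class TestRohAge:
    def test_worked_examples(self):
        """Median-ROH dating at 1 cM/Mb and 32 y/generation."""
        gen, yrs = roh_age(105_976)
        assert round(gen) == 472
        assert gen == pytest.approx(471.8, abs=0.05)
        assert yrs == pytest.approx(15_100, rel=0.01)

        gen, yrs = roh_age(36_883)
        assert int(gen) == 1355
        assert 1355 * 32 == 43_360

        assert roh_age(4_000_000)[0] == pytest.approx(12.5)
        assert roh_age(2_000_000)[0] == pytest.approx(25.0)
        assert roh_age(2_000_000)[1] == pytest.approx(800.0)

    @settings(max_examples=50, deadline=None)
    @given(st.floats(1e3, 1e7), st.floats(0.2, 5.0), st.floats(1.1, 10.0))
    def test_only_product_matters_and_monotonicity(self, length, rate, c):
        g1, _ = roh_age(length, rate)
        g2, _ = roh_age(length * c, rate / c)
        assert g1 == pytest.approx(g2, rel=1e-9)
        assert roh_age(length * c, rate)[0] < g1
        assert roh_age(length, rate * c)[0] < g1

    def test_nonpositive_inputs_rejected(self):
        for bad in [(0, 1.0), (1000, 0.0), (-5, 1.0)]:
            with pytest.raises(ValueError):
                roh_age(*bad)


def _dp_oracle(het, pos, p_het_pop, epsilon, tau, max_switches=4):
    """Best path probability over all state paths with <= max_switches.

    Dynamic program over (site, state, switches); exact restriction of the
    full 2^m enumeration.
    """
    m = len(het)
    p = np.clip(p_het_pop, 1e-12, 1 - 1e-12)
    log_e = np.empty((m, 2))
    log_e[:, 0] = np.where(het, np.log(p), np.log1p(-p))
    e_roh = np.log(epsilon) if epsilon > 0 else -1e30
    log_e[:, 1] = np.where(het, e_roh, np.log1p(-epsilon))
    best = np.full((2, max_switches + 1), -np.inf)
    best[0, 0] = np.log(0.5) + log_e[0, 0]
    best[1, 0] = np.log(0.5) + log_e[0, 1]
    for s in range(1, m):
        d = float(pos[s] - pos[s - 1])
        t = min(max(-np.expm1(-d * tau), 1e-300), 0.5)
        lt = np.log([[1 - t, t], [t, 1 - t]])
        nxt = np.full_like(best, -np.inf)
        for j in (0, 1):
            for k in range(max_switches + 1):
                stay = best[j, k] + lt[j, j]
                sw = best[1 - j, k - 1] + lt[1 - j, j] if k > 0 else -np.inf
                nxt[j, k] = max(stay, sw) + log_e[s, j]
        best = nxt
    return best.max()


class TestDetectRoh:
    def _p(self, n):
        return np.full(n, 0.3)

    def test_all_homozygous_single_segment_all_methods(self):
        pos = np.linspace(1, 5_000_000, 20).astype(np.int64)
        g = np.zeros(20, dtype=np.int8)
        for method in ("hmm", "strict_hmm", "rule"):
            segs = detect_roh(g, pos, self._p(20), method=method)
            assert len(segs) == 1
            assert segs[0].start == int(pos[0]) - 1
            assert segs[0].end >= int(pos[-1]) - 1

    def test_alternating_hets_strict_returns_nothing(self):
        pos = (np.arange(40) * 1000 + 1).astype(np.int64)
        g = np.tile([0, 1], 20).astype(np.int8)
        segs = detect_roh(g, pos, self._p(40), method="strict_hmm",
                          min_length_bp=10_000)
        assert segs == []

    def test_viterbi_matches_restricted_dp_oracle(self):
        """30-site toy with two het islands: Viterbi path optimum equals the
        exhaustive <=4-switch dynamic program."""
        rng = np.random.default_rng(0)
        g = np.zeros(30, dtype=np.int8)
        g[8:11] = 1
        g[20:22] = 1
        pos = np.cumsum(rng.integers(500, 5000, size=30)).astype(np.int64)
        p = self._p(30)
        from whalepop.roh import _viterbi

        path, _ = _viterbi(g == 1, pos, 2 * p * (1 - p), DEFAULT_EPSILON,
                           DEFAULT_TAU)
        # score the Viterbi path and compare to the oracle optimum
        def score(path):
            total = np.log(0.5)
            pr = np.clip(2 * p * (1 - p), 1e-12, 1 - 1e-12)
            for s in range(30):
                het = g[s] == 1
                if path[s] == 1:
                    total += (np.log(DEFAULT_EPSILON) if het
                              else np.log1p(-DEFAULT_EPSILON))
                else:
                    total += np.log(pr[s]) if het else np.log1p(-pr[s])
                if s > 0:
                    d = float(pos[s] - pos[s - 1])
                    t = min(max(-np.expm1(-d * DEFAULT_TAU), 1e-300), 0.5)
                    total += np.log(1 - t) if path[s] == path[s - 1] \
                        else np.log(t)
            return total

        oracle = _dp_oracle(g == 1, pos, 2 * p * (1 - p), DEFAULT_EPSILON,
                            DEFAULT_TAU, max_switches=4)
        assert np.count_nonzero(np.diff(path)) <= 4
        assert score(path) == pytest.approx(oracle, abs=1e-9)

    def test_strict_subset_of_hmm(self, linked_bottleneck_dataset):
        """strict_hmm segments lie inside hmm segments (after splitting)."""
        ds = linked_bottleneck_dataset
        loose = detect_roh_dataset(ds, method="hmm")
        strict = detect_roh_dataset(ds, method="strict_hmm")
        loose_iv = {}
        for s in loose:
            loose_iv.setdefault((s.sample, s.scaffold), []).append(
                (s.start, s.end))
        covered = 0
        total = 0
        for s in strict:
            total += s.length_bp
            for a, b in loose_iv.get((s.sample, s.scaffold), []):
                covered += max(0, min(b, s.end) - max(a, s.start))
        assert total > 0
        assert covered >= 0.95 * total

    def test_rule_respects_mismatch_budget(self):
        rng = np.random.default_rng(5)
        g = (rng.random(200) < 0.05).astype(np.int8)
        pos = (np.arange(200) * 500 + 1).astype(np.int64)
        segs = detect_roh(g, pos, self._p(200), method="rule",
                          max_het_mismatches=2, min_length_bp=5000)
        for s in segs:
            assert s.n_het_mismatches <= 2
        # segments must not overlap
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            assert a.end <= b.start

    def test_unsorted_positions_rejected(self):
        with pytest.raises(ValueError):
            detect_roh(np.zeros(3, dtype=np.int8),
                       np.array([100, 50, 200]), self._p(3))


class TestFroh:
    def _seg(self, start, end, sample="s", scaffold="sc"):
        return ROHSegment(sample=sample, scaffold=scaffold, start=start,
                          end=end, method="hmm", n_het_mismatches=0,
                          score=0.0)

    def test_single_megabase_segment(self):
        out = froh([self._seg(0, 1_000_000)], 100_000_000)
        assert out[0].per_class["[1,inf)Mb"] == pytest.approx(0.01)

    def test_no_segments_all_zero(self):
        assert froh([], 1_000_000) == []

    def test_overlaps_merged_before_summing(self):
        segs = [self._seg(0, 2_000_000), self._seg(1_000_000, 3_000_000)]
        out = froh(segs, 10_000_000)
        assert out[0].total_froh == pytest.approx(0.3)

    def test_fully_homozygous_genome_is_one(self):
        out = froh([self._seg(0, 5_000_000)], 5_000_000)
        assert out[0].total_froh == pytest.approx(1.0)

    def test_nonpositive_genome_rejected(self):
        with pytest.raises(ValueError):
            froh([self._seg(0, 10)], 0)

    def test_full_sib_offspring_quarter_autozygous(self):
        """Offspring of full sibs: F ~ 1/4 from simulator truth tracts."""
        model = DemographicModel.constant(100.0)
        base = simulate_dataset(model, SimulationConfig(
            n_diploids=(2,), mode="linked", n_chromosomes=20,
            chromosome_length_bp=100_000_000, seed=29))
        fs = []
        for rep in range(50):
            sibs = overlay_pedigree(base, "full_sib", parents=(0, 1),
                                    seed=1000 + rep)
            i, j = sibs.n_samples - 2, sibs.n_samples - 1
            child = overlay_pedigree(sibs, "parent_offspring",
                                     parents=(i, j), seed=2000 + rep)
            fs.append(truth_autozygosity(child, child.n_samples - 1))
        fs = np.array(fs)
        se = fs.std(ddof=1) / np.sqrt(len(fs))
        assert abs(fs.mean() - 0.25) < 3 * se
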