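import numpy as np
import pytest

from whalepop.simulate import (DemographicModel, SimulationConfig,
                               GenotypeDataset, simulate_dataset)


@pytest.fixture(scope="session")
def constant_model():
    return DemographicModel.constant(5000.0)


@pytest.fixture(scope="session")
def small_dataset(constant_model):
    """300 independent 10 kb loci, 6 diploids, constant N = 5000."""
    cfg = SimulationConfig(n_diploids=(6,), n_independent_loci=300, seed=11)
    return simulate_dataset(constant_model, cfg)


@pytest.fixture(scope="session")
def linked_bottleneck_dataset():
    """Linked chromosomes with a strong recent bottleneck (ROH/IBD-rich)."""
    model = DemographicModel(populations=(((0.0, 50.0), (30.0, 10000.0)),))
    cfg = SimulationConfig(n_diploids=(5,), n_chromosomes=2,
                           chromosome_length_bp=20_000_000, mode="linked",
                           seed=4, track_ibd=True, ibd_max_time=30.0)
    return simulate_dataset(model, cfg)


def make_dataset(haplotypes, positions=None, scaffold_lengths=None,
                 scaffolds=None, phased=True, dp=None, gq=None, mq=None,
                 ancestral=None, populations=None, truth=None):
    """Hand-built dataset from a haplotype matrix (sites x 2N)."""
    h = np.asarray(haplotypes, dtype=np.int8)
    s, two_n = h.shape
    n = two_n // 2
    if positions is None:
        positions = np.arange(1, s + 1) * 100
    positions = np.asarray(positions, dtype=np.int64)
    if scaffolds is None:
        scaffolds = np.zeros(s, dtype=np.int32)
    scaffolds = np.asarray(scaffolds, dtype=np.int32)
    n_scaff = int(scaffolds.max()) + 1 if s else 1
    if scaffold_lengths is None:
        default = int(positions.max()) + 1000 if s else 10_000
        scaffold_lengths = [default] * n_scaff
    return GenotypeDataset(
        scaffold_ids=[f"sc{i}" for i in range(len(scaffold_lengths))],
        scaffold_lengths=np.asarray(scaffold_lengths, dtype=np.int64),
        site_scaffold=scaffolds,
        positions=positions,
        ref=np.full(s, "A"), alt=np.full(s, "T"),
        haplotypes=h,
        dp=(np.full((s, n), 40, dtype=np.int32) if dp is None
            else np.asarray(dp, dtype=np.int32)),
        gq=(np.full((s, n), 90, dtype=np.int32) if gq is None
            else np.asarray(gq, dtype=np.int32)),
        mq=(np.full(s, 60.0) if mq is None else np.asarray(mq, dtype=float)),
        ancestral=(np.zeros(s, dtype=np.int8) if ancestral is None
                   else np.asarray(ancestral, dtype=np.int8)),
        sample_ids=[f"s{i}" for i in range(n)],
        sample_population=(populations or ["pop0"] * n),
        phased=phased,
        truth=truth or {},
    )
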