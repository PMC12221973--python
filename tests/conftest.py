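import numpy as np
import pytest

from chromarch import ContactMatrix, ice_balance
from chromarch.simulate import (
    SimulationConfig, build_expected_matrix, checkerboard_compartments,
    sample_contact_counts,
)


@pytest.fixture(scope="session")
def checkerboard_map():
    """A balanced 400-bin map with planted A/B compartments (f=2)."""
    n, bs = 400, 10_000
    comp = checkerboard_compartments(n, bs, seed=3)
    cfg = SimulationConfig(
        chrom_lengths={"chr1": n * bs}, bin_size=bs, alpha=1.0,
        compartments={"chr1": comp}, compartment_boost=2.0,
        depth=2_000_000, seed=3,
    )
    exp = build_expected_matrix(cfg)["chr1"]
    counts = sample_contact_counts(exp, cfg.depth, 3)
    m = ice_balance(ContactMatrix("chr1", bs, counts))
    return cfg, exp, m


@pytest.fixture(scope="session")
def boundary_map():
    """A balanced 600-bin map with planted insulation boundaries (b=0.4)."""
    n, bs = 600, 5_000
    positions = [80, 150, 230, 310, 400, 480]
    cfg = SimulationConfig(
        chrom_lengths={"chr1": n * bs}, bin_size=bs, alpha=1.0,
        boundaries={"chr1": [p * bs for p in positions]},
        boundary_attenuation=0.4, depth=5_000_000, seed=4,
    )
    exp = build_expected_matrix(cfg)["chr1"]
    counts = sample_contact_counts(exp, cfg.depth, 4)
    m = ice_balance(ContactMatrix("chr1", bs, counts))
    return positions, exp, m


@pytest.fixture(scope="session")
def gene_dataset():
    """Full simulated dataset with genes, enhancers, tracks and loops."""
    from chromarch.simulate import simulate_dataset
    cfg = SimulationConfig(
        chrom_lengths={"chr1": 3_000_000}, bin_size=2_000, alpha=1.0,
        depth=15_000_000, seed=7, n_genes=60, n_enhancers=25, track_bin=200,
    )
    counts, expected, tracks, truth = simulate_dataset(cfg)
    m = ice_balance(ContactMatrix("chr1", cfg.bin_size, counts["chr1"]))
    return cfg, m, tracks, truth
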