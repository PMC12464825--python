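import numpy as np
import pytest

from ladkit.tracks import BinGrid, BinnedTrack, CountTrack


def track_from_array(values, bin_size=20_000, chrom="chr1"):
    """BinnedTrack over a single chromosome from a plain value vector."""
    values = np.asarray(values, dtype=float)
    grid = BinGrid({chrom: len(values) * bin_size}, bin_size)
    return BinnedTrack(grid, {chrom: values})


def counts_from_array(counts, bin_size=20_000, chrom="chr1", role="antibody"):
    counts = np.asarray(counts, dtype=np.int64)
    grid = BinGrid({chrom: len(counts) * bin_size}, bin_size)
    return CountTrack(grid, {chrom: counts}, role=role)


@pytest.fixture
def small_config():
    from ladkit.simulate import SimulationConfig

    return SimulationConfig(
        chrom_sizes={"chr1": 10_000_000, "chr2": 6_000_000},
        bin_size=20_000,
        lad_mean_len=1_000_000,
        ilad_mean_len=1_000_000,
        mu_lad=1.0,
        mu_ilad=-1.0,
        sigma_bin=0.3,
        dam_depth=500_000,
        ab_depth=500_000,
        dispersion=0.05,
        n_replicates=2,
        spike_fraction=0.20,
        spike_chrom_sizes={"spike_chr1": 5_000_000},
        seed=7,
    )
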