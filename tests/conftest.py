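import numpy as np
import pandas as pd
import pytest

from g4stability import simulate_genome
from g4stability.windows import make_windows, window_gc


@pytest.fixture(scope="session")
def small_genome():
    """~0.5 Mb three-chromosome genome plus mtDNA, with planted G4s."""
    return simulate_genome(
        chrom_sizes={"chrI": 150_000, "chrII": 200_000, "chrIII": 120_000},
        mt_size=20_000,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_grid(small_genome):
    windows = make_windows(small_genome.chrom_sizes)
    gc = window_gc(small_genome.sequences, windows)
    return windows, gc


@pytest.fixture(scope="session")
def large_genome():
    """~5.1 Mb nuclear-only genome (~51k windows) for calibration checks."""
    return simulate_genome(
        chrom_sizes={"chr1": 2_600_000, "chr2": 2_500_000},
        mt_size=0,
        seed=10,
    )


@pytest.fixture(scope="session")
def large_grid(large_genome):
    windows = make_windows(large_genome.chrom_sizes)
    gc = window_gc(large_genome.sequences, windows)
    return windows, gc


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
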