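import numpy as np
import pytest

from methclock.io import PatternSet, ReadPattern, TargetRegion


def make_region(n_cpgs: int = 6, region_id: str = "r1", spacing: int = 10) -> TargetRegion:
    positions = tuple(100 + spacing * i for i in range(n_cpgs))
    return TargetRegion(region_id, "chr1", 100, positions[-1] + 2, positions)


def make_patternset(reads, region: TargetRegion | None = None, sample: str = "S1") -> PatternSet:
    """Build a one-sample PatternSet from (first_cpg_index, states) pairs."""
    if region is None:
        n = max(first + len(states) for first, states in reads)
        region = make_region(n)
    ps = PatternSet([region])
    for first, states in reads:
        ps.add(ReadPattern(sample, region.region_id, first, states))
    return ps


def random_instance(rng: np.random.Generator, max_reads: int = 12, max_cpgs: int = 6):
    """A random small read set: region + (offset, states) segments."""
    n_cpgs = int(rng.integers(1, max_cpgs + 1))
    n_reads = int(rng.integers(1, max_reads + 1))
    region = make_region(n_cpgs, spacing=int(rng.integers(2, 25)))
    segments = []
    for _ in range(n_reads):
        length = int(rng.integers(1, n_cpgs + 1))
        first = int(rng.integers(0, n_cpgs - length + 1))
        states = "".join(rng.choice(["M", "U"], size=length))
        segments.append((first, states))
    return region, segments


@pytest.fixture
def region6() -> TargetRegion:
    return make_region(6)


@pytest.fixture(scope="session")
def benchmark_cohort():
    """One stock 44-sample synthetic cohort, shared across tests."""
    from methclock.synthetic import default_benchmark_config, simulate_cohort, with_seed

    cfg = with_seed(default_benchmark_config(), 12345)
    return simulate_cohort(cfg)
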