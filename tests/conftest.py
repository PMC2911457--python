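import numpy as np
import pytest

from cnapower import GroupAssignment, LogRatioMatrix, RegionSet, build_genome


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_genome():
    """Four chromosomes, 120 probes each, 12 bands: fast but non-trivial."""
    return build_genome(n_chrom=4, probes_per_chrom=120, bands_per_arm=6)


@pytest.fixture(scope="session")
def default_genome():
    return build_genome()


@pytest.fixture
def toy_matrix():
    """3 samples x 4 probes on two chromosomes, deliberately out of order."""
    import pandas as pd

    probes = pd.DataFrame(
        {
            "probe_id": ["p1", "p2", "p3", "p4"],
            "chrom": [1, 1, 2, 2],
            "start_bp": [1, 1001, 1, 1001],
            "end_bp": [1000, 2000, 1000, 2000],
        }
    )
    values = np.arange(12, dtype=float).reshape(3, 4) / 10.0
    return LogRatioMatrix(probes, values, ["s1", "s2", "s3"])


def make_region_set(rwlr: np.ndarray, sample_ids=None) -> RegionSet:
    """RegionSet with synthetic non-overlapping single-probe regions."""
    import pandas as pd

    m = rwlr.shape[0]
    regions = pd.DataFrame(
        {
            "chrom": np.ones(m, dtype=int),
            "start_bp": np.arange(m) * 1000 + 1,
            "end_bp": np.arange(m) * 1000 + 1000,
            "n_probes": np.ones(m, dtype=int),
        }
    )
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(rwlr.shape[1])]
    return RegionSet(regions, rwlr, list(sample_ids))


def two_group_assignment(n_a: int, n_b: int) -> GroupAssignment:
    mapping = {f"s{i}": ("A" if i < n_a else "B") for i in range(n_a + n_b)}
    return GroupAssignment(mapping)
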