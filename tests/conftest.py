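import numpy as np
import pytest

from bcef.datamodel import Dataset, StemSegment, TreeRecord


@pytest.fixture
def toy_wv():
    """The hand-worked three-tree instance used throughout: slope 48/21."""
    return np.array([2.0, 3.0, 10.0]), np.array([1.0, 2.0, 4.0])


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def five_segments():
    return [StemSegment(length=2.0, mid_diameter=10.0) for _ in range(5)]


@pytest.fixture
def small_dataset():
    """Six trees of two species with simple masses (kg) and volumes (m³)."""
    recs = []
    for i, (sp, v) in enumerate(
        [("A", 0.5), ("A", 1.0), ("A", 2.0), ("B", 0.8), ("B", 1.5), ("B", 3.0)]
    ):
        recs.append(
            TreeRecord(
                species=sp,
                dbh=10.0 + i,
                height=8.0 + i,
                stem_volume=v,
                w_stem=400.0 * v,
                w_branches=150.0 * v,
                w_foliage=20.0 * v,
                tree_id=f"t{i}",
            )
        )
    return Dataset(recs)
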