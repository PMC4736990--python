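import numpy as np
import pytest

from rguc import AnalysisConfig, MarkerMatrix, RegionPartition
from rguc.io import PopulationAttributes


@pytest.fixture
def tiny_matrix() -> MarkerMatrix:
    """4 individuals, 2 populations, 3 markers — hand-checkable."""
    values = np.array(
        [
            [1, 0, 1],
            [1, 1, 0],
            [0, 1, 0],
            [0, 1, 1],
        ],
        dtype=float,
    )
    return MarkerMatrix(
        values,
        ["a1", "a2", "b1", "b2"],
        ["m1", "m2", "m3"],
        {"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
    )


@pytest.fixture
def fast_config() -> AnalysisConfig:
    return AnalysisConfig(n_permutations=19, n_bootstrap=20, rng_seed=1)


def random_matrix(
    rng: np.random.Generator,
    n_pops: int = 3,
    n_per_pop: int = 4,
    n_markers: int = 12,
) -> MarkerMatrix:
    pops = [f"p{i}" for i in range(n_pops)]
    values = (rng.random((n_pops * n_per_pop, n_markers)) < rng.uniform(0.1, 0.9, n_markers)).astype(float)
    ids = [f"{p}_{j}" for p in pops for j in range(n_per_pop)]
    mapping = {f"{p}_{j}": p for p in pops for j in range(n_per_pop)}
    return MarkerMatrix(values, ids, [f"m{j}" for j in range(n_markers)], mapping)


@pytest.fixture
def three_pop_matrix() -> MarkerMatrix:
    return random_matrix(np.random.default_rng(42))


@pytest.fixture
def three_region_partition() -> RegionPartition:
    return RegionPartition({"p0": "R1", "p1": "R2", "p2": "R3"})


def make_attributes(pops, **overrides) -> dict:
    base = dict(
        occupation_area="large",
        population_size="high",
        vulnerability="stable",
        legal_status="protected",
    )
    out = {}
    for p in pops:
        kw = dict(base)
        kw.update(overrides.get(p, {}))
        out[p] = PopulationAttributes(**kw)
    return out
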