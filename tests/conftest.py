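import pytest

import acimpute as ac


@pytest.fixture(scope="session")
def small_dataset() -> ac.SyntheticDataset:
    return ac.make_dataset(genes=300, cells=80, clusters=3, seed=11)


@pytest.fixture(scope="session")
def small_result(small_dataset) -> ac.PipelineResult:
    return ac.run_pipeline(small_dataset.observed, ac.ImputeConfig(seed=11))


@pytest.fixture(scope="session")
def desk_dataset() -> ac.SyntheticDataset:
    """Desk-scale benchmark: 1500 genes x 300 cells x 3 clusters, ~60% zeros."""
    return ac.make_dataset(seed=2026)


@pytest.fixture(scope="session")
def desk_result(desk_dataset) -> ac.PipelineResult:
    return ac.run_pipeline(desk_dataset.observed, ac.ImputeConfig(seed=2026))
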