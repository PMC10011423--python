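import pytest

from ctdeconv import SimConfig, lognormalize, simulate_single_cell


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(
        seed=7, n_genes=600, n_cell_types=5, n_markers_per_type=20,
        n_donors=4, cells_per_donor=200,
        base_dirichlet_alpha=(6.0, 4.0, 3.0, 2.0, 1.5),
        case_logodds_shift=(0.7, -0.5, 0.0, 0.0, 0.0),
        direct_effect_genes=("G00150", "G00151"),
    )


@pytest.fixture(scope="session")
def small_sc(small_config):
    counts, meta, labels = simulate_single_cell(small_config)
    return counts, meta, labels


@pytest.fixture(scope="session")
def small_norm(small_sc):
    counts, meta, _ = small_sc
    return lognormalize(counts), meta
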