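import pytest

from mirprof import synthetic


@pytest.fixture(scope="session")
def bundle():
    cfg = synthetic.ReferenceConfig(n_mirna=10, n_novel=3, n_genes=15)
    return synthetic.generate_references(cfg, seed=11)


@pytest.fixture(scope="session")
def design():
    return synthetic.LibraryDesign(
        n_mirna_reads=3000,
        planted_fold_changes={"syn-miR-1": 4.0, "syn-miR-2": 0.25},
        seed=7,
    )


@pytest.fixture(scope="session")
def libraries(bundle, design):
    return synthetic.generate_libraries(bundle, design)
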