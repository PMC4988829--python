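import pytest

from tailte import pipeline
from tailte import synthetic as syn


@pytest.fixture(scope="session")
def small_config():
    return syn.SimConfig(
        n_genes=300,
        stages=("a", "b", "c"),
        coupling_beta=(1.2, 1.2, 0.0),
        depth_rna=500_000,
        depth_rpf=500_000,
        depth_tags=150_000,
        seed=11,
        genotype_specs={
            "wispy": syn.WispySpec(),
            "png": syn.PngSpec(n_up=12, n_down=15),
            "smg": syn.SmgSpec(),
        },
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return syn.simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_quants(small_dataset):
    fix = pipeline.fixture_from_dataset(small_dataset)
    return fix, pipeline.quantify_all(fix)
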