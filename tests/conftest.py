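import numpy as np
import pytest

from rohvar import PlantSpec, simulate_cohort, test_scale_model, write_fixture_bundle


@pytest.fixture(scope="session")
def small_model():
    """4 x 75 Mb autosomes + 60 Mb X at sparse site density for fast tests."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return test_scale_model(site_density=10)


@pytest.fixture(scope="session")
def planted_cohort(small_model):
    """Two families (first-cousin + trio), noise-free, with one planted
    event of every inheritance mode plus regulatory-overlap variants."""
    plants = [
        PlantSpec("de_novo", "F2_c1", known_gene=True),
        PlantSpec("compound_het", "F2_c1"),
        PlantSpec("hom_in_roh", "F1_c1", known_gene=True),
        PlantSpec("x_linked", "F1_c1", effect="intronic"),
        PlantSpec(
            "hom_in_roh", "F1_c1", effect="intronic",
            regulatory_kind="enhancer", known_gene=True,
        ),
        PlantSpec("hom_in_roh", "F1_c1", effect="intronic", regulatory_kind="promoter"),
    ]
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_cohort(
            [("first_cousin", 1, ["male"]), ("trio", 1, ["male"])],
            small_model,
            seed=7,
            plants=plants,
        )


@pytest.fixture(scope="session")
def bundle_dir(planted_cohort, tmp_path_factory):
    d = tmp_path_factory.mktemp("bundle")
    write_fixture_bundle(planted_cohort, d, seed=3)
    return d


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
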