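import pytest

from gbgcdfe.models import DFEModel, GBGCContext


@pytest.fixture(scope="session")
def table_context():
    """The shared parameter context of the theoretical study (B varies)."""

    def make(B: float = 0.0, n: int = 50) -> GBGCContext:
        return GBGCContext(
            B=B, kappa=2.0, gc_content=0.472, theta=0.01, sample_size=n
        )

    return make


@pytest.fixture(scope="session")
def neutral_dfe():
    return DFEModel(shape_beta=1.0, mean_gamma=0.0)


@pytest.fixture(scope="session")
def case_dfes():
    return {
        "case1": DFEModel(shape_beta=0.3, mean_gamma=-200.0),
        "case2": DFEModel(
            shape_beta=0.3,
            mean_gamma=-2000.0,
            beneficial_fraction=0.005,
            beneficial_gamma=3.0,
        ),
        "case3": DFEModel(
            shape_beta=0.2,
            mean_gamma=-40.0,
            beneficial_fraction=0.03,
            beneficial_gamma=10.0,
        ),
    }


@pytest.fixture(scope="session")
def small_engine():
    """A compact Wright-Fisher engine shared across tests (n = 20 sample)."""
    from gbgcdfe.wright_fisher import WrightFisherEngine

    return WrightFisherEngine(n_ref=100, sample_size=20)


@pytest.fixture(scope="session")
def toy_bundle(tmp_path_factory):
    """A small synthetic two-species bundle written once per session."""
    from gbgcdfe.simulate import default_species_pair, make_two_species_dataset

    out = tmp_path_factory.mktemp("bundle")
    pair = default_species_pair(
        n_neutral_sites=200_000, n_selected_sites=200_000, n_genes=60
    )
    bundle = make_two_species_dataset(pair, str(out), seed=7)
    return pair, bundle
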