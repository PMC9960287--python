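import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, max_examples=60, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from viroprof.pipeline import run_pipeline
from viroprof.scenarios import ScenarioSpec, make_fixture
from viroprof.taxonomy import TaxonNode, TaxonomyStore

# Desk-scale scenario dimensions shared by the pipeline-level tests.
SMALL = dict(n_virus=4, virus_length=(8_000, 16_000), host_length=60_000,
             n_bacteria=2, bacteria_length=40_000)


@pytest.fixture(scope="session")
def small_clean_fixture():
    return make_fixture(ScenarioSpec(name="clean", seed=11, **SMALL))


@pytest.fixture(scope="session")
def small_clean_run(small_clean_fixture):
    return run_pipeline(small_clean_fixture)


def build_chain_store() -> TaxonomyStore:
    """Hand-sized tree exercising every rank feature the queries rely on:
    a species chain with subspecies/strain below it, a family on a listed
    phage order, a rank-free clade, and a species directly under a
    superkingdom."""
    return TaxonomyStore(
        [
            TaxonNode(1, 1, "no_rank", "root"),
            TaxonNode(10239, 1, "superkingdom", "Viruses"),
            TaxonNode(2, 1, "superkingdom", "Bacteria"),
            TaxonNode(100, 10239, "family", "Famviridae"),
            TaxonNode(150, 10239, "order", "Tubulavirales"),
            TaxonNode(101, 150, "family", "Plainviridae"),
            TaxonNode(200, 100, "genus", "Genustest"),
            TaxonNode(300, 200, "species", "Species one"),
            TaxonNode(301, 200, "species", "Species two"),
            TaxonNode(310, 300, "subspecies", "Species one sub"),
            TaxonNode(320, 310, "strain", "Species one strain"),
            TaxonNode(201, 101, "genus", "Ordergenus"),
            TaxonNode(302, 201, "species", "Order species"),
            TaxonNode(400, 2, "species", "Bacterium x"),
            TaxonNode(500, 10239, "no_rank", "clade A"),
            TaxonNode(501, 500, "species", "Clade species"),
        ]
    )


@pytest.fixture(scope="session")
def chain_store() -> TaxonomyStore:
    return build_chain_store()
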