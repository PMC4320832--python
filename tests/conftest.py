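import pytest
from pyfaidx import Fasta

from splicescape.annotation import build_annotation_db
from splicescape.conservation import merge_strains
from splicescape.synthetic import LandscapeSpec, generate_landscape

# small, fast landscape reused across unit tests (8 strains, same structure
# as the default landscape, ~600 junctions)
MINI_SPEC = LandscapeSpec(
    n_core_junctions=120,
    n_partial_junctions=200,
    n_private_per_strain=30,
    noise_rate=40.0,
    seed=11,
)


@pytest.fixture(scope="session")
def mini_dataset(tmp_path_factory):
    return generate_landscape(MINI_SPEC, tmp_path_factory.mktemp("mini"))


@pytest.fixture(scope="session")
def mini_sets(mini_dataset):
    return mini_dataset.load_sets()


@pytest.fixture(scope="session")
def mini_profiles(mini_sets):
    return merge_strains(mini_sets)


@pytest.fixture(scope="session")
def mini_db(mini_dataset):
    return build_annotation_db(mini_dataset.gtf_path)


@pytest.fixture(scope="session")
def mini_genome(mini_dataset):
    return Fasta(str(mini_dataset.fasta_path))


@pytest.fixture(scope="session")
def default_dataset(tmp_path_factory):
    """The default study-scale landscape (seed 42), generated once."""
    return generate_landscape(LandscapeSpec(seed=42), tmp_path_factory.mktemp("default"))
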