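import pytest

from qsarspace.curation import curate, split
from qsarspace.synth import SyntheticSpec, generate


@pytest.fixture(scope="session")
def default_synth():
    """One draw of the default synthetic benchmark (n=400, 8 clusters)."""
    return generate(SyntheticSpec())


@pytest.fixture(scope="session")
def default_curated(default_synth):
    """Default benchmark after curation and the standard 80/20 split."""
    return split(curate(default_synth.records), ivs_fraction=0.2, seed=17)


@pytest.fixture(scope="session")
def small_synth():
    """A small, quick dataset for pipeline-level tests."""
    return generate(SyntheticSpec(n_molecules=120, seed=7))
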