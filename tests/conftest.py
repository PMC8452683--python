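import pytest

from mitoduo import SynthConfig, build_reference_genome, diverge_lineages


@pytest.fixture(scope="session")
def default_config():
    return SynthConfig(seed=1)


@pytest.fixture(scope="session")
def reference(default_config):
    return build_reference_genome(default_config)


@pytest.fixture(scope="session")
def pair(reference, default_config):
    """The canonical seed-1 lineage pair with default structural events."""
    return diverge_lineages(reference, default_config)


@pytest.fixture(scope="session")
def assay_design(pair):
    from mitoduo import design_multiplex_assay
    return design_multiplex_assay(pair)


@pytest.fixture(scope="session")
def diagnostic_index(pair):
    from mitoduo import build_diagnostic_index
    return build_diagnostic_index(pair)
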