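import pytest

from scripkit.simulate import SynthConfig, generate_decoys, generate_family


@pytest.fixture(scope="session")
def synth_config():
    return SynthConfig(seed=11, n_subfamilies=4, members_per_subfamily=8, n_decoys=10)


@pytest.fixture(scope="session")
def family(synth_config):
    return generate_family(synth_config)


@pytest.fixture(scope="session")
def decoys(synth_config):
    return generate_decoys(synth_config)


@pytest.fixture(scope="session")
def reference_set(family):
    """A small reference panel drawn from the family itself."""
    return [(r.id, r.aa) for r in family.records[::5]]
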