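import pytest
from hypothesis import settings

from dcjdup.genome_model import Genome, parse_genomes

settings.register_profile("suite", max_examples=60, derandomize=True, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def g():
    """Parse a one-genome document into a Genome."""

    def _parse(text: str, name: str = "G") -> Genome:
        return parse_genomes(f">{name}\n{text}")[0]

    return _parse
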