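import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_protein(rng, length):
    return "".join(rng.choice(list(AA20), size=length))


@pytest.fixture
def small_proteome(tmp_path):
    """A three-protein FASTA on disk plus its path."""
    path = tmp_path / "toy.faa"
    path.write_text(">a first protein\nMKVLT\n>b\nMA\nGW\n>c\nmagwkv*\n")
    return path
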