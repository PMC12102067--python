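import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from fibrilhmm.fixtures import FixtureSpec, generate_fixture  # noqa: E402


@pytest.fixture(scope="session")
def small_fixture(tmp_path_factory):
    """One shared synthetic template (60 positions, 1 CDR, 1 missing segment)
    with a sampled corpus, reused by read-only tests."""
    out = tmp_path_factory.mktemp("fixture")
    return generate_fixture(FixtureSpec(corpus_size=30, rng_seed=11), out)


@pytest.fixture(scope="session")
def clean_fixture(tmp_path_factory):
    """Noise-free fixture: mutation and indel rates zero."""
    out = tmp_path_factory.mktemp("fixture0")
    return generate_fixture(
        FixtureSpec(mutation_rate=0.0, cdr_indel_rate=0.0, corpus_size=10,
                    rng_seed=13),
        out,
    )
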