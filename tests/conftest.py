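import pytest

from pseudoscreen.synthetic import FixtureConfig, make_toy_genome


@pytest.fixture(scope="session")
def toy():
    """Small 10-gene fixture (4 parent/pseudogene pairs + bidirectional
    pair + planted off-target confound) shared across read-only tests."""
    return make_toy_genome(FixtureConfig(seed=3, n_pairs=4))


def overlapping_count(seq: str, pattern: str) -> int:
    """Independent overlapping-occurrence counter used by oracles."""
    n = 0
    i = seq.find(pattern)
    while i != -1:
        n += 1
        i = seq.find(pattern, i + 1)
    return n
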