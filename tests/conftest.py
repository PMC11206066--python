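import numpy as np
import pytest

from ecoassembly.core import OTUTable


@pytest.fixture
def tiny_table() -> OTUTable:
    counts = np.array([[5, 0], [1, 2], [0, 7]])
    return OTUTable(["A", "B", "C"], ["s1", "s2"], counts)


@pytest.fixture
def random_table() -> OTUTable:
    rng = np.random.default_rng(7)
    counts = rng.poisson(3.0, size=(25, 12))
    counts[0] += 1  # guard against an all-zero sample column
    return OTUTable(
        [f"O{i}" for i in range(25)], [f"s{j}" for j in range(12)], counts
    )


def make_table(counts, otu_prefix="O", sample_prefix="s") -> OTUTable:
    counts = np.asarray(counts)
    return OTUTable(
        [f"{otu_prefix}{i}" for i in range(counts.shape[0])],
        [f"{sample_prefix}{j}" for j in range(counts.shape[1])],
        counts,
    )
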