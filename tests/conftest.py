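import numpy as np
import pytest

from castkit.refio import Reference

_BASES = np.array(list("ACGT"))


def random_reference(seed: int, length: int, n_contigs: int = 1) -> Reference:
    rng = np.random.default_rng(seed)
    contigs = []
    per = length // n_contigs
    for i in range(n_contigs):
        n = per if i < n_contigs - 1 else length - per * (n_contigs - 1)
        contigs.append((f"c{i + 1}", "".join(_BASES[rng.integers(0, 4, n)])))
    return Reference(contigs)


@pytest.fixture
def make_reference():
    return random_reference
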