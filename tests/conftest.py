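import numpy as np
import pytest

from snailmorph.genetics import reference_genotypes
from snailmorph.synthetic import shell_template


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def table2():
    """The bundled ten-genotype reference set, keyed by genotype id."""
    return {g.genotype_id: g for g in reference_genotypes()}


@pytest.fixture
def template():
    return shell_template()


def random_configs(rng, n, k=20, noise=0.05):
    """Noisy copies of the shell template (valid chiral configurations)."""
    base = shell_template()[:k]
    return [base + rng.normal(0, noise, (k, 2)) for _ in range(n)]
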