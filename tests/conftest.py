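import numpy as np
import pytest

from wzkit.simulate import gen_haplotype_set
from wzkit.synthetic_examples import banf2w_like_gene

# genotype-by-sex marker tables from the published cohort (n = 96),
# columns (females, males)
MARKER_TABLES = {
    "Banf2_w": [[48, 1], [0, 47]],
    "Banf2_del": [[48, 1], [0, 47]],
    "Paics_short": [[48, 1], [0, 47]],
    "Paics_long": [[27, 14], [21, 29], [0, 5]],
    "M1_like": [[4, 5], [25, 10], [19, 33]],
    "UNH168": [[5, 12], [22, 2], [8, 29], [13, 0], [0, 5]],
}

MARKER_POSITIONS_KBP = {
    "UNH168": 64515.0, "Paics_long": 73159.0, "Banf2_del": 73177.0,
    "Banf2_w": 73178.0, "Paics_short": 73217.0, "M1_like": 73394.0,
}


@pytest.fixture(scope="session")
def gene_model():
    return banf2w_like_gene(seed=0)


@pytest.fixture(scope="session")
def hap_family():
    """3 identical Z copies + 1 W variant (2 substitutions, 3-base deletion)."""
    return gen_haplotype_set(300, 3, True, 3, 2, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
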