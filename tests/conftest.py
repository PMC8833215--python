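import pytest

from delfold import EncodingScheme, default_scheme


@pytest.fixture(scope="session")
def scheme():
    """The full 96 x 192 default encoding scheme (built once per session)."""
    return default_scheme()


@pytest.fixture(scope="session")
def small_scheme():
    """A 2-amino-acid x 3-acid scheme: 24 members, 12 tags, fast to exercise."""
    return EncodingScheme.generate(
        n_r1=2,
        n_acid=3,
        codon_length=6,
        min_hamming=3,
        seed=11,
        primer5="ACGTACGTAC",
        primer3="GTCAGTCAGT",
    )
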