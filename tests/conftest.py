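import numpy as np
import pytest

from asorf import SyntheticGenomeSpec, generate_genome


@pytest.fixture(scope="session")
def planted_bundle():
    """A small deterministic genome with three asORFs planted per frame."""
    spec = SyntheticGenomeSpec(
        seed=11,
        gc=0.40,
        n_cds=12,
        cds_length_codons=(60, 120),
        antisense_fraction=0.5,
        intergenic_length=(150, 400),
        planted_per_frame=(3, 3, 3),
        planted_length_codons=(12, 25),
    )
    return generate_genome(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
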