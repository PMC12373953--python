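import numpy as np
import pytest

from riboneutral import (
    Msa,
    ReferenceSequence,
    ToySpec,
    make_toy_potts,
    make_toy_ribozyme,
)


@pytest.fixture(scope="session")
def toy_ref8():
    return ReferenceSequence(id="r8", residues="ACGUACGU")


@pytest.fixture(scope="session")
def toy_ref4():
    return ReferenceSequence(id="r4", residues="ACGU")


@pytest.fixture(scope="session")
def toy_potts8():
    return make_toy_potts(
        ToySpec(L=8, q=4, topology="chain", coupling_scale=0.5, field_scale=0.5, seed=1)
    )


@pytest.fixture(scope="session")
def toy_ribozyme():
    return make_toy_ribozyme(length=60, seed=0)


@pytest.fixture()
def small_msa():
    rows = [
        "ACGU-U",
        "ACGUAU",
        "GCGU-U",
        "ACGCAU",
        "ACGU-U",
    ]
    return Msa(rows=rows, ids=[f"s{i}" for i in range(len(rows))])


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
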