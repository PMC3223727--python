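import random
import string

import numpy as np
import pytest
from hypothesis import settings

from orfpipe.align import nucleotide_scheme, protein_scheme
from orfpipe.records import SequenceRecord

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

AA20 = "ACDEFGHIKLMNPQRSTVWY"
NT4 = "ACGT"


@pytest.fixture(scope="session")
def prot_scheme():
    return protein_scheme()


@pytest.fixture(scope="session")
def nt_scheme():
    return nucleotide_scheme()


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def random_protein(rng, length, prefix="p"):
    return "".join(rng.choice(list(AA20), size=length))


def random_dna(rng, length):
    return "".join(rng.choice(list(NT4), size=length))


def mutate(seq, identity, rng, alphabet=AA20):
    out = []
    for ch in seq:
        if rng.random() < 1 - identity:
            choices = alphabet.replace(ch, "")
            out.append(choices[rng.integers(len(choices))])
        else:
            out.append(ch)
    return "".join(out)


@pytest.fixture
def protein_record_factory(rng):
    def make(length=60, rid=None):
        rid = rid or "p" + "".join(random.choices(string.ascii_lowercase, k=6))
        return SequenceRecord(rid, random_protein(rng, length), "protein")

    return make
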