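import random

import pytest

import ablcp
from ablcp.digest import DigestParams

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture
def msq_db():
    """The single-protein worked-example database, text 'MSQVQVQV$'."""
    return ablcp.from_sequences([("P1", "MSQVQVQV")])


@pytest.fixture
def mkar_db():
    return ablcp.from_sequences([("P1", "MKAR")])


@pytest.fixture
def omission_db():
    """Two proteins whose shared 'AAK' first occurs in a non-specific
    suffix: the canonical case where the unadjusted LCP loses a peptide."""
    return ablcp.from_sequences([("P1", "XAAKB"), ("P2", "KAAKC")])


def random_protein_db(rng: random.Random, *, max_proteins=4, max_len=60,
                      force_krp=True, duplicate_prob=0.3):
    """A small random database biased to contain cleavage-relevant residues."""
    size = rng.choice([3, 4, 6, 12, 20])
    alphabet = set(AA20[:size])
    if force_krp:
        alphabet |= set("KRP")
    alphabet = "".join(sorted(alphabet))
    n = rng.randint(1, max_proteins)
    prots = [
        (f"P{k}", "".join(rng.choice(alphabet) for _ in range(rng.randint(1, max_len))))
        for k in range(n)
    ]
    if n > 1 and rng.random() < duplicate_prob:
        prots[-1] = (prots[-1][0], prots[0][1])
    return ablcp.from_sequences(prots)


def random_params(rng: random.Random, specificity: str) -> DigestParams:
    return DigestParams(
        specificity=specificity,
        max_missed_cleavages=rng.randint(0, 3),
        min_length=rng.randint(1, 3),
        max_length=rng.randint(5, 25),
        allow_protein_cterm=rng.random() < 0.7,
    )


def run_generator(db, params, enzyme=None):
    """Materialise one digest as a list of Peptide records."""
    return list(ablcp.digest_database(db, params, enzyme))


def digest_string_set(db, params, enzyme=None):
    return {p.sequence for p in run_generator(db, params, enzyme)}
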