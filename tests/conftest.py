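"""Shared fixtures: small synthetic corpora generated at test time."""

import pytest

from presyncodon.corpus import build_corpus
from presyncodon.synthetic import SyntheticConfig, generate_corpus, standard_rules


@pytest.fixture(scope="session")
def small_synth():
    """Deterministic small family-structured corpus with strength-1.0 rules."""
    config = SyntheticConfig(
        n_families=8,
        members_per_family=4,
        gene_length=(105, 130),
        rules=standard_rules(1.0),
        seed=13,
        eval_members_per_family=2,
    )
    return generate_corpus(config)


@pytest.fixture(scope="session")
def small_records(small_synth):
    return small_synth.records


@pytest.fixture(scope="session")
def small_corpus(small_synth):
    """Non-redundant representatives (one founder per family)."""
    return build_corpus(small_synth.records).corpus
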