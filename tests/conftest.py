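"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import pytest

from opilio.homology_search import seeded_translated_search
from opilio.synthetic_data import classical_chronogram, simulate_batch


@pytest.fixture(scope="session")
def chronogram():
    return classical_chronogram()


@pytest.fixture(scope="session")
def small_batch():
    """A 28-family batch with paralogs, fragments and contaminants."""
    return simulate_batch(20, 3, 5, seed=2)


@pytest.fixture(scope="session")
def small_hits(small_batch):
    return seeded_translated_search(small_batch.reference,
                                    small_batch.transcriptomes)


@pytest.fixture(scope="session")
def default_batch():
    """The default study-condition batch: 300 single-copy families,
    30 paralogous, 20 contaminants, fragmentation probability 0.2."""
    return simulate_batch(300, 30, 20, seed=101)


@pytest.fixture(scope="session")
def default_hits(default_batch):
    return seeded_translated_search(default_batch.reference,
                                    default_batch.transcriptomes)


@pytest.fixture(scope="session")
def sequences_of(small_batch):
    return {r.identifier: r.residues
            for recs in small_batch.transcriptomes.values() for r in recs}
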