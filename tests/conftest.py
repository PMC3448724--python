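"""Shared fixtures and independent brute-force oracles.

The oracles work from raw ``(a, b, score)`` triples and plain tag-set
dictionaries, deliberately bypassing the package's network/predictor code
paths so they stay an independent check.
"""

from __future__ import annotations

import pytest

from metpath import SimulationConfig, generate, load_fixture
from metpath.classes import PATHWAY_CLASSES


@pytest.fixture(scope="session")
def table2():
    return load_fixture("table2")


@pytest.fixture(scope="session")
def table6():
    return load_fixture("table6")


def raw_edges(net):
    """Network as a plain list of (a, b, score) triples."""
    return [(e.a, e.b, e.score) for e in net.edges()]


def raw_labels(labels):
    """LabelTable as a plain dict node id -> set of tag strings."""
    return {s: {c.tag for c in labels[s]} for s in labels}


def brute_likelihood(edges, tag_sets, s):
    """Oracle: exhaustive double loop over (edge, class) pairs.

    Returns the 11-tuple of summed scores of s's labeled partners per class.
    """
    values = []
    for cls in PATHWAY_CLASSES:
        total = 0
        for a, b, score in edges:
            if a == s:
                partner = b
            elif b == s:
                partner = a
            else:
                continue
            if cls.tag in tag_sets.get(partner, set()):
                total += score
        values.append(total)
    return tuple(values)


def brute_rank_tags(values):
    """Oracle ranking: descending value, ascending class index on ties."""
    pairs = sorted(
        zip(values, PATHWAY_CLASSES), key=lambda p: (-p[0], p[1].index)
    )
    return [cls.tag for _, cls in pairs]


@pytest.fixture
def small_synthetic():
    """Factory for <=50-node synthetic benchmarks (oracle-checkable size)."""

    def make(seed: int, **overrides):
        params = dict(n_compounds=40, n_enzymes=10, mean_degree=6.0, seed=seed)
        params.update(overrides)
        return generate(SimulationConfig(**params))

    return make
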