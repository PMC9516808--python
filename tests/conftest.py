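"""Shared fixtures: worked-example bundle, synthetic corpora, toy ontology."""

import pytest

from ontogru import fixtures
from ontogru.datatypes import OntologyGraph


@pytest.fixture(scope="session")
def examples():
    return fixtures.paper_examples()


@pytest.fixture(scope="session")
def small_bundle():
    """A mixed corpus exercising all annotation formats."""
    spec = fixtures.FixtureSpec(
        n_articles=6,
        sentences_per_article=(4, 8),
        n_concepts=8,
        p_overlap=0.2,
        p_discontinuous=0.1,
        p_multi_overlap=0.05,
        seed=42,
    )
    return fixtures.generate_corpus(spec)


@pytest.fixture(scope="session")
def toy_ontology():
    """root -> {a, b}; a -> {a1, a2}; b -> b1; a2 also child of b (DAG)."""
    return OntologyGraph(
        concepts=["GO:1", "GO:2", "GO:3", "GO:4", "GO:5", "GO:6"],
        name={f"GO:{i}": f"term {i}" for i in range(1, 7)},
        parents={
            "GO:1": set(),
            "GO:2": {"GO:1"},
            "GO:3": {"GO:1"},
            "GO:4": {"GO:2"},
            "GO:5": {"GO:2", "GO:3"},
            "GO:6": {"GO:3"},
        },
        namespace={
            "GO:1": "biological_process",
            "GO:2": "biological_process",
            "GO:3": "biological_process",
            "GO:4": "biological_process",
            "GO:5": "biological_process",
            "GO:6": "cellular_component",
        },
    )


def brute_force_ancestors(parents: dict, node: str) -> frozenset:
    """Independent transitive-closure oracle (breadth-first, self-inclusive)."""
    seen = {node}
    frontier = [node]
    while frontier:
        current = frontier.pop()
        for p in parents.get(current, ()):
            if p not in seen:
                seen.add(p)
                frontier.append(p)
    return frozenset(seen)
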