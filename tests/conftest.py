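import numpy as np
import pytest

import biotext as bt

TOY_OBO = """format-version: 1.2
ontology: toy

[Term]
id: T:0001
name: root cell
def: "The progenitor of all toy cells." [toy:1]

[Term]
id: T:0002
name: left cell
def: "A toy cell on the left branch." [toy:2]
is_a: T:0001

[Term]
id: T:0003
name: right cell
def: "A toy cell on the right branch." [toy:3]
is_a: T:0001
relationship: part_of T:0002

[Term]
id: T:0004
name: deep cell
def: "A toy cell below both branches." [toy:4]
is_a: T:0002
is_a: T:0003

[Term]
id: T:0005
name: gone cell
is_obsolete: true
"""


@pytest.fixture
def toy_graph():
    """Diamond ontology: 0004 -> {0002, 0003} -> 0001, plus one obsolete term."""
    return bt.parse_obo(TOY_OBO)


@pytest.fixture
def toy_obo_text():
    return TOY_OBO


@pytest.fixture
def chain_graph():
    """Three-term chain c is_a b is_a a."""
    obo = "\n".join(
        [
            "format-version: 1.2",
            "",
            "[Term]\nid: C:a\nname: a term\ndef: \"top.\" []",
            "",
            "[Term]\nid: C:b\nname: b term\ndef: \"middle.\" []\nis_a: C:a",
            "",
            "[Term]\nid: C:c\nname: c term\ndef: \"bottom.\" []\nis_a: C:b",
        ]
    )
    return bt.parse_obo(obo)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_dag_annotations(rng, n_nodes, n_instances=6, edge_prob=0.3):
    """Random DAG (edges child->parent toward lower indices) plus annotations."""
    terms = {}
    for i in range(n_nodes):
        parents = tuple(
            ("is_a", f"R:{j:03d}")
            for j in range(i)
            if rng.random() < edge_prob
        )
        terms[f"R:{i:03d}"] = bt.OntologyTerm(
            id=f"R:{i:03d}", name=f"node {i}", definition="x.", parents=parents
        )
    g = bt.OntologyGraph(terms)
    ids = [f"i{k}" for k in range(n_instances)]
    pairs = [
        (ids[k], f"R:{int(rng.integers(n_nodes)):03d}") for k in range(n_instances)
    ]
    ann = bt.AnnotationMatrix.from_pairs(
        pairs, instance_ids=ids, term_ids=sorted(terms)
    )
    return g, ann
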