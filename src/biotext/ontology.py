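"""Ontology I/O: OBO parsing, term descriptions, annotation propagation, unseen splits.

Controlled vocabularies (Gene Ontology, Cell Ontology, ...) are shipped as OBO
files of ``[Term]`` stanzas carrying an id, a short name, a quoted textual
definition and typed parent relations (``is_a``, ``part_of``).  This module
turns those files into an :class:`OntologyGraph`, joins name and definition
into the free-text class description the text encoder consumes, applies the
true-path rule to annotation tables (an annotation to a term implies
annotation to every ancestor), and builds train/test splits in which held-out
"unseen" classes have no annotated instance left in the training set.
"""

from __future__ import annotations

import io
import json
import logging
import re
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import obonet
import pandas as pd

__all__ = [
    "OntologyTerm",
    "OntologyGraph",
    "AnnotationMatrix",
    "UnseenSplit",
    "parse_obo",
    "write_obo",
    "term_description",
    "propagate_annotations",
    "leaf_terms",
    "make_unseen_split",
    "read_annotation_pairs",
]

#: relations over which graphs/closures are taken unless the caller overrides
DEFAULT_RELATIONS = frozenset({"is_a", "part_of"})

_DEF_RE = re.compile(r'^\s*"(?P<text>.*)"\s*(\[.*\])?\s*$', re.DOTALL)


class OboParseError(ValueError):
    """Raised for a malformed OBO stanza; the message names the line."""


@dataclass(frozen=True)
class OntologyTerm:
    """One ``[Term]`` stanza: id, name, definition and typed parent links."""

    id: str
    name: str = ""
    definition: str = ""
    parents: tuple[tuple[str, str], ...] = ()  # (relation, target id)
    obsolete: bool = False


class OntologyGraph:
    """Terms plus directed child -> parent edges labelled by relation.

    Obsolete terms are retained in :attr:`terms` but excluded from every
    graph view; the relation subsets used downstream must be acyclic.
    """

    def __init__(self, terms: dict[str, OntologyTerm]):
        self.terms = dict(terms)
        self._graph_cache: dict[frozenset, nx.DiGraph] = {}

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    @property
    def active_ids(self) -> list[str]:
        return [t.id for t in self.terms.values() if not t.obsolete]

    def graph(self, relations: frozenset | set = DEFAULT_RELATIONS) -> nx.DiGraph:
        """Child -> parent digraph restricted to ``relations``, obsolete excluded."""
        key = frozenset(relations)
        if key not in self._graph_cache:
            g = nx.DiGraph()
            g.add_nodes_from(self.active_ids)
            for term in self.terms.values():
                if term.obsolete:
                    continue
                for rel, target in term.parents:
                    if rel not in key:
                        continue
                    if target not in self.terms or self.terms[target].obsolete:
                        warnings.warn(
                            f"dropping edge {term.id} -{rel}-> {target}: "
                            "target missing or obsolete",
                            stacklevel=2,
                        )
                        continue
                    g.add_edge(term.id, target, relation=rel)
            self._graph_cache[key] = g
        return self._graph_cache[key]

    def ancestors(self, term_id: str, relations=DEFAULT_RELATIONS) -> set[str]:
        """All terms reachable from ``term_id`` along child->parent edges."""
        g = self.graph(relations)
        if term_id not in g:
            raise KeyError(f"unknown term {term_id!r}")
        return nx.descendants(g, term_id)  # child->parent orientation

    def descriptions(self, delimiter: str = ". ") -> dict[str, str]:
        return {
            t.id: term_description(t, delimiter=delimiter)
            for t in self.terms.values()
            if not t.obsolete
        }


def _clean_definition(raw: str) -> str:
    """Strip the surrounding quotes and trailing dbxref bracket of a def line."""
    m = _DEF_RE.match(raw)
    return m.group("text") if m else raw.strip()


def parse_obo(source) -> OntologyGraph:
    """Parse OBO 1.2/1.4 text (path, file object, or string) into a graph.

    Obsolete terms are flagged and excluded from graph views; edges whose
    target stanza is absent are dropped with a warning at graph-build time.
    """
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    _prevalidate(source)
    logging.disable(logging.WARNING)  # obonet logs about optional header keys
    try:
        nxg = obonet.read_obo(source, ignore_obsolete=False)
    finally:
        logging.disable(logging.NOTSET)

    terms: dict[str, OntologyTerm] = {}
    for node, data in nxg.nodes(data=True):
        if not data and node not in terms:
            continue  # dangling edge target, no stanza of its own
        parents = [("is_a", t) for t in data.get("is_a", [])]
        for entry in data.get("relationship", []):
            rel, _, target = entry.partition(" ")
            if rel == "part_of":
                parents.append((rel, target.strip()))
        terms[node] = OntologyTerm(
            id=node,
            name=data.get("name", ""),
            definition=_clean_definition(data.get("def", "")),
            parents=tuple(parents),
            obsolete=str(data.get("is_obsolete", "")).lower() == "true",
        )
    return OntologyGraph(terms)


def _prevalidate(source) -> None:
    """Cheap line scan so malformed stanza lines fail with a line number."""
    if hasattr(source, "read"):
        text = source.read()
        source.seek(0)
    else:
        with open(source) as fh:
            text = fh.read()
    in_term = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("!"):
            continue
        if stripped.startswith("["):
            in_term = stripped == "[Term]"
            continue
        if in_term and ":" not in stripped:
            raise OboParseError(f"malformed OBO tag-value line {lineno}: {line!r}")


def write_obo(g: OntologyGraph, stream=None) -> str:
    """Serialize a graph back to OBO text (round-trips through parse_obo)."""
    out = io.StringIO()
    out.write("format-version: 1.2\n")
    for term in g.terms.values():
        out.write("\n[Term]\n")
        out.write(f"id: {term.id}\n")
        if term.name:
            out.write(f"name: {term.name}\n")
        if term.definition:
            out.write(f'def: "{term.definition}" []\n')
        for rel, target in term.parents:
            if rel == "is_a":
                out.write(f"is_a: {target}\n")
            else:
                out.write(f"relationship: {rel} {target}\n")
        if term.obsolete:
            out.write("is_obsolete: true\n")
    text = out.getvalue()
    if stream is not None:
        stream.write(text)
    return text


def term_description(term: OntologyTerm, delimiter: str = ". ") -> str:
    """Join name and definition into the class description fed to the encoder."""
    if not term.name:
        raise ValueError(f"term {term.id} has an empty name")
    if not term.definition:
        return term.name
    return f"{term.name}{delimiter}{term.definition}"


@dataclass
class AnnotationMatrix:
    """Binary instance x term annotation table ``A``.

    ``propagated`` records whether the true-path closure has been applied:
    every 1 entry then implies 1 at all ancestors of its term.
    """

    instance_ids: list[str]
    term_ids: list[str]
    A: np.ndarray
    propagated: bool = False
    _term_index: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.A = np.asarray(self.A)
        if self.A.shape != (len(self.instance_ids), len(self.term_ids)):
            raise ValueError("A shape does not match id lists")
        if not np.isin(self.A, (0, 1)).all():
            raise ValueError("annotation matrix entries must be 0/1")
        self.A = self.A.astype(np.uint8)
        self._term_index = {t: j for j, t in enumerate(self.term_ids)}

    def term_column(self, term_id: str) -> np.ndarray:
        return self.A[:, self._term_index[term_id]]

    @classmethod
    def from_pairs(
        cls,
        pairs: list[tuple[str, str]],
        instance_ids: list[str] | None = None,
        term_ids: list[str] | None = None,
    ) -> "AnnotationMatrix":
        if instance_ids is None:
            instance_ids = sorted({i for i, _ in pairs})
        if term_ids is None:
            term_ids = sorted({t for _, t in pairs})
        ii = {x: k for k, x in enumerate(instance_ids)}
        tt = {x: k for k, x in enumerate(term_ids)}
        A = np.zeros((len(instance_ids), len(term_ids)), dtype=np.uint8)
        for inst, term in pairs:
            A[ii[inst], tt[term]] = 1
        return cls(instance_ids, term_ids, A)


def read_annotation_pairs(path_or_buf, **matrix_kwargs) -> AnnotationMatrix:
    """Read a two-column TSV of (instance_id, term_id) pairs."""
    df = pd.read_csv(path_or_buf, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError("annotation table needs two columns: instance_id, term_id")
    pairs = list(df.iloc[:, :2].itertuples(index=False, name=None))
    return AnnotationMatrix.from_pairs(pairs, **matrix_kwargs)


def propagate_annotations(
    ann: AnnotationMatrix,
    g: OntologyGraph,
    relations=DEFAULT_RELATIONS,
) -> AnnotationMatrix:
    """True-path closure: copy every 1 entry to all ancestors of its term.

    Idempotent; raises if the relation subset contains a cycle.
    """
    digraph = g.graph(relations)
    missing = [t for t in ann.term_ids if t not in g.terms]
    if missing:
        raise KeyError(f"annotation terms absent from ontology: {missing[:5]}")
    if not nx.is_directed_acyclic_graph(digraph):
        raise ValueError("relation subset contains a cycle; cannot propagate")

    col = {t: j for j, t in enumerate(ann.term_ids)}
    A = ann.A.astype(bool)
    out = A.copy()
    for term_id in ann.term_ids:
        if term_id not in digraph:
            continue
        for anc in nx.descendants(digraph, term_id):
            if anc in col:
                out[:, col[anc]] |= A[:, col[term_id]]
    return AnnotationMatrix(
        list(ann.instance_ids), list(ann.term_ids), out.astype(np.uint8), propagated=True
    )


def leaf_terms(g: OntologyGraph, relations=DEFAULT_RELATIONS) -> set[str]:
    """Terms with no children under ``relations`` (in-degree 0 child->parent)."""
    digraph = g.graph(relations)
    return {n for n in digraph.nodes if digraph.in_degree(n) == 0}


@dataclass
class UnseenSplit:
    """Instances kept for training plus the seen/unseen term partition."""

    train_instances: list[str]
    train_terms: list[str]
    test_terms: list[str]
    seed: int
    mode: str

    def to_json(self, stream=None) -> str:
        text = json.dumps(
            {
                "mode": self.mode,
                "seed": self.seed,
                "train_instances": self.train_instances,
                "train_terms": self.train_terms,
                "test_terms": self.test_terms,
            },
            indent=1,
        )
        if stream is not None:
            stream.write(text)
        return text

    @classmethod
    def from_json(cls, text: str) -> "UnseenSplit":
        d = json.loads(text)
        return cls(
            d["train_instances"], d["train_terms"], d["test_terms"], d["seed"], d["mode"]
        )


def make_unseen_split(
    ann: AnnotationMatrix,
    g: OntologyGraph,
    mode: str = "leaf",
    fraction: float = 0.5,
    seed: int = 0,
    relations=DEFAULT_RELATIONS,
    propagate: bool = True,
) -> UnseenSplit:
    """Hold out classes as unseen and drop every instance annotated to them.

    ``mode='leaf'`` holds out a seeded random fraction of the annotated leaf
    terms (``fraction=1`` holds out every leaf, which usually errors because
    no annotated instance survives); ``mode='fraction'`` holds out a seeded
    random fraction of all annotated terms.  Terms with no annotation are
    never selectable.  Removing annotated instances prevents information
    leakage from training examples of a supposedly unseen class.
    """
    if mode not in ("leaf", "fraction"):
        raise ValueError(f"unknown split mode {mode!r}")
    work = propagate_annotations(ann, g, relations) if propagate and not ann.propagated else ann
    annotated = [t for t in work.term_ids if work.term_column(t).any()]

    if mode == "leaf":
        candidates = sorted(set(annotated) & leaf_terms(g, relations))
        if not 0 < fraction <= 1:
            raise ValueError("fraction must lie in (0, 1]")
    else:
        candidates = annotated
        if not 0 < fraction < 1:
            raise ValueError("fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    n_test = int(round(fraction * len(candidates)))
    test_terms = sorted(rng.choice(candidates, size=n_test, replace=False).tolist())
    if not test_terms:
        raise ValueError("split selected no unseen terms")

    test_cols = [work._term_index[t] for t in test_terms]
    touches_test = work.A[:, test_cols].any(axis=1)
    train_instances = [i for i, bad in zip(work.instance_ids, touches_test) if not bad]
    if not train_instances:
        raise ValueError("split removed every training instance")
    train_terms = [t for t in annotated if t not in set(test_terms)]
    return UnseenSplit(train_instances, train_terms, test_terms, seed=seed, mode=mode)
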