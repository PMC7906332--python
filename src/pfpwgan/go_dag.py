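"""Gene Ontology DAG handling: parsing, ancestor closure, true-path rule.

The ontology is held as an ``is_a`` DAG only.  Other OBO relationship types
(``part_of`` etc.) are deliberately ignored: the true-path rule ("whenever a
term annotates a protein, so do its parents") and the ancestor set ``anc(t)``
used by the conflict score are defined on the parent relation alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import obonet

from .annotations import AnnotationMatrix

__all__ = [
    "OntologyDag",
    "TermFilterSpec",
    "OboParseError",
    "OntologyStructureError",
    "parse_obo",
    "write_obo",
    "propagate_true_path",
    "filter_terms",
]

_NAMESPACE_CODES = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "cellular_component": "CC",
    "BP": "BP",
    "MF": "MF",
    "CC": "CC",
}

_NAMESPACE_NAMES = {
    "BP": "biological_process",
    "MF": "molecular_function",
    "CC": "cellular_component",
}


class OboParseError(ValueError):
    pass


class OntologyStructureError(ValueError):
    pass


@dataclass
class TermFilterSpec:
    """Per-namespace minimum positive-protein counts for keeping a term."""

    min_count_bp: int = 250
    min_count_mf: int = 50
    min_count_cc: int = 50

    def __post_init__(self):
        for v in (self.min_count_bp, self.min_count_mf, self.min_count_cc):
            if v < 1:
                raise ValueError("term-filter counts must be >= 1")

    def threshold(self, namespace: str) -> int:
        return {"BP": self.min_count_bp, "MF": self.min_count_mf,
                "CC": self.min_count_cc}[namespace]


@dataclass
class OntologyDag:
    """An ``is_a`` DAG over GO-style term identifiers."""

    terms: list
    namespace: dict
    parents: dict
    names: dict = field(default_factory=dict)

    def __post_init__(self):
        self._anc_cache: dict = {}
        self._heights: dict | None = None
        order = {t: i for i, t in enumerate(self.terms)}
        for t, ps in self.parents.items():
            self.parents[t] = set(ps)
            for p in ps:
                if p not in order:
                    raise OntologyStructureError(f"parent {p} of {t} is not a term")
        cycle = self._find_cycle()
        if cycle is not None:
            raise OntologyStructureError(
                "is_a relation contains a cycle: " + " -> ".join(cycle))

    def _find_cycle(self):
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        g.add_edges_from((t, p) for t, ps in self.parents.items() for p in ps)
        try:
            edges = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            return None
        return [e[0] for e in edges] + [edges[-1][1]]

    # -- queries --------------------------------------------------------------
    def __contains__(self, term) -> bool:
        return term in self.parents

    @property
    def roots(self) -> set:
        return {t for t in self.terms if not self.parents[t]}

    def children(self) -> dict:
        ch = {t: set() for t in self.terms}
        for t, ps in self.parents.items():
            for p in ps:
                ch[p].add(t)
        return ch

    def leaves(self) -> list:
        ch = self.children()
        return [t for t in self.terms if not ch[t]]

    def ancestors(self, term) -> set:
        """Transitive ``is_a`` closure of ``term``, excluding the term itself."""
        if term not in self.parents:
            raise KeyError(f"unknown term: {term}")
        cached = self._anc_cache.get(term)
        if cached is not None:
            return cached
        result = set()
        stack = list(self.parents[term])
        while stack:
            p = stack.pop()
            if p in result:
                continue
            hit = self._anc_cache.get(p)
            if hit is not None:
                result.add(p)
                result |= hit
                continue
            result.add(p)
            stack.extend(self.parents[p])
        self._anc_cache[term] = result
        return result

    def term_height(self, term) -> int:
        """Longest ``is_a`` path from ``term`` up to its namespace root."""
        if term not in self.parents:
            raise KeyError(f"unknown term: {term}")
        if self._heights is None:
            heights: dict = {}
            for t in nx.topological_sort(self._parent_first_graph()):
                ps = self.parents[t]
                heights[t] = 0 if not ps else 1 + max(heights[p] for p in ps)
            self._heights = heights
        return self._heights[term]

    def _parent_first_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        g.add_edges_from((p, t) for t, ps in self.parents.items() for p in ps)
        return g

    def write_term_table(self, path, terms=None) -> None:
        """Two-column TSV (term_id, namespace code)."""
        with open(path, "w") as fh:
            for t in (terms if terms is not None else self.terms):
                fh.write(f"{t}\t{self.namespace[t]}\n")


def parse_obo(path) -> OntologyDag:
    """Parse a minimal OBO file into an :class:`OntologyDag`.

    Only ``id``, ``name``, ``namespace``, ``is_a`` and ``is_obsolete`` are
    honored; obsolete terms are dropped; relations other than ``is_a`` are
    ignored.  A cyclic ``is_a`` relation raises
    :class:`OntologyStructureError` naming one cycle.
    """
    try:
        graph = obonet.read_obo(path, ignore_obsolete=True)
    except Exception as exc:  # obonet raises assorted ValueError subclasses
        raise OboParseError(f"cannot parse OBO file {path}: {exc}") from exc
    terms, namespace, parents, names = [], {}, {}, {}
    for node, attrs in graph.nodes(data=True):
        ns = _NAMESPACE_CODES.get(attrs.get("namespace", ""))
        if ns is None:
            raise OboParseError(f"term {node} lacks a recognized namespace")
        terms.append(node)
        namespace[node] = ns
        names[node] = attrs.get("name", node)
        parents[node] = set()
    node_set = set(terms)
    # obonet edges run child -> parent, keyed by relation type
    for child, parent, rel in graph.edges(keys=True):
        if rel != "is_a":
            continue
        if parent in node_set:
            parents[child].add(parent)
    terms.sort()
    return OntologyDag(terms, namespace, parents, names)


def write_obo(dag: OntologyDag, path) -> None:
    """Write the DAG back out as a minimal OBO 1.2 flat file."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n")
        for t in dag.terms:
            fh.write("\n[Term]\n")
            fh.write(f"id: {t}\n")
            fh.write(f"name: {dag.names.get(t, t)}\n")
            fh.write(f"namespace: {_NAMESPACE_NAMES[dag.namespace[t]]}\n")
            for p in sorted(dag.parents[t]):
                fh.write(f"is_a: {p} ! {dag.names.get(p, p)}\n")


def propagate_true_path(dag: OntologyDag, assignments: AnnotationMatrix) -> AnnotationMatrix:
    """Close every protein's annotation set under ancestors (true-path rule).

    The closure is restricted to the matrix's term set: ancestors outside the
    matrix columns are not added, but reachability is still evaluated on the
    full DAG, so a parent missing from the matrix does not break the chain to
    a grandparent that is present.
    """
    for t in assignments.terms:
        if t not in dag:
            raise KeyError(f"annotation term {t} not in ontology")
    terms = assignments.terms
    ti = {t: j for j, t in enumerate(terms)}
    c = len(terms)
    reach = np.eye(c, dtype=np.int8)
    for j, t in enumerate(terms):
        for a in dag.ancestors(t):
            k = ti.get(a)
            if k is not None:
                reach[j, k] = 1
    closed = (assignments.values.astype(np.int64) @ reach > 0).astype(np.int8)
    return AnnotationMatrix(list(assignments.proteins), list(terms), closed)


def filter_terms(dag: OntologyDag, assignments: AnnotationMatrix,
                 spec: TermFilterSpec | None = None):
    """Drop terms annotating fewer proteins than their namespace threshold.

    ``assignments`` is expected to be true-path propagated, so a parent's
    count includes the proteins of its descendants.  Returns a dict mapping
    namespace code to the kept terms (column order preserved) and the reduced
    matrix.
    """
    spec = spec or TermFilterSpec()
    counts = assignments.values.sum(axis=0)
    kept: dict[str, list] = {}
    keep_cols = []
    for j, t in enumerate(assignments.terms):
        ns = dag.namespace[t]
        if counts[j] >= spec.threshold(ns):
            kept.setdefault(ns, []).append(t)
            keep_cols.append(t)
    for ns in sorted({dag.namespace[t] for t in assignments.terms}):
        if not kept.get(ns):
            warnings.warn(f"no terms survive filtering in namespace {ns}")
    return kept, assignments.subset_terms(keep_cols)
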