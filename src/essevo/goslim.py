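"""GO-slim multifunctionality: count nonredundant biological processes.

A protein's multifunctionality is the number of distinct GO-slim
biological-process classes covering its BP annotations, obtained by mapping
each annotated term up to its *minimal* slim ancestors (map2slim
semantics: a slim ancestor is kept only if no other slim term lies strictly
between it and the annotated term).  Traversal follows ``is_a`` and
``part_of`` edges only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import obonet

#: the root biological-process term, ignored when annotated with evidence ND
BP_ROOT = "GO:0008150"
#: immune system process; membership defines the immunity flag
IMMUNITY_TERM = "GO:0002376"

RELATIONS = ("is_a", "part_of")


@dataclass
class GOGraph:
    """Ontology DAG (child -> parent over is_a/part_of) plus a slim subset."""

    graph: nx.MultiDiGraph
    slim: set = field(default_factory=set)

    @classmethod
    def from_obo(cls, path, slim_subset: str = "goslim_generic",
                 slim_terms=None) -> "GOGraph":
        g = obonet.read_obo(path)
        if slim_terms is None:
            slim_terms = {
                node
                for node, data in g.nodes(data=True)
                if slim_subset in data.get("subset", [])
            }
        return cls(g, set(slim_terms))

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def namespace(self, term: str) -> str | None:
        return self.graph.nodes[term].get("namespace")

    def ancestors_or_self(self, term: str) -> set:
        """Transitive is_a/part_of closure including the term itself."""
        seen = {term}
        stack = [term]
        while stack:
            cur = stack.pop()
            for _, parent, rel in self.graph.out_edges(cur, keys=True):
                if rel in RELATIONS and parent not in seen:
                    seen.add(parent)
                    stack.append(parent)
        return seen

    def descendants_or_self(self, term: str) -> set:
        """All terms whose is_a/part_of closure reaches ``term``."""
        seen = {term}
        stack = [term]
        while stack:
            cur = stack.pop()
            for child, _, rel in self.graph.in_edges(cur, keys=True):
                if rel in RELATIONS and child not in seen:
                    seen.add(child)
                    stack.append(child)
        return seen


def map_to_slim(term: str, g: GOGraph) -> set:
    """Minimal covering slim ancestors of ``term`` (self included if slim)."""
    if term not in g:
        warnings.warn(f"unknown GO term {term}; skipped")
        return set()
    candidates = g.ancestors_or_self(term) & g.slim
    if term in g.slim:
        # a slim term maps to itself; more general slim ancestors are redundant
        return {term}
    minimal = set()
    for s in candidates:
        # drop s if another candidate lies strictly below it
        if not any(o != s and s in g.ancestors_or_self(o) for o in candidates):
            minimal.add(s)
    return minimal


def _usable_bp_annotations(annotations, g: GOGraph):
    """Yield BP terms, dropping the ND-annotated root and non-BP aspects."""
    for entry in annotations:
        term, evidence = entry[0], entry[1]
        aspect = entry[2] if len(entry) > 2 else None
        if term == BP_ROOT and evidence == "ND":
            continue
        if aspect is not None and aspect != "P":
            continue
        if term in g and aspect is None and g.namespace(term) not in (
            None, "biological_process"
        ):
            continue
        yield term


def count_multifunctionality(protein: str, annotations: dict,
                             g: GOGraph) -> int | None:
    """Number of nonredundant slim BP classes; ``None`` when no usable data."""
    entries = annotations.get(protein, [])
    usable = list(_usable_bp_annotations(entries, g))
    if not usable:
        return None
    slim_union = set()
    for term in usable:
        slim_union |= map_to_slim(term, g)
    return len(slim_union)


def flag_immunity(protein: str, annotations: dict, g: GOGraph,
                  immunity_term: str = IMMUNITY_TERM) -> bool:
    """True iff any BP annotation lies in the immune-system-process subtree."""
    for term in _usable_bp_annotations(annotations.get(protein, []), g):
        if term in g and immunity_term in g.ancestors_or_self(term):
            return True
    return False


def read_gaf(path) -> dict:
    """Parse a GAF 2.x file into protein -> [(GO id, evidence, aspect), ...]."""
    annotations: dict = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("!") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                continue
            obj_id, go_id, evidence, aspect = cols[1], cols[4], cols[6], cols[8]
            annotations.setdefault(obj_id, []).append((go_id, evidence, aspect))
    return annotations


def multifunctionality_table(annotations: dict, g: GOGraph):
    """Per-protein (count, immunity) rows plus the list of no-data proteins."""
    import pandas as pd

    rows = {}
    no_data = []
    for protein in annotations:
        count = count_multifunctionality(protein, annotations, g)
        if count is None:
            no_data.append(protein)
            continue
        rows[protein] = {
            "multifunctionality": count,
            "immunity": flag_immunity(protein, annotations, g),
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "gene_id"
    return df, no_data
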