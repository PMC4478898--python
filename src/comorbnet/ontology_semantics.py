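"""Wang-style semantic values and similarities over ontology DAGs.

A term ``a`` is viewed through its ancestral sub-DAG ``DAG_a = (a, T_a,
E_a)``: ``T_a`` holds ``a`` and every ancestor reachable through *is_a* /
*part_of* edges, and each ancestor ``t`` receives an S-value — the
semantic contribution of ``t`` to ``a`` — by max-propagation from ``a``
upward, discounting each edge by a relation-specific factor ``w_e``.
Term–term similarity compares two terms through the S-values of their
shared ancestors, and term-set similarity combines the best-matching
term pairs of two annotation sets.

Semantic contribution factors default to the Wang et al. conventions:
w(is_a) = 0.8, w(part_of) = 0.6.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import obonet

__all__ = [
    "OntologyDAG",
    "SValueMap",
    "load_obo",
    "s_values",
    "semantic_value",
    "term_similarity",
    "termset_similarity",
    "hpo_jaccard",
]

DEFAULT_CONTRIBUTION = {"is_a": 0.8, "part_of": 0.6}


@dataclass
class OntologyDAG:
    """Terms plus directed child→parent edges with contribution factors.

    ``parents[t]`` is the set of ``(parent, relation)`` pairs of ``t``;
    ``contribution`` maps each relation to its w_e in (0, 1).
    """

    terms: set[str]
    parents: dict[str, set[tuple[str, str]]]
    contribution: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONTRIBUTION)
    )

    def __post_init__(self) -> None:
        for rel, w in self.contribution.items():
            if not 0.0 < w < 1.0:
                raise ValueError(
                    f"contribution factor for {rel!r} must lie strictly in (0, 1), got {w}"
                )
        for child, ps in self.parents.items():
            for parent, rel in ps:
                if child not in self.terms or parent not in self.terms:
                    raise ValueError(f"edge {child}->{parent} references unknown term")
                if rel not in self.contribution:
                    raise ValueError(f"edge relation {rel!r} has no contribution factor")
        cycle = self._find_cycle()
        if cycle:
            raise ValueError(f"ontology graph is cyclic (involves term {cycle})")

    def _find_cycle(self) -> str | None:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for child, ps in self.parents.items():
            for parent, _ in ps:
                g.add_edge(child, parent)
        try:
            cyc = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            return None
        return cyc[0][0]

    def ancestors(self, term: str) -> set[str]:
        """T_term: the term itself plus everything reachable upward."""
        if term not in self.terms:
            raise KeyError(f"unknown ontology term {term!r}")
        seen = {term}
        stack = [term]
        while stack:
            t = stack.pop()
            for parent, _ in self.parents.get(t, ()):
                if parent not in seen:
                    seen.add(parent)
                    stack.append(parent)
        return seen

    def to_obo(self, path: str | Path) -> None:
        """Serialize as a minimal OBO 1.2 file readable by :func:`load_obo`."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("format-version: 1.2\n")
            for term in sorted(self.terms):
                fh.write(f"\n[Term]\nid: {term}\nname: {term}\n")
                for parent, rel in sorted(self.parents.get(term, ())):
                    if rel == "is_a":
                        fh.write(f"is_a: {parent}\n")
                    else:
                        fh.write(f"relationship: {rel} {parent}\n")


def load_obo(
    path: str | Path, contribution: dict[str, float] | None = None
) -> OntologyDAG:
    """Load an OBO 1.2 file into an :class:`OntologyDAG`.

    Only is_a and part_of relationships are kept; obsolete terms are
    dropped.  A cyclic graph raises a :class:`ValueError` naming a term
    on the cycle.
    """
    graph = obonet.read_obo(path, ignore_obsolete=True)
    keep = set(DEFAULT_CONTRIBUTION if contribution is None else contribution)
    terms = set(graph.nodes)
    parents: dict[str, set[tuple[str, str]]] = {}
    for child, parent, rel in graph.edges(keys=True):
        if rel in keep:
            parents.setdefault(child, set()).add((parent, rel))
    return OntologyDAG(
        terms=terms,
        parents=parents,
        contribution=dict(DEFAULT_CONTRIBUTION if contribution is None else contribution),
    )


@dataclass(frozen=True)
class SValueMap:
    """S-values of every term in T_a relative to the anchor ``a``."""

    anchor: str
    values: dict[str, float]


def s_values(dag: OntologyDAG, a: str) -> SValueMap:
    """Max-propagated semantic contributions of every ancestor of ``a``.

    S_a(a) = 1; for t ≠ a, S_a(t) = max over children t' of t *within
    T_a* of w_e · S_a(t').  The recursion is restricted to the ancestral
    closure of ``a``, and the result is independent of edge iteration
    order.
    """
    t_a = dag.ancestors(a)
    values: dict[str, float] = {a: 1.0}

    # children-within-T_a adjacency: parent -> [(child, w_e)]
    children: dict[str, list[tuple[str, float]]] = {}
    for child in t_a:
        for parent, rel in dag.parents.get(child, ()):
            if parent in t_a:
                children.setdefault(parent, []).append(
                    (child, dag.contribution[rel])
                )

    def resolve(t: str) -> float:
        if t in values:
            return values[t]
        best = max(w * resolve(child) for child, w in children[t])
        values[t] = best
        return best

    for t in t_a:
        resolve(t)
    return SValueMap(anchor=a, values=values)


def semantic_value(sv: SValueMap) -> float:
    """SV(a): the summed semantic contributions of all terms in T_a."""
    return float(sum(sv.values.values()))


def term_similarity(dag: OntologyDAG, a: str, b: str) -> float:
    """Similarity of terms ``a`` and ``b`` through their shared ancestors.

    Σ_{t ∈ T_a ∩ T_b} (S_a(t) + S_b(t)) / (SV(a) + SV(b)); symmetric,
    equal to 1 exactly when a = b, and 0 when the closures are disjoint.
    """
    if a == b:
        if a not in dag.terms:
            raise KeyError(f"unknown ontology term {a!r}")
        return 1.0  # numerator and denominator coincide term by term
    sa = s_values(dag, a)
    sb = s_values(dag, b)
    common = sa.values.keys() & sb.values.keys()
    numerator = sum(sa.values[t] + sb.values[t] for t in common)
    return float(numerator / (semantic_value(sa) + semantic_value(sb)))


def termset_similarity(
    dag: OntologyDAG, A: frozenset[str] | set[str], B: frozenset[str] | set[str]
) -> float:
    """Similarity of two annotation sets by best-match aggregation.

    Each term of A is matched to its most similar term of B and vice
    versa; the matches are pooled and divided by |A| + |B|.
    """
    if not A or not B:
        raise ValueError("termset similarity requires two nonempty term sets")
    sim_a = sum(max(term_similarity(dag, a, b) for b in B) for a in A)
    sim_b = sum(max(term_similarity(dag, b, a) for a in A) for b in B)
    return float((sim_a + sim_b) / (len(A) + len(B)))


def hpo_jaccard(P1: frozenset[str] | set[str], P2: frozenset[str] | set[str]) -> float:
    """Jaccard index of two matched HPO-term sets."""
    union = set(P1) | set(P2)
    if not union:
        raise ValueError("HPO Jaccard undefined for two empty term sets")
    return len(set(P1) & set(P2)) / len(union)
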