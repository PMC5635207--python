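"""Hydrogen-suppressed molecular graphs and extended-connectivity attributes.

The graph view of a molecule keeps one vertex per heavy atom and one edge per
bond (bond order ignored).  On it the Morgan extended-connectivity (EC)
invariant is computed: order 0 is the vertex degree, and each further order
sums the previous-order values over the vertex's neighbours — equivalently,
``EC_k(v)`` counts walks of length ``k+1`` starting at ``v``.  Each vertex
contributes one attribute per order, coded ``EC{k}:{element}:{value}``, so
that chemically different vertices with equal connectivity stay distinct.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

from .smiles_attributes import TokenizeError, _AROMATIC, _BRACKET_RE, _PLAIN_ATOMS, tokenize

__all__ = [
    "MolecularGraph",
    "smiles_to_graph",
    "extended_connectivity",
    "extract_graph_attributes",
]


@dataclass
class MolecularGraph:
    """Vertices are ``(index, element)`` in SMILES order; edges are unordered
    index pairs.  Disconnected components are allowed."""

    elements: list[str] = field(default_factory=list)
    edges: set[frozenset[int]] = field(default_factory=set)

    @property
    def n_vertices(self) -> int:
        return len(self.elements)

    def add_edge(self, a: int, b: int) -> None:
        if a == b:
            raise ValueError("self-loop")
        self.edges.add(frozenset((a, b)))

    def adjacency(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in self.elements]
        for e in self.edges:
            a, b = tuple(e)
            adj[a].append(b)
            adj[b].append(a)
        return adj

    def degrees(self) -> list[int]:
        return [len(nb) for nb in self.adjacency()]


def _atom_element(token: str) -> str | None:
    """Element label of an atom token, or None for non-atom / suppressed H."""
    if token.startswith("["):
        m = _BRACKET_RE.match(token)
        if m is None:
            raise TokenizeError(f"unparseable bracket atom {token!r}")
        el = m.group("element")
        el = el.capitalize() if el.islower() else el
        return None if el == "H" else el
    if token in _PLAIN_ATOMS:
        return token
    if token in _AROMATIC:
        return token.upper()
    return None


def smiles_to_graph(smiles: str) -> MolecularGraph:
    """Parse a SMILES string into its hydrogen-suppressed graph.

    Edges come from sequential adjacency, branches, and matched ring-closure
    digits (or ``%nn`` closures); the ``.`` token separates components.
    Explicit ``[H]`` atoms are suppressed.
    """
    g = MolecularGraph()
    prev: int | None = None
    stack: list[int | None] = []
    ring_open: dict[str, int] = {}
    for tok in tokenize(smiles):
        if tok == "(":
            stack.append(prev)
            continue
        if tok == ")":
            if not stack:
                raise TokenizeError("unmatched ')' during graph parse")
            prev = stack.pop()
            continue
        if tok == ".":
            prev = None
            continue
        if tok.isdigit() or tok.startswith("%"):
            label = tok.lstrip("%")
            if prev is None:
                raise TokenizeError(f"ring closure {tok!r} with no preceding atom")
            if label in ring_open:
                opener = ring_open.pop(label)
                g.add_edge(opener, prev)
            else:
                ring_open[label] = prev
            continue
        el = _atom_element(tok)
        if el is None:
            continue  # bond symbols, stereo marks, suppressed hydrogens
        v = g.n_vertices
        g.elements.append(el)
        if prev is not None:
            g.add_edge(prev, v)
        prev = v
    if ring_open:
        labels = ", ".join(sorted(ring_open))
        raise TokenizeError(f"unmatched ring closure digit(s): {labels}")
    return g


def extended_connectivity(g: MolecularGraph, k_max: int) -> list[list[int]]:
    """EC vectors for orders 0..k_max: EC0 = degrees, EC(k+1) = neighbour sums."""
    if k_max < 0:
        raise ValueError("k_max must be >= 0")
    adj = g.adjacency()
    vectors = [[len(nb) for nb in adj]]
    for _ in range(k_max):
        prev = vectors[-1]
        vectors.append([sum(prev[u] for u in nb) for nb in adj])
    return vectors


def extract_graph_attributes(
    g: MolecularGraph, ec_vectors: Sequence[Sequence[int]]
) -> Counter:
    """Attribute profile: one ``EC{k}:{element}:{value}`` instance per vertex
    per order."""
    profile: Counter = Counter()
    for k, vec in enumerate(ec_vectors):
        for el, val in zip(g.elements, vec):
            profile[f"EC{k}:{el}:{val}"] += 1
    return profile
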