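"""Exhaustive reference search for the most specific common template.

The diagram builder grows templates greedily (largest commonly expandable
atom subset per step).  This module finds the maximum-size common template
by exhaustive search over *all* sequences of single-atom expansions, with
the same move semantics (full-neighborhood growth, ring completion, and
identical enlarged templates across every pseudo-molecule).  It shares no
code with the greedy builder's subset selection and is deliberately slow;
it exists to validate the builder on small inputs.
"""

from __future__ import annotations

import networkx as nx

from .hasse import canonical_hash, match_template
from .hasse import _grow, _ring_sets  # move semantics shared by definition
from .its import extract_reaction_center

__all__ = ["exhaustive_common_template"]


def exhaustive_common_template(its_list: list[nx.Graph],
                               cap: int = 256) -> nx.Graph:
    """Maximum-size template reachable from the common reaction center by
    any sequence of single-atom full-neighborhood expansions that keeps the
    template embeddable, identically, in every pseudo-molecule.

    The template is represented as a subgraph of the first pseudo-molecule.
    """
    its1 = its_list[0]
    center = extract_reaction_center(its1)
    rings = [_ring_sets(g) for g in its_list]

    start = frozenset(center.nodes)
    best: nx.Graph = center
    seen: set[frozenset] = set()

    def graph_of(nodes: frozenset) -> nx.Graph:
        if nodes == start:
            return center
        return its1.subgraph(nodes).copy()

    stack = [start]
    while stack:
        nodes = stack.pop()
        if nodes in seen:
            continue
        seen.add(nodes)
        g = graph_of(nodes)
        if g.number_of_nodes() > best.number_of_nodes():
            best = g

        embs_per_its = [match_template(g, its_k, cap) for its_k in its_list]
        if not all(embs_per_its):
            continue  # should not happen: g was reachable
        for a in sorted(nodes):
            if all(nb in nodes for nb in its1.neighbors(a)):
                continue
            # hashes achievable in every pseudo-molecule by expanding a
            common: set[str] | None = None
            for its_k, rk, embs in zip(its_list, rings, embs_per_its):
                here = set()
                for e in embs:
                    grown = _grow(its_k, rk, e, (a,))
                    if grown.number_of_nodes() > len(e):
                        here.add(canonical_hash(grown))
                common = here if common is None else common & here
                if not common:
                    break
            if not common:
                continue
            for e1 in embs_per_its[0]:
                g1 = _grow(its1, rings[0], e1, (a,))
                if canonical_hash(g1) in common:
                    stack.append(frozenset(g1.nodes))
    return best
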