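"""Extended Hasse diagrams of reaction templates.

A diagram is a rooted tree of templates ordered by subgraph containment.
The root is the reaction center (or a user seed / the maximum common
substructure in single-substrate mode); leaves are the full input ITS
pseudo-molecules; every internal node is a common substructure of all the
leaves below it that contains the root.

Templates grow by iterative conserved-substructure expansion: at each step
the template atoms with unspecified neighbors are shortlisted, and the
largest subset of shortlisted atoms whose full-neighborhood expansion gives
the identical enlarged template in every pseudo-molecule is expanded.  When
no common expansion exists, every shortlisted atom is expanded separately
per pseudo-molecule and the tree branches.  An atom added inside a ring
pulls in the whole ring within the same step.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field

import networkx as nx
from rdkit import Chem
from rdkit.Chem import rdFMCS

from . import its as its_mod
from .reaction_io import AtomMappedReaction

logger = logging.getLogger(__name__)

__all__ = [
    "CenterConflictError",
    "DiagramFormatError",
    "Template",
    "HasseDiagram",
    "match_template",
    "shortlist_expandable",
    "canonical_hash",
    "graphs_isomorphic",
    "build_diagram",
    "most_specific_common",
    "serialize",
    "deserialize",
]

FORMAT_NAME = "rxnhasse-diagram"
FORMAT_VERSION = 1
DEFAULT_EMBEDDING_CAP = 256
_SUBSET_SEARCH_LIMIT = 12


class CenterConflictError(ValueError):
    """Input reactions do not share an isomorphic reaction center.

    This is also the mechanism by which faulty atom maps surface: a wrong
    map produces a unique, non-meaningful center that conflicts with the
    rest of the family.
    """

    def __init__(self, message: str, offending: list[str] | None = None):
        super().__init__(message)
        self.offending = offending or []


class DiagramFormatError(ValueError):
    """Raised when a serialized diagram cannot be loaded."""


# ---------------------------------------------------------------------------
# graph matching primitives
# ---------------------------------------------------------------------------

def _node_match(a: dict, b: dict) -> bool:
    return (
        a["element"] == b["element"]
        and a["charge_r"] == b["charge_r"]
        and a["charge_p"] == b["charge_p"]
        and a["arom_r"] == b["arom_r"]
        and a["arom_p"] == b["arom_p"]
    )


def _edge_match(a: dict, b: dict) -> bool:
    return a["order_r"] == b["order_r"] and a["order_p"] == b["order_p"]


def _node_label(d: dict) -> str:
    return f'{d["element"]}|{d["charge_r"]}|{d["charge_p"]}|{int(d["arom_r"])}|{int(d["arom_p"])}'


def _edge_label(d: dict) -> str:
    return f'{d["order_r"]:g}|{d["order_p"]:g}'


def canonical_hash(graph: nx.Graph) -> str:
    """Isomorphism-invariant hash over element, per-side charges and
    aromatic flags, and per-side bond orders (Weisfeiler-Lehman)."""
    h = nx.Graph()
    for n, d in graph.nodes(data=True):
        h.add_node(n, _l=_node_label(d))
    for a, b, d in graph.edges(data=True):
        h.add_edge(a, b, _l=_edge_label(d))
    return nx.weisfeiler_lehman_graph_hash(h, node_attr="_l", edge_attr="_l", iterations=4)


def graphs_isomorphic(g1: nx.Graph, g2: nx.Graph) -> bool:
    """Exact isomorphism under the template attribute semantics."""
    return nx.is_isomorphic(g1, g2, node_match=_node_match, edge_match=_edge_match)


def match_template(template: nx.Graph, its: nx.Graph,
                   cap: int = DEFAULT_EMBEDDING_CAP) -> list[dict]:
    """All embeddings (subgraph monomorphisms) of *template* into *its*.

    Each embedding maps template node -> ITS node and preserves element,
    per-side charges/aromatic flags and per-side bond orders.  At most
    *cap* embeddings are returned (with a warning when the cap is hit);
    an empty list means no match.
    """
    if template.number_of_nodes() == 0:
        return []
    gm = nx.algorithms.isomorphism.GraphMatcher(
        its, template, node_match=_node_match, edge_match=_edge_match
    )
    out: list[dict] = []
    for mapping in gm.subgraph_monomorphisms_iter():
        out.append({t: i for i, t in mapping.items()})
        if len(out) >= cap:
            logger.debug("embedding cap %d reached while matching template", cap)
            break
    return out


def shortlist_expandable(template: nx.Graph, embeddings_per_its: dict[int, tuple[nx.Graph, list[dict]]]) -> set:
    """Template atoms that have an unspecified (uncovered) neighbor in at
    least one embedding into at least one pseudo-molecule."""
    shortlist = set()
    for its, embeddings in embeddings_per_its.values():
        for emb in embeddings:
            covered = set(emb.values())
            for t_atom, its_atom in emb.items():
                if any(nb not in covered for nb in its.neighbors(its_atom)):
                    shortlist.add(t_atom)
    return shortlist


# ---------------------------------------------------------------------------
# diagram data model
# ---------------------------------------------------------------------------

@dataclass
class Template:
    """A node of the diagram: an ITS subgraph containing the root center.

    Leaves (``is_leaf``) are full input pseudo-molecules and additionally
    record the source reaction text and the canonical SMILES of their
    substrate (reactant-side) molecules.
    """

    id: int
    graph: nx.Graph
    parent: int | None = None
    children: list[int] = field(default_factory=list)
    depth: int = 0
    is_leaf: bool = False
    source: str | None = None
    substrate_smiles: list[str] = field(default_factory=list)
    product_smiles: list[str] = field(default_factory=list)
    # this template's own nodes corresponding to the sorted root-center
    # nodes, in order; lets queries stay anchored to one reaction site
    root_atoms: list = field(default_factory=list)


@dataclass
class HasseDiagram:
    """Rooted tree (or forest, for mutually exclusive centers) of templates
    with precomputed statistics used by the scoring functions."""

    mode: str  # "reaction" | "single_substrate"
    nodes: dict[int, Template] = field(default_factory=dict)
    root_ids: list[int] = field(default_factory=list)
    embedding_cap: int = DEFAULT_EMBEDDING_CAP
    # precomputed statistics
    pairwise_mean_similarity: float = 0.0
    min_edges_to_leaf: dict[int, int] = field(default_factory=dict)

    @property
    def root(self) -> Template:
        if len(self.root_ids) != 1:
            raise ValueError("diagram is a forest; no unique root")
        return self.nodes[self.root_ids[0]]

    @property
    def leaves(self) -> list[Template]:
        return [t for t in self.nodes.values() if t.is_leaf]

    def descendant_leaves(self, node_id: int) -> list[Template]:
        out, stack = [], [node_id]
        while stack:
            nid = stack.pop()
            t = self.nodes[nid]
            if t.is_leaf:
                out.append(t)
            stack.extend(t.children)
        return sorted(out, key=lambda t: t.id)

    def internal_nodes(self) -> list[Template]:
        return [t for t in self.nodes.values() if t.children or not t.is_leaf]

    def stats_summary(self) -> dict:
        depths = [t.depth for t in self.nodes.values()]
        return {
            "n_templates": sum(1 for t in self.nodes.values() if not t.is_leaf),
            "n_leaves": len(self.leaves),
            "max_depth": max(depths, default=0),
            "n_branch_points": sum(1 for t in self.nodes.values() if len(t.children) > 1),
            "mean_pairwise_similarity": self.pairwise_mean_similarity,
        }

    def text_tree(self) -> str:
        """Indented text rendering of the diagram."""
        lines: list[str] = []

        def walk(nid: int, indent: int) -> None:
            t = self.nodes[nid]
            kind = "leaf" if t.is_leaf else "template"
            label = f"[{t.id}] {kind}: {t.graph.number_of_nodes()} atoms"
            if t.is_leaf and t.substrate_smiles:
                label += "  substrates: " + ".".join(t.substrate_smiles)
            lines.append("  " * indent + label)
            for c in t.children:
                walk(c, indent + 1)

        for rid in self.root_ids:
            walk(rid, 0)
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def _ring_sets(graph: nx.Graph) -> list[frozenset]:
    return [frozenset(c) for c in nx.minimum_cycle_basis(graph)]


def _grow(its: nx.Graph, rings: list[frozenset], emb: dict, subset) -> nx.Graph:
    """Enlarge the embedded template by the full neighborhoods of the
    subset atoms (plus ring completion); returns the induced ITS subgraph
    on the enlarged atom set."""
    covered = set(emb.values())
    added: set = set()
    for t_atom in subset:
        its_atom = emb[t_atom]
        for nb in its.neighbors(its_atom):
            if nb not in covered:
                added.add(nb)
    # ring completion: an added ring atom pulls in its whole ring
    changed = True
    while changed:
        changed = False
        for ring in rings:
            if (ring & added) and not ring <= (covered | added):
                added |= set(ring) - covered
                changed = True
    return its.subgraph(covered | added).copy()


class _Builder:
    def __init__(self, its_list: list[nx.Graph], sources: list[str | None],
                 substrate_smiles: list[list[str]], product_smiles: list[list[str]],
                 mode: str, embedding_cap: int):
        self.its_list = its_list
        self.sources = sources
        self.substrate_smiles = substrate_smiles
        self.product_smiles = product_smiles
        self.mode = mode
        self.cap = embedding_cap
        self.rings = [_ring_sets(g) for g in its_list]
        self.diagram = HasseDiagram(mode=mode, embedding_cap=embedding_cap)
        self._next_id = 0

    def new_node(self, graph: nx.Graph, parent: int | None,
                 root_atoms: list | None = None) -> Template:
        t = Template(id=self._next_id, graph=graph, parent=parent,
                     root_atoms=list(root_atoms or []))
        self._next_id += 1
        if parent is not None:
            p = self.diagram.nodes[parent]
            p.children.append(t.id)
            t.depth = p.depth + 1
        self.diagram.nodes[t.id] = t
        return t

    def mark_leaf(self, t: Template, its_index: int) -> None:
        t.is_leaf = True
        t.source = self.sources[its_index]
        t.substrate_smiles = self.substrate_smiles[its_index]
        t.product_smiles = self.product_smiles[its_index]

    def _embeddings(self, template: nx.Graph, indices: list[int]) -> dict:
        out = {}
        for i in indices:
            embs = match_template(template, self.its_list[i], self.cap)
            if not embs:
                raise AssertionError(
                    "internal error: template no longer matches a pseudo-molecule"
                )
            out[i] = (self.its_list[i], embs)
        return out

    def expand(self, node_id: int, indices: list[int]) -> None:
        t = self.diagram.nodes[node_id]
        remaining = []
        for i in indices:
            its = self.its_list[i]
            if (
                its.number_of_nodes() == t.graph.number_of_nodes()
                and its.number_of_edges() == t.graph.number_of_edges()
            ):
                self.mark_leaf(t, i)
            else:
                remaining.append(i)
        if not remaining:
            return
        per_its = self._embeddings(t.graph, remaining)
        shortlist = sorted(shortlist_expandable(t.graph, per_its))
        if not shortlist:
            # template saturated but pseudo-molecules are larger (can only
            # happen for exotic non-induced roots); attach leaves directly
            for i in remaining:
                e = per_its[i][1][0]
                leaf = self.new_node(self.its_list[i], parent=t.id,
                                     root_atoms=[e[a] for a in t.root_atoms])
                self.mark_leaf(leaf, i)
            return

        if len(remaining) > 1 and len(shortlist) <= _SUBSET_SEARCH_LIMIT:
            found = self._common_expansion(per_its, shortlist, remaining)
        elif len(remaining) > 1:
            found = self._common_expansion_greedy(per_its, shortlist, remaining)
        else:
            found = None

        if len(remaining) == 1:
            # single pseudo-molecule: expand all shortlisted atoms, like a
            # diameter-based rule extraction
            i = remaining[0]
            its, embs = per_its[i]
            grown, e = min(
                ((_grow(its, self.rings[i], e, shortlist), e) for e in embs),
                key=lambda ge: (ge[0].number_of_nodes(), canonical_hash(ge[0])),
            )
            child = self.new_node(grown, parent=t.id,
                                  root_atoms=[e[a] for a in t.root_atoms])
            self.expand(child.id, remaining)
            return

        if found is not None:
            grown, e = found
            child = self.new_node(grown, parent=t.id,
                                  root_atoms=[e[a] for a in t.root_atoms])
            self.expand(child.id, remaining)
            return

        # no expansion applies to all pseudo-molecules: expand everything
        # per pseudo-molecule and branch
        groups: dict[str, list[int]] = {}
        grown_of: dict[int, tuple[nx.Graph, dict]] = {}
        for i in remaining:
            its, embs = per_its[i]
            best = None
            for e in embs:
                expandable = [
                    a for a in shortlist
                    if any(nb not in set(e.values()) for nb in its.neighbors(e[a]))
                ]
                g = _grow(its, self.rings[i], e, expandable)
                key = (g.number_of_nodes(), canonical_hash(g))
                if best is None or key < best[0]:
                    best = (key, g, e)
            grown_of[i] = (best[1], best[2])
            groups.setdefault(best[0][1], []).append(i)
        for h in sorted(groups):
            members = groups[h]
            g, e = grown_of[members[0]]
            child = self.new_node(g, parent=t.id,
                                  root_atoms=[e[a] for a in t.root_atoms])
            self.expand(child.id, members)

    def _common_expansion(self, per_its, shortlist, remaining):
        """Largest subset of shortlisted atoms with an identical enlarged
        template across all pseudo-molecules; ties favor fewer hydrogens.
        Returns ``(grown_graph, embedding_used)`` or ``None``."""
        for size in range(len(shortlist), 0, -1):
            candidates = []
            for subset in itertools.combinations(shortlist, size):
                found = self._subset_common(per_its, subset, remaining)
                if found is not None:
                    g, e = found
                    n_h = sum(1 for _, d in g.nodes(data=True) if d["is_h"])
                    candidates.append((n_h, canonical_hash(g), g, e))
            if candidates:
                candidates.sort(key=lambda c: (c[0], c[1]))
                return candidates[0][2], candidates[0][3]
        return None

    def _common_expansion_greedy(self, per_its, shortlist, remaining):
        """Fallback for very large shortlists: try the set of atoms whose
        single-atom expansions are individually common, then singletons."""
        singleton_ok = [
            a for a in shortlist
            if self._subset_common(per_its, (a,), remaining) is not None
        ]
        for subset in ([tuple(singleton_ok)] if len(singleton_ok) > 1 else []) + [
            (a,) for a in singleton_ok
        ]:
            found = self._subset_common(per_its, subset, remaining)
            if found is not None:
                return found
        return None

    def _subset_common(self, per_its, subset, remaining):
        """Common enlarged template for one subset across all
        pseudo-molecules, or ``None``; returns ``(graph, embedding)``."""
        achievable: dict[str, tuple[nx.Graph, dict]] | None = None
        for i in remaining:
            its, embs = per_its[i]
            here: dict[str, tuple[nx.Graph, dict]] = {}
            for e in embs:
                g = _grow(its, self.rings[i], e, subset)
                if g.number_of_nodes() > len(e):  # must actually grow
                    here.setdefault(canonical_hash(g), (g, e))
            achievable = here if achievable is None else {
                h: ge for h, ge in achievable.items() if h in here
            }
            if not achievable:
                return None
        best = sorted(
            (sum(1 for _, d in ge[0].nodes(data=True) if d["is_h"]), h, ge)
            for h, ge in achievable.items()
        )[0]
        return best[2]


def _dedupe(its_list, sources, substrates, products):
    seen: dict[str, int] = {}
    keep = []
    for i, g in enumerate(its_list):
        h = canonical_hash(g)
        if h in seen:
            logger.info("dropping duplicate reaction %r", sources[i])
            continue
        seen[h] = i
        keep.append(i)
    return (
        [its_list[i] for i in keep],
        [sources[i] for i in keep],
        [substrates[i] for i in keep],
        [products[i] for i in keep],
    )


def _mol_smiles_nomap(mol: Chem.Mol) -> str:
    m = Chem.Mol(mol)
    for a in m.GetAtoms():
        a.SetAtomMapNum(0)
    m = Chem.RemoveHs(m, sanitize=False)
    try:
        Chem.SanitizeMol(m)
    except Exception:
        pass
    return Chem.MolToSmiles(m)


def _parse_seed(seed: str) -> nx.Graph:
    params = Chem.SmilesParserParams()
    params.removeHs = False
    mol = Chem.MolFromSmiles(seed, params)
    if mol is None:
        raise ValueError(f"could not parse seed substructure {seed!r}")
    return its_mod.molecule_to_graph(mol, keys="index")


def _mcs_seed(mols: list[Chem.Mol]) -> nx.Graph:
    """Connected maximum common substructure over element + bond order."""
    res = rdFMCS.FindMCS(mols, timeout=30)
    if res.canceled or not res.smartsString:
        raise ValueError("maximum common substructure search failed")
    query = Chem.MolFromSmarts(res.smartsString)
    match = mols[0].GetSubstructMatch(query)
    if not match:
        raise ValueError("maximum common substructure does not match the first input")
    g = its_mod.molecule_to_graph(mols[0], keys="index").subgraph(match).copy()
    if not nx.is_connected(g):
        comp = max(nx.connected_components(g), key=lambda c: (len(c), sorted(c)))
        g = g.subgraph(comp).copy()
    return g


def build_diagram(
    inputs,
    mode: str = "reaction",
    seed: str | None = None,
    embedding_cap: int = DEFAULT_EMBEDDING_CAP,
    allow_multiple_centers: bool = False,
) -> HasseDiagram:
    """Build the extended Hasse diagram for a family of reactions or
    substrates.

    Parameters
    ----------
    inputs:
        In reaction mode, a list of :class:`AtomMappedReaction` (or
        prebuilt ITS graphs).  In single-substrate mode, a list of RDKit
        molecules with explicit hydrogens.
    mode:
        ``"reaction"`` (default) or ``"single_substrate"``.
    seed:
        Optional seed substructure (SMILES with explicit hydrogens) used as
        root in single-substrate mode instead of the maximum common
        substructure.
    allow_multiple_centers:
        When reaction centers fall into several mutually exclusive
        isomorphism classes, build one root per class (a forest) instead of
        raising :class:`CenterConflictError`.
    """
    if not inputs:
        raise ValueError("no inputs given")

    if mode == "reaction":
        its_list, sources, substrates, products = [], [], [], []
        for item in inputs:
            if isinstance(item, AtomMappedReaction):
                g = its_mod.build_its(item)
                its_list.append(g)
                sources.append(item.source_text)
                r_mols, p_mols = its_mod.its_fragment_to_sides(g)
                substrates.append(sorted(_mol_smiles_nomap(m) for m in r_mols))
                products.append(sorted(_mol_smiles_nomap(m) for m in p_mols))
            else:  # prebuilt ITS graph
                its_list.append(item)
                sources.append(None)
                r_mols, p_mols = its_mod.its_fragment_to_sides(item)
                substrates.append(sorted(_mol_smiles_nomap(m) for m in r_mols))
                products.append(sorted(_mol_smiles_nomap(m) for m in p_mols))
        its_list, sources, substrates, products = _dedupe(
            its_list, sources, substrates, products
        )
        centers = [its_mod.extract_reaction_center(g) for g in its_list]
        # group by center isomorphism class
        classes: list[tuple[nx.Graph, list[int]]] = []
        for i, c in enumerate(centers):
            for ref, members in classes:
                if graphs_isomorphic(ref, c):
                    members.append(i)
                    break
            else:
                classes.append((c, [i]))
        if len(classes) > 1 and not allow_multiple_centers:
            minority = sorted(classes, key=lambda x: len(x[1]))[:-1]
            offending = [
                sources[i] or f"input #{i}" for _, ms in minority for i in ms
            ]
            raise CenterConflictError(
                f"{len(classes)} distinct reaction centers found "
                "(possibly faulty atom maps); offending reactions: "
                + "; ".join(offending),
                offending=offending,
            )
    else:
        if mode != "single_substrate":
            raise ValueError(f"unknown mode {mode!r}")
        mols = [Chem.AddHs(m) for m in inputs]
        its_list = [its_mod.molecule_to_graph(m, keys="index") for m in mols]
        sources = [Chem.MolToSmiles(m) for m in mols]
        substrates = [[_mol_smiles_nomap(m)] for m in mols]
        products = [[] for _ in mols]
        its_list, sources, substrates, products = _dedupe(
            its_list, sources, substrates, products
        )
        root_graph = _parse_seed(seed) if seed else _mcs_seed(mols)
        for i, g in enumerate(its_list):
            if not match_template(root_graph, g, cap=1):
                raise CenterConflictError(
                    f"seed does not match substrate {sources[i]!r}",
                    offending=[sources[i]],
                )
        classes = [(root_graph, list(range(len(its_list))))]

    builder = _Builder(its_list, sources, substrates, products, mode, embedding_cap)
    for center, members in classes:
        root = builder.new_node(center.copy(), parent=None,
                                root_atoms=sorted(center.nodes))
        builder.diagram.root_ids.append(root.id)
        builder.expand(root.id, members)

    d = builder.diagram
    _precompute(d)
    return d


def _precompute(d: HasseDiagram) -> None:
    """Precompute per-template leaf distances and the mean pairwise
    substrate similarity used by the promiscuity score."""
    from .scoring import mean_pairwise_leaf_similarity  # local import, no cycle at module load

    dist: dict[int, int] = {}

    def walk(nid: int) -> int:
        t = d.nodes[nid]
        best = 0 if t.is_leaf else 10 ** 9
        for c in t.children:
            best = min(best, 1 + walk(c))
        dist[nid] = best
        return best

    for rid in d.root_ids:
        walk(rid)
    d.min_edges_to_leaf = dist
    d.pairwise_mean_similarity = mean_pairwise_leaf_similarity(d)


def most_specific_common(d: HasseDiagram) -> Template:
    """Deepest template that is an ancestor of every leaf: the last node
    before the first branch point (the root when branching is immediate)."""
    node = d.root
    while len(node.children) == 1:
        child = d.nodes[node.children[0]]
        if child.is_leaf:
            break
        node = child
    return node


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _graph_to_json(g: nx.Graph) -> dict:
    return {
        "nodes": [[n, d] for n, d in sorted(g.nodes(data=True))],
        "edges": [[a, b, d] for a, b, d in sorted(g.edges(data=True))],
    }


def _graph_from_json(obj: dict) -> nx.Graph:
    g = nx.Graph()
    for n, d in obj["nodes"]:
        g.add_node(n, **d)
    for a, b, d in obj["edges"]:
        g.add_edge(a, b, **d)
    return g


def serialize(d: HasseDiagram) -> str:
    """Lossless JSON text for a diagram, including precomputed statistics."""
    if not d.nodes:
        raise ValueError("cannot serialize an empty diagram")
    payload = {
        "format": FORMAT_NAME,
        "version": FORMAT_VERSION,
        "mode": d.mode,
        "embedding_cap": d.embedding_cap,
        "root_ids": d.root_ids,
        "pairwise_mean_similarity": d.pairwise_mean_similarity,
        "min_edges_to_leaf": {str(k): v for k, v in d.min_edges_to_leaf.items()},
        "nodes": [
            {
                "id": t.id,
                "parent": t.parent,
                "children": t.children,
                "depth": t.depth,
                "is_leaf": t.is_leaf,
                "source": t.source,
                "substrate_smiles": t.substrate_smiles,
                "product_smiles": t.product_smiles,
                "root_atoms": t.root_atoms,
                "graph": _graph_to_json(t.graph),
            }
            for t in sorted(d.nodes.values(), key=lambda t: t.id)
        ],
    }
    return json.dumps(payload, indent=1)


def deserialize(text: str) -> HasseDiagram:
    """Load a diagram from JSON text, validating format and tree shape."""
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise DiagramFormatError(f"not valid JSON: {exc}") from exc
    if payload.get("format") != FORMAT_NAME:
        raise DiagramFormatError("not a diagram file")
    if payload.get("version") != FORMAT_VERSION:
        raise DiagramFormatError(
            f"unsupported diagram version {payload.get('version')!r}"
        )
    d = HasseDiagram(
        mode=payload["mode"],
        embedding_cap=payload.get("embedding_cap", DEFAULT_EMBEDDING_CAP),
        root_ids=list(payload["root_ids"]),
        pairwise_mean_similarity=payload["pairwise_mean_similarity"],
        min_edges_to_leaf={int(k): v for k, v in payload["min_edges_to_leaf"].items()},
    )
    for nd in payload["nodes"]:
        d.nodes[nd["id"]] = Template(
            id=nd["id"],
            graph=_graph_from_json(nd["graph"]),
            parent=nd["parent"],
            children=list(nd["children"]),
            depth=nd["depth"],
            is_leaf=nd["is_leaf"],
            source=nd["source"],
            substrate_smiles=list(nd["substrate_smiles"]),
            product_smiles=list(nd["product_smiles"]),
            root_atoms=list(nd.get("root_atoms", [])),
        )
    _validate_tree(d)
    return d


def _validate_tree(d: HasseDiagram) -> None:
    if not d.nodes or not d.root_ids:
        raise DiagramFormatError("diagram has no nodes or no root")
    for t in d.nodes.values():
        if t.parent is None:
            if t.id not in d.root_ids:
                raise DiagramFormatError(f"node {t.id} has no parent and is not a root")
        else:
            p = d.nodes.get(t.parent)
            if p is None or t.id not in p.children:
                raise DiagramFormatError(f"broken parent link at node {t.id}")
            if t.depth != p.depth + 1:
                raise DiagramFormatError(f"depth of node {t.id} is not parent depth + 1")
    # reachability and acyclicity
    seen: set[int] = set()
    stack = list(d.root_ids)
    while stack:
        nid = stack.pop()
        if nid in seen:
            raise DiagramFormatError("cycle in parent/child relation")
        seen.add(nid)
        stack.extend(d.nodes[nid].children)
    if seen != set(d.nodes):
        raise DiagramFormatError("nodes unreachable from the root")
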