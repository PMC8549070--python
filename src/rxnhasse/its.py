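"""Imaginary transition structures (ITS) and reaction centers.

An ITS is the topological superposition of the reactants and products of a
balanced, atom-mapped reaction: one node per mapped atom, and one edge per
bond present on either side, carrying both a reactant-side and a
product-side bond order (0 = bond absent on that side).  It is a purely
graph-theoretic object, not a mechanistic transition state.

The ITS is stored as a ``networkx.Graph`` whose nodes are keyed by atom-map
number with attributes::

    element, is_h,
    charge_r, charge_p, hyb_r, hyb_p, rad_r, rad_p, arom_r, arom_p,
    changed            # any per-side node attribute differs

and whose edges carry ``order_r``, ``order_p`` (one of 0, 1, 1.5, 2, 3) and
``changed`` (order_r != order_p).  Aromatic bonds use order 1.5.

Molecules none of whose atoms change (spectators/reagents) are omitted from
the ITS.  The reaction center is the subgraph of changed atoms, changed
bonds, and unchanged bonds between changed atoms.
"""

from __future__ import annotations

import networkx as nx
from rdkit import Chem

from .reaction_io import AtomMappedReaction

__all__ = [
    "EmptyCenterError",
    "build_its",
    "extract_reaction_center",
    "radius_template",
    "its_fragment_to_sides",
    "molecule_to_graph",
    "graph_to_mol",
    "its_to_dot",
]


class EmptyCenterError(ValueError):
    """Raised for a reaction in which nothing changes (e.g. ``A>>A``)."""


_NODE_SIDE_ATTRS = ("charge", "hyb", "rad", "arom")


def _side_atom_attrs(atom: Chem.Atom) -> dict:
    return {
        "charge": atom.GetFormalCharge(),
        "hyb": str(atom.GetHybridization()),
        "rad": atom.GetNumRadicalElectrons(),
        "arom": atom.GetIsAromatic(),
    }


def _collect_side(mols: list[Chem.Mol]):
    """Per-side tables: map -> atom attrs, (map pair) -> order, map -> mol idx."""
    atoms: dict[int, dict] = {}
    bonds: dict[tuple[int, int], float] = {}
    mol_of: dict[int, int] = {}
    for idx, mol in enumerate(mols):
        for atom in mol.GetAtoms():
            num = atom.GetAtomMapNum()
            atoms[num] = {"element": atom.GetSymbol(), **_side_atom_attrs(atom)}
            mol_of[num] = idx
        for bond in mol.GetBonds():
            a = bond.GetBeginAtom().GetAtomMapNum()
            b = bond.GetEndAtom().GetAtomMapNum()
            key = (min(a, b), max(a, b))
            bonds[key] = bond.GetBondTypeAsDouble()
    return atoms, bonds, mol_of


def build_its(rxn: AtomMappedReaction) -> nx.Graph:
    """Superpose the two sides of a balanced mapped reaction into an ITS.

    Spectator molecules (no changed atom on either side) are omitted.
    Raises :class:`EmptyCenterError` when nothing at all changes.
    """
    r_atoms, r_bonds, r_mol_of = _collect_side(rxn.reactants)
    p_atoms, p_bonds, p_mol_of = _collect_side(rxn.products)
    if set(r_atoms) != set(p_atoms):
        raise ValueError("reaction is not balanced; build ITS from parsed reactions only")

    g = nx.Graph()
    for num in sorted(r_atoms):
        ra, pa = r_atoms[num], p_atoms[num]
        changed = any(ra[k] != pa[k] for k in _NODE_SIDE_ATTRS)
        g.add_node(
            num,
            element=ra["element"],
            is_h=ra["element"] == "H",
            changed=changed,
            **{f"{k}_r": ra[k] for k in _NODE_SIDE_ATTRS},
            **{f"{k}_p": pa[k] for k in _NODE_SIDE_ATTRS},
        )
    for key in sorted(set(r_bonds) | set(p_bonds)):
        order_r = r_bonds.get(key, 0.0)
        order_p = p_bonds.get(key, 0.0)
        # kekulization artifacts: alternating single/double inside a ring that
        # stays aromatic on both sides is not a real change
        if (
            order_r != order_p
            and {order_r, order_p} <= {1.0, 1.5, 2.0}
            and g.nodes[key[0]]["arom_r"] and g.nodes[key[0]]["arom_p"]
            and g.nodes[key[1]]["arom_r"] and g.nodes[key[1]]["arom_p"]
        ):
            order_r = order_p = 1.5
        g.add_edge(*key, order_r=order_r, order_p=order_p, changed=order_r != order_p)

    changed_nodes = {n for n, d in g.nodes(data=True) if d["changed"]}
    changed_edges = [e for e, d in g.edges.items() if d["changed"]]
    if not changed_nodes and not changed_edges:
        raise EmptyCenterError(
            f"reaction has no changed atoms or bonds: {rxn.source_text!r}"
        )

    # omit molecules contributing no changed atom and no changed bond
    center_nodes = set(changed_nodes)
    for a, b in changed_edges:
        center_nodes.update((a, b))
    keep_r = {r_mol_of[n] for n in center_nodes}
    keep_p = {p_mol_of[n] for n in center_nodes}
    keep_nodes = {
        n for n in g.nodes
        if r_mol_of[n] in keep_r or p_mol_of[n] in keep_p
    }
    return g.subgraph(keep_nodes).copy()


def extract_reaction_center(its: nx.Graph) -> nx.Graph:
    """The subgraph of changed atoms/bonds plus unchanged bonds between
    changed atoms.

    Endpoints of changed bonds are included as atoms even when their own
    attributes do not change.  Idempotent: the center of a center is itself.
    """
    changed_nodes = {n for n, d in its.nodes(data=True) if d["changed"]}
    changed_edges = [e for e, d in its.edges.items() if d["changed"]]
    nodes = set(changed_nodes)
    for a, b in changed_edges:
        nodes.update((a, b))

    center = nx.Graph()
    for n in sorted(nodes):
        center.add_node(n, **its.nodes[n])
    for a, b in changed_edges:
        center.add_edge(a, b, **its.edges[a, b])
    for a, b, d in its.edges(data=True):
        if not d["changed"] and a in changed_nodes and b in changed_nodes:
            center.add_edge(a, b, **d)
    return center


def radius_template(its: nx.Graph, r: int) -> nx.Graph:
    """Classic radius-based template: center plus all atoms within *r* bonds.

    Distances are graph distances on the ITS; the returned template is the
    induced subgraph on the included atoms (plus the center's own edges).
    ``r=0`` recovers the reaction center itself.
    """
    if r < 0:
        raise ValueError("radius must be nonnegative")
    center = extract_reaction_center(its)
    if r == 0:
        return center
    dist = nx.multi_source_dijkstra_path_length(its, set(center.nodes), weight=None)
    keep = {n for n, d in dist.items() if d <= r}
    tmpl = its.subgraph(keep).copy()
    return tmpl


def graph_to_mol(graph: nx.Graph, side: str) -> Chem.Mol:
    """Project one side (``'r'`` or ``'p'``) of an ITS-like graph to an
    RDKit molecule; edges with order 0 on that side are dropped.

    Atom map numbers are set to the node keys.  Sanitization is attempted
    but partial fragments are returned unsanitized rather than rejected.
    """
    order_key = f"order_{side}"
    rw = Chem.RWMol()
    index: dict[int, int] = {}
    for n in sorted(graph.nodes):
        d = graph.nodes[n]
        atom = Chem.Atom(d["element"])
        atom.SetFormalCharge(d[f"charge_{side}"])
        atom.SetNumRadicalElectrons(d[f"rad_{side}"])
        atom.SetIsAromatic(bool(d[f"arom_{side}"]))
        atom.SetAtomMapNum(n)
        atom.SetNoImplicit(True)
        index[n] = rw.AddAtom(atom)
    bond_types = {1.0: Chem.BondType.SINGLE, 1.5: Chem.BondType.AROMATIC,
                  2.0: Chem.BondType.DOUBLE, 3.0: Chem.BondType.TRIPLE}
    for a, b, d in graph.edges(data=True):
        order = d[order_key]
        if order:
            rw.AddBond(index[a], index[b], bond_types[order])
    mol = rw.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        Chem.SanitizeMol(
            mol,
            Chem.SanitizeFlags.SANITIZE_FINDRADICALS
            | Chem.SanitizeFlags.SANITIZE_SETCONJUGATION,
            catchErrors=True,
        )
    return mol


def its_fragment_to_sides(graph: nx.Graph) -> tuple[list[Chem.Mol], list[Chem.Mol]]:
    """Project an ITS subgraph onto its reactant- and product-side fragments.

    Returns two lists of molecules, one fragment per connected component of
    each side projection.  Projecting the full ITS of a reaction
    reconstructs the contributing reactant and product molecules.
    """
    out: list[list[Chem.Mol]] = []
    for side in ("r", "p"):
        mol = graph_to_mol(graph, side)
        if mol.GetNumAtoms() == 0:
            out.append([])
            continue
        frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
        out.append([Chem.Mol(f) for f in frags])
    return out[0], out[1]


def molecule_to_graph(mol: Chem.Mol, keys: str = "map") -> nx.Graph:
    """Encode a plain molecule as an ITS-like graph with identical
    reactant- and product-side attributes (used in single-substrate mode).

    ``keys='map'`` uses atom-map numbers as node keys (all atoms must be
    mapped); ``keys='index'`` uses RDKit atom indices.
    """
    g = nx.Graph()
    for atom in mol.GetAtoms():
        key = atom.GetAtomMapNum() if keys == "map" else atom.GetIdx()
        if keys == "map" and key == 0:
            raise ValueError("all atoms must be mapped when keys='map'")
        attrs = _side_atom_attrs(atom)
        g.add_node(
            key,
            element=atom.GetSymbol(),
            is_h=atom.GetAtomicNum() == 1,
            changed=False,
            **{f"{k}_r": attrs[k] for k in _NODE_SIDE_ATTRS},
            **{f"{k}_p": attrs[k] for k in _NODE_SIDE_ATTRS},
        )
    for bond in mol.GetBonds():
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        ka = a.GetAtomMapNum() if keys == "map" else a.GetIdx()
        kb = b.GetAtomMapNum() if keys == "map" else b.GetIdx()
        order = bond.GetBondTypeAsDouble()
        g.add_edge(ka, kb, order_r=order, order_p=order, changed=False)
    return g


def its_to_dot(graph: nx.Graph, name: str = "its") -> str:
    """DOT-text export; changed bonds are drawn dashed and red."""
    lines = [f"graph {name} {{"]
    for n, d in sorted(graph.nodes(data=True)):
        color = "red" if d.get("changed") else "black"
        lines.append(f'  {n} [label="{d["element"]}:{n}", color={color}];')
    for a, b, d in graph.edges(data=True):
        style = "dashed, color=red" if d.get("changed") else "solid"
        lines.append(
            f'  {a} -- {b} [label="{d["order_r"]:g}/{d["order_p"]:g}", style="{style}"];'
        )
    lines.append("}")
    return "\n".join(lines)
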