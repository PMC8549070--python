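"""Scoring of query reactions and substrates on a template diagram.

The score of a query on a diagram combines four components::

    score = c_S * S_S + c_P * S_P + c_M * S_M + c_L * S_L
          =       S_S -       S_P +       S_M - 0.1 * S_L   (defaults)

* ``S_S``: maximum Tanimoto similarity (Morgan fingerprints, radius 2,
  2048 bits, no feature invariants) between the query and the known
  substrates *within the matched branch* of the tree.
* ``S_P``: mean pairwise Tanimoto similarity between all substrates in the
  tree, capped at 0.8 — a specificity measure; ``1 - S_P`` estimates
  enzyme promiscuity.  A single-substrate tree scores the cap exactly.
* ``S_M``: mean Tanimoto similarity between the query and all known
  substrates in the whole tree.  A specific enzyme (large ``S_P``) demands
  a large ``S_M`` for the query to score well.
* ``S_L``: minimum number of tree edges from the deepest matching template
  to its closest descendant leaf, capped at 5, minus 1 (0 is ideal).

In reaction mode the similarity components are averaged over reactants and
products; in substrate mode only reactant molecules enter.  A query whose
reaction center does not occur in the tree scores 0 with null components.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from functools import lru_cache

import networkx as nx
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from rdkit import DataStructs

from . import its as its_mod
from .hasse import HasseDiagram, Template, match_template
from .reaction_io import AtomMappedReaction, parse_reaction_smiles

logger = logging.getLogger(__name__)

__all__ = [
    "SimilarityParams",
    "QueryResult",
    "tanimoto",
    "fingerprint",
    "s_location",
    "s_promiscuity",
    "mean_pairwise_leaf_similarity",
    "score_query_reaction",
    "score_query_substrate",
    "stereo_filter",
    "baseline_similarity_score",
]


@dataclass(frozen=True)
class SimilarityParams:
    """Fingerprint and scoring-function configuration.

    The defaults are the recommended operating point: Morgan radius 2,
    2048 bits, no feature invariants, Tanimoto similarity; promiscuity cap
    0.8; location cap 5; coefficients (+1, -1, +1, -0.1) for
    (S_S, S_P, S_M, S_L); classification threshold 0.5.
    """

    radius: int = 2
    n_bits: int = 2048
    use_features: bool = False
    promiscuity_cap: float = 0.8
    location_cap: int = 5
    coef_s: float = 1.0
    coef_p: float = -1.0
    coef_m: float = 1.0
    coef_l: float = -0.1
    embedding_cap: int = 256
    threshold: float = 0.5

    def __post_init__(self):
        if self.radius <= 0 or self.n_bits <= 0:
            raise ValueError("fingerprint radius and length must be positive")
        if self.promiscuity_cap <= 0 or self.location_cap <= 0:
            raise ValueError("caps must be positive")


DEFAULT_PARAMS = SimilarityParams()


@dataclass
class QueryResult:
    """One scored candidate: total score, its four components, the matched
    template, and any proposed products/cosubstrates."""

    score: float
    s_s: float | None = None
    s_p: float | None = None
    s_m: float | None = None
    s_l: int | None = None
    template_id: int | None = None
    candidate_its: nx.Graph | None = None
    products: list[str] = field(default_factory=list)
    cosubstrates: list[str] = field(default_factory=list)
    branch_leaf_ids: list[int] = field(default_factory=list)
    matched_atoms: tuple = ()
    # root-atom position (in sorted root-node order) -> (query mol index,
    # atom index); used by the stereo filter
    root_to_query: dict = field(default_factory=dict)
    stereo_conflict: bool = False
    note: str = ""


# ---------------------------------------------------------------------------
# fingerprints
# ---------------------------------------------------------------------------

@lru_cache(maxsize=16)
def _generator(radius: int, n_bits: int, use_features: bool):
    if use_features:
        inv = rdFingerprintGenerator.GetMorganFeatureAtomInvGen()
        return rdFingerprintGenerator.GetMorganGenerator(
            radius=radius, fpSize=n_bits, atomInvariantsGenerator=inv
        )
    return rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)


@lru_cache(maxsize=100_000)
def _fp_from_smiles(smiles: str, radius: int, n_bits: int, use_features: bool):
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumAtoms() == 0:
        raise ValueError(f"cannot fingerprint {smiles!r}")
    return _generator(radius, n_bits, use_features).GetFingerprint(mol)


def _as_smiles(m) -> str:
    if isinstance(m, str):
        return m
    mol = Chem.Mol(m)
    for a in mol.GetAtoms():
        a.SetAtomMapNum(0)
    mol = Chem.RemoveHs(mol, sanitize=False)
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        pass
    return Chem.MolToSmiles(mol)


def fingerprint(mol, params: SimilarityParams = DEFAULT_PARAMS):
    """Morgan bit-vector fingerprint of a molecule (Mol or SMILES)."""
    return _fp_from_smiles(_as_smiles(mol), params.radius, params.n_bits,
                           params.use_features)


def tanimoto(a, b, params: SimilarityParams = DEFAULT_PARAMS) -> float:
    """Tanimoto similarity between the Morgan fingerprints of two
    molecules (symmetric; 1.0 for identical canonical structures)."""
    return DataStructs.TanimotoSimilarity(fingerprint(a, params), fingerprint(b, params))


# ---------------------------------------------------------------------------
# similarity over molecule sets
# ---------------------------------------------------------------------------

def _side_similarity(query: list[str], known: list[str], params) -> float:
    """Pair each query molecule with its most similar counterpart and
    average over the query molecules."""
    if not query or not known:
        return 0.0
    return sum(max(tanimoto(q, k, params) for k in known) for q in query) / len(query)


def _set_similarity(a: list[str], b: list[str], params) -> float:
    """Symmetrized best-pairing similarity between two molecule sets."""
    if not a or not b:
        return 0.0
    return 0.5 * (_side_similarity(a, b, params) + _side_similarity(b, a, params))


def _leaf_similarity(q_subs: list[str], q_prods: list[str] | None,
                     leaf: Template, params) -> float:
    """Query-vs-leaf similarity: substrate side only, or averaged over
    reactants and products when the query has products."""
    s = _side_similarity(q_subs, leaf.substrate_smiles, params)
    if q_prods is None:
        return s
    p = _side_similarity(q_prods, leaf.product_smiles, params)
    return 0.5 * (s + p)


def mean_pairwise_leaf_similarity(d: HasseDiagram,
                                  params: SimilarityParams = DEFAULT_PARAMS) -> float:
    """Mean substrate similarity over unordered distinct leaf pairs
    (uncapped); defined as 1.0 for a tree with fewer than two leaves."""
    leaves = d.leaves
    if len(leaves) < 2:
        return 1.0
    sims = [
        _set_similarity(a.substrate_smiles, b.substrate_smiles, params)
        for a, b in itertools.combinations(leaves, 2)
    ]
    return sum(sims) / len(sims)


def s_promiscuity(d: HasseDiagram, params: SimilarityParams = DEFAULT_PARAMS) -> float:
    """Specificity score S_P: mean pairwise substrate similarity capped at
    ``promiscuity_cap`` (0.8); single-leaf trees score the cap exactly."""
    return min(d.pairwise_mean_similarity, params.promiscuity_cap)


def s_location(d: HasseDiagram, template: Template | int,
               params: SimilarityParams = DEFAULT_PARAMS) -> int:
    """Location score S_L: edges from the matched template to its closest
    descendant leaf, capped at ``location_cap``, minus 1 (floor 0)."""
    tid = template.id if isinstance(template, Template) else template
    dist = d.min_edges_to_leaf[tid]
    return max(0, min(dist, params.location_cap) - 1)


def baseline_similarity_score(known: list, query, params: SimilarityParams = DEFAULT_PARAMS) -> float:
    """Plain maximum Tanimoto similarity of the query to all known
    substrates — the conventional similarity baseline."""
    if not known:
        raise ValueError("no known substrates")
    return max(tanimoto(query, k, params) for k in known)


# ---------------------------------------------------------------------------
# template descent
# ---------------------------------------------------------------------------

def _anchored_embeddings(t: Template, query: nx.Graph, anchor: list | None,
                         cap: int) -> list[dict]:
    embs = match_template(t.graph, query, cap)
    if anchor is None:
        return embs
    ra = t.root_atoms
    return [e for e in embs if [e[a] for a in ra] == anchor]


def _deepest_matching_template(d: HasseDiagram, query: nx.Graph,
                               anchor: list | None = None,
                               cap: int = 256) -> Template | None:
    """Deepest internal template embedding into the query ITS (optionally
    anchored: root atoms must map onto the given query atoms, in order)."""
    best: Template | None = None
    stack = list(d.root_ids)
    while stack:
        t = d.nodes[stack.pop()]
        if t.is_leaf and not t.children:
            continue  # leaves are not match targets
        if not _anchored_embeddings(t, query, anchor, cap):
            continue
        if best is None or (t.depth, -t.id) > (best.depth, -best.id):
            best = t
        stack.extend(t.children)
    return best


def _components(d: HasseDiagram, t: Template, q_subs: list[str],
                q_prods: list[str] | None, params) -> tuple:
    branch = d.descendant_leaves(t.id)
    all_leaves = d.leaves
    s_s = max(_leaf_similarity(q_subs, q_prods, leaf, params) for leaf in branch)
    s_m = sum(_leaf_similarity(q_subs, q_prods, leaf, params) for leaf in all_leaves) / len(all_leaves)
    s_p = s_promiscuity(d, params)
    s_l = s_location(d, t, params)
    score = (params.coef_s * s_s + params.coef_p * s_p
             + params.coef_m * s_m + params.coef_l * s_l)
    return score, s_s, s_p, s_m, s_l, [leaf.id for leaf in branch]


# ---------------------------------------------------------------------------
# reaction queries
# ---------------------------------------------------------------------------

def score_query_reaction(d: HasseDiagram, query,
                         params: SimilarityParams = DEFAULT_PARAMS) -> QueryResult:
    """Score a full query reaction against a reaction-mode diagram.

    *query* may be an :class:`AtomMappedReaction`, a mapped reaction-SMILES
    line, or a prebuilt ITS graph.  Returns a zero score with null
    components when the query's reaction center never occurs in the tree.
    """
    if d.mode != "reaction":
        raise ValueError("reaction queries require a reaction-mode diagram")
    if isinstance(query, str):
        query = parse_reaction_smiles(query)
    if isinstance(query, AtomMappedReaction):
        query_its = its_mod.build_its(query)
    else:
        query_its = query
    t = _deepest_matching_template(d, query_its, cap=params.embedding_cap)
    if t is None:
        return QueryResult(score=0.0, note="reaction center not found in tree")
    r_mols, p_mols = its_mod.its_fragment_to_sides(query_its)
    q_subs = [_as_smiles(m) for m in r_mols]
    q_prods = [_as_smiles(m) for m in p_mols]
    score, s_s, s_p, s_m, s_l, branch = _components(d, t, q_subs, q_prods, params)
    return QueryResult(
        score=score, s_s=s_s, s_p=s_p, s_m=s_m, s_l=s_l,
        template_id=t.id, candidate_its=query_its,
        products=q_prods, branch_leaf_ids=branch,
    )


# ---------------------------------------------------------------------------
# substrate queries
# ---------------------------------------------------------------------------

def _fragment_node_match(a: dict, b: dict) -> bool:
    return (
        a["element"] == b["element"]
        and a["charge_r"] == b["charge_r"]
        and a["arom_r"] == b["arom_r"]
    )


def _fragment_edge_match(a: dict, b: dict) -> bool:
    return a["order_r"] == b["order_r"]


def _match_fragment(fragment: nx.Graph, molgraph: nx.Graph, cap: int) -> list[dict]:
    """Embeddings of a reactant-side template fragment into a plain
    molecule graph, comparing reactant-side attributes only."""
    gm = nx.algorithms.isomorphism.GraphMatcher(
        molgraph, fragment,
        node_match=_fragment_node_match, edge_match=_fragment_edge_match,
    )
    out = []
    for mapping in gm.subgraph_monomorphisms_iter():
        out.append({t: i for i, t in mapping.items()})
        if len(out) >= cap:
            break
    return out


def _root_reactant_fragments(root: Template) -> list[nx.Graph]:
    """Connected reactant-side fragments of the minimal template.

    Edges existing only on the product side are dropped; each connected
    component (one per reacting molecule) is returned separately.
    """
    r_graph = nx.Graph()
    for n, dd in root.graph.nodes(data=True):
        r_graph.add_node(n, **dd)
    for a, b, dd in root.graph.edges(data=True):
        if dd["order_r"]:
            r_graph.add_edge(a, b, **dd)
    return [r_graph.subgraph(c).copy() for c in
            sorted(nx.connected_components(r_graph), key=lambda c: sorted(c))]


def _unique_leaf_substrates(d: HasseDiagram) -> list[str]:
    seen: set[str] = set()
    out = []
    for leaf in d.leaves:
        for smi in leaf.substrate_smiles:
            if smi not in seen:
                seen.add(smi)
                out.append(smi)
    return out


def _build_candidate_its(root: Template, hosts: list[nx.Graph],
                         assignments: list[tuple[int, dict]]) -> tuple[nx.Graph, list, dict]:
    """Assemble a candidate ITS from host molecule graphs and per-fragment
    embeddings (fragment template node -> host node).

    Returns the ITS, the root-anchor (query atoms matched by the sorted
    root atoms) and a map root node -> (host index, host atom).
    """
    its = nx.Graph()
    offset: list[dict] = []
    key = 0
    for host in hosts:
        table = {}
        for n in sorted(host.nodes):
            its.add_node(key, **host.nodes[n])
            table[n] = key
            key += 1
        for a, b, dd in host.edges(data=True):
            its.add_edge(table[a], table[b], **dict(dd))
        offset.append(table)

    combined: dict[int, int] = {}  # root node -> its node
    root_to_host: dict[int, tuple[int, int]] = {}
    for host_idx, emb in assignments:
        for t_node, h_node in emb.items():
            combined[t_node] = offset[host_idx][h_node]
            root_to_host[t_node] = (host_idx, h_node)

    # overlay product-side attributes and per-side bond orders of the root
    for t_node, its_node in combined.items():
        src = root.graph.nodes[t_node]
        dst = its.nodes[its_node]
        for k in ("charge", "hyb", "rad", "arom"):
            dst[f"{k}_p"] = src[f"{k}_p"]
        dst["changed"] = any(dst[f"{k}_r"] != dst[f"{k}_p"] for k in ("charge", "hyb", "rad", "arom"))
    for a, b, dd in root.graph.edges(data=True):
        u, v = combined[a], combined[b]
        if its.has_edge(u, v):
            its.edges[u, v]["order_p"] = dd["order_p"]
            its.edges[u, v]["changed"] = its.edges[u, v]["order_r"] != dd["order_p"]
        else:
            its.add_edge(u, v, order_r=dd["order_r"], order_p=dd["order_p"],
                         changed=dd["order_r"] != dd["order_p"])
    anchor = [combined[n] for n in sorted(root.graph.nodes)]
    return its, anchor, root_to_host


def score_query_substrate(d: HasseDiagram, substrates,
                          search_cosubstrates: bool = True,
                          params: SimilarityParams = DEFAULT_PARAMS) -> list[QueryResult]:
    """Score substrate(s) with unknown products against a diagram.

    Enumerates every embedding of the minimal template's reactant
    fragments in the query substrate(s) — each distinct site is one
    regiochemical candidate — completes missing reactant fragments with
    cosubstrates found among the tree's leaves (one candidate per distinct
    cosubstrate), assembles the candidate ITS, derives its products, and
    scores each candidate independently.  With ``search_cosubstrates``
    off, a missing cosubstrate yields a single zero-score result.

    On a single-substrate-mode diagram only one substrate is accepted and
    scoring is similarity-only (no products or cosubstrates).
    """
    if isinstance(substrates, (str, Chem.Mol)):
        substrates = [substrates]
    mols = []
    for s in substrates:
        mol = Chem.MolFromSmiles(s) if isinstance(s, str) else Chem.Mol(s)
        if mol is None:
            raise ValueError(f"could not parse substrate {s!r}")
        mols.append(Chem.AddHs(mol))

    if d.mode == "single_substrate":
        return _score_substrate_on_substrate_tree(d, mols, params)

    root = d.root
    fragments = _root_reactant_fragments(root)
    molgraphs = [its_mod.molecule_to_graph(m, keys="index") for m in mols]

    # which query molecule hosts which fragment
    frag_sites: list[list[tuple[int, dict]]] = []
    for frag in fragments:
        sites: list[tuple[int, dict]] = []
        for qi, g in enumerate(molgraphs):
            seen_sites: set[frozenset] = set()
            for emb in _match_fragment(frag, g, params.embedding_cap):
                site = frozenset(emb.values())
                if site not in seen_sites:  # drop fragment-automorphism copies
                    seen_sites.add(site)
                    sites.append((qi, emb))
        frag_sites.append(sites)

    if all(not s for s in frag_sites):
        return []

    missing = [i for i, s in enumerate(frag_sites) if not s]
    if missing and not search_cosubstrates:
        return [QueryResult(score=0.0, note="missing cosubstrate")]

    # cosubstrate proposal: any distinct leaf substrate containing the
    # missing fragment is an eligible partner
    cosub_options: dict[int, list[tuple[str, nx.Graph, dict]]] = {}
    for i in missing:
        options = []
        for smi in _unique_leaf_substrates(d):
            mol = Chem.AddHs(Chem.MolFromSmiles(smi))
            g = its_mod.molecule_to_graph(mol, keys="index")
            embs = _match_fragment(fragments[i], g, params.embedding_cap)
            if embs:
                options.append((smi, g, embs[0]))
        if not options:
            return [QueryResult(score=0.0, note="no cosubstrate found in tree")]
        cosub_options[i] = options

    results: list[QueryResult] = []
    covered_choices = [frag_sites[i] if i not in missing else [None]
                       for i in range(len(fragments))]
    for choice in itertools.product(*covered_choices):
        # each query molecule may host at most one fragment
        hosts_used = [qi for c in choice if c is not None for qi in [c[0]]]
        if len(set(hosts_used)) != len(hosts_used):
            continue
        cos_lists = [cosub_options[i] for i in missing]
        for cos_choice in itertools.product(*cos_lists) if missing else [()]:
            hosts: list[nx.Graph] = list(molgraphs)
            host_is_query = [True] * len(molgraphs)
            assignments: list[tuple[int, dict]] = []
            cosubs: list[str] = []
            for i, c in enumerate(choice):
                if c is not None:
                    assignments.append((c[0], c[1]))
            for (smi, g, emb) in cos_choice:
                hosts.append(g)
                host_is_query.append(False)
                cosubs.append(smi)
                assignments.append((len(hosts) - 1, emb))
            cand_its, anchor, root_to_host = _build_candidate_its(
                root, hosts, assignments
            )
            t = _deepest_matching_template(d, cand_its, anchor=anchor,
                                           cap=params.embedding_cap)
            if t is None:
                results.append(QueryResult(score=0.0, cosubstrates=cosubs,
                                           note="candidate matches no template"))
                continue
            _, p_mols = its_mod.its_fragment_to_sides(cand_its)
            q_prods = [_as_smiles(m) for m in p_mols]
            q_subs = [_as_smiles(m) for m in mols] + cosubs
            score, s_s, s_p, s_m, s_l, branch = _components(
                d, t, q_subs, q_prods, params
            )
            matched = tuple(sorted(
                (hi, a) for hi, a in (
                    root_to_host[n] for n in root.graph.nodes
                ) if host_is_query[hi]
            ))
            rtq = {
                pos: root_to_host[n]
                for pos, n in enumerate(sorted(root.graph.nodes))
                if host_is_query[root_to_host[n][0]]
            }
            results.append(QueryResult(
                score=score, s_s=s_s, s_p=s_p, s_m=s_m, s_l=s_l,
                template_id=t.id, candidate_its=cand_its, products=q_prods,
                cosubstrates=cosubs, branch_leaf_ids=branch,
                matched_atoms=matched, root_to_query=rtq,
            ))
    results.sort(key=lambda r: -r.score)
    results = stereo_filter(results, d, mols)
    return results


def _score_substrate_on_substrate_tree(d: HasseDiagram, mols, params) -> list[QueryResult]:
    if len(mols) != 1:
        raise ValueError("single-substrate-mode diagrams accept exactly one query substrate")
    g = its_mod.molecule_to_graph(mols[0], keys="index")
    root = d.root
    seen_sites: set[frozenset] = set()
    results = []
    for emb in match_template(root.graph, g, cap=params.embedding_cap):
        site = frozenset(emb.values())
        if site in seen_sites:
            continue
        seen_sites.add(site)
        anchor = [emb[n] for n in sorted(root.graph.nodes)]
        t = _deepest_matching_template(d, g, anchor=anchor, cap=params.embedding_cap)
        if t is None:
            continue
        q_subs = [_as_smiles(mols[0])]
        score, s_s, s_p, s_m, s_l, branch = _components(d, t, q_subs, None, params)
        results.append(QueryResult(
            score=score, s_s=s_s, s_p=s_p, s_m=s_m, s_l=s_l,
            template_id=t.id, branch_leaf_ids=branch,
            matched_atoms=tuple(sorted((0, a) for a in site)),
        ))
    results.sort(key=lambda r: -r.score)
    return results


# ---------------------------------------------------------------------------
# stereo filtering
# ---------------------------------------------------------------------------

def _cip_codes(mol: Chem.Mol) -> dict[int, str]:
    """Atom index -> CIP code for atoms with assigned stereocenters."""
    m = Chem.Mol(mol)
    Chem.AssignStereochemistry(m, cleanIt=True, force=True)
    return {
        a.GetIdx(): a.GetPropsAsDict().get("_CIPCode")
        for a in m.GetAtoms()
        if a.HasProp("_CIPCode")
    }


def stereo_filter(candidates: list[QueryResult], d: HasseDiagram,
                  query_mols: list[Chem.Mol] | None = None) -> list[QueryResult]:
    """Flag candidates whose stereocenters at root-matched atoms contradict
    every known leaf.

    Templates are achiral, so stereochemistry is only compared here: for
    each root atom matched onto a query stereocenter, the CIP code is
    compared with the codes of the corresponding atoms in every leaf
    reaction that specifies one.  A candidate is flagged (kept, not
    removed) only when at least one leaf specifies a code and none agrees.
    """
    if query_mols is None:
        return candidates
    query_cips = [_cip_codes(m) for m in query_mols]
    if not any(query_cips):
        return candidates

    # per leaf: root atom position -> CIP code, from the mapped source text
    leaf_codes: list[dict[int, str]] = []
    for leaf in d.leaves:
        if not leaf.source or not leaf.root_atoms:
            continue
        try:
            rxn = parse_reaction_smiles(leaf.source)
        except Exception:
            continue
        codes: dict[int, str] = {}
        for mol in rxn.reactants:
            cips = _cip_codes(mol)
            for atom in mol.GetAtoms():
                if atom.GetIdx() in cips and atom.GetAtomMapNum() in leaf.root_atoms:
                    pos = leaf.root_atoms.index(atom.GetAtomMapNum())
                    codes[pos] = cips[atom.GetIdx()]
        if codes:
            leaf_codes.append(codes)
    if not leaf_codes:
        return candidates

    out = []
    for cand in candidates:
        conflict = (
            cand.template_id is not None
            and _candidate_conflicts(cand, query_cips, leaf_codes)
        )
        out.append(replace(cand, stereo_conflict=True) if conflict else cand)
    return out


def _candidate_conflicts(cand: QueryResult,
                         query_cips: list[dict[int, str]],
                         leaf_codes: list[dict[int, str]]) -> bool:
    for pos, (host, atom_idx) in cand.root_to_query.items():
        q_code = query_cips[host].get(atom_idx) if host < len(query_cips) else None
        if q_code is None:
            continue
        specified = [codes[pos] for codes in leaf_codes if pos in codes]
        if specified and all(code != q_code for code in specified):
            return True
    return False
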