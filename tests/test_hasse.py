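"""Diagram construction: expansion, branching, invariants, serialization."""

import itertools

import pytest

import rxnhasse as rh
from rxnhasse import families
from rxnhasse.hasse import (
    CenterConflictError,
    DiagramFormatError,
    canonical_hash,
    graphs_isomorphic,
    match_template,
    most_specific_common,
    shortlist_expandable,
)
from rxnhasse.its import extract_reaction_center
from conftest import family_diagram


class TestMatchTemplate:
    def test_center_matches_its_own_its(self, lyase_reactions):
        for rxn in lyase_reactions:
            its = rh.build_its(rxn)
            center = extract_reaction_center(its)
            assert match_template(center, its)

    def test_symmetric_diol_center_matches_twice(self):
        spec = families.FamilySpec(n_reactions=1, depth=1, seed=0,
                                   conserved=((0, 0, "H"), (0, 1, "H")))
        rxn = families.generate_family(spec)[0]
        its = rh.build_its(rxn)
        center = extract_reaction_center(its)
        # a symmetric diol undergoing the same oxidation on either end
        line = (
            "[O:1]([H:2])[C:3]([H:4])([C:20]([H:21])([H:22])[H:23])"
            "[C:5]([H:6])([H:7])"
            "[C:8]([H:9])([C:24]([H:25])([H:26])[H:27])[O:10][H:11]"
            ">>[O:1]=[C:3]([C:20]([H:21])([H:22])[H:23])[C:5]([H:6])([H:7])"
            "[C:8]([H:9])([C:24]([H:25])([H:26])[H:27])[O:10][H:11].[H:2][H:4]"
        )
        diol_its = rh.build_its(rh.parse_reaction_smiles(line))
        # center demands the transformed site; matching the template's
        # reactant fragment alone finds both oxidizable sites
        from rxnhasse.scoring import _match_fragment, _root_reactant_fragments
        from rxnhasse.hasse import Template
        from rxnhasse.its import molecule_to_graph
        from rdkit import Chem

        frag = _root_reactant_fragments(Template(id=0, graph=center))[0]
        diol = Chem.AddHs(Chem.MolFromSmiles("CC(O)CC(C)O"))
        sites = {
            frozenset(e.values())
            for e in _match_fragment(frag, molecule_to_graph(diol, keys="index"), 64)
        }
        assert len(sites) == 2

    def test_wrong_element_never_matches(self, lyase_reactions):
        its = rh.build_its(lyase_reactions[0])
        center = extract_reaction_center(its).copy()
        some_node = sorted(center.nodes)[0]
        center.nodes[some_node]["element"] = "N"
        assert match_template(center, its) == []


class TestShortlist:
    def test_lactate_center_expands_only_at_carbinol_carbon(self, lactate_reaction):
        its = rh.build_its(lactate_reaction)
        center = extract_reaction_center(its)
        embs = match_template(center, its)
        shortlist = shortlist_expandable(center, {0: (its, embs)})
        assert shortlist == {5}  # the carbinol carbon

    def test_full_its_has_empty_shortlist(self, lactate_reaction):
        its = rh.build_its(lactate_reaction)
        embs = match_template(its, its)
        assert shortlist_expandable(its, {0: (its, embs)}) == set()


class TestBuildDiagram:
    def test_lyase_chain_and_branches(self, lyase_diagram):
        d = lyase_diagram
        chain = [d.root]
        while len(chain[-1].children) == 1 and not d.nodes[chain[-1].children[0]].is_leaf:
            chain.append(d.nodes[chain[-1].children[0]])
        assert len(chain) == 4  # center + three conserved expansions
        msc = most_specific_common(d)
        assert msc.id == chain[-1].id
        kids = [d.nodes[c] for c in msc.children]
        assert len(kids) == 3
        assert sum(k.is_leaf for k in kids) == 2

    def test_single_reaction_gives_linear_chain(self, lactate_reaction):
        d = rh.build_diagram([lactate_reaction])
        assert all(len(t.children) <= 1 for t in d.nodes.values())
        assert len(d.leaves) == 1

    def test_two_reactions_differing_at_frontier_branch(self):
        specs = [
            families.FamilySpec(n_reactions=1, depth=1, seed=0,
                                conserved=((0, 0, sub), (0, 1, "C")))
            for sub in ("F", "Cl")
        ]
        rxns = [families.generate_family(s)[0] for s in specs]
        d = rh.build_diagram(rxns)
        branch_points = [t for t in d.nodes.values() if len(t.children) == 2]
        assert len(branch_points) == 1
        children = [d.nodes[c] for c in branch_points[0].children]
        its_list = [rh.build_its(r) for r in rxns]
        for child in children:
            n_matched = sum(bool(match_template(child.graph, g)) for g in its_list)
            assert n_matched == 1

    def test_duplicates_collapse_to_one_leaf(self, lactate_reaction):
        d = rh.build_diagram([lactate_reaction, lactate_reaction])
        assert len(d.leaves) == 1

    def test_center_conflict_reports_offender(self, lyase_reactions, lactate_reaction):
        with pytest.raises(CenterConflictError) as exc:
            rh.build_diagram(lyase_reactions + [lactate_reaction])
        assert exc.value.offending

    def test_mutually_exclusive_centers_build_forest(self, lyase_reactions, lactate_reaction):
        d = rh.build_diagram(lyase_reactions + [lactate_reaction],
                             allow_multiple_centers=True)
        assert len(d.root_ids) == 2
        assert len(d.leaves) == 4

    def test_seeded_single_substrate_root(self):
        from rdkit import Chem

        mols = [Chem.MolFromSmiles(s) for s in ["CC(O)C(=O)O", "CCC(O)C"]]
        d = rh.build_diagram(mols, mode="single_substrate", seed="C([H])O[H]")
        root = d.root.graph
        assert sorted(root.nodes[n]["element"] for n in root.nodes) == ["C", "H", "H", "O"]

    def test_mcs_seed_when_none_given(self):
        from rdkit import Chem

        mols = [Chem.MolFromSmiles(s) for s in ["CCO", "CCCO", "CC(C)O"]]
        d = rh.build_diagram(mols, mode="single_substrate")
        # the shared ethanol backbone is the common substructure
        elements = sorted(
            d.root.graph.nodes[n]["element"] for n in d.root.graph.nodes
        )
        assert elements.count("C") >= 2 and "O" in elements


class TestDiagramInvariants:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_every_leaf_contains_every_ancestor(self, seed):
        d = family_diagram(n=3, depth=2, seed=seed)
        for leaf in d.leaves:
            node = leaf
            while node.parent is not None:
                node = d.nodes[node.parent]
                assert match_template(node.graph, leaf.graph)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_atom_counts_strictly_increase_along_paths(self, seed):
        d = family_diagram(n=3, depth=2, seed=seed)
        for t in d.nodes.values():
            for c in t.children:
                assert (
                    d.nodes[c].graph.number_of_nodes() > t.graph.number_of_nodes()
                )
                assert d.nodes[c].depth == t.depth + 1

    def test_below_branch_templates_exclude_outside_leaves(self, lyase_diagram):
        d = lyase_diagram
        msc = most_specific_common(d)
        below = [d.nodes[c] for c in msc.children if not d.nodes[c].is_leaf]
        for t in below:
            inside = {leaf.id for leaf in d.descendant_leaves(t.id)}
            outside = [leaf for leaf in d.leaves if leaf.id not in inside]
            assert outside
            assert any(not match_template(t.graph, leaf.graph) for leaf in outside)

    def test_deterministic_rebuild_is_byte_identical(self, lyase_reactions):
        a = rh.serialize(rh.build_diagram(lyase_reactions))
        b = rh.serialize(rh.build_diagram(lyase_reactions))
        assert a == b


class TestMostSpecificCommon:
    def test_single_reaction_msc_is_leaf_parent(self, lactate_reaction):
        d = rh.build_diagram([lactate_reaction])
        msc = most_specific_common(d)
        leaf = d.leaves[0]
        assert leaf.parent == msc.id or leaf.id == msc.id

    def test_immediate_branching_returns_root(self):
        specs = [
            families.FamilySpec(n_reactions=1, depth=1, seed=0,
                                conserved=((0, 0, s1), (0, 1, s2)))
            for s1, s2 in (("F", "F"), ("Cl", "Cl"))
        ]
        rxns = [families.generate_family(s)[0] for s in specs]
        d = rh.build_diagram(rxns)
        msc = most_specific_common(d)
        # conserved shell = methyl + carbinol side, then split
        assert msc.id == d.root.id or len(msc.children) > 1


class TestSerialization:
    def test_round_trip_preserves_everything(self, lyase_diagram):
        text = rh.serialize(lyase_diagram)
        d2 = rh.deserialize(text)
        assert rh.serialize(d2) == text
        assert d2.pairwise_mean_similarity == lyase_diagram.pairwise_mean_similarity
        assert d2.min_edges_to_leaf == lyase_diagram.min_edges_to_leaf
        for tid, t in lyase_diagram.nodes.items():
            assert graphs_isomorphic(t.graph, d2.nodes[tid].graph)

    def test_version_mismatch_rejected(self, lyase_diagram):
        import json

        payload = json.loads(rh.serialize(lyase_diagram))
        payload["version"] = 99
        with pytest.raises(DiagramFormatError, match="version"):
            rh.deserialize(json.dumps(payload))

    def test_corrupted_tree_rejected(self, lyase_diagram):
        import json

        payload = json.loads(rh.serialize(lyase_diagram))
        payload["nodes"][1]["depth"] = 7  # violates depth(child)=depth(parent)+1
        with pytest.raises(DiagramFormatError):
            rh.deserialize(json.dumps(payload))

    def test_empty_diagram_rejected(self):
        with pytest.raises(ValueError):
            rh.serialize(rh.HasseDiagram(mode="reaction"))
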