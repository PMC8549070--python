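"""Scoring components, query modes, regiochemistry, cosubstrates, stereo."""

import itertools

import numpy as np
import pytest
from rdkit import Chem

import rxnhasse as rh
from rxnhasse import families
from rxnhasse.scoring import (
    DEFAULT_PARAMS,
    SimilarityParams,
    _fp_from_smiles,
    baseline_similarity_score,
    s_location,
    s_promiscuity,
    tanimoto,
)
from conftest import family_diagram


class TestTanimoto:
    def test_identity_and_symmetry(self):
        assert tanimoto("CC(O)C(=O)[O-]", "CC(O)C(=O)[O-]") == 1.0
        a = tanimoto("CC(O)C(=O)[O-]", "CC(=O)C(=O)[O-]")
        b = tanimoto("CC(=O)C(=O)[O-]", "CC(O)C(=O)[O-]")
        assert a == b
        assert 0.0 < a < 1.0

    def test_matches_bit_count_oracle(self):
        """Tanimoto equals an independent intersection/union bit count on
        the same fingerprint definition."""
        p = DEFAULT_PARAMS
        fa = np.array(list(_fp_from_smiles("CC(O)C(=O)[O-]", p.radius, p.n_bits, False)), bool)
        fb = np.array(list(_fp_from_smiles("CC(=O)C(=O)[O-]", p.radius, p.n_bits, False)), bool)
        inter = int(np.sum(fa & fb))
        union = int(np.sum(fa | fb))
        assert tanimoto("CC(O)C(=O)[O-]", "CC(=O)C(=O)[O-]") == pytest.approx(
            inter / union
        )

    def test_empty_molecule_raises(self):
        with pytest.raises(ValueError):
            tanimoto("", "CC")

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SimilarityParams(radius=0)
        with pytest.raises(ValueError):
            SimilarityParams(promiscuity_cap=0)


class TestLocationScore:
    @pytest.mark.parametrize("dist, expected", [(1, 0), (3, 2), (9, 4)])
    def test_capped_distance_minus_one(self, dist, expected, lyase_diagram):
        d = rh.deserialize(rh.serialize(lyase_diagram))
        d.min_edges_to_leaf[d.root.id] = dist
        assert s_location(d, d.root) == expected

    def test_leaf_parent_scores_zero(self, lactate_reaction):
        d = rh.build_diagram([lactate_reaction])
        leaf = d.leaves[0]
        parent = d.nodes[leaf.parent]
        assert s_location(d, parent) == 0


class TestPromiscuityScore:
    def test_single_leaf_tree_scores_cap(self, lactate_reaction):
        d = rh.build_diagram([lactate_reaction])
        assert s_promiscuity(d) == 0.8

    def test_identical_substrates_capped(self, lactate_reaction):
        d = rh.build_diagram([lactate_reaction, lactate_reaction])
        assert s_promiscuity(d) == 0.8

    def test_three_leaf_tree_matches_hand_computed_mean(self, lyase_diagram):
        subs = [leaf.substrate_smiles for leaf in lyase_diagram.leaves]
        assert all(len(s) == 1 for s in subs)
        sims = [tanimoto(a[0], b[0]) for a, b in itertools.combinations(subs, 2)]
        expected = min(sum(sims) / len(sims), 0.8)
        assert s_promiscuity(lyase_diagram) == pytest.approx(expected, abs=1e-12)


class TestReactionQueries:
    def test_training_reaction_on_own_single_reaction_tree(self, lactate_reaction):
        d = rh.build_diagram([lactate_reaction])
        res = rh.score_query_reaction(d, lactate_reaction)
        assert res.s_s == 1.0
        assert res.s_m == 1.0
        assert res.s_p == 0.8
        assert res.s_l == 0
        assert res.score == pytest.approx(1.2)

    def test_self_queries_recover_ideal_components(self, lyase_diagram, lyase_reactions):
        for rxn in lyase_reactions:
            res = rh.score_query_reaction(lyase_diagram, rxn)
            assert res.s_s == 1.0
            assert res.s_l == 0
            assert -1.2 <= res.score <= 2.0

    def test_foreign_center_scores_zero(self, lyase_diagram, lactate_reaction):
        res = rh.score_query_reaction(lyase_diagram, lactate_reaction)
        assert res.score == 0.0
        assert res.s_s is None and res.s_l is None

    def test_closer_query_scores_at_least_as_high(self):
        # family trained on H/C-decorated members; two queries share the
        # center but one matches a training substrate at the distal shell
        d = family_diagram(n=3, depth=2, seed=11, alphabet=("H", "C"))
        near_spec = families.FamilySpec(n_reactions=1, depth=2, seed=11,
                                        alphabet=("H", "C"))
        near = families.generate_family(near_spec)[0]
        far_spec = families.FamilySpec(n_reactions=1, depth=2, seed=5,
                                       alphabet=("Br", "O"))
        far = families.generate_family(far_spec)[0]
        s_near = rh.score_query_reaction(d, near).score
        s_far = rh.score_query_reaction(d, far).score
        assert s_near >= s_far

    def test_branch_similarity_bounded_by_global_maximum(self, lyase_diagram, lyase_reactions):
        from rxnhasse.scoring import _leaf_similarity
        from rxnhasse.its import its_fragment_to_sides
        from rxnhasse.scoring import _as_smiles

        for rxn in lyase_reactions:
            res = rh.score_query_reaction(lyase_diagram, rxn)
            r_mols, p_mols = its_fragment_to_sides(rh.build_its(rxn))
            q_subs = [_as_smiles(m) for m in r_mols]
            q_prods = [_as_smiles(m) for m in p_mols]
            global_max = max(
                _leaf_similarity(q_subs, q_prods, leaf, DEFAULT_PARAMS)
                for leaf in lyase_diagram.leaves
            )
            assert res.s_s <= global_max + 1e-12


class TestSubstrateQueries:
    def test_unimolecular_substrate_gives_one_candidate_with_product(self, lyase_diagram):
        res = rh.score_query_substrate(lyase_diagram, ["OC(=O)CC(=O)C(=O)[O-]"])
        assert len(res) == 1
        assert "CC(=O)C(=O)[O-]" in res[0].products  # pyruvate
        assert res[0].cosubstrates == []

    def test_symmetric_diol_has_two_equal_regio_candidates(self):
        d = family_diagram(n=2, depth=1, seed=3, alphabet=("H", "C"))
        res = rh.score_query_substrate(d, ["CC(O)CCC(O)C"])
        assert len(res) == 2
        assert res[0].score == pytest.approx(res[1].score)
        assert res[0].matched_atoms != res[1].matched_atoms

    def test_missing_cosubstrate_without_search_scores_zero(self, transaminase_diagram):
        res = rh.score_query_substrate(
            transaminase_diagram, ["CC(=O)CCC"], search_cosubstrates=False
        )
        assert [r.score for r in res] == [0.0]

    def test_cosubstrate_proposed_from_leaves(self, transaminase_diagram):
        res = rh.score_query_substrate(transaminase_diagram, ["CC(=O)CCC"])
        donors = {r.cosubstrates[0] for r in res if r.cosubstrates}
        assert donors == {"CC(C)N", "CCC(C)N"}
        for r in res:
            assert len(r.products) == 2  # amine product + leaving ketone

    def test_similar_donor_ranks_first(self):
        """The donor seen with similar acceptors in training outranks the
        other: promiscuity-aware scoring uses the branch context."""
        toy = families.transaminase_toy(pairs=((0, 0), (1, 0), (2, 1), (3, 1)))
        d = rh.build_diagram(toy)
        # query acceptor with a short tail, like those seen with donor 0
        res = rh.score_query_substrate(d, ["CC(=O)C(C)C"])
        res = [r for r in res if r.cosubstrates]
        assert len(res) >= 2
        assert res[0].score > res[-1].score
        assert res[0].cosubstrates[0] == "CC(C)N"  # the short-tail donor

    def test_nonmatching_substrate_returns_empty(self, lyase_diagram):
        assert rh.score_query_substrate(lyase_diagram, ["c1ccccc1"]) == []

    def test_single_substrate_tree_scores_without_products(self):
        mols = [Chem.MolFromSmiles(s) for s in ["CC(O)C", "CC(O)CC", "CC(O)CCC"]]
        d = rh.build_diagram(mols, mode="single_substrate", seed="C([H])O[H]")
        res = rh.score_query_substrate(d, ["CC(O)CCCC"])
        assert res
        assert res[0].products == []
        assert -1.2 <= res[0].score <= 2.0


class TestStereoFilter:
    def _chiral_line(self, config, extra_ch2=0):
        # (R)- or (S)-alkan-2-ol dehydrogenation, mapped with explicit H;
        # extra_ch2 lengthens the chain so that leaves do not deduplicate
        at = "@@" if config == "R" else "@"
        chain = "".join(
            f"[C:{20 + 3 * i}]([H:{21 + 3 * i}])([H:{22 + 3 * i}])"
            for i in range(extra_ch2)
        )
        tail = f"[C:9]([H:10])([H:11]){chain}[C:12]([H:13])([H:14])[H:15]"
        return (
            f"[C:1]([H:2])([H:3])([H:4])[C{at}:5]([H:6])([O:7][H:8])"
            f"{tail}"
            ">>[C:1]([H:2])([H:3])([H:4])[C:5](=[O:7])"
            f"{tail}.[H:6][H:8]"
        )

    def _chiral_family(self, config):
        return self._chiral_line(config)

    def test_achiral_query_passes_unflagged(self):
        d = rh.build_diagram([rh.parse_reaction_smiles(self._chiral_family("R"))])
        res = rh.score_query_substrate(d, ["CCC(O)CC"])
        assert res and not any(r.stereo_conflict for r in res)

    def test_enantiomeric_query_flagged_but_kept(self):
        d = rh.build_diagram([rh.parse_reaction_smiles(self._chiral_family("R"))])
        res_wrong = rh.score_query_substrate(d, ["CC[C@@H](O)C"])
        res_right = rh.score_query_substrate(d, ["CC[C@H](O)C"])
        flagged = {any(r.stereo_conflict for r in res) for res in (res_wrong, res_right)}
        assert flagged == {True, False}
        assert all(len(res) == 1 for res in (res_wrong, res_right))

    def test_mixed_stereo_leaves_never_flag(self):
        # two different skeletons with opposite configurations at the
        # carbinol: no query configuration can contradict every leaf
        d = rh.build_diagram([
            rh.parse_reaction_smiles(self._chiral_line("R")),
            rh.parse_reaction_smiles(self._chiral_line("S", extra_ch2=1)),
        ])
        for q in ("CC[C@@H](O)C", "CC[C@H](O)C"):
            res = rh.score_query_substrate(d, [q])
            assert res and not any(r.stereo_conflict for r in res)


class TestBaseline:
    def test_known_substrate_scores_one(self, lyase_diagram):
        known = [leaf.substrate_smiles[0] for leaf in lyase_diagram.leaves]
        assert baseline_similarity_score(known, known[0]) == 1.0

    def test_disjoint_fingerprints_score_zero(self):
        assert baseline_similarity_score(["CCCC"], "[O-][O-]") == 0.0

    def test_empty_known_set_raises(self):
        with pytest.raises(ValueError):
            baseline_similarity_score([], "CC")
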