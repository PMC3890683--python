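"""The five identification criteria and leave-one-out evaluation."""

import dendropy
import numpy as np
import pytest

from barcodeid.identify import (
    all_species_barcodes,
    best_close_match,
    best_match,
    evaluate_dataset,
    njt_classify,
    njt_m_classify,
    tally_percentages,
)

from .conftest import (
    make_dataset,
    make_matrix,
    oracle_similarity_verdict,
    random_toy_case,
)


def rooted(newick, dataset=None):
    t = dendropy.Tree.get(data=newick, schema="newick")
    t.is_rooted = True
    return t


class TestBestMatch:
    def test_unique_conspecific_nearest_is_correct(self):
        m, ds = make_matrix(
            [("q", "Sp a"), ("r1", "Sp a"), ("r2", "Sp b")],
            {("q", "r1"): 0.001, ("q", "r2"): 0.01, ("r1", "r2"): 0.01},
        )
        v = best_match("q", m, ds)
        assert v.outcome == "correct"
        assert v.best_distance == pytest.approx(0.001)
        assert v.matched_species == frozenset({"Sp a"})

    def test_tie_across_two_species_is_ambiguous(self):
        m, ds = make_matrix(
            [("q", "Sp a"), ("r1", "Sp a"), ("r2", "Sp b")],
            {("q", "r1"): 0.005, ("q", "r2"): 0.005, ("r1", "r2"): 0.01},
        )
        assert best_match("q", m, ds).outcome == "ambiguous"

    def test_unique_allospecific_nearest_is_incorrect(self):
        m, ds = make_matrix(
            [("q", "Sp a"), ("r1", "Sp a"), ("r2", "Sp b")],
            {("q", "r1"): 0.02, ("q", "r2"): 0.005, ("r1", "r2"): 0.01},
        )
        assert best_match("q", m, ds).outcome == "incorrect"

    def test_tie_across_two_other_species_only_is_ambiguous(self):
        m, ds = make_matrix(
            [("q", "Sp a"), ("r1", "Sp b"), ("r2", "Sp c")],
            {("q", "r1"): 0.005, ("q", "r2"): 0.005, ("r1", "r2"): 0.02},
        )
        assert best_match("q", m, ds).outcome == "ambiguous"

    def test_all_tied_single_other_species_is_incorrect(self):
        m, ds = make_matrix(
            [("q", "Sp a"), ("r1", "Sp b"), ("r2", "Sp b")],
            {("q", "r1"): 0.005, ("q", "r2"): 0.005, ("r1", "r2"): 0.0},
        )
        assert best_match("q", m, ds).outcome == "incorrect"

    def test_near_equal_distances_within_tolerance_tie(self):
        eps = 1e-14  # below the documented 1e-12 tie tolerance
        m, ds = make_matrix(
            [("q", "Sp a"), ("r1", "Sp a"), ("r2", "Sp b")],
            {("q", "r1"): 0.005, ("q", "r2"): 0.005 + eps, ("r1", "r2"): 0.01},
        )
        assert best_match("q", m, ds).outcome == "ambiguous"

    def test_outgroup_never_a_candidate(self):
        m, ds = make_matrix(
            [("q", "Sp a"), ("r1", "Sp a"), ("og", "Out x")],
            {("q", "r1"): 0.01, ("q", "og"): 0.001, ("r1", "og"): 0.001},
            outgroup_ids=("og",),
        )
        v = best_match("q", m, ds)
        assert v.outcome == "correct" and v.best_distance == pytest.approx(0.01)


class TestBestCloseMatch:
    def _fixture(self, d_conspecific):
        return make_matrix(
            [("q", "Sp a"), ("r1", "Sp a"), ("r2", "Sp b")],
            {("q", "r1"): d_conspecific, ("q", "r2"): 0.05, ("r1", "r2"): 0.05},
        )

    def test_within_threshold_behaves_like_bm(self):
        m, ds = self._fixture(0.001)
        v = best_close_match("q", m, ds, threshold=0.003)
        assert v.outcome == "correct"

    def test_above_threshold_is_no_match_regardless_of_species(self):
        m, ds = self._fixture(0.004)
        v = best_close_match("q", m, ds, threshold=0.003)
        assert v.outcome == "no_match"
        assert v.unthresholded_outcome == "correct"

    def test_boundary_distance_counts_as_within(self):
        m, ds = self._fixture(0.003)
        assert best_close_match("q", m, ds, threshold=0.003).outcome == "correct"

    def test_in_threshold_mixed_tie_is_ambiguous(self):
        m, ds = make_matrix(
            [("q", "Sp a"), ("r1", "Sp a"), ("r2", "Sp b")],
            {("q", "r1"): 0.001, ("q", "r2"): 0.001, ("r1", "r2"): 0.01},
        )
        assert best_close_match("q", m, ds, threshold=0.003).outcome == "ambiguous"

    def test_negative_threshold_rejected(self):
        m, ds = self._fixture(0.001)
        with pytest.raises(ValueError, match="threshold"):
            best_close_match("q", m, ds, threshold=-0.1)


class TestAllSpeciesBarcodes:
    def test_all_conspecifics_top_the_list(self):
        m, ds = make_matrix(
            [("q", "Sp a"), ("c1", "Sp a"), ("c2", "Sp a"), ("x", "Sp b")],
            {("q", "c1"): 0.001, ("q", "c2"): 0.002, ("q", "x"): 0.01,
             ("c1", "c2"): 0.001, ("c1", "x"): 0.01, ("c2", "x"): 0.01},
        )
        assert all_species_barcodes("q", m, ds, 0.05).outcome == "correct"

    def test_interleaved_allospecific_is_ambiguous(self):
        m, ds = make_matrix(
            [("q", "Sp a"), ("c1", "Sp a"), ("c2", "Sp a"), ("x", "Sp b")],
            {("q", "c1"): 0.001, ("q", "c2"): 0.01, ("q", "x"): 0.005,
             ("c1", "c2"): 0.01, ("c1", "x"): 0.005, ("c2", "x"): 0.01},
        )
        assert all_species_barcodes("q", m, ds, 0.05).outcome == "ambiguous"

    def test_whole_other_species_closer_is_incorrect(self):
        m, ds = make_matrix(
            [("q", "Sp a"), ("c1", "Sp a"), ("x1", "Sp b"), ("x2", "Sp b")],
            {("q", "c1"): 0.02, ("q", "x1"): 0.003, ("q", "x2"): 0.004,
             ("c1", "x1"): 0.02, ("c1", "x2"): 0.02, ("x1", "x2"): 0.001},
        )
        assert all_species_barcodes("q", m, ds, 0.05).outcome == "incorrect"

    def test_no_match_above_threshold(self):
        m, ds = make_matrix(
            [("q", "Sp a"), ("c1", "Sp a")],
            {("q", "c1"): 0.02},
        )
        assert all_species_barcodes("q", m, ds, 0.003).outcome == "no_match"

    def test_singleton_with_in_threshold_match_is_ambiguous(self):
        m, ds = make_matrix(
            [("q", "Sp a"), ("x1", "Sp b"), ("x2", "Sp b")],
            {("q", "x1"): 0.001, ("q", "x2"): 0.002, ("x1", "x2"): 0.001},
        )
        assert all_species_barcodes("q", m, ds, 0.01).outcome == "ambiguous"


class TestAgainstBruteForceOracle:
    """Exhaustive cross-check of all similarity criteria on random toy
    datasets with frequent exact ties."""

    @pytest.mark.parametrize("criterion", ["BM", "BCM", "ASB"])
    def test_matches_oracle_on_200_random_toys(self, criterion):
        rng = np.random.default_rng(987)
        for _ in range(200):
            m, ds, threshold = random_toy_case(rng)
            for r in ds.ingroup:
                if criterion == "BM":
                    got = best_match(r.specimen_id, m, ds).outcome
                elif criterion == "BCM":
                    got = best_close_match(r.specimen_id, m, ds, threshold).outcome
                else:
                    got = all_species_barcodes(r.specimen_id, m, ds, threshold).outcome
                want = oracle_similarity_verdict(
                    criterion, r.specimen_id, m, ds,
                    threshold if criterion != "BM" else None,
                )
                assert got == want, (criterion, r.specimen_id)

    def test_structural_invariants_on_random_toys(self):
        rng = np.random.default_rng(31337)
        species_counts_cache = {}
        for _ in range(100):
            m, ds, threshold = random_toy_case(rng)
            counts = ds.species_counts()
            for r in ds.ingroup:
                bm = best_match(r.specimen_id, m, ds)
                bcm = best_close_match(r.specimen_id, m, ds, threshold)
                asb = all_species_barcodes(r.specimen_id, m, ds, threshold)
                # BCM agrees with BM within the threshold, else no_match
                if bm.best_distance <= threshold:
                    assert bcm.outcome == bm.outcome
                else:
                    assert bcm.outcome == "no_match"
                # ASB-correct implies BM-correct (strictly stricter)
                if asb.outcome == "correct":
                    assert bm.outcome == "correct"
                # singletons can never be correct
                if counts[r.species] == 1:
                    assert bm.outcome != "correct"
                    assert bcm.outcome != "correct"
                    assert asb.outcome != "correct"
        del species_counts_cache


class TestTreeCriteria:
    def dataset(self):
        return make_dataset(
            [
                ("a1", "Sp a", "ACGT"), ("a2", "Sp a", "ACGT"), ("a3", "Sp a", "ACGT"),
                ("b1", "Sp b", "ACGT"), ("b2", "Sp b", "ACGT"),
                ("s1", "Sp s", "ACGT"),
            ]
        )

    def test_njt_monophyletic_species_all_correct(self):
        t = rooted("(((a1:1,a2:1):1,a3:1):1,((b1:1,b2:1):1,s1:1):1);")
        verdicts = {v.query_id: v.outcome for v in njt_classify(t, self.dataset())}
        assert verdicts["a1"] == verdicts["a2"] == verdicts["a3"] == "correct"
        assert verdicts["b1"] == verdicts["b2"] == "correct"
        assert verdicts["s1"] == "ambiguous"  # singleton

    def test_njt_split_species_all_incorrect(self):
        # Sp a appears at two positions separated by Sp b
        t = rooted("(((a1:1,a2:1):1,(b1:1,b2:1):1):1,(a3:1,s1:1):1);")
        verdicts = {v.query_id: v.outcome for v in njt_classify(t, self.dataset())}
        assert {verdicts[q] for q in ("a1", "a2", "a3")} == {"incorrect"}
        assert verdicts["b1"] == "correct"

    def test_njt_outcome_constant_within_species(self):
        t = rooted("(((a1:1,a2:1):1,(b1:1,b2:1):1):1,(a3:1,s1:1):1);")
        by_species = {}
        for v in njt_classify(t, self.dataset()):
            sp = self.dataset().species_of()[v.query_id]
            by_species.setdefault(sp, set()).add(v.outcome)
        assert all(len(o) == 1 for o in by_species.values())

    def test_njt_m_rules(self):
        ds = make_dataset(
            [
                ("a1", "Sp a", "ACGT"), ("a2", "Sp a", "ACGT"),
                ("a3", "Sp a", "ACGT"), ("a4", "Sp a", "ACGT"),
                ("b1", "Sp b", "ACGT"), ("b2", "Sp b", "ACGT"), ("b3", "Sp b", "ACGT"),
                ("c1", "Sp c", "ACGT"), ("c2", "Sp c", "ACGT"),
                ("s1", "Sp s", "ACGT"),
            ]
        )
        # comb of Sp a: a3 and a4 are one node into an exclusively
        # conspecific cluster (>=2 conspecifics below the parent)
        t = rooted(
            "(((((a1:1,a2:1):1,a3:1):1,a4:1):1,(b1:1,b2:1):2):1,"
            "(b3:1,(c1:1,c2:1,s1:1):1):1);"
        )
        verdicts = {v.query_id: v.outcome for v in njt_m_classify(t, ds)}
        assert verdicts["a3"] == "correct"
        assert verdicts["a4"] == "correct"
        assert verdicts["a1"] == "ambiguous"  # cherry: single conspecific sister
        assert verdicts["b1"] == "ambiguous"  # cherry: single conspecific sister
        assert verdicts["c1"] == "ambiguous"  # mixed polytomy
        assert verdicts["s1"] == "ambiguous"  # singleton
        # one node up from b3: three leaves, all allospecific to Sp b
        assert verdicts["b3"] == "incorrect"

    def test_njt_m_polytomy_of_conspecifics_is_correct(self):
        ds = make_dataset(
            [
                ("a1", "Sp a", "ACGT"), ("a2", "Sp a", "ACGT"), ("a3", "Sp a", "ACGT"),
                ("b1", "Sp b", "ACGT"), ("b2", "Sp b", "ACGT"),
            ]
        )
        t = rooted("((a1:1,a2:1,a3:1):1,(b1:1,b2:1):1);")
        verdicts = {v.query_id: v.outcome for v in njt_m_classify(t, ds)}
        assert verdicts["a1"] == verdicts["a2"] == verdicts["a3"] == "correct"
        # b1's parent holds exactly one conspecific -> ambiguous cherry rule
        assert verdicts["b1"] == "ambiguous"

    def test_njt_m_one_node_into_allospecific_cluster_is_incorrect(self):
        ds = make_dataset(
            [
                ("q1", "Sp q", "ACGT"), ("q2", "Sp q", "ACGT"),
                ("b1", "Sp b", "ACGT"), ("b2", "Sp b", "ACGT"),
            ]
        )
        # q1 grouped inside the Sp b pair (two allospecific leaves below
        # its parent); q2 outside
        t = rooted("((q1:1,b1:1,b2:1):1,q2:1);")
        verdicts = {v.query_id: v.outcome for v in njt_m_classify(t, ds)}
        assert verdicts["q1"] == "incorrect"

    def test_cherry_with_conspecific_is_ambiguous_not_correct(self):
        ds = make_dataset(
            [
                ("a1", "Sp a", "ACGT"), ("a2", "Sp a", "ACGT"),
                ("b1", "Sp b", "ACGT"), ("b2", "Sp b", "ACGT"), ("b3", "Sp b", "ACGT"),
            ]
        )
        t = rooted("((a1:1,a2:1):1,((b1:1,b2:1):1,b3:1):1);")
        verdicts = {v.query_id: v.outcome for v in njt_m_classify(t, ds)}
        assert verdicts["a1"] == "ambiguous"  # sister is a single conspecific
        assert verdicts["b3"] == "correct"  # one node up: two conspecifics

    def test_leaf_mismatch_raises(self):
        t = rooted("((a1:1,a2:1):1,b1:1);")
        with pytest.raises(ValueError, match="match"):
            njt_classify(t, self.dataset())


class TestEvaluateDataset:
    def test_percentage_tallies_match_recount(self):
        rng = np.random.default_rng(5)
        m, ds, threshold = random_toy_case(rng)
        rep = evaluate_dataset(ds, "BCM", m=m, threshold=threshold)
        assert rep.n_queries == len(ds.ingroup)
        recount = {}
        for v in rep.verdicts:
            recount[v.outcome] = recount.get(v.outcome, 0) + 1
        assert rep.tallies == {**{o: 0 for o in rep.tallies}, **recount}
        assert sum(rep.tallies.values()) == rep.n_queries
        assert sum(rep.percentages.values()) == pytest.approx(100.0, abs=0.03)

    def test_printed_count_shapes_round_half_up(self):
        # counts of the shape a published Table-4 row has
        pct = tally_percentages(
            {"correct": 407, "ambiguous": 58, "incorrect": 17, "no_match": 73}, 555
        )
        assert pct == {
            "correct": 73.33, "ambiguous": 10.45,
            "incorrect": 3.06, "no_match": 13.15,
        }

    def test_missing_prerequisites_raise(self):
        ds = make_dataset([("a", "Sp a", "ACGT"), ("b", "Sp a", "ACGT")])
        with pytest.raises(ValueError, match="distance matrix"):
            evaluate_dataset(ds, "BM")
        with pytest.raises(ValueError, match="threshold"):
            evaluate_dataset(ds, "BCM", m=make_matrix([("a", "Sp a"), ("b", "Sp a")], {})[0])
        with pytest.raises(ValueError, match="tree"):
            evaluate_dataset(ds, "NJT")
        with pytest.raises(ValueError, match="criterion"):
            evaluate_dataset(ds, "XXX")

    def test_clean_dataset_bcm_all_correct(self):
        ds = make_dataset(
            [
                ("a1", "Sp a", "AAAAAAAAAA"), ("a2", "Sp a", "AAAAAAAAAA"),
                ("b1", "Sp b", "AAAAGGAAAA"), ("b2", "Sp b", "AAAAGGAAAA"),
            ]
        )
        from barcodeid.distances import distance_matrix

        m = distance_matrix(ds)
        rep = evaluate_dataset(ds, "BCM", m=m, threshold=0.003)
        assert rep.percentages["correct"] == 100.0
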