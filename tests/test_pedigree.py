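import numpy as np
import pytest

import kinmat as km
from kinmat.pedigree import IssueKind

from conftest import random_pedigree_records
from oracles import tabular_A


class TestSortPedigree:
    def test_reorders_parents_first(self):
        recs = [km.PedigreeRecord("3", "1", "2"), km.PedigreeRecord("1"),
                km.PedigreeRecord("2")]
        ped, issues = km.sort_pedigree(recs)
        assert ped is not None and not issues
        assert ped.is_sorted()
        assert ped.ids[-1] == "3"

    def test_loop_is_fatal(self):
        recs = [km.PedigreeRecord("1", "2", None),
                km.PedigreeRecord("2", "1", None)]
        ped, issues = km.sort_pedigree(recs)
        assert ped is None
        assert any(i.kind == IssueKind.LOOP and i.fatal for i in issues)

    def test_self_parenting_is_fatal_loop(self):
        ped, issues = km.sort_pedigree([km.PedigreeRecord("1", "1", None)])
        assert ped is None
        assert any(i.kind == IssueKind.LOOP for i in issues)

    def test_conflicting_duplicate_ids_fatal(self):
        recs = [km.PedigreeRecord("3", "1", "2"),
                km.PedigreeRecord("3", "1", "4")]
        ped, issues = km.sort_pedigree(recs)
        assert ped is None
        assert any(i.kind == IssueKind.DUPLICATE_ID_CONFLICTING_PARENTS
                   for i in issues)

    def test_missing_parents_promoted_to_founders(self):
        ped, issues = km.sort_pedigree([km.PedigreeRecord("3", "1", "2")])
        assert ped is not None
        assert set(ped.ids) == {"1", "2", "3"}
        kinds = [i.kind for i in issues]
        assert kinds.count(IssueKind.MISSING_PARENT_RECORD) == 2
        assert not any(i.fatal for i in issues)

    def test_two_genders_fatal(self):
        recs = [km.PedigreeRecord("3", "1", "2"),
                km.PedigreeRecord("4", "2", "1")]
        ped, issues = km.sort_pedigree(recs)
        assert ped is None
        assert any(i.kind == IssueKind.TWO_GENDERS for i in issues)

    def test_birth_order_conflict_reported_nonfatal(self):
        recs = [km.PedigreeRecord("1", None, None, 5),
                km.PedigreeRecord("2", "1", None, 3)]
        ped, issues = km.sort_pedigree(recs)
        assert ped is not None
        assert any(i.kind == IssueKind.PARENT_AFTER_OFFSPRING for i in issues)

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        recs = random_pedigree_records(rng, 40, 0.3)
        ped1, _ = km.sort_pedigree(recs)
        ped2, issues = km.sort_pedigree(ped1.records)
        assert ped2.ids == ped1.ids
        assert not any(i.fatal for i in issues)

    def test_tie_break_by_birth_order(self):
        recs = [km.PedigreeRecord("b", None, None, 2),
                km.PedigreeRecord("a", None, None, 1)]
        ped, _ = km.sort_pedigree(recs)
        assert ped.ids == ["a", "b"]


class TestSelectPedigree:
    def test_zero_generations(self, toy_pedigree):
        sub = km.select_pedigree(toy_pedigree, ["5"], 0)
        assert sub.ids == ["5"]
        assert sub.records[0].sire is None and sub.records[0].dam is None

    def test_chain_two_generations(self):
        recs = [km.PedigreeRecord("1"), km.PedigreeRecord("3", "1", None),
                km.PedigreeRecord("5", "3", None)]
        ped, _ = km.sort_pedigree(recs)
        sub = km.select_pedigree(ped, ["5"], 2)
        assert set(sub.ids) == {"1", "3", "5"}

    def test_chain_horizon_truncates(self):
        recs = [km.PedigreeRecord(str(i + 1),
                                  str(i) if i >= 1 else None, None)
                for i in range(5)]
        ped, _ = km.sort_pedigree(recs)
        sub = km.select_pedigree(ped, ["5"], 3)
        assert set(sub.ids) == {"2", "3", "4", "5"}
        rec2 = sub.records[sub.index["2"]]
        assert rec2.sire is None and rec2.dam is None

    def test_unknown_target_errors(self, toy_pedigree):
        with pytest.raises(KeyError, match="99"):
            km.select_pedigree(toy_pedigree, ["99"], 1)

    def test_full_selection_preserves_A(self, sim_pedigree):
        sub = km.select_pedigree(sim_pedigree, sim_pedigree.ids, 10_000)
        A_full = km.make_A(sim_pedigree).to_dataframe()
        A_sub = km.make_A(sub).to_dataframe()
        shared = list(A_sub.index)
        np.testing.assert_allclose(
            A_sub.values, A_full.loc[shared, shared].values, atol=1e-12)


class TestMakeA:
    def test_single_founder(self):
        ped, _ = km.sort_pedigree([km.PedigreeRecord("1")])
        np.testing.assert_allclose(km.make_A(ped).dense(), [[1.0]])

    def test_trio_values(self):
        ped, _ = km.sort_pedigree([km.PedigreeRecord("1"),
                                   km.PedigreeRecord("2"),
                                   km.PedigreeRecord("3", "1", "2")])
        A = km.make_A(ped).to_dataframe()
        assert A.loc["1", "3"] == pytest.approx(0.5)
        assert A.loc["2", "3"] == pytest.approx(0.5)
        assert A.loc["3", "3"] == pytest.approx(1.0)
        assert A.loc["1", "2"] == pytest.approx(0.0)

    def test_fullsib_mating_inbreeding(self, toy_pedigree):
        A = km.make_A(toy_pedigree).to_dataframe()
        assert A.loc["5", "5"] == pytest.approx(1.25)
        assert A.loc["3", "4"] == pytest.approx(0.5)

    def test_unsorted_rejected(self):
        ped = km.PedigreeTable([km.PedigreeRecord("3", "1", "2"),
                                km.PedigreeRecord("1"),
                                km.PedigreeRecord("2")])
        with pytest.raises(km.PedigreeError, match="sort_pedigree"):
            km.make_A(ped)

    def test_sparse_equals_dense(self, sim_pedigree):
        dense = km.make_A(sim_pedigree, sparse=False).dense()
        sparse = km.make_A(sim_pedigree, sparse=True).dense()
        np.testing.assert_array_equal(dense, sparse)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_tabular_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 80))
        recs = random_pedigree_records(rng, n, float(rng.uniform(0.1, 0.6)))
        ped, _ = km.sort_pedigree(recs)
        s, d = ped.parent_indices()
        expected = tabular_A(s, d)
        got = km.make_A(ped).dense()
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_psd_and_symmetric(self, sim_pedigree):
        A = km.make_A(sim_pedigree).dense()
        assert np.max(np.abs(A - A.T)) <= 1e-12
        assert np.linalg.eigvalsh(A).min() >= -1e-8


class TestMakeD:
    def test_unrelated_founders_identity(self):
        ped, _ = km.sort_pedigree([km.PedigreeRecord("1"),
                                   km.PedigreeRecord("2")])
        np.testing.assert_array_equal(km.make_D(ped).dense(), np.eye(2))

    def test_full_sibs(self, toy_pedigree):
        D = km.make_D(toy_pedigree).to_dataframe()
        assert D.loc["3", "4"] == pytest.approx(0.25)

    def test_half_sibs_zero(self):
        recs = [km.PedigreeRecord("1"), km.PedigreeRecord("2"),
                km.PedigreeRecord("5"),
                km.PedigreeRecord("3", "1", "2"),
                km.PedigreeRecord("4", "1", "5")]
        ped, _ = km.sort_pedigree(recs)
        D = km.make_D(ped).to_dataframe()
        # sharing only the sire: 0.25 * (A_11 * A_25 + A_15 * A_21) = 0
        assert D.loc["3", "4"] == pytest.approx(0.0)

    def test_diagonal_is_one(self, sim_pedigree):
        D = km.make_D(sim_pedigree).dense()
        np.testing.assert_array_equal(np.diag(D), np.ones(len(sim_pedigree)))


class TestCoefficients:
    def test_inbreeding_from_A(self, toy_pedigree):
        F = km.inbreeding_coefficients(km.make_A(toy_pedigree))
        assert F["5"] == pytest.approx(0.25)
        assert F["1"] == pytest.approx(0.0)

    def test_negative_genomic_inbreeding_allowed(self):
        K = km.KinshipMatrix(np.array([[0.98, 0.0], [0.0, 1.02]]),
                             ["a", "b"])
        F = km.inbreeding_coefficients(K)
        assert F["a"] == pytest.approx(-0.02)

    def test_coancestry_halves_A(self, toy_pedigree):
        A = km.make_A(toy_pedigree)
        theta = km.kinship_coefficients(A).to_dataframe()
        assert theta.loc["1", "3"] == pytest.approx(0.25)
        assert theta.loc["1", "1"] == pytest.approx(0.5)
        assert theta.loc["1", "2"] == pytest.approx(0.0)
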