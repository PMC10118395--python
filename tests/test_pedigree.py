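import numpy as np
import pytest

from ssblup.errors import PedigreeError
from ssblup.pedigree import (
    MISSING,
    PedigreeRecord,
    assign_phantom_groups,
    build_a22,
    build_a_inverse,
    compute_inbreeding,
    sort_and_validate,
    tabular_relationship,
)

from conftest import random_pedigree
from oracles import relationship_oracle


def _oracle_A(ped):
    sire = {a: (ped.ids[ped.sire[i]] if ped.sire[i] != MISSING else None) for i, a in enumerate(ped.ids)}
    dam = {a: (ped.ids[ped.dam[i]] if ped.dam[i] != MISSING else None) for i, a in enumerate(ped.ids)}
    return relationship_oracle(sire, dam, list(ped.ids))


class TestSortAndValidate:
    def test_parents_precede_offspring_any_input_order(self):
        ped = sort_and_validate(
            [
                PedigreeRecord("3", "1", "2", 2001, "M"),
                PedigreeRecord("1", None, None, 2000, "M"),
                PedigreeRecord("2", None, None, 2000, "F"),
            ]
        )
        assert ped.ids == ["1", "2", "3"]

    def test_mutual_parentage_is_a_cycle_error(self):
        recs = [
            PedigreeRecord("1", "2", None, 2000, "M"),
            PedigreeRecord("2", "1", None, 2000, "M"),
        ]
        with pytest.raises(PedigreeError, match="cycle"):
            sort_and_validate(recs)

    def test_sex_conflict_rejected(self):
        recs = [
            PedigreeRecord("1", None, None, 2000, "M"),
            PedigreeRecord("2", None, None, 2000, "F"),
            PedigreeRecord("3", "1", "2", 2001, "F"),
            PedigreeRecord("4", "2", None, 2001, "M"),  # dam 2 used as sire
        ]
        with pytest.raises(PedigreeError, match="sire"):
            sort_and_validate(recs)

    def test_duplicate_ids_rejected(self):
        recs = [
            PedigreeRecord("1", None, None, 2000, "M"),
            PedigreeRecord("1", None, None, 2000, "M"),
        ]
        with pytest.raises(PedigreeError, match="duplicate"):
            sort_and_validate(recs)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_large_random_pedigree_is_topologically_ordered(self, seed):
        ped = random_pedigree(seed, n=1000, n_founders=50)
        for i in range(ped.n):
            assert ped.sire[i] < i and ped.dam[i] < i  # exhaustive parent-link scan


class TestPhantomGroups:
    def test_paths_times_bins_product(self):
        # founders in two year layers, missing parents on both sides
        recs = [
            PedigreeRecord(f"f{i}", None, None, 2000 + 5 * (i % 2), "M" if i % 2 else "F")
            for i in range(8)
        ]
        ped = sort_and_validate(recs)
        groups = assign_phantom_groups(ped, year_bins=[2000, 2003, 2006])
        # 4 paths (sire/dam x offspring sex) x 2 bins in use
        assert groups.n == 8
        assert (groups.sire_group >= 0).all() and (groups.dam_group >= 0).all()

    def test_no_missing_parents_no_groups(self):
        recs = [
            PedigreeRecord("1", None, None, 2000, "M"),
            PedigreeRecord("2", None, None, 2000, "F"),
            PedigreeRecord("3", "1", "2", 2001, "M"),
        ]
        ped = sort_and_validate(recs)
        groups = assign_phantom_groups(ped)
        assert groups.sire_group[2] == MISSING and groups.dam_group[2] == MISSING

    def test_paper_scale_group_count_from_config(self):
        # a 3-path x 11-bin configuration yields 33 groups
        rng = np.random.default_rng(0)
        recs = [
            PedigreeRecord(f"f{i}", None, None, 2000 + int(rng.integers(0, 11)), "M", selection_path=f"p{i % 3}")
            for i in range(300)
        ]
        ped = sort_and_validate(recs)
        groups = assign_phantom_groups(
            ped,
            path_defs=lambda role, i, p: p.selection_path[i],
            year_bins=list(range(2000, 2012)),
        )
        assert groups.n == 33

    def test_out_of_range_years_clamped_to_boundary_bins(self):
        recs = [
            PedigreeRecord("old", None, None, 1990, "M"),
            PedigreeRecord("new", None, None, 2030, "M"),
        ]
        ped = sort_and_validate(recs)
        groups = assign_phantom_groups(ped, year_bins=[2000, 2005, 2010])
        assert groups.n > 0
        assert (groups.sire_group >= 0).all()


class TestInbreeding:
    def test_founders_have_zero_inbreeding(self, trio_ped):
        F = compute_inbreeding(trio_ped)
        assert F[0] == 0.0 and F[1] == 0.0 and F[2] == 0.0

    def test_full_sib_mating_gives_quarter(self):
        recs = [
            PedigreeRecord("1", None, None, 0, "M"),
            PedigreeRecord("2", None, None, 0, "F"),
            PedigreeRecord("3", "1", "2", 1, "M"),
            PedigreeRecord("4", "1", "2", 1, "F"),
            PedigreeRecord("5", "3", "4", 2, "M"),
        ]
        F = compute_inbreeding(sort_and_validate(recs))
        assert F[-1] == pytest.approx(0.25)

    @pytest.mark.parametrize("seed", [0, 7])
    def test_matches_tabular_oracle(self, seed):
        ped = random_pedigree(seed, n=200, p_known=0.85)
        A = _oracle_A(ped)
        F = compute_inbreeding(ped)
        for i in range(ped.n):
            s, d = ped.sire[i], ped.dam[i]
            expected = 0.5 * A[s, d] if (s != MISSING and d != MISSING) else 0.0
            assert F[i] == pytest.approx(expected, abs=1e-12)
        assert (F >= 0).all() and (F < 1).all()


class TestAInverse:
    def test_trio_closed_form(self, trio_ped):
        M = build_a_inverse(trio_ped).matrix.toarray()
        np.testing.assert_allclose(
            M, [[1.5, 0.5, -1.0], [0.5, 1.5, -1.0], [-1.0, -1.0, 2.0]]
        )

    def test_single_founder(self):
        ped = sort_and_validate([PedigreeRecord("1", None, None, 0, "M")])
        np.testing.assert_allclose(build_a_inverse(ped).matrix.toarray(), [[1.0]])

    def test_founder_only_pedigree_is_identity(self):
        recs = [PedigreeRecord(f"f{i}", None, None, 0, "M") for i in range(5)]
        ped = sort_and_validate(recs)
        np.testing.assert_allclose(build_a_inverse(ped).matrix.toarray(), np.eye(5))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_equals_dense_inverse_of_oracle_A(self, seed):
        ped = random_pedigree(seed, n=150)
        A = _oracle_A(ped)
        M = build_a_inverse(ped).matrix.toarray()
        assert np.abs(M - np.linalg.inv(A)).max() < 1e-8

    def test_group_rows_receive_westell_contributions(self, trio_ped):
        groups = assign_phantom_groups(trio_ped)
        ai = build_a_inverse(trio_ped, groups=groups, group_prior=0.0)
        M = ai.matrix.toarray()
        # two founders, each with two missing slots: 4 role-x-sex paths in use
        assert ai.n_groups == 4
        n = trio_ped.n
        sg, dg = groups.sire_group[0], groups.dam_group[0]
        # founder rule with both parents unknown: b=1 -> -1/2 on group links,
        # b/4 on group diagonals and the cross term
        assert M[0, n + sg] == pytest.approx(-0.5)
        assert M[0, n + dg] == pytest.approx(-0.5)
        assert M[n + sg, n + sg] == pytest.approx(0.25)
        assert M[n + sg, n + dg] == pytest.approx(0.25)

    def test_unknown_genotyped_id_rejected(self, trio_ped):
        with pytest.raises(PedigreeError, match="nope"):
            build_a22(trio_ped, ["1", "nope"])


class TestA22:
    def test_full_sibs_block(self):
        recs = [
            PedigreeRecord("1", None, None, 0, "M"),
            PedigreeRecord("2", None, None, 0, "F"),
            PedigreeRecord("3", "1", "2", 1, "M"),
            PedigreeRecord("4", "1", "2", 1, "F"),
        ]
        ped = sort_and_validate(recs)
        np.testing.assert_allclose(build_a22(ped, ["3", "4"]), [[1.0, 0.5], [0.5, 1.0]])

    def test_single_founder(self):
        ped = sort_and_validate([PedigreeRecord("1", None, None, 0, "M")])
        np.testing.assert_allclose(build_a22(ped, ["1"]), [[1.0]])

    def test_matches_oracle_subblock_and_is_psd(self):
        ped = random_pedigree(11, n=300, p_known=0.85)
        rng = np.random.default_rng(1)
        gen_ids = [ped.ids[i] for i in rng.choice(ped.n, size=50, replace=False)]
        A = _oracle_A(ped)
        idx = [ped.index[a] for a in gen_ids]
        sub = A[np.ix_(idx, idx)]
        a22 = build_a22(ped, gen_ids)
        assert np.abs(a22 - sub).max() < 1e-10
        F = compute_inbreeding(ped)
        np.testing.assert_allclose(np.diag(a22), 1.0 + F[idx], atol=1e-10)
        evals = np.linalg.eigvalsh(a22)
        assert evals.min() > -1e-10

    def test_tabular_diag_equals_one_plus_inbreeding(self):
        ped = random_pedigree(5, n=120, p_known=0.9)
        A = tabular_relationship(ped)
        F = compute_inbreeding(ped)
        np.testing.assert_allclose(np.diag(A), 1.0 + F, atol=1e-12)
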