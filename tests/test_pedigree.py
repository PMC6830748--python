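import numpy as np
import pandas as pd
import pytest

from wildqg import (PedigreeError, additive_relationship_matrix,
                    gene_drop_breeding_values, genetic_group_proportions,
                    inbreeding_coefficients, read_pedigree_csv,
                    validate_pedigree, write_pedigree_csv)

from oracles import (oracle_inbreeding, oracle_relationship_matrix,
                     parents_dict, random_pedigree)


def ped_frame(rows):
    return pd.DataFrame(rows, columns=["id", "sire", "dam", "sex", "cohort"])


TRIO = ped_frame([("s", "", "", "M", 0), ("d", "", "", "F", 0), ("c", "s", "d", "F", 1)])

# sire x daughter, then full-sib mating: classic inbreeding test pedigrees
FULL_SIB_MATING = ped_frame([
    ("s", "", "", "M", 0), ("d", "", "", "F", 0),
    ("b1", "s", "d", "M", 1), ("b2", "s", "d", "F", 1),
    ("x", "b1", "b2", "F", 2),
])
HALF_SIB_MATING = ped_frame([
    ("s", "", "", "M", 0), ("d1", "", "", "F", 0), ("d2", "", "", "F", 0),
    ("h1", "s", "d1", "M", 1), ("h2", "s", "d2", "F", 1),
    ("x", "h1", "h2", "F", 2),
])


class TestValidation:
    def test_trio_sorted_child_last(self):
        ped = validate_pedigree(pd.DataFrame({"id": ["c", "s", "d"], "sire": ["s", "", ""],
                                              "dam": ["d", "", ""], "sex": ["F", "M", "F"],
                                              "cohort": [1, 0, 0]}))
        assert len(ped) == 3
        assert ped.ids[-1] == "c"
        assert ped.sire_idx[-1] == ped.position("s")

    def test_self_parent_is_cycle(self):
        df = ped_frame([("a", "a", "", "M", 0)])
        with pytest.raises(PedigreeError, match="cycle"):
            validate_pedigree(df)

    def test_two_cycle(self):
        df = ped_frame([("a", "b", "", "M", 0), ("b", "a", "", "M", 0)])
        with pytest.raises(PedigreeError, match="cycle"):
            validate_pedigree(df)

    def test_sex_inconsistent_parent(self):
        df = ped_frame([("s", "", "", "F", 0), ("d", "", "", "F", 0), ("c", "s", "d", "F", 1)])
        with pytest.raises(PedigreeError, match="sex-inconsistent"):
            validate_pedigree(df)

    def test_unknown_parent_id(self):
        df = ped_frame([("c", "ghost", "", "F", 0)])
        with pytest.raises(PedigreeError, match="not in individual list"):
            validate_pedigree(df)

    def test_duplicate_ids(self):
        df = ped_frame([("a", "", "", "M", 0), ("a", "", "", "M", 0)])
        with pytest.raises(PedigreeError, match="duplicate"):
            validate_pedigree(df)

    def test_csv_round_trip(self, small_dataset, tmp_path):
        ped = small_dataset.pedigree
        path = tmp_path / "ped.csv"
        write_pedigree_csv(ped, path)
        back = read_pedigree_csv(path)
        pd.testing.assert_frame_equal(
            ped.table.astype(str), back.table.astype(str)
        )


class TestRelationshipMatrix:
    def test_trio(self):
        A = additive_relationship_matrix(validate_pedigree(TRIO))
        assert np.allclose(np.diag(A), 1.0)
        assert A[0, 2] == 0.5 and A[1, 2] == 0.5 and A[0, 1] == 0.0

    def test_full_sibs(self):
        ped = validate_pedigree(FULL_SIB_MATING)
        A = additive_relationship_matrix(ped)
        i, j = ped.position("b1"), ped.position("b2")
        assert A[i, j] == 0.5

    def test_full_sib_mating_offspring(self):
        ped = validate_pedigree(FULL_SIB_MATING)
        A = additive_relationship_matrix(ped)
        x = ped.position("x")
        assert A[x, x] == pytest.approx(1.25)
        assert inbreeding_coefficients(ped)[x] == pytest.approx(0.25)
        # independent recursive-coancestry oracle over the whole pedigree
        oA = oracle_relationship_matrix(parents_dict(FULL_SIB_MATING), list(ped.ids))
        assert np.allclose(A, oA, atol=1e-12)

    def test_half_sib_mating_inbreeding(self):
        ped = validate_pedigree(HALF_SIB_MATING)
        F = inbreeding_coefficients(ped)
        oF = oracle_inbreeding(parents_dict(HALF_SIB_MATING), list(ped.ids))
        assert F[ped.position("x")] == pytest.approx(0.125)
        assert np.allclose(F, oF, atol=1e-12)

    def test_founders_not_inbred(self):
        ped = validate_pedigree(TRIO)
        assert np.all(inbreeding_coefficients(ped)[:2] == 0.0)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_recursive_oracle_on_random_pedigrees(self, seed):
        rng = np.random.default_rng(seed)
        df = random_pedigree(rng, n=int(rng.integers(5, 31)))
        ped = validate_pedigree(df)
        A = additive_relationship_matrix(ped)
        oA = oracle_relationship_matrix(parents_dict(df), list(ped.ids))
        assert np.allclose(A, oA, atol=1e-12)
        # diagonal minus one is the inbreeding vector
        assert np.allclose(np.diag(A) - 1.0, inbreeding_coefficients(ped), atol=1e-12)
        # A is symmetric PSD
        assert np.linalg.eigvalsh(A).min() > -1e-10

    @pytest.mark.parametrize("seed", [1, 7])
    def test_a_inverse_inverts_a(self, seed):
        rng = np.random.default_rng(seed)
        ped = validate_pedigree(random_pedigree(rng, n=25))
        A = additive_relationship_matrix(ped)
        Ainv = ped.a_inverse().toarray()
        assert np.allclose(A @ Ainv, np.eye(len(ped)), atol=1e-9)

    def test_ancestor_closure_preserves_relationships(self, small_dataset):
        ped = small_dataset.pedigree
        keep = sorted(set(small_dataset.records["female"]))[:40]
        sub = ped.ancestor_closure(keep)
        A_full = additive_relationship_matrix(ped)
        A_sub = additive_relationship_matrix(sub)
        ix_full = ped.positions(sub.ids)
        assert np.allclose(A_sub, A_full[np.ix_(ix_full, ix_full)], atol=1e-12)


class TestGeneticGroups:
    def test_resident_parents_give_zero(self):
        q = genetic_group_proportions(validate_pedigree(TRIO))
        assert np.all(q == 0.0)

    def test_immigrant_sire(self):
        ped = validate_pedigree(TRIO)
        q = genetic_group_proportions(ped, {"s": 1.0})
        assert q[ped.position("c")] == 0.5

    def test_one_immigrant_grandparent(self):
        df = ped_frame([
            ("gs", "", "", "M", 0), ("gd", "", "", "F", 0),
            ("s2", "", "", "M", 0), ("p", "gs", "gd", "F", 1),
            ("c", "s2", "p", "F", 2),
        ])
        ped = validate_pedigree(df)
        q = genetic_group_proportions(ped, {"gs": 1.0})
        assert q[ped.position("c")] == pytest.approx(0.25)

    def test_unassigned_founder_fatal_without_default(self):
        with pytest.raises(PedigreeError, match="genetic-group"):
            genetic_group_proportions(validate_pedigree(TRIO), {}, default=None)

    def test_preserved_under_reordering(self):
        rng = np.random.default_rng(11)
        df = random_pedigree(rng, n=20)
        groups = {r.id: 1.0 for r in df.itertuples()
                  if r.sire == "" and r.dam == "" and rng.random() < 0.4}
        ped1 = validate_pedigree(df)
        ped2 = validate_pedigree(df.iloc[::-1].reset_index(drop=True))
        q1 = dict(zip(ped1.ids, genetic_group_proportions(ped1, groups)))
        q2 = dict(zip(ped2.ids, genetic_group_proportions(ped2, groups)))
        assert q1 == q2


class TestGeneDrop:
    def test_zero_variance_gives_zero(self):
        ped = validate_pedigree(FULL_SIB_MATING)
        bv = gene_drop_breeding_values(ped, 0.0, seed=1)
        assert np.all(bv == 0.0)

    def test_negative_variance_fatal(self):
        with pytest.raises(ValueError):
            gene_drop_breeding_values(validate_pedigree(TRIO), -1.0, seed=1)

    def test_founder_variance(self):
        founders = ped_frame([(f"f{i}", "", "", "F", 0) for i in range(50)])
        ped = validate_pedigree(founders)
        bv = gene_drop_breeding_values(ped, 4.0, seed=2, n_reps=200)
        assert np.var(bv) == pytest.approx(4.0, rel=0.05)

    def test_descendant_variance_maintained(self, small_dataset):
        """Monte-Carlo: without inbreeding, the variance of BVs in the last
        cohort stays near sigma_A."""
        ped = small_dataset.pedigree
        last = ped.cohort >= ped.cohort.max() - 1
        bv = gene_drop_breeding_values(ped, 9.0, seed=3, n_reps=400)
        v = np.var(bv[:, last], axis=1).mean()
        F = ped.inbreeding[last].mean()
        # inbreeding shrinks within-cohort variance slightly
        assert v == pytest.approx(9.0 * (1 + F) * 0.99, rel=0.12)

    def test_parent_offspring_regression(self):
        ped = validate_pedigree(TRIO)
        bv = gene_drop_breeding_values(ped, 1.0, seed=4, n_reps=4000)
        mid = 0.5 * (bv[:, 0] + bv[:, 1])
        child = bv[:, 2]
        slope = np.cov(child, mid)[0, 1] / np.var(mid)
        assert slope == pytest.approx(1.0, abs=0.1)
        assert np.var(child - mid) == pytest.approx(0.5, rel=0.1)

    def test_multitrait_covariance(self):
        founders = ped_frame([(f"f{i}", "", "", "F", 0) for i in range(200)])
        ped = validate_pedigree(founders)
        S = np.array([[2.0, -0.8], [-0.8, 0.5]])
        bv = gene_drop_breeding_values(ped, S, seed=5, n_reps=50)
        flat = bv.reshape(-1, 2)
        assert np.allclose(np.cov(flat.T), S, atol=0.08)

    def test_generation_levels_parents_earlier(self, small_dataset):
        ped = small_dataset.pedigree
        level_of = np.empty(len(ped), dtype=int)
        for g, idx in enumerate(ped.generation_levels()):
            level_of[idx] = g
        for i in range(len(ped)):
            for p in (ped.sire_idx[i], ped.dam_idx[i]):
                if p >= 0:
                    assert level_of[p] < level_of[i]
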