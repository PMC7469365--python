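"""Covariate encoding, treatment contrasts and the D_s criterion."""

import numpy as np
import pandas as pd
import pytest

import dsalloc as da
from dsalloc.design import ValidationError, covariate_matrix_from_array

from conftest import random_full_rank_instance


def make_table(n=6, **cols):
    data = {"subject_id": [f"s{i}" for i in range(n)]}
    data.update(cols)
    return pd.DataFrame(data)


class TestSubjectTable:
    def test_duplicate_ids_rejected(self):
        df = make_table(3, x=[1.0, 2.0, 3.0])
        df.loc[2, "subject_id"] = "s0"
        with pytest.raises(ValidationError, match="duplicate"):
            da.SubjectTable(df, continuous=("x",))

    def test_missing_value_rejected_with_location(self):
        df = make_table(4, bmi=[21.0, None, 23.0, 24.0])
        with pytest.raises(ValidationError, match=r"bmi.*row 1"):
            da.SubjectTable(df, continuous=("bmi",))

    def test_non_numeric_continuous_rejected(self):
        df = make_table(3, x=["a", "b", "c"])
        with pytest.raises(ValidationError, match="non-numeric"):
            da.SubjectTable(df, continuous=("x",))

    def test_single_subject_rejected(self):
        with pytest.raises(ValidationError, match="at least 2"):
            da.SubjectTable(make_table(1, x=[1.0]), continuous=("x",))


class TestEncodeCovariates:
    def test_intercept_only(self):
        table = da.SubjectTable(make_table(5, unused=[0.0] * 5))
        X = da.encode_covariates(table)
        assert X.n_columns == 1
        assert X.rank == 1
        assert np.allclose(X.matrix[:, 0], 1.0)

    def test_trial_structure_columns_and_rank(self, replica_table, replica_X):
        # intercept + 2 gender indicators + 17 group indicators + 3 continuous
        assert replica_X.n_columns == 1 + 2 + 17 + 3
        # two dependencies: each indicator set sums to the intercept
        expected_rank = np.linalg.matrix_rank(replica_X.matrix)
        assert replica_X.rank == expected_rank == 21

    def test_basis_is_orthonormal_and_spans_columns(self, replica_X):
        B = replica_X.basis
        assert np.allclose(B.T @ B, np.eye(replica_X.rank), atol=1e-10)
        X = replica_X.matrix
        proj = B @ (B.T @ X)
        norms = np.linalg.norm(X, axis=0)
        assert np.all(np.linalg.norm(X - proj, axis=0) <= 1e-8 * norms)

    def test_merged_indicator_columns_leave_ds_unchanged(self):
        rng = np.random.default_rng(3)
        labels = np.array(["a", "b"] * 5)
        table = da.SubjectTable(make_table(10, g=labels), categorical=("g",))
        X_full = da.encode_covariates(table)
        # hand-code the same information: one merged column a+b = intercept
        merged = np.column_stack(
            [np.ones(10), (labels == "a").astype(float) + (labels == "b").astype(float),
             (labels == "a").astype(float)]
        )
        X_merged = covariate_matrix_from_array(merged)
        spec = da.DesignSpec(arm_sizes=(5, 5))
        alloc = da.initial_allocation(spec, rng)
        T = da.treatment_contrasts(alloc, spec)
        assert da.ds_criterion(X_full, T).ds_value == pytest.approx(
            da.ds_criterion(X_merged, T).ds_value, rel=1e-9
        )

    def test_constant_continuous_warns(self):
        table = da.SubjectTable(make_table(4, x=[2.0] * 4), continuous=("x",))
        with pytest.warns(UserWarning, match="constant"):
            X = da.encode_covariates(table)
        assert X.rank == 1
        assert X.warnings_


class TestTreatmentContrasts:
    def test_two_arm_contrast_is_plus_minus_one(self):
        spec = da.DesignSpec(arm_sizes=(3, 3))
        T = da.treatment_contrasts(da.Allocation(np.array([0, 0, 0, 1, 1, 1])), spec)
        col = T.matrix[:, 0]
        assert np.allclose(col, [1, 1, 1, -1, -1, -1])
        assert col @ col == pytest.approx(6.0)

    def test_three_arms_of_54_gram_is_N_times_identity(self, spec_3x54):
        alloc = da.initial_allocation(spec_3x54, 0)
        T = da.treatment_contrasts(alloc, spec_3x54).matrix
        assert np.allclose(T.T @ T, 162 * np.eye(2), atol=1e-8)
        assert np.linalg.det(T.T @ T) == pytest.approx(162**2, rel=1e-6)

    def test_unequal_arms_match_rowwise_accumulation(self):
        spec = da.DesignSpec(arm_sizes=(2, 1, 1))
        alloc = da.Allocation(np.array([0, 1, 0, 2]))
        T = da.treatment_contrasts(alloc, spec).matrix
        H = np.sqrt(3) * da.helmert_contrasts(3)
        expected = np.zeros((2, 2))
        for arm in alloc.arm_of:
            expected += np.outer(H[arm], H[arm])
        assert np.allclose(T.T @ T, expected, atol=1e-10)

    def test_gram_determinant_bounded_by_N_power(self):
        # AM-GM: trace(T'T) = N(t-1) so det(T'T) <= N^(t-1), any arm sizes
        rng = np.random.default_rng(8)
        for _ in range(50):
            t = int(rng.integers(2, 5))
            sizes = tuple(int(s) for s in rng.integers(1, 8, size=t))
            spec = da.DesignSpec(arm_sizes=sizes)
            N = spec.n_subjects
            T = da.treatment_contrasts(da.initial_allocation(spec, rng), spec).matrix
            assert np.linalg.det(T.T @ T) <= N ** (t - 1) * (1 + 1e-10)

    def test_size_mismatch_rejected(self):
        spec = da.DesignSpec(arm_sizes=(3, 3))
        with pytest.raises(ValidationError, match="arm counts"):
            da.treatment_contrasts(da.Allocation(np.array([0, 0, 0, 0, 1, 1])), spec)


class TestDsCriterion:
    def test_intercept_only_reaches_maximum(self):
        N, t = 12, 3
        X = covariate_matrix_from_array(np.ones((N, 1)))
        spec = da.DesignSpec(arm_sizes=(4, 4, 4))
        T = da.treatment_contrasts(da.initial_allocation(spec, 0), spec)
        ev = da.ds_criterion(X, T)
        assert ev.ds_value == pytest.approx(N ** (t - 1), rel=1e-10)
        assert ev.ds_efficiency == pytest.approx(1.0, abs=1e-10)

    def test_arm_indicator_in_X_gives_zero_efficiency(self):
        spec = da.DesignSpec(arm_sizes=(4, 4, 4))
        alloc = da.initial_allocation(spec, 5)
        indicator = (alloc.arm_of == 0).astype(float)
        X = covariate_matrix_from_array(np.column_stack([np.ones(12), indicator]))
        T = da.treatment_contrasts(alloc, spec)
        ev = da.ds_criterion(X, T)
        assert ev.ds_efficiency == 0.0

    def test_appending_contrast_column_forces_zero(self):
        rng = np.random.default_rng(11)
        for t in (2, 3, 4):
            N = 4 * t
            spec = da.DesignSpec(arm_sizes=(4,) * t)
            alloc = da.initial_allocation(spec, rng)
            T = da.treatment_contrasts(alloc, spec)
            for col in range(t - 1):
                X = covariate_matrix_from_array(
                    np.column_stack([np.ones(N), T.matrix[:, col]])
                )
                assert da.ds_criterion(X, T).ds_value == 0.0

    def test_matches_ratio_oracle_on_line_example(self):
        # N=6, t=2, X = [1, (1..6)], arms {1,2,3} vs {4,5,6}
        X = np.column_stack([np.ones(6), np.arange(1.0, 7.0)])
        spec = da.DesignSpec(arm_sizes=(3, 3))
        T = da.treatment_contrasts(da.Allocation(np.array([0, 0, 0, 1, 1, 1])), spec)
        expected = da.ds_via_ratio(X, T)
        got = da.ds_criterion(covariate_matrix_from_array(X), T).ds_value
        assert got == pytest.approx(expected, rel=1e-8)

    def test_dimension_mismatch_rejected(self, replica_X):
        spec = da.DesignSpec(arm_sizes=(3, 3))
        T = da.treatment_contrasts(da.initial_allocation(spec, 0), spec)
        with pytest.raises(ValidationError):
            da.ds_criterion(replica_X, T)


class TestDsEfficiency:
    def test_endpoints_and_inversion(self):
        assert da.ds_efficiency(162.0**2, 162, 3) == pytest.approx(1.0)
        assert da.ds_efficiency(0.0, 162, 3) == 0.0
        assert da.ds_efficiency((0.992 * 162) ** 2, 162, 3) == pytest.approx(0.992)

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            da.ds_efficiency(-1.0, 10, 2)


class TestDsViaRatio:
    def test_orthogonal_two_arm_case(self):
        X = np.ones((6, 1))
        spec = da.DesignSpec(arm_sizes=(3, 3))
        T = da.treatment_contrasts(da.initial_allocation(spec, 0), spec)
        assert da.ds_via_ratio(X, T) == pytest.approx(6.0, rel=1e-10)

    def test_duplicated_column_rejected(self):
        X = np.column_stack([np.ones(6), np.arange(6.0), np.arange(6.0)])
        spec = da.DesignSpec(arm_sizes=(3, 3))
        T = da.treatment_contrasts(da.initial_allocation(spec, 0), spec)
        with pytest.raises(ValidationError, match="singular"):
            da.ds_via_ratio(X, T)

    def test_agrees_with_projection_form_on_200_random_instances(self):
        rng = np.random.default_rng(202)
        for _ in range(200):
            N = int(rng.integers(9, 41))
            p = int(rng.integers(1, 6))
            t = int(rng.choice([2, 3, 4]))
            X, spec, alloc = random_full_rank_instance(rng, N, p, t)
            T = da.treatment_contrasts(alloc, spec)
            ratio = da.ds_via_ratio(X, T)
            proj = da.ds_criterion(covariate_matrix_from_array(X), T).ds_value
            assert proj == pytest.approx(ratio, rel=1e-8)


class TestInvariances:
    def test_ds_invariant_under_column_recombination(self):
        rng = np.random.default_rng(77)
        for _ in range(20):
            X, spec, alloc = random_full_rank_instance(rng, 20, 4, 3)
            T = da.treatment_contrasts(alloc, spec)
            base = da.ds_criterion(covariate_matrix_from_array(X), T).ds_value
            A = rng.standard_normal((5, 5))
            while abs(np.linalg.det(A)) < 1e-3:
                A = rng.standard_normal((5, 5))
            XA = X @ A
            UA = da.CovariateMatrix(
                matrix=XA,
                column_names=tuple(f"x{j}" for j in range(5)),
                basis=np.linalg.qr(XA)[0],
                rank=5,
                rank_tolerance=0.0,
            )
            assert da.ds_criterion(UA, T).ds_value == pytest.approx(base, rel=1e-9)

    def test_ds_invariant_under_centering_and_rescaling(self):
        rng = np.random.default_rng(78)
        X, spec, alloc = random_full_rank_instance(rng, 24, 3, 3)
        T = da.treatment_contrasts(alloc, spec)
        base = da.ds_criterion(covariate_matrix_from_array(X), T).ds_value
        X2 = X.copy()
        X2[:, 1:] = (X2[:, 1:] - X2[:, 1:].mean(axis=0)) / X2[:, 1:].std(axis=0)
        got = da.ds_criterion(covariate_matrix_from_array(X2), T).ds_value
        assert got == pytest.approx(base, rel=1e-9)

    def test_ds_invariant_under_arm_relabeling(self):
        rng = np.random.default_rng(79)
        X, spec, alloc = random_full_rank_instance(rng, 12, 2, 3)
        T = da.treatment_contrasts(alloc, spec)
        base = da.ds_criterion(covariate_matrix_from_array(X), T).ds_value
        for perm in ([1, 0, 2], [2, 0, 1], [1, 2, 0]):
            relabeled = da.Allocation(np.asarray(perm)[alloc.arm_of])
            T2 = da.treatment_contrasts(relabeled, spec)
            got = da.ds_criterion(covariate_matrix_from_array(X), T2).ds_value
            assert got == pytest.approx(base, rel=1e-9)

    def test_efficiency_never_exceeds_one(self):
        rng = np.random.default_rng(80)
        for _ in range(50):
            t = int(rng.integers(2, 5))
            sizes = tuple(int(s) for s in rng.integers(1, 8, size=t))
            spec = da.DesignSpec(arm_sizes=sizes)
            N = spec.n_subjects
            p = int(rng.integers(0, 4))
            X = np.column_stack([np.ones(N), rng.standard_normal((N, p))])
            alloc = da.initial_allocation(spec, rng)
            T = da.treatment_contrasts(alloc, spec)
            ev = da.ds_criterion(covariate_matrix_from_array(X), T)
            assert ev.ds_efficiency <= 1.0 + 1e-10
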