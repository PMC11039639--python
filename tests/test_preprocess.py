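"""Preprocessing: CPM filtering, duplicate collapsing, residualisation,
variance attribution, Pearson co-expression."""

import numpy as np
import pandas as pd
import pytest

import diffpanda as dp
from diffpanda.containers import ExpressionMatrix


def _expr(values, genes=None, samples=None, kind="counts"):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), kind=kind)


class TestCpmFilter:
    def test_hand_computed_cpm_keeps_gene(self):
        # two genes so library sizes are 1e6; row (10,10) has CPM (10,10) > 0.5
        expr = _expr([[10, 10], [999_990, 999_990]])
        kept = dp.cpm_filter(expr, cpm_threshold=0.5, sample_fraction=1.0)
        assert "G0" in kept.gene_names

    def test_all_zero_gene_removed(self, small_counts):
        values = small_counts.values.copy()
        values.iloc[0] = 0.0
        kept = dp.cpm_filter(ExpressionMatrix(values))
        assert values.index[0] not in kept.gene_names

    def test_ceiling_rule_on_required_samples(self):
        # 10 samples, fraction 0.3 -> ceil(3.0) = 3 samples required
        counts = np.zeros((2, 10))
        counts[0, :3] = 1000.0  # exactly 3 samples above threshold
        counts[1, :2] = 1000.0  # only 2
        counts += 0.0
        filler = np.full((1, 10), 1e6)
        expr = _expr(np.vstack([counts, filler]))
        kept = dp.cpm_filter(expr, cpm_threshold=0.5, sample_fraction=0.3)
        assert "G0" in kept.gene_names and "G1" not in kept.gene_names

    def test_invariant_to_row_and_column_order(self, small_counts):
        kept = dp.cpm_filter(small_counts)
        shuffled = ExpressionMatrix(
            small_counts.values.iloc[::-1, ::-1], kind="counts"
        )
        kept_shuffled = dp.cpm_filter(shuffled)
        assert sorted(kept.gene_names) == sorted(kept_shuffled.gene_names)

    def test_all_zero_sample_rejected(self):
        expr = _expr([[1.0, 0.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="all-zero sample"):
            dp.cpm_filter(expr)

    def test_raw_counts_returned_not_cpm(self, small_counts):
        kept = dp.cpm_filter(small_counts)
        pd.testing.assert_frame_equal(kept.values, small_counts.values.loc[kept.gene_names])


class TestCollapseDuplicates:
    def test_duplicates_averaged_in_first_occurrence_order(self):
        values = pd.DataFrame(
            [[1.0, 3.0], [5.0, 5.0], [3.0, 5.0]],
            index=["G1", "G2", "G1"], columns=["S1", "S2"],
        )
        with pytest.warns(UserWarning):
            expr = ExpressionMatrix(values)
        out = dp.collapse_duplicates(expr)
        assert out.gene_names == ["G1", "G2"]
        np.testing.assert_array_equal(out.values.loc["G1"], [2.0, 4.0])

    def test_zero_rows_removed_and_identity_otherwise(self, small_counts):
        values = small_counts.values.copy()
        values.iloc[2] = 0.0
        out = dp.collapse_duplicates(ExpressionMatrix(values))
        assert values.index[2] not in out.gene_names
        untouched = dp.collapse_duplicates(small_counts)
        pd.testing.assert_frame_equal(untouched.values, small_counts.values)


class TestResidualize:
    def test_only_diagnosis_means_output_equals_input(self):
        rng = np.random.default_rng(2)
        expr = _expr(rng.normal(10, 1, size=(4, 8)))
        cov = pd.DataFrame({"diagnosis": ["a", "b"] * 4}, index=expr.sample_names)
        out = dp.residualize(expr, cov)
        np.testing.assert_allclose(out.values.to_numpy(), expr.values.to_numpy(),
                                   atol=1e-10)

    def test_batch_effect_removed(self):
        rng = np.random.default_rng(3)
        n = 40
        batch = np.array(["x", "y"] * (n // 2))
        y = 2.0 * (batch == "y") + rng.normal(0, 0.1, n)
        expr = _expr(y[None, :], kind="residuals")
        cov = pd.DataFrame({"diagnosis": ["a"] * (n // 2) + ["b"] * (n // 2),
                            "batch": batch}, index=expr.sample_names)
        out = dp.residualize(expr, cov)
        resid = out.values.to_numpy()[0]
        bind = (batch == "y").astype(float)
        bc = bind - bind.mean()
        slope = resid @ bc / (bc @ bc)
        assert abs(slope) < 1e-10

    def test_diagnosis_contrast_preserved(self, small_counts, small_covariates):
        out = dp.residualize(small_counts, small_covariates)
        X = pd.get_dummies(small_covariates, columns=["batch"], drop_first=True,
                           dtype=float)
        X["diagnosis"] = (small_covariates["diagnosis"] == "control").astype(float)
        # fitted group-mean difference equals the output group-mean difference
        import numpy.linalg as la
        design = np.column_stack([np.ones(len(X)), X["diagnosis"], X["age"],
                                  X["batch_b2"]])
        for g in range(small_counts.n_genes):
            y = small_counts.values.iloc[g].to_numpy()
            beta = la.lstsq(design, y, rcond=None)[0]
            o = out.values.iloc[g]
            diff = (o[small_covariates["diagnosis"] == "control"].mean()
                    - o[small_covariates["diagnosis"] == "case"].mean())
            assert diff == pytest.approx(beta[1], abs=1e-8)

    def test_idempotent(self, small_counts, small_covariates):
        once = dp.residualize(small_counts, small_covariates)
        twice = dp.residualize(once, small_covariates)
        np.testing.assert_allclose(twice.values.to_numpy(), once.values.to_numpy(),
                                   atol=1e-10)

    def test_collinear_design_rejected(self, small_counts, small_covariates):
        cov = small_covariates.copy()
        cov["age_copy"] = cov["age"]
        with pytest.raises(ValueError, match="collinear"):
            dp.residualize(small_counts, cov)


class TestVariancePartition:
    def test_gene_equal_to_covariate_gets_full_fraction(self):
        # orthogonal design: age pattern identical in both diagnosis groups
        age = np.array([50.0, 60.0, 70.0, 50.0, 60.0, 70.0])
        diagnosis = ["a", "a", "a", "b", "b", "b"]
        expr = _expr(age[None, :])
        cov = pd.DataFrame({"diagnosis": diagnosis, "age": age},
                           index=expr.sample_names)
        vp = dp.variance_partition(expr, cov)
        assert vp.loc["G0", "age"] == pytest.approx(1.0, abs=1e-8)
        assert vp.loc["G0", "residual"] == pytest.approx(0.0, abs=1e-8)

    def test_pure_noise_attributes_to_residual(self):
        fractions = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 200
            expr = _expr(rng.normal(size=(1, n)), kind="residuals")
            cov = pd.DataFrame(
                {"diagnosis": ["a", "b"] * (n // 2), "age": rng.normal(size=n)},
                index=expr.sample_names)
            vp = dp.variance_partition(expr, cov)
            fractions.append(vp.loc["G0", "residual"])
        assert np.mean(fractions) > 0.95

    def test_fractions_sum_to_one(self, small_counts, small_covariates):
        vp = dp.variance_partition(small_counts, small_covariates)
        np.testing.assert_allclose(vp.sum(axis=1).to_numpy(), 1.0, atol=1e-8)
        assert (vp.to_numpy() > -1e-8).all()


class TestPearsonCoexpression:
    def test_hand_computed_correlation(self):
        expr = _expr([[1.0, 2.0, 3.0], [1.0, 2.0, 4.0]], kind="residuals")
        corr = dp.pearson_coexpression(expr)
        expected = np.corrcoef([1, 2, 3], [1, 2, 4])[0, 1]
        assert corr.loc["G0", "G1"] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.9819805060619657, abs=1e-12)

    def test_perfect_anticorrelation_and_diagonal(self):
        expr = _expr([[1.0, 2.0, 3.0], [-1.0, -2.0, -3.0]], kind="residuals")
        corr = dp.pearson_coexpression(expr)
        assert corr.loc["G0", "G1"] == pytest.approx(-1.0)
        np.testing.assert_array_equal(np.diag(corr.to_numpy()), 1.0)

    def test_zero_variance_gene_filled_with_zeros(self):
        expr = _expr([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], kind="residuals")
        with pytest.warns(UserWarning, match="zero-variance"):
            corr = dp.pearson_coexpression(expr)
        assert corr.loc["G0", "G1"] == 0.0
        assert corr.loc["G0", "G0"] == 1.0

    def test_positive_semidefinite_without_fill_ins(self):
        rng = np.random.default_rng(4)
        expr = _expr(rng.normal(size=(10, 25)), kind="residuals")
        corr = dp.pearson_coexpression(expr)
        eigenvalues = np.linalg.eigvalsh(corr.to_numpy())
        assert eigenvalues.min() > -1e-10

    def test_too_few_samples_rejected(self):
        expr = _expr([[1.0, 2.0]], kind="residuals")
        with pytest.raises(ValueError, match="3 samples"):
            dp.pearson_coexpression(expr)


class TestLogTransform:
    def test_values_and_kind(self, small_counts):
        out = dp.log_transform(small_counts)
        np.testing.assert_allclose(
            out.values.to_numpy(), np.log2(small_counts.values.to_numpy() + 1)
        )

    def test_residuals_input_rejected(self, small_counts):
        residuals = ExpressionMatrix(small_counts.values, kind="residuals")
        with pytest.raises(ValueError):
            dp.log_transform(residuals)
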