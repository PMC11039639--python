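"""Synthetic-study generator: planted structure, determinism, priors,
drug database."""

import numpy as np
import pandas as pd
import pytest

import diffpanda as dp
from diffpanda.simulate import SimulationParams


class TestSimulateTruth:
    def test_no_perturbation_gives_identical_matrices(self):
        p = SimulationParams(n_perturbed_up=0, n_perturbed_down=0, n_reversers=0, seed=3)
        t = dp.simulate_truth(p)
        np.testing.assert_array_equal(t.B_case, t.B_control)
        assert not t.perturbed_tfs_up and not t.perturbed_tfs_down

    def test_perturbed_rows_scaled_exactly(self, truth, default_params):
        m = default_params.effect_multiplier
        for tf in truth.perturbed_tfs_up:
            i = truth.tf_names.index(tf)
            np.testing.assert_array_equal(truth.B_case[i], truth.B_control[i] * m)
        for tf in truth.perturbed_tfs_down:
            i = truth.tf_names.index(tf)
            np.testing.assert_array_equal(truth.B_case[i], truth.B_control[i] / m)

    def test_unperturbed_rows_untouched(self, truth):
        planted = truth.perturbed_tfs_up | truth.perturbed_tfs_down
        for i, tf in enumerate(truth.tf_names):
            if tf not in planted:
                np.testing.assert_array_equal(truth.B_case[i], truth.B_control[i])

    def test_deterministic_under_seed(self, default_params, truth):
        again = dp.simulate_truth(default_params)
        np.testing.assert_array_equal(again.B_control, truth.B_control)
        np.testing.assert_array_equal(again.B_case, truth.B_case)
        assert again.perturbed_tfs_up == truth.perturbed_tfs_up

    def test_sparse_support_within_bounds(self, truth, default_params):
        per_gene = (truth.B_control != 0).sum(axis=0)
        assert per_gene.min() >= default_params.min_regulators
        assert per_gene.max() <= default_params.max_regulators

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_tfs": 0},
            {"effect_multiplier": 1.0},
            {"n_perturbed_up": 20, "n_perturbed_down": 20},
            {"n_reversers": 200},
            {"prior_false_positive_rate": 1.5},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationParams(**kwargs)


class TestSimulateCounts:
    def test_shapes_names_and_covariates(self, study, default_params):
        expr, cov = study["expr"], study["covariates"]
        n = 2 * default_params.n_samples_per_group
        assert expr.n_samples == n
        # TF transcripts appended after the target genes
        assert expr.gene_names[-default_params.n_tfs:] == study["truth"].tf_names
        assert set(cov["diagnosis"]) == {"case", "control"}
        assert np.issubdtype(cov["age"].dtype, np.number)
        assert cov["batch"].nunique() > 1

    def test_deterministic_under_seed(self, study, default_params):
        expr2, cov2 = dp.simulate_counts(study["truth"], default_params)
        pd.testing.assert_frame_equal(expr2.values, study["expr"].values)
        pd.testing.assert_frame_equal(cov2, study["covariates"])

    def test_zero_covariate_effect_leaves_no_slope(self):
        p = SimulationParams(covariate_effect_sd=0.0, n_samples_per_group=150, seed=11)
        t = dp.simulate_truth(p)
        expr, cov = dp.simulate_counts(t, p)
        log = np.log2(expr.values.to_numpy() + 1)
        age = (cov["age"] - cov["age"].mean()).to_numpy()
        slopes = log @ age / (age @ age)
        # per-gene regression slopes on age scatter around zero
        assert abs(np.mean(slopes)) < 0.01

    def test_perturbed_tf_target_correlation_shifts_in_planted_direction(self):
        """Across seeds, the mean correlation between an amplified TF's
        transcript and its targets is higher in cases than controls, and
        lower for attenuated TFs (Monte-Carlo over 10 seeds)."""
        up_shift, down_shift = [], []
        for seed in range(10):
            p = SimulationParams(seed=seed)
            t = dp.simulate_truth(p)
            expr, cov = dp.simulate_counts(t, p)
            log = np.log2(expr.values + 1)
            groups = {
                g: log[cov.index[cov["diagnosis"] == g]] for g in ("case", "control")
            }
            for tfset, out in ((t.perturbed_tfs_up, up_shift),
                               (t.perturbed_tfs_down, down_shift)):
                for tf in tfset:
                    i = t.tf_names.index(tf)
                    targets = [t.gene_names[j] for j in np.nonzero(t.B_control[i])[0]]
                    shift = 0.0
                    for g, sign in (("case", 1), ("control", -1)):
                        sub = groups[g]
                        r = sub.loc[targets].T.corrwith(sub.loc[tf]).mean()
                        shift += sign * r
                    out.append(shift)
        assert np.mean(up_shift) > 0
        assert np.mean(down_shift) < 0

    def test_null_truth_gives_uncorrelated_genes(self):
        p = SimulationParams(n_perturbed_up=0, n_perturbed_down=0, n_reversers=0,
                             n_samples_per_group=100, seed=5)
        t = dp.simulate_truth(p)
        t.B_control[:] = 0.0
        t.B_case[:] = 0.0
        expr, cov = dp.simulate_counts(t, p)
        # correlations of depth-adjusted residuals, the pipeline's object
        residuals = dp.residualize(dp.log_transform(expr), cov)
        corr = np.corrcoef(residuals.values.to_numpy()[: p.n_genes])
        off = corr[np.triu_indices_from(corr, k=1)]
        # pure noise: correlations concentrate near 0 at n = 200 samples
        assert np.abs(off).mean() < 0.08

    def test_axis_mismatch_rejected(self, truth):
        bad = SimulationParams(n_tfs=5, n_genes=10, n_perturbed_up=1,
                               n_perturbed_down=1, seed=0)
        with pytest.raises(ValueError, match="axes"):
            dp.simulate_counts(truth, bad)


class TestSimulatePriors:
    def test_noiseless_prior_equals_support(self, truth, default_params):
        p = default_params.replace(prior_false_positive_rate=0.0,
                                   prior_false_negative_rate=0.0)
        motif, ppi = dp.simulate_priors(truth, p)
        np.testing.assert_array_equal(
            motif.weights.to_numpy(), (truth.B_control != 0).astype(float)
        )

    def test_total_false_negatives_erase_support(self, truth, default_params):
        p = default_params.replace(prior_false_negative_rate=1.0)
        motif, _ = dp.simulate_priors(truth, p)
        on_support = motif.weights.to_numpy()[truth.B_control != 0]
        assert (on_support == 0).all()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_ppi_symmetric_unit_diagonal(self, truth, default_params, seed):
        _, ppi = dp.simulate_priors(truth, default_params.replace(seed=seed))
        arr = ppi.scores.to_numpy()
        np.testing.assert_array_equal(arr, arr.T)
        np.testing.assert_array_equal(np.diag(arr), 1.0)

    def test_noiseless_ppi_is_shared_target_indicator(self, truth, default_params):
        p = default_params.replace(prior_false_positive_rate=0.0,
                                   prior_false_negative_rate=0.0)
        _, ppi = dp.simulate_priors(truth, p)
        support = (truth.B_control != 0).astype(float)
        expected = ((support @ support.T) > 0).astype(float)
        np.fill_diagonal(expected, 1.0)
        np.testing.assert_array_equal(ppi.scores.to_numpy(), expected)


class TestSimulateDrugDB:
    def test_noiseless_reverser_is_exact_sign_flip(self, truth, default_params):
        db, planted = dp.simulate_drug_db(truth, default_params)
        rev = db.drugs["reverser01"]
        assert rev.positive == sorted(truth.perturbed_tfs_down)
        assert rev.negative == sorted(truth.perturbed_tfs_up)
        assert "reverser01" in planted

    def test_noiseless_reverser_cosine_is_minus_one(self, truth, default_params):
        db, _ = dp.simulate_drug_db(truth, default_params)
        assert dp.cosine_score(truth.disease_signature(), db.drugs["reverser01"]) == -1.0

    def test_zero_reversers_plants_nothing(self, truth, default_params):
        db, planted = dp.simulate_drug_db(truth, default_params.replace(n_reversers=0))
        assert planted == set()
        assert len(db) == default_params.n_drugs

    def test_reverser_without_perturbation_rejected(self, default_params):
        p = default_params.replace(n_perturbed_up=0, n_perturbed_down=0)
        t = dp.simulate_truth(p)
        with pytest.raises(ValueError, match="perturbation"):
            dp.simulate_drug_db(t, p)

    def test_deterministic_under_seed(self, truth, default_params):
        db1, _ = dp.simulate_drug_db(truth, default_params)
        db2, _ = dp.simulate_drug_db(truth, default_params)
        assert {n: (s.positive, s.negative) for n, s in db1.drugs.items()} == {
            n: (s.positive, s.negative) for n, s in db2.drugs.items()
        }
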