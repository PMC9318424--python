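"""Regression fit oracles, cross-validation contracts and noise consistency."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from synergrasp.config import FeatureConfig, Protocol, SimulationParams
from synergrasp.decoder import (cross_validate, fit, fit_fold,
                                predict_weights, subject_features)
from synergrasp.features import FeatureMatrix, LeakageError
from synergrasp.synergy import SynergySet, SynergyWeights
from synergrasp.synthetic import generate_cohort, make_ground_truth, true_weights


def _fm(X: np.ndarray, grasp=None) -> FeatureMatrix:
    m, p = X.shape
    return FeatureMatrix(
        X=X,
        provenance=pd.DataFrame({"electrode": ["e"] * p, "window": range(p)}),
        band=(0.1, 56.0),
        trial_index=pd.DataFrame({
            "subject": "s", "trial_id": np.arange(m),
            "grasp": grasp if grasp is not None else np.ones(m, int)}),
    )


def _weights(C: np.ndarray, grasp=None) -> SynergyWeights:
    m = C.shape[0]
    idx = pd.DataFrame({"subject": "s", "trial_id": np.arange(m),
                        "grasp": grasp if grasp is not None
                        else np.ones(m, int)})
    return SynergyWeights(C=C, trial_index=idx)


def _sset(n_syn: int, n: int = 20) -> SynergySet:
    S = np.zeros((n_syn, n))
    for j in range(n_syn):
        S[j, j] = 1.0
    return SynergySet(S=S, variance_fractions=np.full(n_syn, 1 / n_syn),
                      threshold=0.85, epoch_samples=n // 2, n_joints=2)


class TestFit:
    def test_recovers_planted_beta(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(60, 8))
        beta0 = rng.normal(size=(8, 3))
        C = X @ beta0
        model = fit(_fm(X), _weights(C), _sset(3), intercept=True)
        assert np.abs(model.betas[1] - beta0).max() < 1e-8

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 6))
        C = rng.normal(size=(50, 2))
        model = fit(_fm(X), _weights(C), _sset(2), intercept=False)
        beta_oracle = np.linalg.solve(X.T @ X, X.T @ C)
        assert np.abs(model.betas[1] - beta_oracle).max() < 1e-8

    def test_zero_feature_column_gets_zero_row(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 5))
        X[:, 2] = 0.0
        C = rng.normal(size=(30, 2))
        model = fit(_fm(X), _weights(C), _sset(2), intercept=False)
        assert np.abs(model.betas[1][2]).max() < 1e-12  # minimum-norm

    def test_zero_targets_zero_beta(self):
        X = np.random.default_rng(3).normal(size=(20, 4))
        model = fit(_fm(X), _weights(np.zeros((20, 2))), _sset(2))
        assert np.abs(model.betas[1]).max() < 1e-12

    def test_row_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fit(_fm(np.zeros((10, 3))), _weights(np.zeros((9, 2))), _sset(2))

    def test_per_task_fits_separately(self):
        rng = np.random.default_rng(4)
        grasp = np.repeat([1, 2], 25)
        X = rng.normal(size=(50, 4))
        C = rng.normal(size=(50, 2))
        model = fit(_fm(X, grasp), _weights(C, grasp), _sset(2))
        assert set(model.betas) == {1, 2}


class TestPredict:
    def test_zero_features_zero_weights_without_intercept(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 4))
        C = rng.normal(size=(30, 2))
        model = fit(_fm(X), _weights(C), _sset(2), intercept=False)
        out = predict_weights(_fm(np.zeros((3, 4))), model)
        assert np.all(out.C == 0)

    def test_linearity_duplicated_row(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(30, 4))
        C = rng.normal(size=(30, 2))
        model = fit(_fm(X), _weights(C), _sset(2))
        X_test = np.vstack([X[0], X[0]])
        out = predict_weights(_fm(X_test), model)
        assert np.array_equal(out.C[0], out.C[1])

    def test_reducer_mismatch_rejected(self):
        from synergrasp.features import FeatureReducer
        rng = np.random.default_rng(7)
        fm = _fm(rng.normal(size=(30, 6)))
        red = FeatureReducer(rule=3).fit(fm)
        model = fit(red.transform(fm), _weights(rng.normal(size=(30, 2))),
                    _sset(2), reducer=red)
        other = FeatureReducer(rule=3).fit(fm)
        with pytest.raises(ValueError):
            predict_weights(other.transform(fm), model)


class TestCrossValidate:
    def test_split_sizes_and_disjointness(self, cohort_noiseless):
        folds = cross_validate(cohort_noiseless, n_folds=3, seed=0)
        for f in folds:
            assert len(f.train_subjects) == 1 and len(f.test_subjects) == 1
            assert not set(f.train_subjects) & set(f.test_subjects)

    def test_deterministic_given_seed(self, cohort_noiseless):
        a = cross_validate(cohort_noiseless, n_folds=2, seed=9)
        b = cross_validate(cohort_noiseless, n_folds=2, seed=9)
        for fa, fb in zip(a, b):
            assert fa.train_subjects == fb.train_subjects
            pd.testing.assert_frame_equal(fa.rho_table, fb.rho_table)

    def test_invalid_fold_count(self, cohort_noiseless):
        with pytest.raises(ValueError):
            cross_validate(cohort_noiseless, n_folds=0, seed=0)

    def test_noiseless_weight_recovery(self, gt_noiseless, tiny_protocol,
                                       cohort_noiseless, feature_cfg):
        """Without noise the decoded weights match the generator's draw."""
        cfg = FeatureConfig(pca_rule=6)  # keep all encoding dimensions
        features = subject_features(cohort_noiseless, cfg)
        ids = cohort_noiseless.subject_ids()
        model = fit_fold(cohort_noiseless, [ids[0]], features, cfg,
                         threshold=0.9999)
        X_test = model.reducer.transform(features[ids[1]])
        decoded = predict_weights(X_test, model)
        sub_seed = int(np.random.SeedSequence(3).generate_state(2)[1])
        _, C_true = true_weights(gt_noiseless, tiny_protocol, sub_seed)
        # decoded weights refer to the training-set synergy basis; rotate
        # the generator's weights into that basis for comparison
        R = gt_noiseless.synergies @ model.synergy_set.S.T
        C_ref = C_true @ R
        rel = (np.abs(decoded.C - C_ref).max()
               / np.abs(C_ref).max())
        assert rel < 1e-3

    def test_noiseless_rho_approaches_one(self, cohort_noiseless):
        folds = cross_validate(cohort_noiseless, n_folds=2, seed=1,
                               cfg=FeatureConfig(pca_rule=6),
                               threshold=0.9999)
        pooled = pd.concat([f.rho_table for f in folds])
        assert pooled["rho"].mean() > 0.999

    def test_accuracy_monotone_in_feature_noise(self, tiny_protocol):
        """Decoding degrades as band-power noise grows (3-point sweep)."""
        means = []
        for sd in (0.0, 10.0, 80.0):
            params = SimulationParams(noise_sd_kin=0.0, noise_sd_feat=sd,
                                      background_scale=0.0)
            gt = make_ground_truth(6, 10, tiny_protocol.kin_epoch_samples,
                                   6, seed=5, params=params)
            cohort = generate_cohort(gt, 2, tiny_protocol, seed=4)
            folds = cross_validate(cohort, n_folds=1, seed=2)
            means.append(pd.concat([f.rho_table for f in folds])["rho"].mean())
        assert means[0] > means[1] > means[2]

    def test_no_leakage_guard_trips_on_full_fit(self, cohort_noiseless,
                                                feature_cfg):
        from synergrasp.features import FeatureReducer, concat_features
        features = subject_features(cohort_noiseless, feature_cfg)
        ids = cohort_noiseless.subject_ids()
        leaky = FeatureReducer(rule=3).fit(
            concat_features([features[s] for s in ids]))
        with pytest.raises(LeakageError):
            leaky.assert_fitted_on(features[ids[0]].trial_index)
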