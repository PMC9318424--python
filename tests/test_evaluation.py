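"""Accuracy scoring, aggregation and independency-density maps."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from synergrasp.config import FeatureConfig
from synergrasp.decoder import subject_features
from synergrasp.evaluation import (IndependencyMap, UndefinedCorrelationError,
                                   aggregate, band_modulation,
                                   decoding_error, format_task_subject_table,
                                   independency_density, independency_map,
                                   pearson_rho)
from synergrasp.features import concat_features
from synergrasp.montage import CHANNEL_NAMES, neighborhood
from synergrasp.synergy import SynergyWeights
from synergrasp.synthetic import true_weights


class TestPearsonRho:
    def test_identical_series(self):
        x = np.array([1.0, 5.0, 2.0, 4.0])
        assert pearson_rho(x, x) == pytest.approx(1.0)

    def test_negated_series(self):
        x = np.array([1.0, 5.0, 2.0, 4.0])
        assert pearson_rho(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        assert pearson_rho([1, 2, 3], [1, 2, 4]) == pytest.approx(0.982,
                                                                  abs=5e-4)

    def test_constant_series_flagged(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_rho([1, 1, 1], [1, 2, 3])
        with pytest.raises(UndefinedCorrelationError):
            pearson_rho([1, 2, 3], [2, 2, 2])

    def test_length_validation(self):
        with pytest.raises(ValueError):
            pearson_rho([1, 2], [1, 2])
        with pytest.raises(ValueError):
            pearson_rho([1, 2, 3], [1, 2])


class TestDecodingError:
    @pytest.mark.parametrize("rho,err", [(1.0, 0.0), (-1.0, 0.0),
                                         (0.3, 0.7), (0.0, 1.0)])
    def test_values(self, rho, err):
        assert decoding_error(rho) == pytest.approx(err)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            decoding_error(1.5)

    def test_sign_flip_symmetry(self):
        for rho in np.linspace(-1, 1, 11):
            assert decoding_error(rho) == pytest.approx(decoding_error(-rho))


def _table(rows):
    return pd.DataFrame(rows, columns=["subject", "trial_id", "grasp",
                                       "joint", "rho"])


class TestAggregate:
    def test_single_entry(self):
        t = _table([("s1", 0, 1, "TMCP", 0.8)])
        out = aggregate(t, "overall")
        assert out.at[0, "mean"] == pytest.approx(80.0)
        assert out.at[0, "sd"] == 0.0

    def test_two_entry_hand_sd(self):
        t = _table([("s1", 0, 1, "TMCP", 0.6), ("s1", 1, 1, "TMCP", 0.8)])
        out = aggregate(t, "overall")
        assert out.at[0, "mean"] == pytest.approx(70.0)
        # hand oracle: sd of [60, 80] with ddof=1 is 10*sqrt(2)
        assert out.at[0, "sd"] == pytest.approx(10 * np.sqrt(2))

    def test_grouping_partitions_all_entries(self):
        rng = np.random.default_rng(0)
        t = _table([(f"s{i % 3}", i, (i % 6) + 1, "TMCP", rng.uniform(-1, 1))
                    for i in range(60)])
        per_grasp = aggregate(t, "grasp")
        assert per_grasp["n"].sum() == len(t)
        overall = aggregate(t, "overall")
        # overall mean equals trial-weighted mean of group means
        weighted = (per_grasp["mean"] * per_grasp["n"]).sum() / len(t)
        assert overall.at[0, "mean"] == pytest.approx(weighted)

    def test_nan_rows_excluded(self):
        t = _table([("s1", 0, 1, "TMCP", 0.5),
                    ("s1", 1, 1, "TMCP", np.nan)])
        assert aggregate(t, "overall").at[0, "n"] == 1

    def test_error_metric(self):
        t = _table([("s1", 0, 1, "TMCP", -0.8)])
        out = aggregate(t, "overall", metric="error")
        assert out.at[0, "mean"] == pytest.approx(0.2)

    def test_task_subject_layout(self):
        t = _table([("s1", 0, g, "TMCP", 0.5) for g in (1, 2)]
                   + [("s2", 0, g, "TMCP", 0.7) for g in (1, 2)])
        fmt = format_task_subject_table(t)
        assert list(fmt.index) == ["Task 1", "Task 2"]
        assert fmt.at["Task 1", "s2"] == "70.0 ± 0.0%"


class TestIndependencyDensity:
    def test_zero_betas_zero_density(self):
        betas = {e: [np.zeros((3, 2))] for e in range(4)}
        D = independency_density(betas, 4, 2)
        assert np.all(D == 0)

    def test_single_coefficient_squared(self):
        betas = {0: [np.array([[2.0]])]}
        D = independency_density(betas, 1, 1)
        assert D[0, 0] == 4.0

    def test_missing_electrode_rejected(self):
        with pytest.raises(ValueError, match="electrode 1"):
            independency_density({0: [np.zeros((2, 1))]}, 2, 1)

    def test_task_ordering_invariance(self):
        rng = np.random.default_rng(1)
        tasks = [rng.normal(size=(3, 2)) for _ in range(4)]
        a = independency_density({0: tasks}, 1, 2)
        b = independency_density({0: tasks[::-1]}, 1, 2)
        assert np.allclose(a, b)


@pytest.fixture(scope="module")
def recovery_setup(gt_default, cohort3, default_protocol, feature_cfg):
    """True weights + raw features for the three default-noise subjects."""
    feats = subject_features(cohort3, feature_cfg)
    sub_seeds = np.random.SeedSequence(11).generate_state(3)
    allC = np.vstack([true_weights(gt_default, default_protocol, int(s))[1]
                      for s in sub_seeds])
    fm = concat_features([feats[s] for s in cohort3.subject_ids()])
    return fm, SynergyWeights(C=allC, trial_index=fm.trial_index), cohort3


def _argmax_on_planted_patch(gt, stat_row: np.ndarray, j: int) -> bool:
    """True if the densest electrode's regression neighborhood overlaps the
    strong part of synergy j's planted coupling patch."""
    argmax = int(np.argmax(stat_row))
    members = neighborhood(argmax)
    peak = gt.coupling[:, j].max()
    return max(gt.coupling[m, j] for m in members) >= 0.5 * peak


class TestIndependencyMap:
    def test_planted_coupling_recovered(self, gt_default, recovery_setup):
        fm, weights, _ = recovery_setup
        imap = independency_map(fm, weights, CHANNEL_NAMES)
        assert np.all(imap.D >= 0)
        for j in range(gt_default.n_syn):
            assert _argmax_on_planted_patch(gt_default, imap.D[j], j), (
                f"synergy {j + 1} density peaks at "
                f"{CHANNEL_NAMES[int(np.argmax(imap.D[j]))]}, planted at "
                f"{CHANNEL_NAMES[gt_default.coupling_centers[j]]}"
            )

    def test_correlation_statistic_also_recovers(self, gt_default,
                                                 recovery_setup):
        fm, weights, _ = recovery_setup
        imap = independency_map(fm, weights, CHANNEL_NAMES)
        for j in range(gt_default.n_syn):
            assert _argmax_on_planted_patch(gt_default, imap.R[j], j)

    def test_full_band_consistency_with_band_modulation(self, recovery_setup):
        fm, weights, _ = recovery_setup
        direct = independency_map(fm, weights, CHANNEL_NAMES)
        via_bands = band_modulation({"full": fm}, weights, CHANNEL_NAMES)
        assert np.allclose(direct.D, via_bands["full"].D)

    def test_encoding_band_dominates(self, recovery_setup, feature_cfg):
        """The 24 Hz carrier encodes in beta: its map dwarfs the mu map."""
        fm, weights, cohort = recovery_setup
        feats_beta, feats_mu = [], []
        for sid, (_, eeg) in zip(cohort.subject_ids(), cohort.subjects):
            from synergrasp.features import extract_features, preprocess
            sess = preprocess(eeg)
            sess.subject = sid
            feats_beta.append(extract_features(sess, feature_cfg,
                                               band=(18.0, 30.0)))
            feats_mu.append(extract_features(sess, feature_cfg,
                                             band=(8.0, 12.0)))
        maps = band_modulation({"beta": feats_beta, "mu": feats_mu},
                               weights, CHANNEL_NAMES)
        assert maps["beta"].D.max() > 2 * maps["mu"].D.max()

    def test_empty_band_list(self, recovery_setup):
        _, weights, _ = recovery_setup
        assert band_modulation({}, weights, CHANNEL_NAMES) == {}

    def test_map_frame_layout(self, recovery_setup):
        fm, weights, _ = recovery_setup
        imap = independency_map(fm, weights, CHANNEL_NAMES)
        df = imap.to_frame()
        assert list(df.index) == list(CHANNEL_NAMES)
        assert df.shape == (32, weights.C.shape[1])
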