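"""Cross-subject neural decoder: EEG features -> synergy weights -> kinematics.

The decoder is a multivariate linear regression C = X beta fitted on the
training subject group (one regression per grasp type by default) and
applied to held-out subjects, whose hand kinematics are then reconstructed
by linearly combining the decoded weights with the training-set synergies.
Generalization is evaluated with repeated shuffled half/half subject
splits ("10-fold cross-validation with shuffled subjects").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import synergy as syn
from .config import FeatureConfig
from .features import (FeatureMatrix, FeatureReducer, concat_features,
                       extract_features, preprocess)
from .kinematics import cohort_velocity_matrix, session_velocity_matrix
from .sessions import Cohort
from .synergy import SynergySet, SynergyWeights

logger = logging.getLogger(__name__)


@dataclass
class DecoderModel:
    """Fitted regression plus everything needed to decode new subjects."""

    betas: dict[int, np.ndarray]          # grasp -> [p x n_syn]
    x_means: dict[int, np.ndarray]        # grasp -> [p] training feature mean
    c_means: dict[int, np.ndarray]        # grasp -> [n_syn] training weight mean
    reducer: Optional[FeatureReducer]
    synergy_set: SynergySet
    per_task: bool = True
    intercept: bool = True
    fold_meta: dict = field(default_factory=dict)

    @property
    def n_syn(self) -> int:
        return self.synergy_set.n_syn

    #: key used for the pooled (non-per-task) regression
    POOLED: int = 0


def fit(
    X: FeatureMatrix,
    C: SynergyWeights,
    synergy_set: SynergySet,
    reducer: Optional[FeatureReducer] = None,
    per_task: bool = True,
    intercept: bool = True,
) -> DecoderModel:
    """Least-squares fit of beta in C = X beta on training rows.

    With ``per_task`` (default) one regression is fitted per grasp type.
    ``intercept`` centers X and C on their training means and restores the
    weight mean at prediction; with ``intercept=False`` the raw bilinear
    form is fitted. Rank-deficient feature matrices fall back to the
    minimum-norm solution (logged).
    """
    if X.X.shape[0] != C.C.shape[0]:
        raise ValueError(
            f"{X.X.shape[0]} feature rows but {C.C.shape[0]} weight rows"
        )
    groups = (
        {int(g): np.flatnonzero(X.trial_index["grasp"].to_numpy() == g)
         for g in np.unique(X.trial_index["grasp"])}
        if per_task else {DecoderModel.POOLED: np.arange(X.X.shape[0])}
    )
    betas, x_means, c_means = {}, {}, {}
    for g, rows in groups.items():
        Xg, Cg = X.X[rows], C.C[rows]
        xm = Xg.mean(axis=0) if intercept else np.zeros(Xg.shape[1])
        cm = Cg.mean(axis=0) if intercept else np.zeros(Cg.shape[1])
        beta, _, rank, sv = np.linalg.lstsq(Xg - xm, Cg - cm, rcond=None)
        if rank < Xg.shape[1]:
            logger.warning(
                "rank-deficient features for task %s (rank %d < %d); "
                "using the minimum-norm solution", g, rank, Xg.shape[1]
            )
        if sv.size and sv[-1] > 0:
            logger.debug("task %s condition number %.3g", g, sv[0] / sv[-1])
        betas[g], x_means[g], c_means[g] = beta, xm, cm
    return DecoderModel(betas=betas, x_means=x_means, c_means=c_means,
                        reducer=reducer, synergy_set=synergy_set,
                        per_task=per_task, intercept=intercept)


def predict_weights(X_test: FeatureMatrix, model: DecoderModel) -> SynergyWeights:
    """Decode synergy weights C-hat = X beta for held-out trials."""
    if model.reducer is not None and X_test.reducer_id != model.reducer.reducer_id:
        raise ValueError(
            "test features were not produced with the model's training-fit "
            "reducer"
        )
    n = X_test.X.shape[0]
    C_hat = np.zeros((n, model.n_syn))
    if model.per_task:
        grasp = X_test.trial_index["grasp"].to_numpy()
        for g, beta in model.betas.items():
            rows = np.flatnonzero(grasp == g)
            if rows.size == 0:
                continue
            C_hat[rows] = ((X_test.X[rows] - model.x_means[g]) @ beta
                           + model.c_means[g])
    else:
        g = DecoderModel.POOLED
        C_hat = (X_test.X - model.x_means[g]) @ model.betas[g] + model.c_means[g]
    return SynergyWeights(C=C_hat, trial_index=X_test.trial_index)


def decode_kinematics(weights: SynergyWeights,
                      synergies: SynergySet) -> list[np.ndarray]:
    """Reconstruct velocity epochs from decoded weights (delegates to the
    synergy module)."""
    return syn.reconstruct(weights, synergies)


@dataclass
class FoldResult:
    """One shuffled train/test split and its decoded-trial scores."""

    fold: int
    train_subjects: list[str]
    test_subjects: list[str]
    n_syn: int
    n_components: int
    rho_table: pd.DataFrame    # columns subject, trial_id, grasp, joint, rho
    decoded_weights: Optional[SynergyWeights] = None
    decoded_epochs: Optional[list[np.ndarray]] = None
    recorded_epochs: Optional[list[np.ndarray]] = None
    model: Optional[DecoderModel] = None


def _split_subjects(ids: Sequence[str],
                    rng: np.random.Generator) -> tuple[list[str], list[str]]:
    """Random half/half partition (floor/ceil for odd counts)."""
    perm = rng.permutation(len(ids))
    n_train = len(ids) // 2
    train = [ids[i] for i in perm[:n_train]]
    test = [ids[i] for i in perm[n_train:]]
    return train, test


def subject_features(
    cohort: Cohort,
    cfg: FeatureConfig,
    band: tuple[float, float] | None = None,
    do_preprocess: bool = True,
) -> dict[str, FeatureMatrix]:
    """Raw (unreduced) per-subject feature matrices, computed once.

    Feature extraction involves no fitting, so it can safely be cached
    across folds; only the reducer and regression are fold-specific.
    """
    out: dict[str, FeatureMatrix] = {}
    for sid, (_, eeg) in zip(cohort.subject_ids(), cohort.subjects):
        sess = preprocess(eeg) if do_preprocess else eeg
        if sess.subject is None:
            sess.subject = sid
        out[sid] = extract_features(sess, cfg, band=band)
    return out


def _per_joint_rho(recorded: np.ndarray, decoded: np.ndarray) -> np.ndarray:
    """Pearson correlation per joint column; NaN where undefined."""
    out = np.full(recorded.shape[1], np.nan)
    for j in range(recorded.shape[1]):
        a, b = recorded[:, j], decoded[:, j]
        sa, sb = a.std(), b.std()
        if sa > 0 and sb > 0:
            out[j] = float(np.corrcoef(a, b)[0, 1])
    return out


def fit_fold(
    cohort: Cohort,
    train_ids: Sequence[str],
    features: dict[str, FeatureMatrix],
    cfg: FeatureConfig,
    threshold: float = 0.85,
    per_task: bool = True,
    intercept: bool = True,
) -> DecoderModel:
    """Fit synergies, reducer and regression on the training subjects only."""
    ids = cohort.subject_ids()
    kin_by_id = {sid: kin for sid, (kin, _) in zip(ids, cohort.subjects)}
    for sid, kin in kin_by_id.items():
        if kin.subject is None:
            kin.subject = sid

    V_train = cohort_velocity_matrix([kin_by_id[s] for s in train_ids],
                                     cfg.epoch_s)
    decomp = syn.decompose(V_train)
    sset = syn.select(decomp, threshold,
                      joint_labels=cohort.subjects[0][0].joint_labels)
    C_train = syn.project_weights(V_train, sset)

    X_train_raw = concat_features([features[s] for s in train_ids])
    reducer = FeatureReducer(rule=cfg.pca_rule).fit(X_train_raw)
    reducer.assert_fitted_on(X_train_raw.trial_index)  # no-leakage guard
    X_train = reducer.transform(X_train_raw)

    model = fit(X_train, C_train, sset, reducer=reducer,
                per_task=per_task, intercept=intercept)
    model.fold_meta = {"train_subjects": list(train_ids)}
    return model


def decode_subjects(
    cohort: Cohort,
    test_ids: Sequence[str],
    model: DecoderModel,
    features: dict[str, FeatureMatrix],
    cfg: FeatureConfig,
    keep_epochs: bool = False,
) -> tuple[pd.DataFrame, SynergyWeights, list, list]:
    """Decode held-out subjects and score per-joint correlations."""
    ids = cohort.subject_ids()
    kin_by_id = {sid: kin for sid, (kin, _) in zip(ids, cohort.subjects)}
    X_test_raw = concat_features([features[s] for s in test_ids])
    X_test = model.reducer.transform(X_test_raw)
    weights = predict_weights(X_test, model)
    decoded = decode_kinematics(weights, model.synergy_set)

    recorded_parts = []
    for sid in test_ids:
        Vs = session_velocity_matrix(kin_by_id[sid], cfg.epoch_s)
        recorded_parts.extend(Vs.epoch(i) for i in range(Vs.V.shape[0]))

    rows = []
    idx = weights.trial_index.reset_index(drop=True)
    joint_labels = model.synergy_set.joint_labels or tuple(
        f"J{j}" for j in range(model.synergy_set.n_joints))
    for i, (rec, dec) in enumerate(zip(recorded_parts, decoded)):
        rho = _per_joint_rho(rec, dec)
        for j, r in enumerate(rho):
            rows.append(
                (idx.at[i, "subject"], int(idx.at[i, "trial_id"]),
                 int(idx.at[i, "grasp"]), joint_labels[j], r)
            )
    table = pd.DataFrame(rows, columns=["subject", "trial_id", "grasp",
                                        "joint", "rho"])
    if keep_epochs:
        return table, weights, decoded, recorded_parts
    return table, weights, [], []


def cross_validate(
    cohort: Cohort,
    n_folds: int = 10,
    seed: int = 0,
    cfg: FeatureConfig | None = None,
    threshold: float = 0.85,
    per_task: bool = True,
    intercept: bool = True,
    keep_models: bool = False,
    features: dict[str, FeatureMatrix] | None = None,
) -> list[FoldResult]:
    """Repeated shuffled half/half cross-subject validation.

    Each fold draws an independent random half/half subject partition,
    fits synergies, feature reduction and regression on the training half
    only, decodes the other half, and scores per-joint Pearson rho for
    every test trial. Deterministic given ``seed``.
    """
    if n_folds < 1:
        raise ValueError("n_folds must be >= 1")
    if cohort.n_subjects < 2:
        raise ValueError("cohort must contain at least 2 subjects")
    cfg = cfg or FeatureConfig()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if features is None:
        features = subject_features(cohort, cfg)

    results: list[FoldResult] = []
    ids = cohort.subject_ids()
    for fold in range(n_folds):
        train_ids, test_ids = _split_subjects(ids, rng)
        assert not set(train_ids) & set(test_ids)
        model = fit_fold(cohort, train_ids, features, cfg,
                         threshold=threshold, per_task=per_task,
                         intercept=intercept)
        table, weights, dec, rec = decode_subjects(
            cohort, test_ids, model, features, cfg, keep_epochs=False)
        logger.info("fold %d: %d synergies, %d components, mean rho %.3f",
                    fold, model.n_syn, model.reducer.n_components,
                    np.nanmean(table["rho"]))
        results.append(FoldResult(
            fold=fold, train_subjects=train_ids, test_subjects=test_ids,
            n_syn=model.n_syn, n_components=model.reducer.n_components,
            rho_table=table, decoded_weights=weights,
            model=model if keep_models else None,
        ))
    return results
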