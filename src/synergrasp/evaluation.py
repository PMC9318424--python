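"""Decoding accuracy scores and cortical-correlate maps.

Accuracy is the Pearson correlation rho between recorded and decoded
joint-velocity trajectories (reported as a percentage); decoding error is
1 - |rho|. The neural independency density D_n of synergy n maps which
electrode neighborhoods carry its encoding: features are re-extracted from
each electrode plus its nearest neighbors, regressed per grasp task onto
the synergy weights, and the squared regression coefficients are summed
over features and tasks, D_n = sum_k sum_m beta_mk^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import FeatureMatrix, concat_features
from .montage import DEFAULT_RADIUS, neighborhood
from .synergy import SynergyWeights


class UndefinedCorrelationError(ValueError):
    """Pearson correlation requested for a constant series."""


def pearson_rho(recorded: np.ndarray, decoded: np.ndarray) -> float:
    """Sample Pearson correlation between two equally long series."""
    a = np.asarray(recorded, float).ravel()
    b = np.asarray(decoded, float).ravel()
    if a.size != b.size:
        raise ValueError("series lengths differ")
    if a.size < 3:
        raise ValueError("need at least 3 samples")
    if a.std() == 0 or b.std() == 0:
        raise UndefinedCorrelationError("correlation undefined for a "
                                        "constant series")
    return float(np.corrcoef(a, b)[0, 1])


def decoding_error(rho: float) -> float:
    """Decoding error 1 - |rho| (anti-correlation counts as zero error)."""
    if not -1.0 <= rho <= 1.0 + 1e-12:
        raise ValueError(f"rho={rho} outside [-1, 1]")
    return 1.0 - abs(min(rho, 1.0))


_GROUP_COLS = {"joint": ["joint"], "grasp": ["grasp"], "subject": ["subject"],
               "overall": [], "task_subject": ["grasp", "subject"]}


def aggregate(table: pd.DataFrame, by: str = "overall",
              metric: str = "accuracy") -> pd.DataFrame:
    """Mean +/- sd of accuracy (100*rho, %) or error (1-|rho|) by group.

    ``by`` is one of overall, joint, grasp, subject or task_subject (the
    task x subject layout of the headline accuracy table). Rows with
    undefined rho (NaN) are excluded; sd uses ddof=1 (0 for singletons).
    """
    if by not in _GROUP_COLS:
        raise ValueError(f"unknown grouping {by!r}")
    if len(table) == 0:
        raise ValueError("empty accuracy table")
    t = table.dropna(subset=["rho"]).copy()
    if metric == "accuracy":
        t["value"] = 100.0 * t["rho"]
    elif metric == "error":
        t["value"] = 1.0 - t["rho"].abs()
    else:
        raise ValueError(f"unknown metric {metric!r}")
    cols = _GROUP_COLS[by]
    if not cols:
        g = pd.DataFrame(
            {"mean": [t["value"].mean()],
             "sd": [t["value"].std(ddof=1) if len(t) > 1 else 0.0],
             "n": [len(t)]}
        )
        return g
    grouped = t.groupby(cols)["value"]
    out = grouped.agg(mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1
                      else 0.0, n="count").reset_index()
    return out


def accuracy_summary(tables: list[pd.DataFrame]) -> dict:
    """Overall mean +/- sd accuracy (%) pooled across folds."""
    pooled = pd.concat(tables, ignore_index=True)
    overall = aggregate(pooled, "overall")
    return {
        "mean_accuracy_pct": float(overall.at[0, "mean"]),
        "sd_accuracy_pct": float(overall.at[0, "sd"]),
        "n": int(overall.at[0, "n"]),
    }


def format_task_subject_table(table: pd.DataFrame) -> pd.DataFrame:
    """Task x subject table of "mean +/- sd%" accuracy strings."""
    agg = aggregate(table, "task_subject")
    out = agg.pivot(index="grasp", columns="subject", values="mean")
    sd = agg.pivot(index="grasp", columns="subject", values="sd")
    fmt = out.copy().astype(object)
    for i in out.index:
        for c in out.columns:
            fmt.at[i, c] = f"{out.at[i, c]:.1f} ± {sd.at[i, c]:.1f}%"
    fmt.index = [f"Task {g}" for g in fmt.index]
    return fmt


@dataclass
class IndependencyMap:
    """Per-synergy, per-electrode density D (and optional r^2 analogue)."""

    D: np.ndarray                 # [n_syn x n_electrodes], >= 0
    electrodes: tuple[str, ...]
    band: tuple[float, float]
    band_label: str = "full"
    R: np.ndarray | None = None   # correlation-based alternative statistic

    @property
    def n_syn(self) -> int:
        return self.D.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.D.T, index=list(self.electrodes),
                          columns=[f"synergy_{j + 1}"
                                   for j in range(self.n_syn)])
        df.index.name = "electrode"
        return df


def independency_density(
    betas_by_electrode: dict[int, list[np.ndarray]], n_electrodes: int,
    n_syn: int,
) -> np.ndarray:
    """D_n(e) = sum over tasks k and coefficients m of beta_mk^2.

    ``betas_by_electrode`` maps electrode index -> one [M x n_syn] beta
    per task. Missing electrodes raise.
    """
    D = np.zeros((n_syn, n_electrodes))
    for e in range(n_electrodes):
        if e not in betas_by_electrode or not betas_by_electrode[e]:
            raise ValueError(f"missing neighborhood fit for electrode {e}")
        for beta in betas_by_electrode[e]:
            if beta.shape[1] != n_syn:
                raise ValueError("beta column count does not match n_syn")
            D[:, e] += np.sum(beta ** 2, axis=0)
    return D


def _neighborhood_columns(provenance: pd.DataFrame,
                          names: tuple[str, ...],
                          members: list[int]) -> np.ndarray:
    wanted = {names[m] for m in members}
    return np.flatnonzero(provenance["electrode"].isin(wanted).to_numpy())


def independency_map(
    features: FeatureMatrix | list[FeatureMatrix],
    weights: SynergyWeights,
    electrodes: tuple[str, ...],
    radius: float = DEFAULT_RADIUS,
    band_label: str = "full",
    standardize: bool = True,
    reduce_rule: float | int | None = 10,
) -> IndependencyMap:
    """Fit per-electrode-neighborhood regressions and sum squared betas.

    ``features`` must be the raw (unreduced, electrode-tagged) feature
    matrix whose rows align with ``weights``. For each electrode, the
    windowed features of that electrode and its montage neighbors are
    reduced to a fixed number of whitened principal components
    (overlapping windows make raw window features nearly collinear, which
    would let ordinary least squares inflate coefficients along noise
    directions; a fixed count keeps the summed-beta^2 noise floor
    comparable across electrodes and bands), then regressed per grasp
    task onto the synergy weights with within-subject-centered least
    squares. Alongside D, a correlation-based statistic R (sum of squared
    feature-weight Pearson correlations) is computed.
    """
    if isinstance(features, list):
        features = concat_features(features)
    X, prov = features.X, features.provenance
    C = weights.C
    if X.shape[0] != C.shape[0]:
        raise ValueError("feature and weight row counts differ")
    grasp = np.asarray(
        pd.DataFrame(weights.trial_index)["grasp"], dtype=int)
    n_syn = C.shape[1]
    n_elec = len(electrodes)
    betas: dict[int, list[np.ndarray]] = {}
    R = np.zeros((n_syn, n_elec))
    for e in range(n_elec):
        members = neighborhood(e, radius)
        cols = _neighborhood_columns(prov, electrodes, members)
        if cols.size == 0:
            raise ValueError(f"no features found for electrode "
                             f"{electrodes[e]}")
        Xe = X[:, cols]
        Xe = Xe - Xe.mean(axis=0)
        if standardize:
            sd = Xe.std(axis=0)
            sd[sd == 0] = 1.0
            Xe = Xe / sd
        if reduce_rule is not None:
            from sklearn.decomposition import PCA

            if isinstance(reduce_rule, float):
                pca = PCA(n_components=None, svd_solver="full").fit(Xe)
                cum = np.cumsum(pca.explained_variance_ratio_)
                k = int(np.searchsorted(cum, reduce_rule - 1e-12) + 1)
            else:
                pca = PCA(n_components=None, svd_solver="full").fit(Xe)
                k = min(int(reduce_rule), pca.components_.shape[0])
            Xe = (Xe - pca.mean_) @ pca.components_[:k].T
            # whiten: coefficient noise then has the same scale for every
            # retained component, so summed beta^2 is comparable across
            # electrodes instead of being dominated by small-eigenvalue
            # directions
            sd = Xe.std(axis=0)
            sd[sd == 0] = 1.0
            Xe = Xe / sd
        betas[e] = []
        subj = pd.DataFrame(weights.trial_index)["subject"].to_numpy()
        for g in np.unique(grasp):
            rows = np.flatnonzero(grasp == g)
            # center within subject so between-subject offsets (resting
            # rhythm amplitude etc.) cannot masquerade as weight coding
            Xg, Cg = Xe[rows].copy(), C[rows].copy()
            for s in np.unique(subj[rows]):
                sub_rows = subj[rows] == s
                Xg[sub_rows] -= Xg[sub_rows].mean(axis=0)
                Cg[sub_rows] -= Cg[sub_rows].mean(axis=0)
            beta, *_ = np.linalg.lstsq(Xg, Cg, rcond=None)
            betas[e].append(beta)
            # correlation-based alternative (sum of squared r over features)
            cs = Cg.std(axis=0)
            xs = Xg.std(axis=0)
            ok = (xs > 0)[:, None] & (cs > 0)[None, :]
            r = np.zeros((Xg.shape[1], n_syn))
            denom = np.outer(xs, cs) * len(rows)
            r[ok] = ((Xg.T @ Cg) / np.where(denom == 0, 1, denom))[ok]
            R[:, e] += np.sum(r ** 2, axis=0)
    D = independency_density(betas, n_elec, n_syn)
    return IndependencyMap(D=D, electrodes=tuple(electrodes),
                           band=features.band, band_label=band_label, R=R)


def band_modulation(
    features_by_band: dict[str, FeatureMatrix | list[FeatureMatrix]],
    weights: SynergyWeights,
    electrodes: tuple[str, ...],
    radius: float = DEFAULT_RADIUS,
    reduce_rule: float | int | None = 10,
) -> dict[str, IndependencyMap]:
    """Independency maps recomputed with features restricted to each band.

    ``features_by_band`` maps a band label (e.g. the keys of
    :data:`synergrasp.config.BANDS`) to the corresponding band-restricted
    raw feature matrices. An empty mapping yields an empty result.
    """
    out: dict[str, IndependencyMap] = {}
    for label, feats in features_by_band.items():
        out[label] = independency_map(feats, weights, electrodes,
                                      radius=radius, band_label=label,
                                      reduce_rule=reduce_rule)
    return out


def plot_topography(imap: IndependencyMap, positions: np.ndarray,
                    path: str, synergy: int = 0) -> None:
    """Schematic scalp map of one synergy's density (optional, matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    vals = imap.D[synergy]
    sc = ax.scatter(positions[:, 0], positions[:, 1], c=vals, s=250,
                    cmap="viridis")
    for (x, y), name in zip(positions, imap.electrodes):
        ax.annotate(name, (x, y), ha="center", va="center", fontsize=5)
    ax.set_title(f"synergy {synergy + 1} ({imap.band_label} band)")
    ax.set_aspect("equal")
    ax.axis("off")
    fig.colorbar(sc, ax=ax, shrink=0.7)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
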