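"""Kinematic synergy extraction by singular value decomposition.

The trial-velocity matrix V (m trials x concatenated joint velocities) is
factored V = U Sigma S; the rows of S are spatiotemporal synergies and
C = U Sigma their per-trial weights, so every movement is a weighted sum
of a few synergies, v_t = sum_j c_j S_j(t). Synergies are kept up to a
cumulative-variance threshold (default 85%), and velocities are
reconstructed as C S.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinematics import VelocityMatrix, unflatten_epoch


@dataclass
class SynergyDecomposition:
    """Full SVD of a velocity matrix with a fixed sign convention."""

    U: np.ndarray                 # [m x r]
    singular_values: np.ndarray   # [r], non-increasing
    S: np.ndarray                 # [r x n] orthonormal rows
    variance_fractions: np.ndarray  # sigma_i^2 / sum sigma^2
    epoch_samples: int
    n_joints: int

    @property
    def rank(self) -> int:
        return len(self.singular_values)


@dataclass
class SynergySet:
    """Selected leading synergies plus the layout needed to unflatten them."""

    S: np.ndarray                 # [n_syn x n]
    variance_fractions: np.ndarray
    threshold: float
    epoch_samples: int
    n_joints: int
    joint_labels: tuple[str, ...] = ()

    @property
    def n_syn(self) -> int:
        return self.S.shape[0]

    def synergy_epoch(self, j: int) -> np.ndarray:
        """Synergy j as a [epoch_samples x n_joints] velocity pattern."""
        return unflatten_epoch(self.S[j], self.epoch_samples, self.n_joints)


@dataclass
class SynergyWeights:
    """Per-trial synergy weight matrix C aligned with a SynergySet."""

    C: np.ndarray                 # [m x n_syn]
    trial_index: "object"         # pandas DataFrame, one row per trial

    @property
    def n_syn(self) -> int:
        return self.C.shape[1]


def _fix_signs(U: np.ndarray, S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Make each right vector's largest-magnitude element positive.

    Resolves the SVD sign ambiguity so repeated decompositions of the same
    matrix are bitwise identical and weight maps are comparable.
    """
    S = S.copy()
    U = U.copy()
    for i in range(S.shape[0]):
        k = int(np.argmax(np.abs(S[i])))
        if S[i, k] < 0:
            S[i] *= -1.0
            U[:, i] *= -1.0
    return U, S


def decompose(V: VelocityMatrix, center: bool = False) -> SynergyDecomposition:
    """Singular value decomposition of V (optionally column-centered).

    The decomposition is applied to the velocity matrix directly — not to
    a covariance matrix — so V = U Sigma S to machine precision.
    """
    M = V.V
    if M.size == 0:
        raise ValueError("empty velocity matrix")
    if center:
        M = M - M.mean(axis=0, keepdims=True)
    U, s, St = np.linalg.svd(M, full_matrices=False)
    U, St = _fix_signs(U, St)
    total = float(np.sum(s ** 2))
    fractions = s ** 2 / total if total > 0 else np.zeros_like(s)
    return SynergyDecomposition(
        U=U, singular_values=s, S=St, variance_fractions=fractions,
        epoch_samples=V.epoch_samples, n_joints=V.n_joints,
    )


def select(decomp: SynergyDecomposition, threshold: float = 0.85,
           joint_labels: tuple[str, ...] = ()) -> SynergySet:
    """Smallest leading synergy set reaching the cumulative-variance threshold.

    The comparison is inclusive: if the cumulative fraction equals the
    threshold exactly (to 1e-9), that count is selected.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    cum = np.cumsum(decomp.variance_fractions)
    reached = np.flatnonzero(cum >= threshold - 1e-9)
    n_syn = int(reached[0]) + 1 if reached.size else decomp.rank
    return SynergySet(
        S=decomp.S[:n_syn].copy(),
        variance_fractions=decomp.variance_fractions[:n_syn].copy(),
        threshold=threshold,
        epoch_samples=decomp.epoch_samples,
        n_joints=decomp.n_joints,
        joint_labels=tuple(joint_labels),
    )


def project_weights(V: VelocityMatrix, synergies: SynergySet) -> SynergyWeights:
    """Orthonormal projection C = V S^T.

    Because the rows of S are orthonormal this equals the least-squares
    weight solution, and C S is the best approximation of V within the
    selected synergy span.
    """
    if V.epoch_samples != synergies.epoch_samples or V.n_joints != synergies.n_joints:
        raise ValueError("velocity matrix and synergy set layouts differ")
    C = V.V @ synergies.S.T
    return SynergyWeights(C=C, trial_index=V.trial_index)


def reconstruct(weights: SynergyWeights, synergies: SynergySet) -> list[np.ndarray]:
    """Velocity epochs v = c^T S for each trial, unflattened to
    [epoch_samples x n_joints] deg/s."""
    if weights.C.shape[1] != synergies.n_syn:
        raise ValueError(
            f"{weights.C.shape[1]} weights per trial but "
            f"{synergies.n_syn} synergies"
        )
    rows = weights.C @ synergies.S
    return [
        unflatten_epoch(r, synergies.epoch_samples, synergies.n_joints)
        for r in rows
    ]


def error_curve(V: VelocityMatrix, decomp: SynergyDecomposition,
                max_count: int | None = None) -> dict[str, np.ndarray]:
    """Reconstruction error as a function of retained synergy count.

    Two equivalent measures are reported for counts 1..max_count:

    - ``by_energy``: 1 - cumulative variance fraction (tail singular-value
      energy),
    - ``by_residual``: the squared Frobenius norm of V - C_k S_k divided by
      the squared norm of V.

    By the Eckart-Young theorem the two agree to numerical precision.
    """
    r = decomp.rank if max_count is None else min(max_count, decomp.rank)
    cum = np.cumsum(decomp.variance_fractions)
    by_energy = 1.0 - cum[:r]
    total = float(np.sum(V.V ** 2))
    by_residual = np.empty(r)
    approx = np.zeros_like(V.V)
    for k in range(r):
        approx += np.outer(decomp.U[:, k] * decomp.singular_values[k],
                           decomp.S[k])
        by_residual[k] = float(np.sum((V.V - approx) ** 2)) / total
    return {
        "counts": np.arange(1, r + 1),
        "by_energy": by_energy,
        "by_residual": by_residual,
    }
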