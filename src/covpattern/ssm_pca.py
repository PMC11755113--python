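"""Principal component decomposition of the subject-residual-profile matrix.

The SRP matrix (subjects x voxels) is decomposed by singular values without
additional centering: rows are already deviations from the control-group
mean profile, and no across-subject voxel demeaning is applied by default
(``center_columns=True`` switches it on).  "Variance" therefore means total
squared SRP mass; the variance fraction of component j is
sigma_j^2 / sum(sigma^2).  The smallest leading set of components reaching a
cumulative fraction of at least ``variance_target`` (default 0.90) is
selected for downstream pattern regression.

The SVD route on the subjects x voxels matrix is equivalent to an
eigendecomposition of the small subjects x subjects covariance matrix and
is preferred because voxel count vastly exceeds subject count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_RANK_RTOL = 1e-12


@dataclass
class PcBasis:
    """Orthonormal voxel-loading eigenvectors with subject scores.

    Attributes
    ----------
    components : (k, V) array
        Unit-norm voxel loadings, ordered by decreasing variance fraction.
        Sign convention: the largest-magnitude loading of each component is
        positive.
    scores : (n, k) array
        Projection of each SRP row onto each component.
    variance_fractions : (k,) array
        sigma_j^2 / sum(sigma^2), non-increasing, summing to <= 1.
    n_selected : int
        Smallest k whose cumulative variance fraction reaches the target.
    variance_target : float
    """

    components: np.ndarray
    scores: np.ndarray
    variance_fractions: np.ndarray
    n_selected: int
    variance_target: float

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    @property
    def selected_components(self) -> np.ndarray:
        return self.components[: self.n_selected]

    @property
    def selected_scores(self) -> np.ndarray:
        return self.scores[:, : self.n_selected]


def _n_for_target(variance_fractions: np.ndarray, target: float) -> int:
    cum = np.cumsum(variance_fractions)
    reached = np.flatnonzero(cum >= target - 1e-12)
    # if numerical mass never reaches the target, keep everything
    return int(reached[0]) + 1 if reached.size else len(variance_fractions)


def fit_pca(
    srp, variance_target: float = 0.90, center_columns: bool = False
) -> PcBasis:
    """Decompose an SRP matrix (or plain 2-D array) into principal components.

    Parameters
    ----------
    srp
        ``SrpMatrix`` or (n_subjects, n_voxels) array.
    variance_target
        Cumulative variance fraction the selected leading components must
        reach (inclusive).
    center_columns
        Demean each voxel across subjects before decomposition.  Off by
        default: the SRP is already referenced to the control mean profile.
    """
    X = np.asarray(getattr(srp, "matrix", srp), dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError(f"need a matrix with >= 2 subjects and >= 2 voxels, got {X.shape}")
    if not 0 < variance_target <= 1:
        raise ValueError(f"variance_target must be in (0, 1], got {variance_target}")
    if center_columns:
        X = X - X.mean(axis=0)
    if not np.any(X):
        raise ValueError("rank-0 matrix: all entries zero")

    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    keep = s > s[0] * _RANK_RTOL
    U, s, Vt = U[:, keep], s[keep], Vt[keep]

    # deterministic sign: largest-magnitude voxel loading positive
    for j in range(Vt.shape[0]):
        pivot = np.argmax(np.abs(Vt[j]))
        if Vt[j, pivot] < 0:
            Vt[j] = -Vt[j]
            U[:, j] = -U[:, j]

    variance_fractions = s**2 / np.sum(s**2)
    scores = U * s
    n_selected = _n_for_target(variance_fractions, variance_target)
    return PcBasis(Vt, scores, variance_fractions, n_selected, variance_target)


def project_onto_basis(basis: PcBasis, srp_row: np.ndarray) -> np.ndarray:
    """Component scores of an (possibly held-out) SRP row: inner products
    with each eigenvector."""
    srp_row = np.asarray(srp_row, dtype=float)
    if srp_row.shape != (basis.components.shape[1],):
        raise ValueError(
            f"row length {srp_row.shape} does not match basis voxel count "
            f"{basis.components.shape[1]}"
        )
    return basis.components @ srp_row
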