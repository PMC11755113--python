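"""Bootstrap voxel-stability analysis of a covariance pattern.

The pattern determination (PCA + stepwise selection + reconstruction) is
repeated on subject resamples drawn with replacement; per-voxel two-tailed
95% percentile intervals over the replicate weights identify voxels whose
interval straddles zero, which are excluded from the original pattern.
The common mask and group mean profile are fixed at their original-sample
values inside replicates so all replicate patterns share one voxel space.

Disease-pattern resampling is stratified by class (class counts preserved,
so every replicate contains both classes); cognition-pattern resampling is
simple resampling within the patient group, with constant-response draws
redrawn.  Empty-model replicates contribute zero weight vectors, biasing
the intervals toward conservatively including zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from covpattern.ssm_pca import fit_pca
from covpattern.regression import stepwise_fit, reconstruct_pattern

logger = logging.getLogger(__name__)


@dataclass
class BootstrapSummary:
    """Per-voxel bootstrap CI bounds and the derived stable pattern."""

    n_boot: int
    seed: int
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    stable_mask: np.ndarray  # CI excludes zero AND original weight nonzero
    stable_pattern: np.ndarray  # original weights restricted to stable voxels
    original_weights: np.ndarray
    n_empty_replicates: int
    n_redrawn: int = 0

    @property
    def n_stable(self) -> int:
        return int(self.stable_mask.sum())


def _resample_stratified(rng: np.random.Generator, labels: np.ndarray) -> np.ndarray:
    idx = []
    for cls in (0, 1):
        members = np.flatnonzero(labels == cls)
        idx.append(rng.choice(members, size=len(members), replace=True))
    return np.concatenate(idx)


def bootstrap_pattern(
    srp,
    response: np.ndarray,
    family: str,
    n_boot: int = 5000,
    seed: int = 0,
    variance_target: float = 0.90,
    ci_level: float = 0.95,
) -> BootstrapSummary:
    """Bootstrap the pattern determination and mask unstable voxels.

    Parameters
    ----------
    srp
        ``SrpMatrix`` or plain (n_subjects, n_voxels) array, already on the
        fixed common mask and referenced to the fixed group mean profile.
        For a cognition pattern pass the patient rows only.
    response
        0/1 labels (logistic) or cognition z-scores (linear), aligned with
        the SRP rows.
    n_boot
        Number of replicates (default 5000).
    seed
        Seed of the single random stream consumed by the resampling draws.
    """
    X = np.asarray(getattr(srp, "matrix", srp), dtype=float)
    response = np.asarray(response, dtype=float)
    if X.shape[0] != response.shape[0]:
        raise ValueError("SRP rows and response differ in length")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")

    # original-sample pattern: defines the voxels eligible for stability
    basis = fit_pca(X, variance_target)
    model = stepwise_fit(
        basis.selected_scores, response, family,
        variance_fractions=basis.variance_fractions[: basis.n_selected],
    )
    if model.is_empty:
        raise ValueError("no pattern identified on the original sample")
    original = reconstruct_pattern(basis, model).weights

    rng = np.random.default_rng(seed)
    labels = response.astype(int) if family == "logistic" else None
    n, n_voxels = X.shape
    replicate_weights = np.zeros((n_boot, n_voxels), dtype=np.float32)
    n_empty = 0
    n_redrawn = 0
    for b in range(n_boot):
        if family == "logistic":
            idx = _resample_stratified(rng, labels)
        else:
            idx = rng.choice(n, size=n, replace=True)
            while np.ptp(response[idx]) == 0:
                n_redrawn += 1
                idx = rng.choice(n, size=n, replace=True)
        Xb, yb = X[idx], response[idx]
        try:
            basis_b = fit_pca(Xb, variance_target)
            model_b = stepwise_fit(
                basis_b.selected_scores, yb, family,
                variance_fractions=basis_b.variance_fractions[: basis_b.n_selected],
            )
        except (ValueError, np.linalg.LinAlgError):
            n_empty += 1
            continue
        if model_b.is_empty:
            n_empty += 1
            continue
        replicate_weights[b] = reconstruct_pattern(basis_b, model_b).weights

    alpha = (1.0 - ci_level) / 2.0
    ci_lo = np.percentile(replicate_weights, 100 * alpha, axis=0)
    ci_hi = np.percentile(replicate_weights, 100 * (1 - alpha), axis=0)
    stable = ((ci_lo > 0) | (ci_hi < 0)) & (original != 0)
    if n_redrawn:
        logger.info("bootstrap: %d constant-response draws redrawn", n_redrawn)
    return BootstrapSummary(
        n_boot=n_boot,
        seed=seed,
        ci_lo=np.asarray(ci_lo, dtype=float),
        ci_hi=np.asarray(ci_hi, dtype=float),
        stable_mask=stable,
        stable_pattern=np.where(stable, original, 0.0),
        original_weights=original,
        n_empty_replicates=n_empty,
        n_redrawn=n_redrawn,
    )
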