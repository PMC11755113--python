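"""Leave-one-out cross-validation and performance statistics for patterns.

Each fold re-derives everything — subject masks, common mask, control-group
mean profile, PCA, stepwise model, pattern — from the training subjects
only, then scores the held-out subject by vectorizing their volume on the
TRAINING common mask and taking the inner product with the training
pattern.  Disease validation rotates over all subjects; cognition
validation rotates over patients only, with the control set fixed as the
reference for the group mean profile in every fold.

Summary statistics: pooled-variance two-sample t-test and ROC/AUC
(Mann-Whitney with ties counted 1/2, operating point by Youden's J) for the
disease pattern; Pearson correlation for cognition patterns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from collections.abc import Sequence

import numpy as np
from scipy import stats

from covpattern.image_prep import (
    SuvrVolume,
    build_subject_mask,
    build_common_mask,
    extract_log_matrix,
    group_mean_profile,
    compute_srp,
)
from covpattern.ssm_pca import fit_pca
from covpattern.regression import stepwise_fit, reconstruct_pattern, subject_score

logger = logging.getLogger(__name__)


@dataclass
class CrossValResult:
    """Per-subject held-out pattern scores with fold manifests and summary."""

    subject_ids: tuple
    scores: np.ndarray  # one held-out score per eligible subject
    truth: np.ndarray  # labels (disease) or composites (cognition)
    empty_model_flags: np.ndarray  # folds whose stepwise model was empty
    folds: list[dict] = field(default_factory=list)
    summary: dict = field(default_factory=dict)


def ttest_scores(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Pooled-variance two-sample Student's t (disease minus control),
    two-tailed p on n1+n2-2 df."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    a, b = scores[labels == 1], scores[labels == 0]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 observations per group")
    n1, n0 = len(a), len(b)
    pooled = ((n1 - 1) * a.var(ddof=1) + (n0 - 1) * b.var(ddof=1)) / (n1 + n0 - 2)
    if pooled == 0:
        raise ValueError("zero pooled variance")
    t = (a.mean() - b.mean()) / np.sqrt(pooled * (1 / n1 + 1 / n0))
    p = 2 * stats.t.sf(abs(t), n1 + n0 - 2)
    return float(t), float(p)


def roc_auc(scores: np.ndarray, labels: np.ndarray):
    """ROC curve, AUC and the Youden-optimal operating point.

    AUC is the Mann-Whitney probability that a random diseased subject
    scores above a random control, ties counted 1/2.  The operating point
    is the threshold (predict diseased when score >= threshold) maximizing
    sensitivity + specificity - 1; ties go to the higher-specificity
    (higher) threshold.

    Returns (curve, auc, sensitivity, specificity, threshold) where curve
    is a (fpr, tpr) pair of arrays.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos, neg = scores[labels == 1], scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")

    diff = pos[:, None] - neg[None, :]
    auc = float((np.sum(diff > 0) + 0.5 * np.sum(diff == 0)) / diff.size)

    # candidate thresholds: each observed score, plus one above the maximum
    thresholds = np.concatenate([np.unique(scores), [np.inf]])[::-1]
    tpr = np.array([(pos >= th).mean() for th in thresholds])
    fpr = np.array([(neg >= th).mean() for th in thresholds])
    youden = tpr - fpr
    # argmax takes the first maximum; thresholds descend, so that is the
    # highest (most specific) threshold among ties
    best = int(np.argmax(youden))
    return (
        (fpr, tpr),
        auc,
        float(tpr[best]),
        float(1 - fpr[best]),
        float(thresholds[best]),
    )


def pearson_r(scores: np.ndarray, z: np.ndarray) -> tuple[float, float]:
    """Product-moment correlation, two-tailed p via the t transform."""
    scores = np.asarray(scores, dtype=float)
    z = np.asarray(z, dtype=float)
    if len(scores) < 3:
        raise ValueError("need n >= 3")
    if np.ptp(scores) == 0 or np.ptp(z) == 0:
        raise ValueError("constant input")
    res = stats.pearsonr(scores, z)
    return float(res.statistic), float(res.pvalue)


def _heldout_srp_row(vol: SuvrVolume, common_mask, profile) -> np.ndarray:
    """Vectorize a held-out volume on the training mask and reference it to
    the training profile.  Non-positive values inside the training mask are
    clamped to the smallest positive training uptake (scoring-time only)."""
    vec = common_mask.vectorize(vol.data)
    bad = vec <= 0
    if bad.any():
        floor = float(np.exp(profile.values.min()))
        logger.warning(
            "held-out subject '%s': %d non-positive values inside the "
            "training mask clamped to %g", vol.subject_id, int(bad.sum()), floor,
        )
        vec = np.where(bad, floor, vec)
    return np.log(vec) - profile.values


def _fit_fold_disease(train_vols, train_labels, reference_ids, mask_fraction,
                      variance_target, subject_masks):
    common = build_common_mask([subject_masks[v.subject_id] for v in train_vols])
    logmat, ids = extract_log_matrix(train_vols, common)
    profile = group_mean_profile(logmat, ids, reference_ids)
    srp = compute_srp(logmat, ids, profile, common)
    basis = fit_pca(srp, variance_target)
    model = stepwise_fit(
        basis.selected_scores,
        train_labels,
        "logistic",
        variance_fractions=basis.variance_fractions[: basis.n_selected],
    )
    return common, profile, basis, model


def loocv_disease(
    vols: Sequence[SuvrVolume],
    labels: Sequence[int],
    mask_fraction: float = 0.03,
    variance_target: float = 0.90,
) -> CrossValResult:
    """LOOCV of the disease pattern over all subjects.

    Folds whose stepwise model is empty yield a held-out score of 0 and are
    flagged rather than aborting the cross-validation.
    """
    labels = np.asarray(labels).astype(int)
    if len(vols) != len(labels):
        raise ValueError("volumes and labels differ in length")
    for cls in (0, 1):
        if np.sum(labels == cls) < 2:
            raise ValueError(f"class {cls} needs >= 2 members")

    # per-subject masks depend only on that subject's own volume
    subject_masks = {v.subject_id: build_subject_mask(v, mask_fraction) for v in vols}
    hc_ids = {v.subject_id for v, l in zip(vols, labels) if l == 0}

    scores, flags, folds = [], [], []
    for i, heldout in enumerate(vols):
        train_vols = [v for j, v in enumerate(vols) if j != i]
        train_labels = np.delete(labels, i)
        if not np.any(train_labels == 0):
            raise ValueError(f"fold {i}: no controls left in training set")
        common, profile, basis, model = _fit_fold_disease(
            train_vols, train_labels, hc_ids, mask_fraction,
            variance_target, subject_masks,
        )
        if model.is_empty:
            score, empty = 0.0, True
        else:
            pattern = reconstruct_pattern(basis, model, target="disease")
            row = _heldout_srp_row(heldout, common, profile)
            score, empty = subject_score(pattern, row), False
        scores.append(score)
        flags.append(empty)
        folds.append({
            "held_out": heldout.subject_id,
            "training_ids": [v.subject_id for v in train_vols],
            "n_components": int(basis.n_selected),
            "included": list(model.included),
            "bic": model.bic,
            "empty_model": empty,
        })

    scores = np.asarray(scores)
    flags = np.asarray(flags)
    t, p = ttest_scores(scores, labels)
    _, auc, sens, spec, thr = roc_auc(scores, labels)
    return CrossValResult(
        subject_ids=tuple(v.subject_id for v in vols),
        scores=scores,
        truth=labels,
        empty_model_flags=flags,
        folds=folds,
        summary={"t": t, "p": p, "auc": auc, "sensitivity": sens,
                 "specificity": spec, "threshold": thr,
                 "n_empty_folds": int(flags.sum())},
    )


def loocv_cognition(
    vols: Sequence[SuvrVolume],
    labels: Sequence[int],
    composites: Sequence[float],
    mask_fraction: float = 0.03,
    variance_target: float = 0.90,
) -> CrossValResult:
    """LOOCV of a cognition pattern over patients only.

    ``composites`` aligns with ``vols``; entries for controls are ignored
    and patients with an undefined (NaN) composite are dropped from the
    rotation.  Controls are never held out: they stay in every fold as the
    fixed reference supplying the group mean profile, and the per-fold PCA
    uses patient SRP rows only.
    """
    labels = np.asarray(labels).astype(int)
    composites = np.asarray(composites, dtype=float)
    if not (len(vols) == len(labels) == len(composites)):
        raise ValueError("volumes, labels and composites differ in length")
    pd_idx = [i for i in range(len(vols))
              if labels[i] == 1 and np.isfinite(composites[i])]
    n_dropped = int(np.sum(labels == 1)) - len(pd_idx)
    if n_dropped:
        logger.info("cognition LOOCV: %d patients without a composite dropped",
                    n_dropped)
    if len(pd_idx) < 5:
        raise ValueError(f"need >= 5 patients with a composite, got {len(pd_idx)}")
    hc_ids = {v.subject_id for v, l in zip(vols, labels) if l == 0}
    if not hc_ids:
        raise ValueError("no controls to define the group mean profile")

    subject_masks = {v.subject_id: build_subject_mask(v, mask_fraction) for v in vols}

    scores, flags, folds = [], [], []
    for i in pd_idx:
        heldout = vols[i]
        train_vols = [v for j, v in enumerate(vols)
                      if j != i and (labels[j] == 0 or j in pd_idx)]
        common = build_common_mask([subject_masks[v.subject_id] for v in train_vols])
        logmat, ids = extract_log_matrix(train_vols, common)
        profile = group_mean_profile(logmat, ids, hc_ids)
        srp = compute_srp(logmat, ids, profile, common)
        # patient-only PCA and regression
        pd_rows = [k for k, sid in enumerate(ids) if sid not in hc_ids]
        basis = fit_pca(srp.matrix[pd_rows], variance_target)
        y = np.array([composites[j] for j in pd_idx if j != i])
        model = stepwise_fit(
            basis.selected_scores, y, "linear",
            variance_fractions=basis.variance_fractions[: basis.n_selected],
        )
        if model.is_empty:
            score, empty = 0.0, True
        else:
            pattern = reconstruct_pattern(basis, model, target="cognition")
            row = _heldout_srp_row(heldout, common, profile)
            score, empty = subject_score(pattern, row), False
        scores.append(score)
        flags.append(empty)
        folds.append({
            "held_out": heldout.subject_id,
            "training_ids": [v.subject_id for v in train_vols],
            "n_components": int(basis.n_selected),
            "included": list(model.included),
            "bic": model.bic,
            "empty_model": empty,
        })

    scores = np.asarray(scores)
    flags = np.asarray(flags)
    truth = composites[pd_idx]
    summary: dict = {"n_empty_folds": int(flags.sum())}
    if np.ptp(scores) > 0 and np.ptp(truth) > 0:
        r, p = pearson_r(scores, truth)
        summary.update({"r": r, "p": p})
    else:
        summary.update({"r": float("nan"), "p": float("nan")})
        logger.warning("cognition LOOCV: constant scores or composites; "
                       "correlation undefined")
    return CrossValResult(
        subject_ids=tuple(vols[i].subject_id for i in pd_idx),
        scores=scores,
        truth=truth,
        empty_model_flags=flags,
        folds=folds,
        summary=summary,
    )
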