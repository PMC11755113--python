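"""Stepwise BIC model selection on component scores and pattern reconstruction.

Components retained by the variance rule serve as candidate predictors of
disease state (logistic) or of a cognition composite (linear).  Selection is
bidirectional stepwise under BIC: forward additions from the intercept-only
model, each followed by backward sweeps, until no single move lowers BIC.
The voxel-weight pattern is the coefficient-weighted sum of the selected
components' eigenvectors; a subject expresses the pattern as the inner
product of those weights with their SRP row (subject score).

BIC conventions (constants fixed across candidate models, so comparisons
are exact):
  logistic: -2 log L + k ln n
  linear (Gaussian, profiled variance): n ln(RSS/n) + k ln n
with k counting the intercept.  Logistic fits under (near-)perfect
separation are handled by clipping coefficients to ``coef_cap`` and
re-evaluating the likelihood at the clipped parameters, keeping BIC finite
and selection deterministic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

logger = logging.getLogger(__name__)

_IMPROVE_TOL = 1e-9  # a move must beat the incumbent BIC by more than this
_RSS_FLOOR = 1e-290  # keeps the linear BIC finite on exact fits


@dataclass
class SelectedModel:
    """A stepwise-selected regression of a response on component scores."""

    family: str  # "logistic" or "linear"
    included: tuple[int, ...]  # component indices, sorted ascending
    coefficients: np.ndarray  # aligned with `included`
    intercept: float
    bic: float
    total_variance_selected: float = float("nan")
    warnings: tuple[str, ...] = field(default_factory=tuple)

    @property
    def is_empty(self) -> bool:
        return len(self.included) == 0


@dataclass
class VoxelPattern:
    """Voxel-weight map: coefficient-weighted sum of eigenvectors."""

    weights: np.ndarray
    family: str
    target: str = ""
    included: tuple[int, ...] = ()
    coefficients: np.ndarray = field(default_factory=lambda: np.empty(0))


def _linear_bic(X: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    n, k = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    bic = n * np.log(max(rss, _RSS_FLOOR) / n) + k * np.log(n)
    return bic, beta


def _logistic_bic(
    X: np.ndarray, y: np.ndarray, coef_cap: float
) -> tuple[float, np.ndarray, str | None]:
    n, k = X.shape
    model = sm.Logit(y, X)
    # box-constrained MLE: under (near-)perfect separation the unconstrained
    # coefficients diverge; the cap keeps the likelihood finite and the
    # candidate comparable, with the remaining parameters re-optimized at
    # the bound rather than naively clipped
    bounds = [(-coef_cap, coef_cap)] * k
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(method="lbfgs", maxiter=500, disp=0, bounds=bounds)
            params = np.asarray(res.params, dtype=float)
        except Exception:  # singular design, total non-convergence
            params = np.zeros(k)
    if not np.all(np.isfinite(params)):
        params = np.zeros(k)
    params = np.clip(params, -coef_cap, coef_cap)
    note = None
    if np.any(np.abs(params) >= coef_cap - 1e-8):
        note = "coefficient at the cap (separation or near-separation)"
    llf = float(model.loglike(params))
    bic = -2.0 * llf + k * np.log(n)
    return bic, params, note


def _fit_candidate(
    scores: np.ndarray,
    response: np.ndarray,
    included: tuple[int, ...],
    family: str,
    coef_cap: float,
) -> tuple[float, np.ndarray, str | None]:
    """BIC and parameters (intercept first) for one candidate index set."""
    n = scores.shape[0]
    X = np.column_stack([np.ones(n)] + [scores[:, j] for j in included])
    if family == "linear":
        bic, params = _linear_bic(X, response)
        return bic, params, None
    return _logistic_bic(X, response, coef_cap)


def stepwise_fit(
    scores: np.ndarray,
    response: np.ndarray,
    family: str,
    variance_fractions: np.ndarray | None = None,
    direction: str = "bidirectional",
    coef_cap: float = 20.0,
) -> SelectedModel:
    """Bidirectional stepwise selection of component predictors under BIC.

    Parameters
    ----------
    scores : (n_subjects, n_candidates) array
        Component scores of the candidate pool (the variance-rule-selected
        components, in basis order).
    response : (n_subjects,) array
        0/1 disease labels (logistic) or cognition z-scores (linear).
    family : {"logistic", "linear"}
    variance_fractions
        Per-candidate variance fractions; if given, their sum over the
        included set is reported as ``total_variance_selected``.
    direction : {"bidirectional", "forward"}
    coef_cap
        Magnitude bound for logistic coefficients under separation.

    Ties in BIC are broken toward the lowest component index, so the result
    does not depend on candidate ordering.
    """
    scores = np.asarray(scores, dtype=float)
    response = np.asarray(response, dtype=float)
    if scores.ndim != 2 or scores.shape[0] != response.shape[0]:
        raise ValueError(f"scores {scores.shape} incompatible with response "
                         f"{response.shape}")
    if not np.all(np.isfinite(response)):
        raise ValueError("response contains non-finite values (drop those subjects first)")
    if family not in ("logistic", "linear"):
        raise ValueError(f"unknown family '{family}'")
    if direction not in ("bidirectional", "forward"):
        raise ValueError(f"unknown direction '{direction}'")
    if family == "logistic" and len(np.unique(response)) < 2:
        raise ValueError("logistic response contains a single class")

    n_candidates = scores.shape[1]
    notes: list[str] = []

    def evaluate(included: tuple[int, ...]):
        bic, params, note = _fit_candidate(scores, response, included, family, coef_cap)
        if note:
            notes.append(f"{included}: {note}")
        return bic, params

    included: tuple[int, ...] = ()
    best_bic, best_params = evaluate(included)

    improved = True
    while improved:
        improved = False
        # forward: add the candidate with the lowest resulting BIC
        best_add = None
        for j in range(n_candidates):  # ascending index = deterministic tie-break
            if j in included:
                continue
            trial = tuple(sorted(included + (j,)))
            bic, params = evaluate(trial)
            if best_add is None or bic < best_add[0] - _IMPROVE_TOL:
                best_add = (bic, trial, params)
        if best_add is not None and best_add[0] < best_bic - _IMPROVE_TOL:
            best_bic, included, best_params = best_add
            improved = True
        # backward sweeps: drop any term whose removal lowers BIC
        if direction == "bidirectional":
            dropped = True
            while dropped and len(included) > 0:
                dropped = False
                best_drop = None
                for j in included:
                    trial = tuple(k for k in included if k != j)
                    bic, params = evaluate(trial)
                    if best_drop is None or bic < best_drop[0] - _IMPROVE_TOL:
                        best_drop = (bic, trial, params)
                if best_drop is not None and best_drop[0] < best_bic - _IMPROVE_TOL:
                    best_bic, included, best_params = best_drop
                    dropped = True
                    improved = True

    tvs = float("nan")
    if variance_fractions is not None:
        tvs = float(np.sum(np.asarray(variance_fractions)[list(included)]))
    if notes:
        logger.debug("stepwise %s: %d capped candidate fits", family, len(notes))
    return SelectedModel(
        family=family,
        included=included,
        coefficients=np.asarray(best_params[1:], dtype=float),
        intercept=float(best_params[0]),
        bic=float(best_bic),
        total_variance_selected=tvs,
        warnings=tuple(notes),
    )


def reconstruct_pattern(basis, model: SelectedModel, target: str = "") -> VoxelPattern:
    """Voxel weights = sum of coefficient x eigenvector over included
    components; the intercept is not spatialized."""
    if model.is_empty:
        raise ValueError("no pattern identified: stepwise model is empty")
    comps = basis.components[list(model.included)]
    weights = model.coefficients @ comps
    return VoxelPattern(
        weights=weights,
        family=model.family,
        target=target,
        included=model.included,
        coefficients=model.coefficients.copy(),
    )


def subject_score(pattern: VoxelPattern, srp_row: np.ndarray) -> float:
    """Pattern expression in a subject: plain inner product of the pattern
    weights with the subject's SRP over all common-mask voxels."""
    srp_row = np.asarray(srp_row, dtype=float)
    if srp_row.shape != pattern.weights.shape:
        raise ValueError(
            f"SRP row shape {srp_row.shape} does not match pattern "
            f"{pattern.weights.shape}"
        )
    return float(pattern.weights @ srp_row)
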