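"""Run orchestration: derive, cross-validate and bootstrap patterns from disk.

A run reads a cohort (NIfTI volumes + subject table + cognition table),
executes the masking/SRP/PCA/stepwise chain for the disease target (all
subjects, logistic on HC/PD) and each cognition target (patient-only PCA,
linear on the domain composite), and writes patterns (NIfTI + JSON
sidecar), subject scores (TSV) and a manifest binding every output to the
configuration that produced it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from covpattern.cognition import (
    DOMAINS, DEFAULT_DOMAIN_MAP, DEFAULT_INVERTED,
    validate_table, zscore_tests, composite_scores,
)
from covpattern.image_prep import SuvrVolume, prepare_srp
from covpattern.ssm_pca import fit_pca
from covpattern.regression import stepwise_fit, reconstruct_pattern
from covpattern.validation import loocv_disease, loocv_cognition
from covpattern.bootstrap import bootstrap_pattern

logger = logging.getLogger(__name__)

COGNITION_TARGETS = DOMAINS + ("global",)
ALL_TARGETS = ("disease",) + COGNITION_TARGETS


@dataclass
class RunConfig:
    """Everything needed to reproduce a run; serialized into the manifest."""

    volumes_dir: str
    subject_table: str
    out_dir: str
    cognition_table: str | None = None
    mask_fraction: float = 0.03
    variance_target: float = 0.90
    stepwise_direction: str = "bidirectional"
    n_boot: int = 5000
    seed: int = 0
    targets: tuple[str, ...] = ALL_TARGETS
    domain_map: dict = field(default_factory=lambda: dict(DEFAULT_DOMAIN_MAP))
    inverted_tests: tuple[str, ...] = tuple(sorted(DEFAULT_INVERTED))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "targets" in raw:
            raw["targets"] = tuple(raw["targets"])
        if "inverted_tests" in raw:
            raw["inverted_tests"] = tuple(raw["inverted_tests"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["targets"] = list(d["targets"])
        d["inverted_tests"] = list(d["inverted_tests"])
        return d


def load_cohort(config: RunConfig):
    """Read volumes, labels and (optionally) the cognition table from disk."""
    subjects = pd.read_csv(config.subject_table, sep="\t")
    for col in ("subject_id", "group"):
        if col not in subjects.columns:
            raise ValueError(f"subject table must have a '{col}' column")
    vols = []
    vol_dir = Path(config.volumes_dir)
    for sid in subjects["subject_id"]:
        candidates = [vol_dir / f"{sid}.nii.gz", vol_dir / f"{sid}.nii"]
        path = next((p for p in candidates if p.exists()), None)
        if path is None:
            raise FileNotFoundError(f"no volume for subject '{sid}' in {vol_dir}")
        vols.append(SuvrVolume.from_nifti(path, sid))
    labels = (subjects["group"].astype(str).str.upper() == "PD").astype(int).to_numpy()

    cognition = None
    wants_cognition = any(t in COGNITION_TARGETS for t in config.targets)
    if wants_cognition:
        if config.cognition_table is None:
            raise ValueError("cognition targets requested but no cognition table given")
        cognition = pd.read_csv(config.cognition_table, sep="\t")
        validate_table(cognition, config.domain_map)
    return vols, labels, cognition


def compute_composites(config: RunConfig, cognition: pd.DataFrame, vols, labels):
    """Control-referenced composite z-scores aligned with the volume order."""
    hc_ids = [v.subject_id for v, l in zip(vols, labels) if l == 0]
    ztab = zscore_tests(cognition, hc_ids, config.inverted_tests)
    comp = composite_scores(ztab, config.domain_map)
    return comp.reindex([v.subject_id for v in vols])


def _write_pattern(out_dir: Path, name: str, pattern, srp, model, basis):
    nifti = srp.mask.unvectorize(pattern.weights)
    nib.save(nib.Nifti1Image(nifti.astype(np.float32), srp.mask.affine),
             out_dir / f"{name}_pattern.nii.gz")
    sidecar = {
        "family": model.family,
        "target": name,
        "included_components": list(model.included),
        "coefficients": [float(c) for c in model.coefficients],
        "intercept": model.intercept,
        "bic": model.bic,
        "total_variance_selected": model.total_variance_selected,
        "n_components_candidate": int(basis.n_selected),
    }
    with open(out_dir / f"{name}_pattern.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)
    return sidecar


def run_derive(config: RunConfig) -> dict:
    """Derive the disease pattern and each requested cognition pattern."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vols, labels, cognition = load_cohort(config)
    hc_ids = [v.subject_id for v, l in zip(vols, labels) if l == 0]

    srp = prepare_srp(vols, hc_ids, config.mask_fraction)
    srp.mask.to_nifti(out_dir / "common_mask.nii.gz")
    manifest: dict = {"config": config.to_dict(),
                      "n_common_voxels": srp.mask.n_voxels,
                      "subjects": list(srp.subject_ids),
                      "patterns": {}}
    score_table = pd.DataFrame({"subject_id": list(srp.subject_ids),
                                "group": np.where(labels == 1, "PD", "HC")})

    if "disease" in config.targets:
        basis = fit_pca(srp, config.variance_target)
        model = stepwise_fit(
            basis.selected_scores, labels, "logistic",
            variance_fractions=basis.variance_fractions[: basis.n_selected],
            direction=config.stepwise_direction,
        )
        if model.is_empty:
            raise ValueError("disease target: no pattern identified")
        pattern = reconstruct_pattern(basis, model, target="disease")
        manifest["patterns"]["disease"] = _write_pattern(
            out_dir, "disease", pattern, srp, model, basis)
        score_table["disease"] = srp.matrix @ pattern.weights

    cog_targets = [t for t in config.targets if t in COGNITION_TARGETS]
    if cog_targets:
        composites = compute_composites(config, cognition, vols, labels)
        composites.to_csv(out_dir / "composites.tsv", sep="\t")
        pd_rows = np.flatnonzero(labels == 1)
        basis_pd = fit_pca(srp.matrix[pd_rows], config.variance_target)
        for target in cog_targets:
            y_all = composites[target].to_numpy()
            ok = np.isfinite(y_all[pd_rows])
            if ok.sum() < 5:
                logger.warning("target '%s': < 5 patients with a composite; skipped",
                               target)
                continue
            if ok.all():
                basis_t, rows_t = basis_pd, pd_rows
            else:
                rows_t = pd_rows[ok]
                basis_t = fit_pca(srp.matrix[rows_t], config.variance_target)
            model = stepwise_fit(
                basis_t.selected_scores, y_all[rows_t], "linear",
                variance_fractions=basis_t.variance_fractions[: basis_t.n_selected],
                direction=config.stepwise_direction,
            )
            if model.is_empty:
                logger.warning("target '%s': stepwise selected no components", target)
                manifest["patterns"][target] = {"empty_model": True}
                continue
            pattern = reconstruct_pattern(basis_t, model, target=target)
            manifest["patterns"][target] = _write_pattern(
                out_dir, target, pattern, srp, model, basis_t)
            score_table[target] = srp.matrix @ pattern.weights

    score_table.to_csv(out_dir / "subject_scores.tsv", sep="\t", index=False)
    manifest["outputs"] = sorted(
        {p.name for p in out_dir.iterdir()} | {"manifest.json"})
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def run_crossval(config: RunConfig, target: str) -> dict:
    """Leave-one-out cross-validation for one target; writes scores + summary."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vols, labels, cognition = load_cohort(config)
    if target == "disease":
        result = loocv_disease(vols, labels, config.mask_fraction,
                               config.variance_target)
    elif target in COGNITION_TARGETS:
        composites = compute_composites(config, cognition, vols, labels)
        result = loocv_cognition(vols, labels, composites[target].to_numpy(),
                                 config.mask_fraction, config.variance_target)
    else:
        raise ValueError(f"unknown target '{target}'")

    pd.DataFrame({"subject_id": result.subject_ids,
                  "heldout_score": result.scores,
                  "truth": result.truth,
                  "empty_model": result.empty_model_flags}).to_csv(
        out_dir / f"crossval_{target}_scores.tsv", sep="\t", index=False)
    with open(out_dir / f"crossval_{target}_folds.json", "w") as fh:
        json.dump(result.folds, fh, indent=2)
    with open(out_dir / f"crossval_{target}_summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=2)
    return result.summary


def run_bootstrap(config: RunConfig, target: str,
                  n_boot: int | None = None, seed: int | None = None) -> dict:
    """Bootstrap voxel stability for one target; writes CI/stable volumes."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n_boot = config.n_boot if n_boot is None else n_boot
    seed = config.seed if seed is None else seed
    vols, labels, cognition = load_cohort(config)
    hc_ids = [v.subject_id for v, l in zip(vols, labels) if l == 0]
    srp = prepare_srp(vols, hc_ids, config.mask_fraction)

    if target == "disease":
        summary = bootstrap_pattern(srp, labels, "logistic", n_boot, seed,
                                    config.variance_target)
    elif target in COGNITION_TARGETS:
        composites = compute_composites(config, cognition, vols, labels)
        y = composites[target].to_numpy()
        rows = np.flatnonzero((labels == 1) & np.isfinite(y))
        summary = bootstrap_pattern(srp.matrix[rows], y[rows], "linear",
                                    n_boot, seed, config.variance_target)
    else:
        raise ValueError(f"unknown target '{target}'")

    for name, vec in (("ci_lo", summary.ci_lo), ("ci_hi", summary.ci_hi),
                      ("stable_pattern", summary.stable_pattern)):
        img = srp.mask.unvectorize(vec)
        nib.save(nib.Nifti1Image(img.astype(np.float32), srp.mask.affine),
                 out_dir / f"bootstrap_{target}_{name}.nii.gz")
    nib.save(nib.Nifti1Image(
        srp.mask.unvectorize(summary.stable_mask.astype(float)).astype(np.uint8),
        srp.mask.affine), out_dir / f"bootstrap_{target}_stable_mask.nii.gz")
    out = {"target": target, "n_boot": summary.n_boot, "seed": summary.seed,
           "n_stable_voxels": summary.n_stable,
           "n_common_voxels": srp.mask.n_voxels,
           "n_empty_replicates": summary.n_empty_replicates}
    with open(out_dir / f"bootstrap_{target}_summary.json", "w") as fh:
        json.dump(out, fh, indent=2)
    return out


def run_report(results_dir: str | Path) -> str:
    """Tabulate per-target results found in a completed run directory."""
    results_dir = Path(results_dir)
    manifest_path = results_dir / "manifest.json"
    if not results_dir.is_dir() or not any(results_dir.iterdir()):
        raise FileNotFoundError(f"no run outputs in {results_dir}")
    lines = [f"covpattern run report: {results_dir}"]
    if manifest_path.exists():
        with open(manifest_path) as fh:
            manifest = json.load(fh)
        lines.append(f"  subjects: {len(manifest.get('subjects', []))}, "
                     f"common-mask voxels: {manifest.get('n_common_voxels')}")
        for target, info in manifest.get("patterns", {}).items():
            if info.get("empty_model"):
                lines.append(f"  [{target}] no components selected")
                continue
            lines.append(
                f"  [{target}] components {info['included_components']} "
                f"(total variance {info['total_variance_selected']:.1%}), "
                f"BIC {info['bic']:.2f}")
    found_any = manifest_path.exists()
    for target in ALL_TARGETS:
        cv = results_dir / f"crossval_{target}_summary.json"
        if cv.exists():
            found_any = True
            with open(cv) as fh:
                s = json.load(fh)
            if "auc" in s:
                lines.append(
                    f"  [{target}] LOOCV: t={s['t']:.2f} p={s['p']:.2g} "
                    f"AUC={s['auc']:.2f} sens={s['sensitivity']:.0%} "
                    f"spec={s['specificity']:.0%}")
            else:
                lines.append(f"  [{target}] LOOCV: r={s['r']:.2f} p={s['p']:.2g}")
        bs = results_dir / f"bootstrap_{target}_summary.json"
        if bs.exists():
            found_any = True
            with open(bs) as fh:
                s = json.load(fh)
            lines.append(
                f"  [{target}] bootstrap ({s['n_boot']} reps): "
                f"{s['n_stable_voxels']}/{s['n_common_voxels']} stable voxels")
    if not found_any:
        raise FileNotFoundError(
            f"{results_dir}: missing run artifacts (no manifest.json, "
            "crossval_*_summary.json or bootstrap_*_summary.json)")
    return "\n".join(lines)
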