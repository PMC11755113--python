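"""Synthetic phantom cohorts with embedded covariance patterns.

Generates SUVr-like volumes for a two-group cohort (controls and patients)
in which the ground truth is known exactly: a brain-shaped ellipsoidal
support, a smooth baseline uptake profile shared by everyone, a unit-norm
disease pattern map D added (scaled by a log-unit effect size) to patient
volumes, a unit-norm cognition pattern map C expressed with per-subject
Gaussian loadings, and spatially smoothed voxel noise.  Effects live in
log-uptake space, so the analysis pipeline's log transform linearizes them
exactly and derived patterns are directly comparable to D and C.

Cognition test scores are driven by latent domain abilities tied to the
cognition-pattern loadings, with per-test offsets, scales, noise, and
timed (inverted) endpoints, exercising the composite-scoring chain.

Scale convention: pattern maps have unit vector norm over the grid, so the
stated effect sizes are norms of the whole-brain signal, not per-voxel
changes; the default voxel noise SD is chosen on the same scale (see the
methods note).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

from covpattern.cognition import DOMAINS, DEFAULT_DOMAIN_MAP, DEFAULT_INVERTED
from covpattern.image_prep import SuvrVolume


@dataclass
class PhantomSpec:
    """Study conditions for one synthetic cohort.

    Defaults emulate a 10-control / 34-patient VAChT-PET cohort on a
    desk-scale 32x32x32 grid.
    """

    shape: tuple[int, int, int] = (32, 32, 32)
    support_fraction: float = 0.42  # ellipsoid semi-axes as fraction of grid
    n_hc: int = 10
    n_pd: int = 34
    baseline_level: float = 0.7  # log-SUVr at center (SUVr ~ 2 vs white matter)
    baseline_gradient: float = 0.2  # mild radial falloff, log units
    disease_effect: float = 0.2  # delta: norm of the PD log-uptake shift along D
    # per-pattern loading SDs tau_k: pattern 0 drives cognition, the rest are
    # nuisance covariance modes (anterior-posterior gradient, left-right
    # asymmetry) that give the eigenspectrum realistic structure
    loading_sd: tuple[float, ...] = (0.1, 0.1, 0.1)
    noise_sd: float = 0.001  # per-voxel log-noise SD after smoothing
    smoothing: float = 1.5  # gaussian sigma in voxels; 0 = white noise
    orthogonal_patterns: bool = True  # make the C_k orthogonal to D
    # a_k: domain composites = a_k * standardized loading_k + eps, summed
    cognition_strength: tuple[float, ...] = (1.0, 0.0, 0.0)
    cognition_noise_sd: float = 0.5  # eps SD of the domain ability
    test_noise_sd: float = 0.3  # per-test measurement noise (ability units)
    pd_cognition_shift: float = -1.0  # mean ability offset of patients
    background_uptake: float = 0.01  # near-zero uptake outside the support
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(s < 8 for s in self.shape):
            raise ValueError(f"grid shape must be 3-D with dims >= 8, got {self.shape}")
        if self.n_hc < 0 or self.n_pd < 0:
            raise ValueError("group sizes must be non-negative")
        if np.isscalar(self.loading_sd):
            self.loading_sd = (float(self.loading_sd),)
        else:
            self.loading_sd = tuple(float(t) for t in self.loading_sd)
        if np.isscalar(self.cognition_strength):
            self.cognition_strength = (float(self.cognition_strength),)
        else:
            self.cognition_strength = tuple(float(a) for a in self.cognition_strength)
        if len(self.cognition_strength) != len(self.loading_sd):
            raise ValueError("cognition_strength and loading_sd lengths differ")
        if self.noise_sd < 0 or any(t < 0 for t in self.loading_sd):
            raise ValueError("noise_sd and loading_sd must be >= 0")


def _grid_coords(shape):
    axes = [np.arange(s, dtype=float) - (s - 1) / 2 for s in shape]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid_support(shape, fraction):
    xs = _grid_coords(shape)
    semi = [fraction * s for s in shape]
    r2 = sum((x / a) ** 2 for x, a in zip(xs, semi))
    return r2 <= 1.0, np.sqrt(np.clip(r2, 0, None))


def _gaussian_blob(shape, center_frac, width_frac):
    """Unnormalized Gaussian bump; center/width as fractions of the grid."""
    xs = _grid_coords(shape)
    out = np.ones(shape)
    for x, c, w, s in zip(xs, center_frac, width_frac, shape):
        out = out * np.exp(-0.5 * ((x - c * s) / (w * s)) ** 2)
    return out


def _unit_norm(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("cannot normalize a zero map")
    return v / n


def _default_disease_map(shape, support):
    """Posterior deficit (negative lobe) with a smaller frontal increase."""
    posterior = _gaussian_blob(shape, (0.0, -0.22, 0.05), (0.16, 0.13, 0.13))
    frontal = _gaussian_blob(shape, (0.0, 0.25, 0.1), (0.12, 0.10, 0.10))
    d = (-posterior + 0.5 * frontal) * support
    return _unit_norm(d)


def _covariance_maps(shape, support, d_map, orthogonal, n_maps):
    """Unit-norm covariance pattern maps C_k, Gram-Schmidt orthogonalized
    against D (optional) and against each other.

    Map 0 is a bilateral fronto-parietal pattern (the cognition-driving
    one); later maps are broad nuisance modes — anterior-posterior
    gradient, left-right asymmetry, then low-order coordinate products.
    """
    xs = _grid_coords(shape)
    left = _gaussian_blob(shape, (-0.2, 0.08, 0.12), (0.12, 0.14, 0.12))
    right = _gaussian_blob(shape, (0.2, 0.08, 0.12), (0.12, 0.14, 0.12))
    medial = _gaussian_blob(shape, (0.0, -0.05, -0.15), (0.10, 0.10, 0.10))
    raw = [
        left + right - 0.8 * medial,
        xs[1],          # anterior-posterior gradient
        xs[0],          # left-right asymmetry
        xs[2],          # inferior-superior gradient
        xs[0] * xs[1],
        xs[1] * xs[2],
    ]
    if n_maps > len(raw):
        raise ValueError(f"at most {len(raw)} covariance maps supported")
    maps: list[np.ndarray] = []
    previous = [d_map] if orthogonal else []
    for k in range(n_maps):
        c = raw[k] * support
        for other in previous + maps:
            c = c - (c.ravel() @ other.ravel()) * other
            c = c * support
        maps.append(_unit_norm(c))
    return maps


def _smoothed_noise(rng, shape, support, sd, smoothing):
    if sd == 0:
        return np.zeros(shape)
    noise = rng.standard_normal(shape)
    if smoothing > 0:
        noise = ndimage.gaussian_filter(noise, smoothing)
    noise *= sd / noise[support].std()
    return noise


# fixed per-test raw-score units (offset, scale); timed tests run "seconds"
_TEST_UNITS = {
    "VAT": (10.0, 1.5), "MoCA_MIS": (12.0, 2.0),
    "SDMT": (45.0, 9.0), "TMT_A": (40.0, 12.0), "Stroop_B": (55.0, 10.0),
    "Stroop_C_B": (35.0, 15.0), "TMT_B": (90.0, 30.0), "letter_fluency": (38.0, 10.0),
    "VOSP_cube": (9.0, 1.2), "TEA_map_search": (60.0, 12.0), "JOLO": (24.0, 4.0),
}


def _cognition_tables(rng, spec, subject_ids, labels, loadings):
    """Latent abilities per domain from the standardized loadings, then raw
    test scores in test-native units (timed tests inverted)."""
    n = len(subject_ids)
    signal = np.zeros(n)
    for k, (a, tau) in enumerate(zip(spec.cognition_strength, spec.loading_sd)):
        if a != 0 and tau > 0:
            signal = signal + a * loadings[:, k] / tau
    abilities = {}
    for domain in DOMAINS:
        eps = rng.normal(0.0, spec.cognition_noise_sd, size=n)
        ability = signal + eps
        ability = ability + spec.pd_cognition_shift * (labels == 1)
        abilities[domain] = ability

    rows = []
    for test_id, domain in DEFAULT_DOMAIN_MAP.items():
        mu, scale = _TEST_UNITS[test_id]
        measured = abilities[domain] + rng.normal(0.0, spec.test_noise_sd, size=n)
        sign = -1.0 if test_id in DEFAULT_INVERTED else 1.0
        raw = mu + sign * scale * measured
        for sid, r in zip(subject_ids, raw):
            rows.append({"subject_id": sid, "test_id": test_id,
                         "raw_score": float(r)})
    return pd.DataFrame(rows), abilities


def make_phantom_cohort(spec: PhantomSpec | None = None, seed: int | None = None):
    """Generate a phantom cohort with known ground truth.

    Returns
    -------
    volumes : list of SuvrVolume (controls first, then patients)
    labels : (n,) int array, 0 = control, 1 = patient
    cognition : long-format DataFrame (subject_id, test_id, raw_score)
    truth : dict with the embedded structure — support mask, disease map D,
        cognition map C, per-subject loadings, latent domain abilities,
        the disease-map support (|D| >= 10% of its max), and the spec.
    """
    spec = spec if spec is not None else PhantomSpec()
    rng = np.random.default_rng(spec.seed if seed is None else seed)

    shape = tuple(spec.shape)
    support, radius = _ellipsoid_support(shape, spec.support_fraction)
    baseline = spec.baseline_level - spec.baseline_gradient * radius**2
    d_map = _default_disease_map(shape, support)
    c_maps = _covariance_maps(shape, support, d_map, spec.orthogonal_patterns,
                              len(spec.loading_sd))

    n = spec.n_hc + spec.n_pd
    labels = np.array([0] * spec.n_hc + [1] * spec.n_pd)
    subject_ids = [f"HC{i+1:02d}" for i in range(spec.n_hc)] + [
        f"PD{i+1:02d}" for i in range(spec.n_pd)
    ]
    loadings = rng.normal(0.0, 1.0, size=(n, len(c_maps))) * np.asarray(
        spec.loading_sd
    )

    volumes = []
    for i, sid in enumerate(subject_ids):
        log_uptake = baseline.copy()
        for k, c_map in enumerate(c_maps):
            log_uptake = log_uptake + loadings[i, k] * c_map
        if labels[i] == 1:
            log_uptake = log_uptake + spec.disease_effect * d_map
        log_uptake = log_uptake + _smoothed_noise(
            rng, shape, support, spec.noise_sd, spec.smoothing
        )
        data = np.where(support, np.exp(log_uptake), spec.background_uptake)
        volumes.append(SuvrVolume(sid, data))

    cognition, abilities = _cognition_tables(rng, spec, subject_ids, labels, loadings)
    truth = {
        "support": support,
        "disease_map": d_map,
        "cognition_maps": c_maps,
        "cognition_map": c_maps[0],
        "disease_support": np.abs(d_map) >= 0.1 * np.abs(d_map).max(),
        "loadings": loadings,
        "abilities": abilities,
        "labels": labels,
        "subject_ids": subject_ids,
        "spec": spec,
    }
    return volumes, labels, cognition, truth


def make_toy_matrix(
    n_subjects: int, n_voxels: int, rank: int, seed: int, noise_sd: float = 0.0
) -> np.ndarray:
    """Reproducible low-rank(+noise) matrix with known singular structure.

    Singular values decay geometrically (10, 5, 2.5, ...) so the leading
    structure is unambiguous in tests.
    """
    if not 1 <= rank <= min(n_subjects, n_voxels):
        raise ValueError(f"rank must be in [1, {min(n_subjects, n_voxels)}], got {rank}")
    rng = np.random.default_rng(seed)
    u, _ = np.linalg.qr(rng.standard_normal((n_subjects, rank)))
    v, _ = np.linalg.qr(rng.standard_normal((n_voxels, rank)))
    s = 10.0 * 0.5 ** np.arange(rank)
    X = (u * s) @ v.T
    if noise_sd > 0:
        X = X + rng.normal(0.0, noise_sd, size=X.shape)
    return X


def spec_to_dict(spec: PhantomSpec) -> dict:
    d = asdict(spec)
    d["shape"] = list(d["shape"])
    return d
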