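"""Synthetic phantom cohort with known planted structure.

Each phantom case is three co-registered MR-like volumes (T1, T2, Gd-T1)
containing an axis-aligned ellipsoidal enhancing core surrounded by a
uniform-thickness edema shell, all inside a brain ellipsoid. The core on
Gd-T1 carries a smoothed Gaussian random texture field whose standard
deviation (``heterogeneity``) and correlation length are known per case,
so texture-recovery experiments have ground truth.

Overall survival follows an exponential proportional-hazards model whose
log-hazard is a linear function of the planted lesion properties
(standardized heterogeneity and log core volume) plus an optional direct
effect of the molecular label; censoring is an independent exponential.
The binary MGMT-promoter-methylation-like label is Bernoulli with a
logistic dependence on standardized heterogeneity, giving a weak,
controllable imaging-molecular association.

All randomness derives from one master seed: case ``i`` uses the stream
seeded by ``(seed, i)``, cohort-level draws use fixed offsets, so cases
are independent and order-insensitive.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .preproc import Image3D, write_nifti


class LesionSizingError(ValueError):
    """The configured lesion does not fit inside the brain/grid."""


@dataclass
class CohortConfig:
    """Generator settings; defaults emulate a newly diagnosed GBM cohort.

    Intensities are arbitrary scanner-like units. Hazards are per month:
    the default baseline gives a median survival of about 15 months for an
    average lesion, and the default censoring rate yields roughly 25-30 %
    censoring — both in the range reported for GBM cohorts.
    """

    n_cases: int = 10
    grid_shape: tuple = (64, 64, 64)
    spacing_mm: tuple = (2.0, 2.0, 2.0)
    # tissue intensity means per sequence (air is 0)
    t1_means: dict = field(default_factory=lambda: {"brain": 100.0, "core": 80.0, "edema": 90.0})
    t2_means: dict = field(default_factory=lambda: {"brain": 100.0, "core": 130.0, "edema": 170.0})
    t1gd_means: dict = field(default_factory=lambda: {"brain": 100.0, "core": 180.0, "edema": 90.0})
    noise_sd: float = 4.0          # acquisition noise, all sequences
    # lesion geometry sampling ranges (mm)
    core_radius_range: tuple = (8.0, 14.0)
    edema_margin_range: tuple = (5.0, 12.0)
    center_jitter_mm: float = 8.0
    # texture field sampling ranges
    heterogeneity_range: tuple = (5.0, 25.0)
    corr_len_range_mm: tuple = (2.0, 6.0)
    # survival model (per month)
    beta_heterogeneity: float = 0.7   # log-HR per SD of heterogeneity
    beta_volume: float = 0.4          # log-HR per SD of log core volume
    beta_mgmt: float = 0.5            # extra log-hazard for unmethylated
    baseline_hazard: float = np.log(2) / 15.0
    censor_rate: float = 0.02
    # molecular label model (on standardized heterogeneity)
    mgmt_beta0: float = 0.0
    mgmt_beta1: float = -0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 2:
            raise ValueError("n_cases must be at least 2")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be non-negative")
        if np.any(np.asarray(self.spacing_mm) <= 0):
            raise ValueError("spacing must be positive")

    # --- standardization constants of the sampled lesion parameters -------
    @property
    def heterogeneity_mean_sd(self) -> tuple:
        lo, hi = self.heterogeneity_range
        sd = (hi - lo) / np.sqrt(12.0)
        return (lo + hi) / 2.0, (sd if sd > 0 else 1.0)

    @property
    def log_volume_mean_sd(self) -> tuple:
        # radii iid uniform: E/var of log(4/3 pi r1 r2 r3) in closed form
        a, b = self.core_radius_range
        if b <= a:
            return float(np.log(4 / 3 * np.pi) + 3 * np.log(a)), 1.0
        m1 = (b * np.log(b) - a * np.log(a)) / (b - a) - 1.0
        m2_grid = np.linspace(a, b, 20001)
        v1 = np.trapezoid(np.log(m2_grid) ** 2, m2_grid) / (b - a) - m1**2
        return float(np.log(4 / 3 * np.pi) + 3 * m1), float(np.sqrt(3 * v1))


@dataclass
class SyntheticTruth:
    """Planted parameters of one phantom case."""

    case_id: str
    core_center_mm: tuple
    core_radii_mm: tuple
    edema_margin_mm: float
    heterogeneity: float
    texture_corr_len_mm: float
    linear_predictor: float
    mgmt_prob: float

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.core_radii_mm) <= 0):
            raise ValueError("core radii must be positive")
        if self.heterogeneity < 0:
            raise ValueError("heterogeneity must be non-negative")
        if not 0.0 <= self.mgmt_prob <= 1.0:
            raise ValueError("mgmt_prob must be a probability")


@dataclass
class SyntheticCase:
    truth: SyntheticTruth
    t1: Image3D
    t2: Image3D
    t1gd: Image3D
    core_mask: np.ndarray
    t2_mask: np.ndarray


def _case_rng(config: CohortConfig, case_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, case_index]))


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def sample_truth(config: CohortConfig, case_index: int) -> SyntheticTruth:
    """Draw the planted lesion parameters for one case (no volumes)."""
    rng = _case_rng(config, case_index)
    radii = rng.uniform(*config.core_radius_range, size=3)
    margin = float(rng.uniform(*config.edema_margin_range))
    center = rng.uniform(-config.center_jitter_mm, config.center_jitter_mm, size=3)
    het = float(rng.uniform(*config.heterogeneity_range))
    corr = float(rng.uniform(*config.corr_len_range_mm))

    h_mean, h_sd = config.heterogeneity_mean_sd
    lv_mean, lv_sd = config.log_volume_mean_sd
    z_h = (het - h_mean) / h_sd
    log_vol = float(np.log(4 / 3 * np.pi) + np.sum(np.log(radii)))
    z_v = (log_vol - lv_mean) / lv_sd
    lp = config.beta_heterogeneity * z_h + config.beta_volume * z_v
    mgmt_p = float(_logistic(config.mgmt_beta0 + config.mgmt_beta1 * z_h))
    return SyntheticTruth(
        case_id=f"case{case_index:03d}",
        core_center_mm=tuple(center),
        core_radii_mm=tuple(radii),
        edema_margin_mm=margin,
        heterogeneity=het,
        texture_corr_len_mm=corr,
        linear_predictor=float(lp),
        mgmt_prob=mgmt_p,
    )


def _ellipsoid_mask(shape, spacing, center_mm, radii_mm) -> np.ndarray:
    coords = [
        (np.arange(n) - (n - 1) / 2.0) * s
        for n, s in zip(shape, spacing)
    ]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij")
    cx, cy, cz = center_mm
    rx, ry, rz = radii_mm
    return ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 + ((zz - cz) / rz) ** 2 <= 1.0


def _texture_field(shape, spacing, corr_len_mm, target_sd, mask, rng) -> np.ndarray:
    """Smoothed white noise rescaled to the target SD over the mask."""
    if target_sd == 0:
        return np.zeros(shape)
    white = rng.standard_normal(shape)
    sigma_vox = [corr_len_mm / s for s in spacing]
    smooth = ndimage.gaussian_filter(white, sigma=sigma_vox)
    inside = smooth[mask]
    sd = inside.std()
    if sd == 0:
        return np.zeros(shape)
    return (smooth - inside.mean()) / sd * target_sd


def generate_case(config: CohortConfig, case_index: int):
    """Build one phantom case: three volumes, two lesion masks, and truth.

    Reproducible: the same (config.seed, case_index) yields bit-identical
    output. Raises :class:`LesionSizingError` if core + edema shell would
    leave the brain ellipsoid.
    """
    truth = sample_truth(config, case_index)
    rng = _case_rng(config, case_index + 2**20)  # independent of sampling stream
    shape = tuple(config.grid_shape)
    spacing = tuple(config.spacing_mm)
    extent = np.array([n * s for n, s in zip(shape, spacing)])
    brain_radii = extent / 2.0 - 2.0 * np.asarray(spacing)
    outer = np.asarray(truth.core_radii_mm) + truth.edema_margin_mm
    reach = np.abs(np.asarray(truth.core_center_mm)) + outer
    if np.any(reach >= brain_radii):
        raise LesionSizingError(
            f"lesion (reach {reach}) does not fit inside brain radii {brain_radii}"
        )

    brain = _ellipsoid_mask(shape, spacing, (0, 0, 0), brain_radii)
    core = _ellipsoid_mask(shape, spacing, truth.core_center_mm, truth.core_radii_mm)
    t2les = _ellipsoid_mask(shape, spacing, truth.core_center_mm, outer)
    edema = t2les & ~core

    tex = _texture_field(
        shape, spacing, truth.texture_corr_len_mm, truth.heterogeneity, core, rng
    )

    vols = {}
    for tag, means in (("T1", config.t1_means), ("T2", config.t2_means),
                       ("T1Gd", config.t1gd_means)):
        v = np.zeros(shape)
        v[brain] = means["brain"]
        v[edema] = means["edema"]
        v[core] = means["core"]
        if tag == "T1Gd":
            v[core] += tex[core]
        if config.noise_sd > 0:
            v = v + rng.normal(0.0, config.noise_sd, size=shape)
            v[~brain] = 0.0  # air stays exactly zero so nonzero = brain mask
        vols[tag] = v

    affine = np.diag(list(spacing) + [1.0])
    # world origin at volume centre
    affine[:3, 3] = -(np.asarray(shape) - 1) / 2.0 * np.asarray(spacing)
    imgs = {
        tag: Image3D(v, np.asarray(spacing), affine.copy(), tag)
        for tag, v in vols.items()
    }
    return SyntheticCase(truth, imgs["T1"], imgs["T2"], imgs["T1Gd"], core, t2les)


def simulate_survival(linear_predictors, config: CohortConfig, seed: int):
    """Exponential event times under proportional hazards, with censoring.

    Event time ~ Exp(rate = baseline_hazard * exp(lp)); censoring time
    ~ Exp(censor_rate) (infinite when censor_rate is 0). Returns a list of
    (observed_time_months, event_flag).
    """
    lps = np.asarray(linear_predictors, dtype=float)
    if lps.size == 0:
        raise ValueError("empty linear-predictor list")
    rng = np.random.default_rng(seed)
    rates = config.baseline_hazard * np.exp(lps)
    event_t = rng.exponential(1.0 / rates)
    if config.censor_rate > 0:
        censor_t = rng.exponential(1.0 / config.censor_rate, size=lps.size)
    else:
        censor_t = np.full(lps.size, np.inf)
    observed = np.minimum(event_t, censor_t)
    event = (event_t <= censor_t).astype(int)
    return list(zip(observed.tolist(), event.tolist()))


def simulate_mgmt_labels(feature_values, beta0: float, beta1: float, seed: int):
    """Bernoulli labels with logistic dependence on a driving feature."""
    x = np.asarray(feature_values, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("feature values must be finite")
    rng = np.random.default_rng(seed)
    p = _logistic(beta0 + beta1 * x)
    return (rng.uniform(size=x.size) < p).astype(int).tolist()


def generate_clinical(config: CohortConfig, truths) -> pd.DataFrame:
    """Clinical table: covariates independent of imaging, survival and
    molecular label driven by the planted truth."""
    n = len(truths)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2**24]))
    age = np.clip(np.round(rng.normal(60, 12, n)), 20, 90).astype(int)
    sex = rng.choice(["M", "F"], size=n)
    kps = rng.choice([50, 60, 70, 80, 90, 100], size=n, p=[0.05, 0.1, 0.2, 0.3, 0.2, 0.15])
    surgery = rng.choice(["total", "partial", "biopsy"], size=n, p=[0.5, 0.3, 0.2])

    h_mean, h_sd = config.heterogeneity_mean_sd
    z_h = [(t.heterogeneity - h_mean) / h_sd for t in truths]
    mgmt = simulate_mgmt_labels(
        z_h, config.mgmt_beta0, config.mgmt_beta1,
        seed=int(np.random.SeedSequence([config.seed, 2**24 + 1]).generate_state(1)[0] % 2**31),
    )
    lps = [
        t.linear_predictor + config.beta_mgmt * (1 - m)
        for t, m in zip(truths, mgmt)
    ]
    surv = simulate_survival(
        lps, config,
        seed=int(np.random.SeedSequence([config.seed, 2**24 + 2]).generate_state(1)[0] % 2**31),
    )
    return pd.DataFrame({
        "case_id": [t.case_id for t in truths],
        "age": age,
        "sex": sex,
        "kps": kps,
        "surgery": surgery,
        "pmgmt": mgmt,                       # 1 = methylated
        "os_months": [s[0] for s in surv],
        "event": [s[1] for s in surv],
    })


def generate_cohort(config: CohortConfig):
    """All cases' volumes plus the clinical table; heavy for large n."""
    cases = [generate_case(config, i) for i in range(config.n_cases)]
    clinical = generate_clinical(config, [c.truth for c in cases])
    return cases, clinical


def write_cohort(cases, clinical: pd.DataFrame, out_dir) -> dict:
    """Write NIfTI volumes/masks per case plus clinical and truth CSVs.

    Returns a manifest mapping artifact names to file paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {}
    for case in cases:
        cid = case.truth.case_id
        cdir = out / cid
        for tag, img in (("t1", case.t1), ("t2", case.t2), ("t1gd", case.t1gd)):
            p = write_nifti(img, cdir / f"{tag}.nii.gz")
            manifest[f"{cid}/{tag}"] = str(p)
        for tag, mask in (("core_mask", case.core_mask), ("t2_mask", case.t2_mask)):
            img = Image3D(mask.astype(float), case.t1gd.spacing_mm,
                          case.t1gd.grid_to_world, "T1Gd")
            p = write_nifti(img, cdir / f"{tag}.nii.gz")
            manifest[f"{cid}/{tag}"] = str(p)
    clin_path = out / "clinical.csv"
    clinical.to_csv(clin_path, index=False)
    manifest["clinical"] = str(clin_path)
    truth_df = pd.DataFrame([asdict(c.truth) for c in cases])
    truth_path = out / "truth.csv"
    truth_df.to_csv(truth_path, index=False)
    manifest["truth"] = str(truth_path)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    manifest["manifest"] = str(out / "manifest.json")
    return manifest
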