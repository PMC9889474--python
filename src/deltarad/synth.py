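"""Synthetic time-serial lesion cohorts with a planted prognostic signal.

Each synthetic patient is an ellipsoidal lung lesion rendered on a small
HU-like voxel grid at two timepoints (baseline F0 and first follow-up F1,
separated by a patient-specific interval of 16-128 days).  Three per-day
progression rates drive the change between the scans:

* ``volume_rate_per_day``  — fractional change of lesion volume,
* ``texture_rate_per_day`` — fractional change of the intratumoral texture
  amplitude (a Gaussian random field added to the lesion core),
* ``peri_rate_per_day``    — fractional change of the peritumoral rim decay
  constant, i.e. how sharply intensity falls off outside the lesion border.

A linear combination of the three rates is the patient's latent risk, which
sets the hazard of an exponential proportional-hazards progression time.
The prognostic signal therefore lives in the *change* between scans — and
partly in the tissue *around* the tumor — while baseline appearance and all
clinical covariates are, by default, independent of outcome.  This is the
regime the downstream models are meant to distinguish.

Clinical covariates are sampled from fixed marginal frequencies typical of
an EGFR-mutant lung adenocarcinoma cohort under TKI therapy.  A re-test
segmentation of F0 (a jittered mask, emulating a radiologist re-contouring
the same scan weeks later) supports ICC-based feature stability analysis.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import BinaryMask, VoxelGrid, mask_volume_ml, write_mask, write_volume

log = logging.getLogger(__name__)

#: Shrinkage floor for evolved lesion volume / texture amplitude / rim decay:
#: a lesion may regress but never vanishes entirely.
EVOLUTION_FLOOR = 0.05


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------

@dataclass
class LesionParams:
    """Geometry and appearance of one lesion at baseline."""

    center_mm: np.ndarray
    radii_mm: np.ndarray            # ellipsoid semi-axes
    core_intensity: float           # HU-like plateau inside the lesion
    texture_scale_mm: float         # correlation length of the texture field
    texture_amplitude: float        # HU amplitude of the texture field
    rim_gradient: float             # peritumoral intensity decay per mm

    def __post_init__(self) -> None:
        self.center_mm = np.asarray(self.center_mm, dtype=float).reshape(3)
        self.radii_mm = np.asarray(self.radii_mm, dtype=float).reshape(3)
        if np.any(self.radii_mm <= 0):
            raise ValueError("ellipsoid semi-axes must be positive")
        if self.texture_scale_mm <= 0:
            raise ValueError("texture correlation length must be positive")


@dataclass
class ProgressionProfile:
    """Per-day progression rates and the latent risk they induce.

    ``latent_risk`` is a deterministic linear combination of the three
    rates with the supplied weights (it is never sampled independently).
    """

    volume_rate_per_day: float
    texture_rate_per_day: float
    peri_rate_per_day: float
    latent_risk: float = field(init=False)
    weights: tuple[float, float, float] = (110.0, 150.0, 210.0)

    def __post_init__(self) -> None:
        w = self.weights
        self.latent_risk = (
            w[0] * self.volume_rate_per_day
            + w[1] * self.texture_rate_per_day
            + w[2] * self.peri_rate_per_day
        )


@dataclass
class SurvivalOutcome:
    """Observed progression-free survival in months with event indicator."""

    time_months: float
    event: bool

    def __post_init__(self) -> None:
        if self.time_months <= 0:
            raise ValueError("survival time must be positive")


@dataclass
class ClinicalRecord:
    sex: str                 # female | male
    age: float               # years
    smoking: str             # no | yes
    ethnicity: str           # han | minority
    t_stage: str             # T1..T4
    n_stage: str             # N0..N3
    m_stage: str             # M0 | M1
    tki_drug: str
    baseline_volume_ml: float


@dataclass
class GridSpec:
    """How to rasterize one patient's scans."""

    shape: tuple[int, int, int]
    spacing_mm: float = 1.0
    lung_background: float = -800.0
    noise_sd: float = 20.0          # per-scan acquisition noise, HU
    chest_wall: bool = False
    wall_gap_mm: float = 4.0        # lesion surface to chest-wall face
    wall_intensity: float = 200.0


@dataclass
class ScanPair:
    """One patient's F0/F1 volumes, masks, lung mask and inter-scan interval."""

    f0: VoxelGrid
    f0_mask: BinaryMask
    f1: VoxelGrid
    f1_mask: BinaryMask
    lung_mask: BinaryMask
    interval_days: int


@dataclass
class SyntheticPatient:
    patient_id: str
    cohort: str                    # train | valid
    scan_pair: ScanPair
    retest_mask: BinaryMask
    clinical: ClinicalRecord
    outcome: SurvivalOutcome
    profile: ProgressionProfile


# --------------------------------------------------------------------------
# cohort-level configuration (defaults are the study conditions)
# --------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Defaults emulate a two-cohort EGFR-TKI study population.

    Interval: log-normal with median 35 days truncated to [16, 128].
    Event fraction ~0.83 at defaults (censor window calibrated once against
    the exponential proportional-hazards outcome model).
    """

    n_train: int = 131
    n_valid: int = 41
    spacing_mm: float = 1.0
    # inter-scan interval (days)
    interval_median_days: float = 35.0
    interval_sigma_log: float = 0.45
    interval_min_days: int = 16
    interval_max_days: int = 128
    # lesion geometry/appearance
    radius_min_mm: float = 6.0
    radius_max_mm: float = 16.0
    axis_anisotropy: float = 0.2          # semi-axes = r0 * U(1-a, 1+a)
    core_intensity_mean: float = 40.0
    core_intensity_sd: float = 15.0
    texture_scale_range_mm: tuple[float, float] = (2.0, 5.0)
    texture_amplitude_range: tuple[float, float] = (30.0, 80.0)
    rim_gradient_range: tuple[float, float] = (0.2, 0.5)
    lung_background: float = -800.0
    noise_sd: float = 20.0
    chest_wall_fraction: float = 0.3
    # progression rates (per day) and risk weights
    volume_rate_mean: float = -0.002
    volume_rate_sd: float = 0.004
    #: links between baseline appearance and aggressiveness: the volume-rate
    #: and peritumoral-rate means shift by these many rate-SDs per unit of
    #: standardized baseline texture amplitude, so baseline heterogeneity
    #: carries a moderate prognostic signal (as single-timepoint models show
    #: in practice) while the bulk of the signal stays in the per-day change
    baseline_link: float = 1.1
    peri_link: float = 0.5
    texture_rate_sd: float = 0.004
    peri_rate_sd: float = 0.004
    risk_weights: tuple[float, float, float] = (110.0, 150.0, 210.0)
    # outcome model (months); the censor window is calibrated once so that
    # ~83% of patients progress under the default risk distribution
    baseline_scale_months: float = 16.0
    censor_window_months: float = 193.5
    # optional weak clinical signal: adds volume_log_hr * baseline volume (mL)
    # to the latent risk, echoing a marginal baseline-volume hazard ratio
    clinical_volume_effect: bool = False
    volume_log_hr_per_ml: float = 0.006
    # re-test segmentation
    retest_jitter_mm: float = 1.0
    retest_n: int = 30
    dice_floor: float = 0.90


#: Clinical covariate marginals (training-cohort frequencies of a typical
#: EGFR-mutant LUAD population); covariates are sampled independently of the
#: latent risk unless ``clinical_volume_effect`` is on.
CLINICAL_MARGINALS = {
    "sex": (["female", "male"], [0.565, 0.435]),
    "age_lt60": 0.534,
    "smoking": (["no", "yes"], [0.748, 0.252]),
    "ethnicity": (["han", "minority"], [0.565, 0.435]),
    "t_stage": (["T1", "T2", "T3", "T4"], [0.038, 0.061, 0.122, 0.779]),
    "n_stage": (["N0", "N1", "N2", "N3"], [0.122, 0.260, 0.366, 0.252]),
    "m_stage": (["M0", "M1"], [0.038, 0.962]),
    "tki_drug": (
        ["afatinib", "erlotinib", "gefitinib", "icotinib", "osimertinib"],
        [0.031, 0.038, 0.626, 0.252, 0.053],
    ),
}


# --------------------------------------------------------------------------
# lesion rendering
# --------------------------------------------------------------------------

def _evolved(value: float, rate_per_day: float, days: float) -> float:
    return value * max(1.0 + rate_per_day * days, EVOLUTION_FLOOR)


def _coords_mm(shape, spacing):
    ax = [np.arange(n) * spacing for n in shape]
    return np.meshgrid(*ax, indexing="ij")


def _render_scan(
    spec: GridSpec,
    center: np.ndarray,
    radii: np.ndarray,
    core: float,
    amplitude: float,
    rim: float,
    texture_field: np.ndarray,
    rng: np.random.Generator,
    wall_mask: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize one scan; returns (intensities, lesion mask)."""
    xs, ys, zs = _coords_mm(spec.shape, spec.spacing_mm)
    q = (
        ((xs - center[0]) / radii[0]) ** 2
        + ((ys - center[1]) / radii[1]) ** 2
        + ((zs - center[2]) / radii[2]) ** 2
    )
    mask = q <= 1.0
    dist_out = ndimage.distance_transform_edt(~mask, sampling=spec.spacing_mm)
    bg = spec.lung_background
    contrast = core - bg + 0.5 * amplitude * texture_field
    img = bg + contrast * np.exp(-rim * dist_out)
    img[mask] = core + amplitude * texture_field[mask]
    if wall_mask is not None:
        img[wall_mask] = spec.wall_intensity
    img += rng.normal(0.0, spec.noise_sd, size=spec.shape)
    return img.astype(np.float32), mask


def _wall_region(spec: GridSpec, center: np.ndarray, max_radius_x: float) -> np.ndarray | None:
    """Chest-wall slab at the low-x side, a few mm off the lesion surface."""
    if not spec.chest_wall:
        return None
    inner_mm = center[0] - max_radius_x - spec.wall_gap_mm
    if inner_mm <= spec.spacing_mm:
        return None
    xs = np.arange(spec.shape[0]) * spec.spacing_mm
    wall_1d = xs <= inner_mm
    if not wall_1d.any():
        return None
    wall = np.zeros(spec.shape, dtype=bool)
    wall[wall_1d, :, :] = True
    return wall


def simulate_lesion_pair(
    params: LesionParams,
    profile: ProgressionProfile,
    interval_days: int,
    grid_spec: GridSpec,
    seed: int,
) -> ScanPair:
    """Render the F0/F1 scan pair for one patient.

    F1 lesion volume is ``F0 volume x (1 + volume_rate_per_day x interval)``
    (floored at 5%); texture amplitude and rim decay evolve with the same
    linear law.  The texture random field is shared between timepoints
    (the lesion is the same object) while acquisition noise is drawn
    independently per scan.  Identical seeds give identical voxels.
    """
    if interval_days < 1:
        raise ValueError("interval must be >= 1 day")
    rng = np.random.default_rng(seed)

    factor = max(1.0 + profile.volume_rate_per_day * interval_days, EVOLUTION_FLOOR)
    radii_f1 = params.radii_mm * factor ** (1.0 / 3.0)
    amp_f1 = _evolved(params.texture_amplitude, profile.texture_rate_per_day, interval_days)
    rim_f1 = _evolved(params.rim_gradient, profile.peri_rate_per_day, interval_days)

    # margin check: the 10 mm dilation of either mask must stay inside the grid
    extent = np.array(grid_spec.shape) * grid_spec.spacing_mm
    rmax = np.maximum(params.radii_mm, radii_f1)
    lo = params.center_mm - rmax - 10.0
    hi = params.center_mm + rmax + 10.0
    if np.any(lo < grid_spec.spacing_mm) or np.any(hi > extent - 2 * grid_spec.spacing_mm):
        raise ValueError(
            "lesion plus 10 mm dilation margin exceeds the grid: "
            f"needs [{lo.round(1)}, {hi.round(1)}] mm inside extent {extent} mm"
        )

    field = ndimage.gaussian_filter(
        rng.normal(size=grid_spec.shape),
        sigma=params.texture_scale_mm / grid_spec.spacing_mm,
    )
    field /= max(field.std(), 1e-12)

    wall = _wall_region(grid_spec, params.center_mm, rmax[0])
    img0, mask0 = _render_scan(
        grid_spec, params.center_mm, params.radii_mm, params.core_intensity,
        params.texture_amplitude, params.rim_gradient, field, rng, wall,
    )
    img1, mask1 = _render_scan(
        grid_spec, params.center_mm, radii_f1, params.core_intensity,
        amp_f1, rim_f1, field, rng, wall,
    )
    spacing = np.full(3, grid_spec.spacing_mm)
    lung = np.ones(grid_spec.shape, dtype=bool) if wall is None else ~wall
    return ScanPair(
        f0=VoxelGrid(img0, spacing),
        f0_mask=BinaryMask(mask0, spacing),
        f1=VoxelGrid(img1, spacing),
        f1_mask=BinaryMask(mask1, spacing),
        lung_mask=BinaryMask(lung, spacing),
        interval_days=int(interval_days),
    )


# --------------------------------------------------------------------------
# outcome model
# --------------------------------------------------------------------------

def simulate_survival(
    latent_risk: float,
    baseline_scale: float,
    censor_window: float,
    seed: int | np.random.Generator,
) -> SurvivalOutcome:
    """Draw an observed PFS under an exponential proportional-hazards model.

    Event time ``T ~ Exp(scale = baseline_scale * exp(-latent_risk))`` so the
    hazard is proportional to ``exp(latent_risk)``; censoring time
    ``C ~ Uniform(0, censor_window)``.  Returns ``min(T, C)`` in months with
    the event flag.  ``censor_window = inf`` disables censoring.
    """
    if baseline_scale <= 0:
        raise ValueError("baseline scale must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = rng.exponential(baseline_scale * np.exp(-latent_risk))
    c = np.inf if np.isinf(censor_window) else rng.uniform(0.0, censor_window)
    time = max(min(t, c), 1e-3)
    return SurvivalOutcome(time_months=float(time), event=bool(t <= c))


# --------------------------------------------------------------------------
# re-test segmentation
# --------------------------------------------------------------------------

def perturb_mask_for_retest(
    mask: BinaryMask,
    boundary_jitter_mm: float,
    seed: int,
    dice_floor: float = 0.90,
    smoothness_mm: float = 4.0,
) -> BinaryMask:
    """Jitter the mask boundary to emulate a repeated manual segmentation.

    The signed Euclidean distance to the boundary is thresholded at a
    smooth random field capped at ``boundary_jitter_mm``, i.e. the contour
    moves in or out by at most the jitter, in spatially coherent patches.
    If the Dice overlap with the original falls below ``dice_floor`` the
    field amplitude is shrunk until the floor holds (the jitter is an upper
    bound on boundary displacement, not an exact displacement).
    ``jitter = 0`` returns the mask unchanged.
    """
    if boundary_jitter_mm < 0:
        raise ValueError("jitter must be >= 0")
    if boundary_jitter_mm == 0:
        return mask
    rng = np.random.default_rng(seed)
    d_out = ndimage.distance_transform_edt(~mask.values, sampling=mask.spacing_mm)
    d_in = ndimage.distance_transform_edt(mask.values, sampling=mask.spacing_mm)
    # signed distance of voxel centers to the mask *surface* (the union-of-
    # cubes boundary sits half a voxel beyond the outermost centers), so a
    # sub-voxel jitter can flip boundary voxels
    half = 0.5 * float(mask.spacing_mm.mean())
    signed = np.where(mask.values, -(d_in - half), d_out - half)
    field = ndimage.gaussian_filter(
        rng.normal(size=mask.values.shape),
        sigma=smoothness_mm / mask.spacing_mm,
    )
    scale = float(np.quantile(np.abs(field), 0.95))
    field = np.clip(field / max(scale, 1e-12), -1.0, 1.0)

    amplitude = boundary_jitter_mm
    for _ in range(8):
        out = signed <= amplitude * field
        if not out.any():
            raise ValueError("re-test perturbation emptied the mask")
        inter = np.logical_and(out, mask.values).sum()
        dice = 2.0 * inter / (out.sum() + mask.n_voxels)
        if dice >= dice_floor:
            break
        amplitude *= 0.8
        log.info("retest jitter shrunk to %.2f mm to hold Dice >= %.2f", amplitude, dice_floor)
    return BinaryMask(values=out, spacing_mm=mask.spacing_mm, origin_mm=mask.origin_mm)


# --------------------------------------------------------------------------
# cohort assembly
# --------------------------------------------------------------------------

def _sample_interval(cfg: CohortConfig, rng: np.random.Generator) -> int:
    """Truncated log-normal interval, median ~35 days, range [16, 128]."""
    mu = np.log(cfg.interval_median_days)
    while True:
        d = int(round(float(rng.lognormal(mu, cfg.interval_sigma_log))))
        if cfg.interval_min_days <= d <= cfg.interval_max_days:
            return d


def _sample_clinical(rng: np.random.Generator) -> dict:
    m = CLINICAL_MARGINALS
    pick = lambda key: str(rng.choice(m[key][0], p=m[key][1]))
    lt60 = rng.random() < m["age_lt60"]
    age = float(rng.uniform(35, 60) if lt60 else rng.uniform(60, 82))
    return {
        "sex": pick("sex"),
        "age": round(age, 1),
        "smoking": pick("smoking"),
        "ethnicity": pick("ethnicity"),
        "t_stage": pick("t_stage"),
        "n_stage": pick("n_stage"),
        "m_stage": pick("m_stage"),
        "tki_drug": pick("tki_drug"),
    }


def _sample_patient(cfg: CohortConfig, patient_id: str, cohort: str,
                    rng: np.random.Generator) -> SyntheticPatient:
    r0 = rng.uniform(cfg.radius_min_mm, cfg.radius_max_mm)
    radii = r0 * rng.uniform(1 - cfg.axis_anisotropy, 1 + cfg.axis_anisotropy, size=3)
    interval = _sample_interval(cfg, rng)
    amp_lo, amp_hi = cfg.texture_amplitude_range
    amplitude = float(rng.uniform(amp_lo, amp_hi))
    amp_z = 2.0 * (amplitude - amp_lo) / (amp_hi - amp_lo) - 1.0
    vr_mean = cfg.volume_rate_mean + cfg.baseline_link * cfg.volume_rate_sd * amp_z
    pr_mean = cfg.peri_link * cfg.peri_rate_sd * amp_z
    profile = ProgressionProfile(
        volume_rate_per_day=float(rng.normal(vr_mean, cfg.volume_rate_sd)),
        texture_rate_per_day=float(rng.normal(0.0, cfg.texture_rate_sd)),
        peri_rate_per_day=float(rng.normal(pr_mean, cfg.peri_rate_sd)),
        weights=cfg.risk_weights,
    )
    growth = max(1.0 + profile.volume_rate_per_day * interval, EVOLUTION_FLOOR) ** (1 / 3)
    margin = 13.5
    half = radii.max() * max(growth, 1.0) + margin
    n = int(np.ceil(2 * half / cfg.spacing_mm))
    spec = GridSpec(
        shape=(n, n, n),
        spacing_mm=cfg.spacing_mm,
        lung_background=cfg.lung_background,
        noise_sd=cfg.noise_sd,
        chest_wall=bool(rng.random() < cfg.chest_wall_fraction),
    )
    center = np.full(3, n * cfg.spacing_mm / 2.0)
    params = LesionParams(
        center_mm=center,
        radii_mm=radii,
        core_intensity=float(rng.normal(cfg.core_intensity_mean, cfg.core_intensity_sd)),
        texture_scale_mm=float(rng.uniform(*cfg.texture_scale_range_mm)),
        texture_amplitude=amplitude,
        rim_gradient=float(rng.uniform(*cfg.rim_gradient_range)),
    )
    pair_seed = int(rng.integers(0, 2**31 - 1))
    pair = simulate_lesion_pair(params, profile, interval, spec, pair_seed)
    retest = perturb_mask_for_retest(
        pair.f0_mask, cfg.retest_jitter_mm, int(rng.integers(0, 2**31 - 1)),
        dice_floor=cfg.dice_floor,
    )
    clin = _sample_clinical(rng)
    volume_ml = mask_volume_ml(pair.f0_mask)
    risk = profile.latent_risk
    if cfg.clinical_volume_effect:
        risk = risk + cfg.volume_log_hr_per_ml * volume_ml
    outcome = simulate_survival(risk, cfg.baseline_scale_months, cfg.censor_window_months, rng)
    record = ClinicalRecord(baseline_volume_ml=round(volume_ml, 3), **clin)
    return SyntheticPatient(
        patient_id=patient_id, cohort=cohort, scan_pair=pair, retest_mask=retest,
        clinical=record, outcome=outcome, profile=profile,
    )


def simulate_cohort(
    config: CohortConfig, seed: int, out_dir: str | Path | None = None
) -> list[SyntheticPatient]:
    """Generate the training + validation cohorts; optionally write to disk.

    Layout (when ``out_dir`` is given)::

        <out_dir>/<patient_id>/{F0,F1}.nii.gz, {F0,F1}_mask.nii.gz,
                               F0_mask_retest.nii.gz, lung_mask.nii.gz
        <out_dir>/clinical.csv, outcomes.csv, intervals.csv, cohorts.csv
    """
    if config.n_train < 10 or config.n_valid < 10:
        raise ValueError("cohorts need at least 10 patients each for downstream models")
    rng = np.random.default_rng(seed)
    patients: list[SyntheticPatient] = []
    for cohort, n, tag in (("train", config.n_train, "T"), ("valid", config.n_valid, "V")):
        for i in range(n):
            pid = f"LUAD-{tag}-{i + 1:03d}"
            patients.append(_sample_patient(config, pid, cohort, rng))
    if out_dir is not None:
        write_cohort(patients, out_dir)
    return patients


def write_cohort(patients: list[SyntheticPatient], out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    clin_rows, outcome_rows, interval_rows, cohort_rows = [], [], [], []
    for p in patients:
        pdir = out / p.patient_id
        pdir.mkdir(exist_ok=True)
        sp = p.scan_pair
        write_volume(sp.f0, pdir / "F0.nii.gz")
        write_mask(sp.f0_mask, pdir / "F0_mask.nii.gz")
        write_mask(p.retest_mask, pdir / "F0_mask_retest.nii.gz")
        write_volume(sp.f1, pdir / "F1.nii.gz")
        write_mask(sp.f1_mask, pdir / "F1_mask.nii.gz")
        write_mask(sp.lung_mask, pdir / "lung_mask.nii.gz")
        c = p.clinical
        clin_rows.append({
            "patient_id": p.patient_id, "sex": c.sex, "age": c.age,
            "smoking": c.smoking, "ethnicity": c.ethnicity,
            "t_stage": c.t_stage, "n_stage": c.n_stage, "m_stage": c.m_stage,
            "tki_drug": c.tki_drug, "baseline_volume_ml": c.baseline_volume_ml,
        })
        outcome_rows.append({
            "patient_id": p.patient_id,
            "pfs_months": round(p.outcome.time_months, 4),
            "event": int(p.outcome.event),
        })
        interval_rows.append({"patient_id": p.patient_id, "diff_days": sp.interval_days})
        cohort_rows.append({"patient_id": p.patient_id, "cohort": p.cohort})
    pd.DataFrame(clin_rows).to_csv(out / "clinical.csv", index=False)
    pd.DataFrame(outcome_rows).to_csv(out / "outcomes.csv", index=False)
    pd.DataFrame(interval_rows).to_csv(out / "intervals.csv", index=False)
    pd.DataFrame(cohort_rows).to_csv(out / "cohorts.csv", index=False)


def outcomes_frame(patients: list[SyntheticPatient]) -> pd.DataFrame:
    return pd.DataFrame({
        "patient_id": [p.patient_id for p in patients],
        "pfs_months": [p.outcome.time_months for p in patients],
        "event": [int(p.outcome.event) for p in patients],
    }).set_index("patient_id")
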