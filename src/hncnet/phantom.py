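"""Phantom CT cohorts with a controllable prognostic signal.

The generator stands in for real multi-center head-and-neck cohorts so the
whole pipeline (pre-processing, training, selection, evaluation) can be
exercised end to end. Each phantom is a noisy soft-tissue volume with fixed
air and bone inclusions and one ellipsoidal tumor. The tumor's *texture
heterogeneity* — the standard deviation of the Gaussian HU texture inside
the GTV — is the latent prognostic variable:

    P(event) = logistic(b0 + effect_size * z),   z = standardized heterogeneity,

with b0 calibrated numerically so the marginal event rate matches the
requested prevalence. Tumor size is drawn with a positive dependence on z
(more heterogeneous tumors tend to be larger), so the image carries the
signal through both texture and size, as real prognostic cohorts do.
Clinical covariates depend on the same latent risk with documented
linear-in-log-odds coefficients. Event-free patients are right-censored:
a configurable fraction receives follow-up below the outcome time frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .cohort import PatientRecord, records_to_frame
from .errors import ConfigurationError
from .preprocess import CTVolume, GTVMask, HU_MAX, HU_MIN, save_nifti_pair

#: HU parameters of the phantom tissue model.
TUMOR_MEAN_HU = 100.0
BACKGROUND_NOISE_HU = 20.0
AIR_HU = -1000.0
BONE_HU = 700.0

INSTITUTIONS = ("SYN_A", "SYN_B", "SYN_C", "SYN_D", "SYN_E")
#: Sampling weights over the five synthetic centers (multi-center imbalance).
INSTITUTION_WEIGHTS = (0.21, 0.23, 0.09, 0.15, 0.32)


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one phantom volume/mask pair."""

    volume_shape: tuple[int, int, int] = (32, 160, 160)
    spacing: tuple[float, float, float] = (3.0, 1.0, 1.0)
    tumor_center: tuple[int, int, int] = (16, 80, 80)
    tumor_radii: tuple[float, float, float] = (12.0, 15.0, 15.0)  # mm per axis
    texture_heterogeneity: float = 30.0
    base_tissue_hu: float = 40.0
    seed: int = 0

    def __post_init__(self):
        if any(s <= 0 for s in self.spacing):
            raise ConfigurationError("spacing must be positive")
        if self.texture_heterogeneity < 0:
            raise ConfigurationError("texture_heterogeneity must be >= 0")
        for ax in range(3):
            lo = self.tumor_center[ax] * self.spacing[ax] - self.tumor_radii[ax]
            hi = self.tumor_center[ax] * self.spacing[ax] + self.tumor_radii[ax]
            if lo < 0 or hi > (self.volume_shape[ax] - 1) * self.spacing[ax]:
                raise ConfigurationError(
                    f"tumor ellipsoid leaves the volume along axis {ax} "
                    f"(center {self.tumor_center}, radii {self.tumor_radii})"
                )


@dataclass(frozen=True)
class SyntheticCohortConfig:
    n_patients: int = 100
    prevalence: float = 0.135
    effect_size: float = 2.0
    censoring_fraction: float = 0.15
    time_frame_days: int = 730
    #: mm of in-plane tumor radius per SD of standardized heterogeneity;
    #: 0 confines the prognostic signal to texture alone
    size_risk_coupling: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 2:
            raise ConfigurationError("n_patients must be >= 2")
        if not 0.0 < self.prevalence < 1.0:
            raise ConfigurationError("prevalence must lie in (0, 1)")
        if not 0.0 <= self.censoring_fraction < 1.0:
            raise ConfigurationError("censoring_fraction must lie in [0, 1)")
        if self.time_frame_days <= 0:
            raise ConfigurationError("time_frame_days must be > 0")


# ---------------------------------------------------------------------------
# single phantom
# ---------------------------------------------------------------------------

def generate_phantom_volume(spec: PhantomSpec) -> tuple[CTVolume, GTVMask]:
    """One phantom: tissue noise + fixed air/bone inclusions + textured tumor."""
    rng = np.random.default_rng(spec.seed)
    S, R, C = spec.volume_shape
    dz, dy, dx = spec.spacing

    vox = spec.base_tissue_hu + BACKGROUND_NOISE_HU * rng.standard_normal((S, R, C))
    vox = vox.astype(np.float32)

    # fixed inclusions at relative positions: an air cavity and a bone bar
    vox[:, int(0.05 * R) : int(0.15 * R), int(0.40 * C) : int(0.60 * C)] = AIR_HU
    vox[:, int(0.82 * R) : int(0.90 * R), int(0.20 * C) : int(0.80 * C)] = BONE_HU

    zz, yy, xx = np.ogrid[:S, :R, :C]
    cz, cy, cx = spec.tumor_center
    rz, ry, rx = spec.tumor_radii
    dist2 = (
        ((zz - cz) * dz / rz) ** 2
        + ((yy - cy) * dy / ry) ** 2
        + ((xx - cx) * dx / rx) ** 2
    )
    mask = (dist2 <= 1.0).astype(np.uint8)
    if mask.sum() == 0:
        raise ConfigurationError("tumor radii too small for the voxel grid")

    inside = mask.astype(bool)
    tumor = TUMOR_MEAN_HU + spec.texture_heterogeneity * rng.standard_normal(int(inside.sum()))
    vox[inside] = tumor.astype(np.float32)

    np.clip(vox, HU_MIN, HU_MAX, out=vox)
    return CTVolume(vox, spec.spacing), GTVMask(mask, spec.spacing)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def calibrate_intercept(z: np.ndarray, effect_size: float, prevalence: float) -> float:
    """Solve mean(expit(b0 + effect*z)) = prevalence for b0."""

    def marginal(b0):
        return float(np.mean(expit(b0 + effect_size * z))) - prevalence

    return brentq(marginal, -30.0, 30.0, xtol=1e-10)


def _draw_stage(rng, eta, cuts, labels, noise=1.0):
    """Ordinal draw: latent eta + noise thresholded at ``cuts``."""
    u = eta + noise * rng.standard_normal()
    return labels[int(np.searchsorted(cuts, u))]


def cohort_phantom_specs(cfg: SyntheticCohortConfig) -> tuple[list[PhantomSpec], list[PatientRecord]]:
    """Per-patient phantom recipes and clinical records, without rendering
    any volume (rendering is deferred so big cohorts can stream)."""
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    n = cfg.n_patients
    frame = float(cfg.time_frame_days)

    # latent heterogeneity: lognormal, median 30 HU
    het = np.exp(rng.normal(math.log(30.0), 0.45, size=n))
    z = (het - het.mean()) / max(het.std(), 1e-12)
    b0 = calibrate_intercept(z, cfg.effect_size, cfg.prevalence)
    eta = b0 + cfg.effect_size * z  # log-odds of the primary event

    p_event = expit(eta)
    event_dm = (rng.random(n) < p_event).astype(int)
    # secondary outcomes share the latent risk with damped effects
    event_lrf = (rng.random(n) < expit(b0 + 0.7 * cfg.effect_size * z)).astype(int)
    p_death = np.clip(1.6 * expit(b0 + 0.5 * cfg.effect_size * z), 0.0, 0.95)
    event_death = (rng.random(n) < p_death).astype(int)

    # tumor size grows with standardized heterogeneity (documented coupling)
    r_inplane = np.clip(15.0 + cfg.size_risk_coupling * z + 1.5 * rng.standard_normal(n), 7.0, 24.0)
    r_axial = np.clip(0.8 * r_inplane + 1.0 * rng.standard_normal(n), 5.0, 20.0)

    specs, records = [], []
    t_cuts, t_labels = [-1.0, 0.0, 1.0], ["T1", "T2", "T3", "T4"]
    n_cuts, n_labels = [0.0, 1.2, 2.2], ["N0", "N1", "N2", "N3"]
    for i in range(n):
        center = (
            16 + int(rng.integers(-2, 3)),
            80 + int(rng.integers(-8, 9)),
            80 + int(rng.integers(-8, 9)),
        )
        spec = PhantomSpec(
            tumor_center=center,
            tumor_radii=(float(r_axial[i]), float(r_inplane[i]), float(r_inplane[i])),
            texture_heterogeneity=float(het[i]),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        specs.append(spec)

        # event / censoring times
        def _etime(flag):
            return float(rng.uniform(1.0, frame)) if flag else None

        t_dm, t_lrf, t_death = _etime(event_dm[i]), _etime(event_lrf[i]), _etime(event_death[i])
        if event_dm[i]:
            followup = t_dm
        elif rng.random() < cfg.censoring_fraction:
            followup = float(rng.uniform(0.2, 0.999) * frame)  # censored short
        else:
            followup = float(frame * (1.0 + rng.uniform(0.0, 1.0)))

        # clinical covariates: linear-in-log-odds dependence on eta
        age = float(np.clip(62.0 + 4.0 * eta[i] + 9.0 * rng.standard_normal(), 30.0, 92.0))
        sex = "male" if rng.random() < 0.75 else "female"
        hpv = "positive" if rng.random() < expit(0.6 - 0.5 * eta[i]) else "negative"
        site = str(rng.choice(["oropharynx", "larynx", "hypopharynx", "oral_cavity"]))
        # T stage from size, N stage from latent risk
        t_stage = t_labels[int(np.searchsorted([11.0, 15.0, 19.0], r_inplane[i]))]
        n_stage = _draw_stage(rng, eta[i], n_cuts, n_labels)
        advanced = t_stage in ("T3", "T4") or n_stage in ("N2", "N3")
        overall = "IV" if (t_stage == "T4" or n_stage == "N3") else ("III" if advanced else "II")
        treatment = "chemoradiation" if advanced else "radiation"

        rz, ry, rx = spec.tumor_radii
        records.append(PatientRecord(
            patient_id=f"P{i:04d}", age=age, sex=sex, hpv_status=hpv, site=site,
            t_stage=t_stage, n_stage=n_stage, overall_stage=overall, treatment=treatment,
            event_dm=int(event_dm[i]), time_dm_days=t_dm,
            event_lrf=int(event_lrf[i]), time_lrf_days=t_lrf,
            event_death=int(event_death[i]), time_death_days=t_death,
            followup_days=followup,
            gtv_area_mm2=float(math.pi * ry * rx),
            gtv_volume_mm3=float(4.0 / 3.0 * math.pi * rz * ry * rx),
            institution=str(rng.choice(INSTITUTIONS, p=INSTITUTION_WEIGHTS)),
            texture_heterogeneity=float(het[i]),
        ))
    return specs, records


def generate_synthetic_cohort(cfg: SyntheticCohortConfig, with_volumes: bool = True):
    """Full cohort: list of (CTVolume, GTVMask) pairs and patient records.

    With ``with_volumes=False`` the image pairs are omitted (empty list);
    use :func:`cohort_phantom_specs` + :func:`generate_phantom_volume` to
    stream volumes one at a time instead.
    """
    specs, records = cohort_phantom_specs(cfg)
    pairs = [generate_phantom_volume(s) for s in specs] if with_volumes else []
    return pairs, records


def write_cohort(cfg: SyntheticCohortConfig, out_dir) -> Path:
    """Materialize a cohort on disk: NIfTI image/mask pairs + clinical CSV."""
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    specs, records = cohort_phantom_specs(cfg)
    for spec, rec in zip(specs, records):
        vol, mask = generate_phantom_volume(spec)
        save_nifti_pair(
            vol, mask,
            out_dir / "images" / f"{rec.patient_id}_image.nii.gz",
            out_dir / "images" / f"{rec.patient_id}_mask.nii.gz",
        )
    records_to_frame(records).to_csv(out_dir / "clinical.csv", index=False)
    return out_dir
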