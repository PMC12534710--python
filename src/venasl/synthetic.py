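"""Digital phantoms, simulated acquisitions, and synthetic cohorts.

Every downstream quantifier in this package is validated against forward
simulations with known ground truth:

* :func:`make_phantom` builds a labeled head geometry (GM/WM/CSF/bone, a
  mid-sagittal venous sinus tube, and carotid stubs) with smooth CBF/ATT
  fields at stated tissue means;
* :func:`simulate_asl` generates label/control pCASL series through the same
  kinetic model the quantifiers invert, injects a venous difference signal
  of known nominal amplitude into the sinus, and optionally applies
  frame-wise rigid motion;
* :func:`simulate_trust` and :func:`simulate_pc` are exact forward models of
  the TRUST decay and phase-contrast velocity encoding;
* :func:`simulate_cohort` draws a subject table whose latent "capillary
  shunt severity" simultaneously raises the venous ASL signal (VHS) and
  lowers the oxygen extraction fraction (OEF) independently of oxygen
  delivery — the mechanism the cohort statistics are meant to detect.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .asl import ASLSeries, compute_do2
from .kinetics import (
    AcquisitionTiming,
    BloodProperties,
    KineticConstants,
    kinetic_model_signal,
    t1_blood,
)
from .pc import VesselROI, rasterize_roi
from .trust import CalibrationModel, TrustMeasurement

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "CohortGenParams",
    "make_phantom",
    "simulate_asl",
    "simulate_trust",
    "simulate_pc",
    "simulate_cohort",
    "HEMODYNAMIC_VARIABLES",
]

# The hemodynamic variable family used for the correlation matrix: 13
# variables, hence 13*12/2 = 78 pairwise tests in the Bonferroni family.
HEMODYNAMIC_VARIABLES = (
    "vhs",
    "oef",
    "cbf",
    "att",
    "do2",
    "do2_single",
    "hb",
    "sss_area",
    "sss_velocity",
    "sss_flow",
    "ica_area",
    "ica_velocity",
    "ica_flow",
)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and sampling parameters of the digital head phantom."""

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0)
    sinus_radius: int = 2
    gm_cbf: float = 68.0
    wm_cbf: float = 25.0
    gm_att: float = 1.35
    wm_att: float = 1.6
    cbf_field_rel_sd: float = 0.05
    att_field_sd: float = 0.05
    smooth_sigma: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.grid_shape) < 16:
            raise ValueError("phantom grid must be at least 16 voxels per axis")
        if self.sinus_radius < 1 or self.sinus_radius >= min(self.grid_shape) // 4:
            raise ValueError("sinus radius degenerate for this grid")


@dataclass
class GroundTruth:
    """Known truth behind a simulated acquisition."""

    cbf_map: np.ndarray
    att_map: np.ndarray
    pd_map: np.ndarray  # relative proton density / M0 tissue fraction
    masks: dict[str, np.ndarray]
    venous_amplitude: float = 90.0
    motion_params: np.ndarray | None = None
    yv_true: float | None = None
    velocity_true: dict[str, float] | None = None
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0)

    def __post_init__(self) -> None:
        tissue = self.masks.get("GM", 0) | self.masks.get("WM", 0)
        if np.any(self.cbf_map[np.asarray(tissue, dtype=bool)] < 0):
            raise ValueError("tissue CBF must be non-negative")
        if np.any(self.att_map <= 0):
            raise ValueError("ATT map must be positive everywhere")
        if self.yv_true is not None and not 0 < self.yv_true < 1:
            raise ValueError("venous saturation must lie in (0, 1)")


def _smooth_field(shape, sigma, rng) -> np.ndarray:
    """Zero-mean, unit-variance smooth Gaussian random field."""
    field = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    field -= field.mean()
    sd = field.std()
    return field / sd if sd > 0 else field


def make_phantom(spec: PhantomSpec) -> tuple[dict[str, np.ndarray], GroundTruth]:
    """Build region masks and smooth ground-truth CBF/ATT/PD maps.

    Axis convention: axis 0 = left-right (the mid-sagittal plane is at index
    n0//2), axis 1 = posterior-anterior, axis 2 = inferior-superior.  The
    venous sinus is a straight mid-sagittal tube running posterior-anterior
    just under the inner skull surface, so it always intersects the
    mid-sagittal slab.  Labels are mutually exclusive by construction.
    """
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.grid_shape
    x, y, z = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2

    def ellipsoid(rx, ry, rz):
        return ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2 <= 1

    head = ellipsoid(0.46 * nx, 0.46 * ny, 0.46 * nz)
    inner_skull = ellipsoid(0.42 * nx, 0.42 * ny, 0.42 * nz)
    brain_outer = ellipsoid(0.40 * nx, 0.40 * ny, 0.40 * nz)
    wm_core = ellipsoid(0.28 * nx, 0.28 * ny, 0.28 * nz)
    ventricles = ellipsoid(0.08 * nx, 0.12 * ny, 0.08 * nz)

    bone = head & ~inner_skull
    csf = (inner_skull & ~brain_outer) | ventricles
    gm = brain_outer & ~wm_core
    wm = wm_core & ~ventricles

    # venous sinus: mid-sagittal tube under the inner skull, posterior half
    r = spec.sinus_radius
    z_sinus = int(round(cz + 0.34 * nz))
    sinus = (
        (np.abs(x - nx // 2) <= r)
        & (np.abs(z - z_sinus) <= r)
        & (y >= int(0.2 * ny))
        & (y <= int(0.8 * ny))
    )
    if not np.any(sinus & inner_skull):
        raise ValueError("venous sinus tube falls outside the head geometry")
    sinus &= inner_skull

    # carotid stubs: bilateral vertical tubes at the base
    ica_l = (
        (np.abs(x - (cx - 0.15 * nx)) <= 1.5)
        & (np.abs(y - cy) <= 1.5)
        & (z <= int(0.18 * nz))
    )
    ica_r = (
        (np.abs(x - (cx + 0.15 * nx)) <= 1.5)
        & (np.abs(y - cy) <= 1.5)
        & (z <= int(0.18 * nz))
    )

    # enforce mutual exclusivity (priority: sinus > ICA > CSF > GM > WM > bone)
    gm &= ~sinus
    wm &= ~sinus
    csf &= ~sinus
    bone &= ~sinus
    for m in (gm, wm, csf, bone):
        m &= ~(ica_l | ica_r)

    masks = {
        "GM": gm,
        "WM": wm,
        "CSF": csf,
        "bone": bone,
        "venous_sinus": sinus,
        "ICA_left": ica_l,
        "ICA_right": ica_r,
    }
    for name, m in masks.items():
        if not np.any(m):
            raise ValueError(f"phantom region '{name}' is empty")

    cbf = np.zeros(spec.grid_shape)
    field = _smooth_field(spec.grid_shape, spec.smooth_sigma, rng)
    cbf[gm] = spec.gm_cbf * (1.0 + spec.cbf_field_rel_sd * field[gm])
    cbf[wm] = spec.wm_cbf * (1.0 + spec.cbf_field_rel_sd * field[wm])
    np.clip(cbf, 0.0, None, out=cbf)

    att = np.full(spec.grid_shape, 1.3)
    att_field = _smooth_field(spec.grid_shape, spec.smooth_sigma, rng)
    att[gm] = spec.gm_att + spec.att_field_sd * att_field[gm]
    att[wm] = spec.wm_att + spec.att_field_sd * att_field[wm]
    np.clip(att, 0.25, 2.45, out=att)

    pd_map = np.zeros(spec.grid_shape)
    for name, val in (
        ("GM", 0.85),
        ("WM", 0.7),
        ("CSF", 1.0),
        ("bone", 0.2),
        ("venous_sinus", 0.8),
        ("ICA_left", 0.8),
        ("ICA_right", 0.8),
    ):
        pd_map[masks[name]] = val

    truth = GroundTruth(cbf_map=cbf, att_map=att, pd_map=pd_map, masks=masks)
    return masks, truth


def _apply_rigid(volume: np.ndarray, params, voxel_size) -> np.ndarray:
    """Resample a volume under a rigid transform (linear interpolation).

    ``params`` = (tx, ty, tz [mm], rx, ry, rz [rad]); rotations are about
    the volume center.  Zero parameters return the input unchanged.
    """
    params = np.asarray(params, dtype=float)
    if np.allclose(params, 0):
        return volume
    t_vox = params[:3] / np.asarray(voxel_size, dtype=float)
    ax, ay, az = params[3:]
    rx = np.array(
        [[1, 0, 0], [0, np.cos(ax), -np.sin(ax)], [0, np.sin(ax), np.cos(ax)]]
    )
    ry = np.array(
        [[np.cos(ay), 0, np.sin(ay)], [0, 1, 0], [-np.sin(ay), 0, np.cos(ay)]]
    )
    rz = np.array(
        [[np.cos(az), -np.sin(az), 0], [np.sin(az), np.cos(az), 0], [0, 0, 1]]
    )
    rot = rz @ ry @ rx
    center = (np.asarray(volume.shape) - 1) / 2.0
    # moved(x) = original(R^T (x - c - t) + c): rotate about the center, then
    # translate; affine_transform samples input at matrix @ output + offset
    inv = rot.T
    offset = center - inv @ (center + t_vox)
    return ndimage.affine_transform(volume, inv, offset=offset, order=1, mode="nearest")


def simulate_asl(
    truth: GroundTruth,
    timing: AcquisitionTiming,
    blood: BloodProperties | None = None,
    consts: KineticConstants | None = None,
    noise_sd: float = 0.0,
    motion: np.ndarray | None = None,
    seed: int = 0,
    m0_value: float = 1000.0,
) -> ASLSeries:
    """Forward-simulate a pCASL label/control series from ground truth.

    control = M0 * proton-density fraction (+ noise); label = control - dM
    with dM from the shared kinetic model at the pair's delay.  Venous sinus
    voxels receive a difference signal generated by evaluating the same
    model at the *assumed* single-delay transit time with CBF equal to
    ``truth.venous_amplitude`` — so single-delay quantification recovers the
    injected nominal amplitude exactly.  Rigid motion (one 6-parameter row
    per frame; frame order control0, label0, control1, ...) is applied by
    resampling before noise.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    blood = blood or BloodProperties()
    consts = consts or KineticConstants()
    rng = np.random.default_rng(seed)

    schedule = timing.pld_schedule()
    n_pairs = timing.n_pairs
    shape = truth.cbf_map.shape
    m0 = m0_value * truth.pd_map
    sinus = np.asarray(truth.masks["venous_sinus"], dtype=bool)

    controls = np.empty(shape + (n_pairs,))
    labels = np.empty(shape + (n_pairs,))
    if motion is None:
        motion = np.zeros((2 * n_pairs, 6))
    motion = np.asarray(motion, dtype=float)
    if motion.shape != (2 * n_pairs, 6):
        raise ValueError("motion must supply one 6-dof row per frame (2 per pair)")

    for i, pld in enumerate(schedule):
        t = pld + timing.labeling_duration
        dm = m0 * kinetic_model_signal(
            truth.cbf_map, truth.att_map, t, timing, blood, consts
        )
        # venous injection through the single-delay scaling at the assumed ATT
        dm_sinus = m0[sinus] * kinetic_model_signal(
            truth.venous_amplitude, consts.assumed_att, t, timing, blood, consts
        )
        dm[sinus] = dm_sinus
        ctrl = m0.copy()
        lbl = ctrl - dm
        ctrl = _apply_rigid(ctrl, motion[2 * i], truth.voxel_size)
        lbl = _apply_rigid(lbl, motion[2 * i + 1], truth.voxel_size)
        if noise_sd > 0:
            ctrl = ctrl + rng.normal(0.0, noise_sd, shape)
            lbl = lbl + rng.normal(0.0, noise_sd, shape)
        controls[..., i] = ctrl
        labels[..., i] = lbl

    return ASLSeries(
        labels=labels,
        controls=controls,
        m0=m0,
        timing=timing,
        voxel_size=truth.voxel_size,
        pld_schedule=schedule,
    )


def simulate_trust(
    yv_true: float,
    hct: float = 0.42,
    s0: float = 100.0,
    etes_ms=(0.0, 40.0, 80.0, 160.0),
    noise_sd: float = 0.0,
    n_pairs_per_ete: int = 3,
    seed: int = 0,
    calib: CalibrationModel | None = None,
    consts: KineticConstants | None = None,
) -> TrustMeasurement:
    """Forward-model TRUST blood signals at the given venous saturation.

    S(eTE) = s0 * exp(-eTE * (1/T2b(yv, hct) + 1/T1b(hct))), with T2b from
    the same calibration the quantifier inverts; per-pair Gaussian noise is
    averaged over ``n_pairs_per_ete`` repeats.
    """
    if not 0 < yv_true < 1:
        raise ValueError("venous saturation must lie in (0, 1)")
    calib = calib or CalibrationModel()
    rng = np.random.default_rng(seed)
    etes = np.asarray(etes_ms, dtype=float)
    r_total = calib.r2_blood(yv_true, hct) + 1.0 / t1_blood(hct, consts)
    clean = s0 * np.exp(-etes / 1000.0 * r_total)
    if noise_sd > 0:
        reps = clean[:, None] + rng.normal(0.0, noise_sd, (etes.size, n_pairs_per_ete))
        signals = reps.mean(axis=1)
    else:
        signals = clean
    return TrustMeasurement(etes=etes, signals=signals, n_pairs_per_ete=n_pairs_per_ete)


def simulate_pc(
    vessel_rois: list[VesselROI],
    velocity_true: dict[str, float],
    venc: float = 40.0,
    shape: tuple[int, int] = (64, 64),
    noise_sd_phase: float = 0.0,
    profile: str = "plug",
    allow_alias: bool = False,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Forward-model a phase-contrast acquisition (phase + magnitude images).

    Inside each rasterized vessel the phase is pi * v / VENC (plug profile by
    default; ``profile="parabolic"`` scales the profile to the requested mean
    with zero velocity at the rim).  Velocities beyond VENC alias and are
    refused unless ``allow_alias`` is set.
    """
    rng = np.random.default_rng(seed)
    phase = np.zeros(shape)
    magnitude = np.full(shape, 20.0)
    for roi in vessel_rois:
        v = velocity_true[roi.name]
        if abs(v) > venc and not allow_alias:
            raise ValueError(
                f"velocity {v} cm/s exceeds VENC {venc} cm/s for '{roi.name}'"
            )
        mask = rasterize_roi(roi, shape)
        if profile == "plug":
            vel = np.full(int(mask.sum()), v)
        elif profile == "parabolic":
            ii, jj = np.nonzero(mask)
            ci, cj = ii.mean(), jj.mean()
            r2 = (ii - ci) ** 2 + (jj - cj) ** 2
            rmax2 = max(r2.max(), 1.0)
            prof = 1.0 - r2 / rmax2
            vel = v * prof / prof.mean()  # mean over ROI equals v
        else:
            raise ValueError(f"unknown flow profile '{profile}'")
        phase[mask] = np.pi * vel / venc
        magnitude[mask] = 200.0
    if noise_sd_phase > 0:
        phase = phase + rng.normal(0.0, noise_sd_phase, shape)
        phase = np.clip(phase, -np.pi, np.pi)
        magnitude = magnitude + rng.normal(0.0, 2.0, shape)
    return phase, magnitude


@dataclass(frozen=True)
class CohortGenParams:
    """Generative parameters of the synthetic cohort.

    Means and SDs default to the demographic structure of a typically aging
    study population (ages 60-80): GM CBF 68.1 +/- 11.0 mL/100g/min, Hb
    13.9 +/- 1.3 g/dL, Hct 0.417 +/- 0.032, ATT 1.35 +/- 0.21 s, OEF around
    0.37.  A lognormal latent "capillary shunt severity" raises the venous
    ASL signal (``beta_shunt_vhs`` nominal units per unit severity) and
    multiplies the extraction efficiency by (1 - beta_shunt_oef * severity),
    independently of oxygen delivery.  ``beta_cbf_vhs`` encodes the
    perfusion weighting of VHS.
    """

    n_subjects: int = 36
    cbf_mean: float = 68.1
    cbf_sd: float = 11.0
    att_mean: float = 1.35
    att_sd: float = 0.21
    att_cbf_r: float = -0.4
    hb_mean: float = 13.9
    hb_sd: float = 1.3
    hct_mean: float = 0.417
    hct_sd: float = 0.032
    ya_mean: float = 0.98
    ya_sd: float = 0.005
    cmro2_mean: float = 4.95
    cmro2_sd: float = 0.55
    shunt_mu: float = 0.0
    shunt_sigma: float = 0.5
    beta_shunt_vhs: float = 25.0
    beta_shunt_oef: float = 0.06
    beta_cbf_vhs: float = 1.0
    vhs_noise_sd: float = 8.0
    oef_noise_sd: float = 0.015
    flow_noise_sd: float = 30.0
    brain_vol_mean: float = 1047.0
    brain_vol_sd: float = 109.0
    ica_flow_fraction: float = 0.56
    sss_flow_fraction: float = 0.36
    do2_single_scale: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("a cohort needs at least 3 subjects")
        for name in (
            "cbf_sd", "att_sd", "hb_sd", "hct_sd", "ya_sd", "cmro2_sd",
            "vhs_noise_sd", "oef_noise_sd", "flow_noise_sd", "brain_vol_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.beta_shunt_oef < 0 or self.beta_shunt_oef >= 1:
            raise ValueError("extraction-efficiency penalty must lie in [0, 1)")


def simulate_cohort(
    params: CohortGenParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a synthetic subject table plus its latent ground truth.

    Per subject: CBF, Hb, Hct, Ya, and CMRO2 are drawn independently; ATT is
    a central-volume-consistent decreasing function of CBF plus noise tuned
    to a Pearson r(ATT, CBF) of about ``att_cbf_r``; DO2 follows from the
    delivery equation; OEF = clip(CMRO2/DO2 * (1 - beta_shunt_oef*severity),
    0.05, 0.95) plus noise; VHS = beta_cbf_vhs*CBF + beta_shunt_vhs*severity
    plus noise; SSS/ICA flows are proportional to CBF x brain mass plus
    noise.  Emits a warning when OEF clipping affects more than 10% of
    subjects.  Returns ``(cohort, truth)`` data frames.
    """
    p = params or CohortGenParams()
    rng = np.random.default_rng(p.seed)
    n = p.n_subjects

    cbf = np.clip(rng.normal(p.cbf_mean, p.cbf_sd, n), 20.0, None)
    hb = np.clip(rng.normal(p.hb_mean, p.hb_sd, n), 5.0, 20.0)
    hct = np.clip(rng.normal(p.hct_mean, p.hct_sd, n), 0.25, 0.55)
    ya = np.clip(rng.normal(p.ya_mean, p.ya_sd, n), 0.9, 1.0)
    severity = rng.lognormal(p.shunt_mu, p.shunt_sigma, n)
    cmro2 = np.clip(rng.normal(p.cmro2_mean, p.cmro2_sd, n), 1.0, None)

    # ATT decreasing in CBF (central volume theorem), target correlation
    slope = -p.att_cbf_r * p.att_sd / p.cbf_sd if p.cbf_sd > 0 else 0.0
    resid_sd = p.att_sd * np.sqrt(max(1.0 - p.att_cbf_r**2, 0.0))
    att = np.clip(
        p.att_mean - slope * (cbf - p.cbf_mean) + rng.normal(0.0, resid_sd, n),
        0.3,
        2.4,
    )

    do2 = np.array(
        [
            compute_do2(c, BloodProperties(hct=h, hb=b, ya=a))
            for c, h, b, a in zip(cbf, hct, hb, ya)
        ]
    )

    efficiency = 1.0 - p.beta_shunt_oef * severity
    oef_raw = cmro2 / do2 * efficiency
    clipped = (oef_raw < 0.05) | (oef_raw > 0.95)
    if clipped.mean() > 0.10:
        warnings.warn(
            f"OEF clipping affected {clipped.mean():.0%} of subjects; "
            "generator parameters force unphysical extraction fractions",
            stacklevel=2,
        )
    oef = np.clip(oef_raw, 0.05, 0.95) + rng.normal(0.0, p.oef_noise_sd, n)

    vhs = (
        p.beta_cbf_vhs * cbf
        + p.beta_shunt_vhs * severity
        + rng.normal(0.0, p.vhs_noise_sd, n)
    )
    # ordinal rating thresholds on the noisy rater's view of the signal
    rater_view = vhs + rng.normal(0.0, 8.0, n)
    vhs_rating = np.digitize(rater_view, [90.0, 125.0])

    brain_vol = np.clip(rng.normal(p.brain_vol_mean, p.brain_vol_sd, n), 700, None)
    brain_mass = brain_vol * 1.05  # g, density of brain tissue ~1.05 g/cm^3
    total_flow = cbf / 100.0 * brain_mass + rng.normal(0.0, p.flow_noise_sd, n)
    ica_flow = p.ica_flow_fraction * total_flow + rng.normal(0.0, p.flow_noise_sd, n)
    sss_flow = p.sss_flow_fraction * total_flow + rng.normal(
        0.0, p.flow_noise_sd * 0.7, n
    )
    ica_area = np.clip(rng.normal(0.35, 0.065, n), 0.15, None)
    sss_area = np.clip(rng.normal(0.25, 0.05, n), 0.10, None)
    ica_velocity = ica_flow / (60.0 * ica_area)
    sss_velocity = sss_flow / (60.0 * sss_area)

    cbf_single = np.clip(p.do2_single_scale * cbf + rng.normal(0.0, 5.0, n), 5.0, None)
    do2_single = np.array(
        [
            compute_do2(c, BloodProperties(hct=h, hb=b, ya=a))
            for c, h, b, a in zip(cbf_single, hct, hb, ya)
        ]
    )

    gm_signal = cbf + rng.normal(0.0, 8.0, n)
    csf_signal = 0.25 * gm_signal + rng.normal(0.0, 5.0, n)
    bone_signal = rng.normal(0.0, 4.0, n)
    mean_fd = rng.lognormal(np.log(0.18), 0.4, n)

    age = np.clip(rng.normal(68.1, 5.4, n), 60, 80)
    sex = rng.choice(["F", "M"], size=n, p=[0.583, 0.417])
    race = rng.choice(
        ["Asian", "Black", "White", "Other"], size=n, p=[0.111, 0.139, 0.722, 0.028]
    )
    apoe_e4 = rng.random(n) < 0.333
    wmlv_log = rng.normal(0.10, 1.63, n)
    gm_vol = np.clip(rng.normal(581, 56, n), 350, None)
    st_vol = np.clip(rng.normal(923, 98, n), 600, None)

    cohort = pd.DataFrame(
        {
            "id": [f"sub-{i:03d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "race": race,
            "apoe_e4": apoe_e4,
            "hb": hb,
            "hct": hct,
            "ya": ya,
            "wmlv_log": wmlv_log,
            "brain_vol": brain_vol,
            "gm_vol": gm_vol,
            "st_vol": st_vol,
            "vhs": vhs,
            "vhs_rating": vhs_rating,
            "oef": oef,
            "cbf": cbf,
            "att": att,
            "do2": do2,
            "do2_single": do2_single,
            "sss_area": sss_area,
            "sss_velocity": sss_velocity,
            "sss_flow": sss_flow,
            "ica_area": ica_area,
            "ica_velocity": ica_velocity,
            "ica_flow": ica_flow,
            "mean_fd": mean_fd,
            "gm_signal": gm_signal,
            "csf_signal": csf_signal,
            "bone_signal": bone_signal,
        }
    )
    truth = pd.DataFrame(
        {
            "id": cohort["id"],
            "shunt_severity": severity,
            "cmro2": cmro2,
            "oef_unclipped": oef_raw,
            "oef_clipped_flag": clipped,
        }
    )
    return cohort, truth
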