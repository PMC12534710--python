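"""Quantification of perfusion and venous signal from pCASL series.

Covers the two acquisitions of the study design this package models:

* a multi-delay pCASL series, from which arterial transit times (ATT) are
  estimated by a two-stage normalized cross-correlation search and cerebral
  blood flow (CBF) by per-voxel nonlinear least squares over all delays;
* a single-delay pCASL series, quantified voxelwise by inverting the kinetic
  model at an assumed transit time.  The resulting map carries *nominal*
  mL/100g/min values everywhere, including venous sinuses, CSF and bone,
  where the perfusion model is deliberately not valid — that nominal venous
  value is the venous hyperintense signal (VHS) readout.

Also provides the mid-sagittal slab extraction of venous and adjacent-region
signals, Power-style framewise displacement, and oxygen delivery (DO2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .kinetics import (
    AcquisitionTiming,
    BloodProperties,
    KineticConstants,
    kinetic_model_signal,
    t1_blood,
)

__all__ = [
    "ASLSeries",
    "PerfusionMaps",
    "VHSMeasures",
    "AttGrid",
    "subtract_average",
    "estimate_att_xcorr",
    "fit_multidelay",
    "quantify_single_pld",
    "extract_vhs",
    "extract_adjacent_signals",
    "framewise_displacement",
    "compute_do2",
    "mid_sagittal_slab",
]


@dataclass
class ASLSeries:
    """A label/control pCASL acquisition plus its M0 reference.

    ``labels`` and ``controls`` are 4D arrays (x, y, z, pair); ``pld_schedule``
    gives the post-labeling delay of each pair (defaults to cycling through
    ``timing.plds``).
    """

    labels: np.ndarray
    controls: np.ndarray
    m0: np.ndarray
    timing: AcquisitionTiming
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0)
    pld_schedule: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.labels.shape != self.controls.shape:
            raise ValueError("label and control frame stacks must match in shape")
        if self.labels.shape[:3] != self.m0.shape:
            raise ValueError("M0 grid must match the label/control grid")
        if self.pld_schedule is None:
            self.pld_schedule = self.timing.pld_schedule()[: self.n_pairs]
        self.pld_schedule = np.asarray(self.pld_schedule, dtype=float)
        if self.pld_schedule.shape != (self.n_pairs,):
            raise ValueError("pld_schedule must assign one delay per pair")

    @property
    def n_pairs(self) -> int:
        return self.labels.shape[3]


@dataclass
class PerfusionMaps:
    """Voxelwise CBF (mL/100g/min), ATT (s), residuals, and validity."""

    cbf: np.ndarray
    att: np.ndarray
    residual_norm: np.ndarray
    valid_mask: np.ndarray


@dataclass
class VHSMeasures:
    """Mid-sagittal slab signal summary of a nominal single-delay CBF map."""

    vhs: float
    gm_signal: float | None = None
    csf_signal: float | None = None
    bone_signal: float | None = None
    slab_width: int = 12
    mean_fd: float | None = None
    rating: int | None = None


@dataclass(frozen=True)
class AttGrid:
    """Two-stage ATT search grid (seconds)."""

    coarse_min: float = 0.2
    coarse_max: float = 2.5
    coarse_step: float = 0.1
    fine_halfwidth: float = 0.1
    fine_step: float = 0.01

    def coarse(self) -> np.ndarray:
        n = int(round((self.coarse_max - self.coarse_min) / self.coarse_step)) + 1
        return self.coarse_min + self.coarse_step * np.arange(n)

    def fine_offsets(self) -> np.ndarray:
        n = int(round(2 * self.fine_halfwidth / self.fine_step)) + 1
        return -self.fine_halfwidth + self.fine_step * np.arange(n)


def subtract_average(series: ASLSeries) -> dict[float, np.ndarray]:
    """Mean control-label difference volume per post-labeling delay."""
    out: dict[float, np.ndarray] = {}
    for pld in series.timing.plds:
        sel = np.isclose(series.pld_schedule, pld)
        if not np.any(sel):
            raise ValueError(f"no label/control pairs assigned to PLD {pld} s")
        diff = series.controls[..., sel] - series.labels[..., sel]
        out[pld] = diff.mean(axis=3)
    return out


def _delta_stack(delta: dict[float, np.ndarray] | np.ndarray, plds) -> np.ndarray:
    if isinstance(delta, dict):
        return np.stack([np.asarray(delta[p], dtype=float) for p in plds], axis=0)
    arr = np.asarray(delta, dtype=float)
    if arr.shape[0] != len(plds):
        raise ValueError("first axis of the delta stack must index the PLDs")
    return arr


def estimate_att_xcorr(
    delta,
    timing: AcquisitionTiming,
    blood: BloodProperties,
    consts: KineticConstants,
    grid: AttGrid | None = None,
    shape_cbf: float = 60.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Voxelwise ATT by two-stage normalized cross-correlation.

    Stage 1 correlates each voxel's measured per-delay curve against model
    curves on a coarse ATT grid; stage 2 repeats on a fine grid around the
    stage-1 argmax.  Normalization makes the match invariant to positive
    scaling of the voxel curve, so a nominal shape CBF suffices for the
    templates.  Ties resolve toward the smaller ATT (first argmax).

    Returns ``(att_map, valid_mask)``.  Voxels whose curve has non-positive
    mean signal (all-zero or noise-dominated) are flagged invalid and not
    searched.
    """
    if timing.n_plds < 3:
        raise ValueError("ATT cross-correlation requires at least 3 delays")
    grid = grid or AttGrid()
    stack = _delta_stack(delta, timing.plds)  # (n_pld, ...)
    n_pld = stack.shape[0]
    spatial = stack.shape[1:]
    data = stack.reshape(n_pld, -1)

    norms = np.linalg.norm(data, axis=0)
    valid = (data.mean(axis=0) > 0) & (norms > 0)
    att_map = np.full(data.shape[1], np.nan)

    t = np.asarray(timing.plds) + timing.labeling_duration

    def templates(atts: np.ndarray) -> np.ndarray:
        # (n_att, n_pld), row-normalized
        m = kinetic_model_signal(
            shape_cbf, atts[:, None], t[None, :], timing, blood, consts
        )
        m = np.atleast_2d(m)
        mn = np.linalg.norm(m, axis=1, keepdims=True)
        mn[mn == 0] = 1.0
        return m / mn

    if np.any(valid):
        d = data[:, valid] / norms[valid]
        coarse = grid.coarse()
        corr = templates(coarse) @ d  # (n_att, n_valid)
        best = np.argmax(corr, axis=0)  # first max -> smaller ATT on ties
        att_coarse = coarse[best]

        offsets = grid.fine_offsets()
        fine_att = np.empty(att_coarse.shape)
        for ci in np.unique(best):
            sel = best == ci
            atts = np.maximum(coarse[ci] + offsets, 1e-3)
            corr_f = templates(atts) @ d[:, sel]
            fine_att[sel] = atts[np.argmax(corr_f, axis=0)]
        att_map[valid] = fine_att

    return att_map.reshape(spatial), valid.reshape(spatial)


def fit_multidelay(
    delta,
    m0: np.ndarray,
    att_map: np.ndarray,
    timing: AcquisitionTiming,
    blood: BloodProperties,
    consts: KineticConstants,
    valid_mask: np.ndarray | None = None,
    refine_att: bool = True,
    att_refine_halfwidth: float = 0.01,
) -> PerfusionMaps:
    """Per-voxel nonlinear least-squares CBF fit over all delays.

    The transit time is taken from ``att_map`` (cross-correlation output or
    ground truth) and optionally refined continuously within one fine-grid
    step.  Absolute units come from dividing the measured signal by the
    voxel's M0.  Non-convergent voxels are flagged with infinite residual.
    """
    stack = _delta_stack(delta, timing.plds)
    spatial = stack.shape[1:]
    data = stack.reshape(stack.shape[0], -1)
    m0f = np.asarray(m0, dtype=float).reshape(-1) * consts.m0_scale
    attf = np.asarray(att_map, dtype=float).reshape(-1)

    m0_floor = 0.1 * np.median(m0f[m0f > 0]) if np.any(m0f > 0) else 0.0
    fit_ok = np.isfinite(attf) & (m0f > m0_floor)
    if valid_mask is not None:
        fit_ok &= np.asarray(valid_mask, dtype=bool).reshape(-1)

    t = np.asarray(timing.plds) + timing.labeling_duration
    cbf = np.zeros(data.shape[1])
    att_out = attf.copy()
    resid = np.full(data.shape[1], np.inf)

    for idx in np.flatnonzero(fit_ok):
        y = data[:, idx] / m0f[idx]
        att0 = attf[idx]

        if refine_att:
            def model(p):
                return kinetic_model_signal(p[0], p[1], t, timing, blood, consts)

            x0 = np.array([_cbf_init(y, att0, t, timing, blood, consts), att0])
            lo = [-1e4, max(att0 - att_refine_halfwidth, 1e-3)]
            hi = [1e4, att0 + att_refine_halfwidth]
        else:
            def model(p):
                return kinetic_model_signal(p[0], att0, t, timing, blood, consts)

            x0 = np.array([_cbf_init(y, att0, t, timing, blood, consts)])
            lo, hi = [-1e4], [1e4]

        try:
            sol = optimize.least_squares(
                lambda p: model(p) - y, x0, bounds=(lo, hi), xtol=1e-12, ftol=1e-12
            )
        except Exception:  # pragma: no cover - defensive
            continue
        if not sol.success:
            continue
        cbf[idx] = sol.x[0]
        if refine_att:
            att_out[idx] = sol.x[1]
        resid[idx] = float(np.linalg.norm(sol.fun))

    return PerfusionMaps(
        cbf=cbf.reshape(spatial),
        att=att_out.reshape(spatial),
        residual_norm=resid.reshape(spatial),
        valid_mask=fit_ok.reshape(spatial),
    )


def _cbf_init(y, att, t, timing, blood, consts) -> float:
    """Linear-scaling initial CBF guess from the unit-CBF model curve."""
    ref = kinetic_model_signal(1.0, att, t, timing, blood, consts)
    denom = float(np.dot(ref, ref))
    if denom == 0:
        return 0.0
    return float(np.dot(ref, y) / denom)


def quantify_single_pld(
    delta: np.ndarray,
    m0: np.ndarray,
    timing: AcquisitionTiming,
    blood: BloodProperties,
    consts: KineticConstants,
    assumed_att: float | None = None,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Voxelwise nominal CBF from a single-delay difference volume.

    Inverts the kinetic model at the acquisition's single (LD, PLD) for a
    fixed assumed transit time by damped fixed-point iteration on the
    perfusion-dependent scale factor (the dependence of T1app on CBF is
    weak, so convergence is fast).  The returned map keeps nominal values in
    venous, CSF, and bone voxels — including negative values — because the
    venous readout of interest *is* this nominal signal.

    Returns ``(cbf_map, valid_mask)``; voxels with M0 at or below 10% of the
    robust (positive-median) M0 are excluded.
    """
    if timing.n_plds != 1:
        raise ValueError("single-delay quantification requires exactly one PLD")
    att = assumed_att if assumed_att is not None else consts.assumed_att
    if att <= 0:
        raise ValueError("assumed transit time must be positive")
    t = timing.plds[0] + timing.labeling_duration

    delta = np.asarray(delta, dtype=float)
    m0 = np.asarray(m0, dtype=float) * consts.m0_scale
    pos = m0 > 0
    m0_floor = 0.1 * np.median(m0[pos]) if np.any(pos) else 0.0
    valid = m0 > m0_floor

    ratio = np.zeros_like(delta)
    ratio[valid] = delta[valid] / m0[valid]

    def scale(cbf):
        # kinetic_model_signal(cbf)/cbf, finite and positive near cbf = 0
        eps = 1e-9
        c = np.where(np.abs(cbf) < eps, eps, cbf)
        return kinetic_model_signal(c, att, t, timing, blood, consts) / c

    cbf = ratio / scale(np.zeros_like(ratio))
    for _ in range(max_iter):
        new = ratio / scale(cbf)
        if np.max(np.abs(new - cbf)) < tol:
            cbf = new
            break
        cbf = new
    cbf = np.where(valid, cbf, np.nan)
    return cbf, valid


def mid_sagittal_slab(shape, slab_width: int = 12, axis: int = 0) -> np.ndarray:
    """Boolean mask of a mid-sagittal slab of ``slab_width`` voxels.

    The slab is centered on the midline index floor(n/2); for even widths it
    spans [mid - w//2, mid + w - w//2).
    """
    if slab_width <= 0:
        raise ValueError("slab width must be positive")
    n = shape[axis]
    mid = n // 2
    start = max(mid - slab_width // 2, 0)
    stop = min(start + slab_width, n)
    mask = np.zeros(shape, dtype=bool)
    sl = [slice(None)] * len(shape)
    sl[axis] = slice(start, stop)
    mask[tuple(sl)] = True
    return mask


def extract_vhs(
    cbf_map: np.ndarray,
    sinus_mask: np.ndarray,
    slab_width: int = 12,
    axis: int = 0,
) -> float:
    """Mean nominal CBF in the venous sinus within the mid-sagittal slab."""
    slab = mid_sagittal_slab(cbf_map.shape, slab_width, axis)
    sel = slab & np.asarray(sinus_mask, dtype=bool)
    if not np.any(sel):
        raise ValueError("venous sinus mask does not intersect the mid-sagittal slab")
    return float(np.nanmean(cbf_map[sel]))


def extract_adjacent_signals(
    cbf_map: np.ndarray,
    masks: dict[str, np.ndarray],
    sinus_mask: np.ndarray | None = None,
    slab_width: int = 12,
    axis: int = 0,
) -> dict[str, float]:
    """Mean nominal CBF of adjacent regions (GM, CSF, bone) in the same slab.

    Region masks must be disjoint from the sinus mask (and are checked when
    it is supplied) — a venous voxel cannot double as tissue control.
    """
    out: dict[str, float] = {}
    for name, mask in masks.items():
        mask = np.asarray(mask, dtype=bool)
        if sinus_mask is not None and np.any(mask & np.asarray(sinus_mask, dtype=bool)):
            raise ValueError(f"region mask '{name}' overlaps the venous sinus mask")
        out[name] = extract_vhs(cbf_map, mask, slab_width, axis)
    return out


def framewise_displacement(
    motion_params: np.ndarray, radius: float = 50.0
) -> tuple[np.ndarray, float]:
    """Framewise displacement of a rigid motion trace.

    ``motion_params`` is (n_frames, 6): three translations in mm followed by
    three rotations in radians.  FD_i sums the absolute frame-to-frame
    translation differentials plus the rotation differentials converted to
    arc length on a sphere of ``radius`` mm (Power-style).  Returns the
    per-transition FD series (length n_frames - 1) and its mean.
    """
    p = np.asarray(motion_params, dtype=float)
    if p.ndim != 2 or p.shape[1] != 6:
        raise ValueError("motion parameters must be (n_frames, 6)")
    if p.shape[0] < 2:
        raise ValueError("framewise displacement needs at least 2 frames")
    d = np.abs(np.diff(p, axis=0))
    fd = d[:, :3].sum(axis=1) + radius * d[:, 3:].sum(axis=1)
    return fd, float(fd.mean())


def compute_do2(cbf_gm: float, blood: BloodProperties, phi: float = 1.34) -> float:
    """Oxygen delivery DO2 = phi * Ya * [Hb] * CBF, in mL O2/100g/min.

    ``phi`` is the oxygen-carrying capacity of hemoglobin (mL O2 per gram).
    Dividing by 100 reconciles [Hb] in g/dL (per 100 mL blood) with CBF in
    mL blood per 100 g tissue per minute.
    """
    return phi * blood.ya * blood.hb * cbf_gm / 100.0
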