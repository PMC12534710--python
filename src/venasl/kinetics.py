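"""Shared pCASL kinetic signal model and blood relaxation constants.

The difference-signal model is the standard single-exchange solution of the
continuous-labeling kinetic equations: magnetically labeled arterial water
decays with the longitudinal relaxation time of blood (T1b) during transit,
arrives at the voxel after the arterial transit time (ATT) as a boxcar bolus
of the labeling duration (LD), and thereafter relaxes with the apparent
tissue relaxation time T1app, which accounts for venous clearance of the
label at the perfusion rate.

All perfusion values are in mL/100g/min, times in seconds, and the returned
difference signal is expressed per unit equilibrium tissue magnetization
(M0).  Keeping this forward model in one place guarantees that simulators
and quantifiers share a single implementation, so round-trip recovery is
limited only by solver tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AcquisitionTiming",
    "BloodProperties",
    "KineticConstants",
    "t1_blood",
    "kinetic_model_signal",
]


@dataclass(frozen=True)
class AcquisitionTiming:
    """pCASL timing: labeling duration, post-labeling delays, TR, pair count.

    ``plds`` holds the distinct post-labeling delays in seconds, strictly
    increasing.  For a single-delay acquisition it has one element.
    """

    labeling_duration: float = 1.5
    plds: tuple[float, ...] = (0.2, 0.7, 1.2, 1.7, 2.2)
    tr: float = 4.0
    n_pairs: int = 43

    def __post_init__(self) -> None:
        plds = np.asarray(self.plds, dtype=float)
        if plds.ndim != 1 or plds.size < 1:
            raise ValueError("at least one post-labeling delay is required")
        if np.any(plds <= 0) or np.any(np.diff(plds) <= 0):
            raise ValueError("plds must be strictly increasing and positive")
        if self.labeling_duration <= 0:
            raise ValueError("labeling_duration must be positive")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        object.__setattr__(self, "plds", tuple(float(p) for p in plds))

    @property
    def n_plds(self) -> int:
        return len(self.plds)

    def pld_schedule(self) -> np.ndarray:
        """Per-pair PLD assignment: pairs cycle through the delay list."""
        idx = np.arange(self.n_pairs) % self.n_plds
        return np.asarray(self.plds, dtype=float)[idx]


@dataclass(frozen=True)
class BloodProperties:
    """Subject blood labs: hematocrit, hemoglobin (g/dL), arterial saturation."""

    hct: float = 0.42
    hb: float = 13.9
    ya: float = 0.98

    def __post_init__(self) -> None:
        if not 0.2 <= self.hct <= 0.6:
            raise ValueError(f"hematocrit {self.hct} outside plausible range [0.2, 0.6]")
        if not 5.0 <= self.hb <= 20.0:
            raise ValueError(f"hemoglobin {self.hb} g/dL outside plausible range [5, 20]")
        if not 0.8 <= self.ya <= 1.0:
            raise ValueError(f"arterial saturation {self.ya} outside [0.8, 1.0]")


@dataclass(frozen=True)
class KineticConstants:
    """Quantification constants.

    alpha
        pCASL labeling efficiency (fraction).
    lambda_bp
        Blood-brain partition coefficient of water, mL/g.
    t1_tissue
        Longitudinal relaxation time of brain tissue, s.
    t1b_slope, t1b_intercept
        Linear hematocrit model of the blood relaxation *rate*:
        1/T1b = t1b_slope * hct + t1b_intercept  (1/s).
    assumed_att
        Transit time assumed for single-delay quantification, s.
    m0_scale
        Optional unitless scaling of the M0 image.
    """

    alpha: float = 0.85
    lambda_bp: float = 0.9
    t1_tissue: float = 1.3
    t1b_slope: float = 0.52
    t1b_intercept: float = 0.38
    assumed_att: float = 1.5
    m0_scale: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("labeling efficiency must be in (0, 1]")
        if not 0.5 < self.lambda_bp < 1.2:
            raise ValueError("partition coefficient outside plausible (0.5, 1.2) mL/g")
        if self.t1_tissue <= 0 or self.assumed_att <= 0:
            raise ValueError("relaxation and transit times must be positive")


def t1_blood(hct: float, consts: KineticConstants | None = None) -> float:
    """T1 of blood (s) from hematocrit via a linear rate model."""
    c = consts or KineticConstants()
    rate = c.t1b_slope * hct + c.t1b_intercept
    if rate <= 0:
        raise ValueError("non-positive blood relaxation rate")
    return 1.0 / rate


def kinetic_model_signal(
    cbf,
    att,
    t,
    timing: AcquisitionTiming,
    blood: BloodProperties,
    consts: KineticConstants,
):
    """ASL difference signal per unit M0 at readout time ``t``.

    ``t`` is measured from the start of labeling, i.e. t = LD + PLD for a
    readout at the given post-labeling delay.  ``cbf`` in mL/100g/min,
    ``att`` and ``t`` in seconds.  Broadcasts over array inputs.

    Piecewise solution with boxcar bolus over [att, att + LD]:

    * t < att: no label has arrived, signal 0.
    * att <= t < att + LD: 2*alpha/lambda * f * T1app * exp(-att/T1b)
      * (1 - exp(-(t - att)/T1app))
    * t >= att + LD: the end-of-bolus value decayed by
      exp(-(t - att - LD)/T1app)

    with f = cbf/6000 (1/s) and 1/T1app = 1/T1_tissue + f/lambda.
    Negative ``cbf`` is accepted (nominal, non-perfusion voxels) by odd
    extension of the perfusion-rate dependence.
    """
    cbf = np.asarray(cbf, dtype=float)
    att = np.asarray(att, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(att <= 0):
        raise ValueError("arterial transit time must be positive")

    ld = timing.labeling_duration
    t1b = t1_blood(blood.hct, consts)
    f = cbf / 6000.0  # mL/g/s
    # apparent tissue relaxation includes venous clearance of label
    r1app = 1.0 / consts.t1_tissue + f / consts.lambda_bp
    t1app = 1.0 / r1app

    amp = 2.0 * consts.alpha * f / consts.lambda_bp * t1app * np.exp(-att / t1b)
    dt = t - att
    during = amp * (1.0 - np.exp(-np.clip(dt, 0.0, ld) / t1app))
    after = np.where(dt > ld, np.exp(-(np.maximum(dt - ld, 0.0)) / t1app), 1.0)
    signal = np.where(dt <= 0, 0.0, during * after)
    if signal.ndim == 0:
        return float(signal)
    return signal
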