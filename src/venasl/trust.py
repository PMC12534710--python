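"""TRUST-style venous oxygenation: apparent T2 decay -> T2,blood -> Yv -> OEF.

The acquisition isolates pure venous blood signal in the superior sagittal
sinus by label-control subtraction and measures it at several effective echo
times (eTE) of a T2 preparation.  The signal decays mono-exponentially with
an apparent rate that combines transverse blood relaxation with the
longitudinal decay accrued during the preparation; subtracting the
hematocrit-dependent 1/T1,blood isolates 1/T2,blood.  A calibration model of
human blood — 1/T2b quadratic in (1 - Y) with hematocrit-dependent
coefficients — is then inverted for the venous oxygen saturation Yv, and the
oxygen extraction fraction follows as OEF = (Ya - Yv) / Ya.

Calibration coefficients vary between published blood preparations and
refocusing intervals; the package ships one documented default set and
accepts any coefficient table of the same quadratic form via configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .kinetics import KineticConstants, t1_blood

__all__ = [
    "TrustMeasurement",
    "CalibrationModel",
    "TrustFit",
    "fit_apparent_decay",
    "correct_for_t1",
    "t2_to_yv",
    "compute_oef",
    "fit_trust",
]


@dataclass
class TrustMeasurement:
    """Per-eTE mean venous blood difference signals.

    ``etes`` in milliseconds (must include distinct, non-negative values);
    ``signals`` are the pair-averaged label-control difference amplitudes.
    """

    etes: np.ndarray
    signals: np.ndarray
    n_pairs_per_ete: int = 3

    def __post_init__(self) -> None:
        self.etes = np.asarray(self.etes, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        if self.etes.shape != self.signals.shape or self.etes.size < 2:
            raise ValueError("need >= 2 matched (eTE, signal) points")
        if np.any(self.etes < 0) or len(np.unique(self.etes)) != self.etes.size:
            raise ValueError("eTEs must be distinct and non-negative")


@dataclass(frozen=True)
class CalibrationModel:
    """Quadratic blood calibration 1/T2b = A + B*(1-Y) + C*(1-Y)^2  (1/s).

    Each coefficient is a polynomial in hematocrit, stored lowest order
    first: A(h) = sum(a_poly[k] * h**k), likewise B and C.  The default set
    reproduces the shape of established human-blood calibrations at a 10 ms
    refocusing interval and is strictly increasing in (1 - Y) over the valid
    range, so the inversion for Y is unique.
    """

    a_poly: tuple[float, ...] = (-13.5, 80.2, -75.9)
    b_poly: tuple[float, ...] = (-0.5, 3.4)
    c_poly: tuple[float, ...] = (0.0, 0.0, 247.4)
    y_range: tuple[float, float] = (0.0, 1.0)
    hct_range: tuple[float, float] = (0.2, 0.6)

    def _eval(self, poly, hct: float) -> float:
        return float(np.polynomial.polynomial.polyval(hct, poly))

    def coefficients(self, hct: float) -> tuple[float, float, float]:
        lo, hi = self.hct_range
        if not lo <= hct <= hi:
            raise ValueError(f"hematocrit {hct} outside calibration range [{lo}, {hi}]")
        a = self._eval(self.a_poly, hct)
        b = self._eval(self.b_poly, hct)
        c = self._eval(self.c_poly, hct)
        if b < 0 or c < 0:
            raise ValueError("calibration not monotone decreasing in Y at this hct")
        return a, b, c

    def r2_blood(self, yv: float, hct: float) -> float:
        """Forward map: transverse relaxation rate 1/T2b (1/s) at (Yv, hct)."""
        a, b, c = self.coefficients(hct)
        x = 1.0 - yv
        return a + b * x + c * x * x


@dataclass
class TrustFit:
    """Fitted decay and derived oxygenation of one TRUST measurement."""

    s0: float
    r_apparent: float  # 1/s
    t2_blood: float  # s
    yv: float
    oef: float
    rmse: float
    oef_in_range: bool = True


def fit_apparent_decay(m: TrustMeasurement) -> tuple[float, float, float]:
    """Least-squares mono-exponential fit S = s0 * exp(-eTE * R).

    Returns ``(s0, r_apparent, rmse)`` with the rate in 1/s (eTEs are ms).
    A log-linear fit initializes the nonlinear solve when all signals are
    positive; otherwise a heuristic start from the largest signal is used.
    All signals non-positive is an error (no decaying signal to fit).
    """
    s = m.signals
    te_s = m.etes / 1000.0
    if np.all(s <= 0):
        raise ValueError("all signals non-positive; no exponential decay to fit")

    if np.all(s > 0):
        coef = np.polyfit(te_s, np.log(s), 1)
        r0, s0_0 = -float(coef[0]), float(np.exp(coef[1]))
    else:
        s0_0 = float(np.max(s))
        r0 = 10.0

    def resid(p):
        return p[0] * np.exp(-te_s * p[1]) - s

    sol = optimize.least_squares(resid, x0=[s0_0, r0], xtol=1e-15, ftol=1e-15)
    s0, r = float(sol.x[0]), float(sol.x[1])
    rmse = float(np.sqrt(np.mean(sol.fun**2)))
    return s0, r, rmse


def correct_for_t1(
    r_apparent: float, hct: float, consts: KineticConstants | None = None
) -> float:
    """Remove the T1,blood contribution from the apparent decay rate.

    1/T2b = R_apparent - 1/T1b(hct); an apparent rate at or below the blood
    longitudinal rate would imply an unphysical (infinite or negative) T2
    and raises.
    """
    r1b = 1.0 / t1_blood(hct, consts)
    r2 = r_apparent - r1b
    if r2 <= 0:
        raise ValueError(
            f"apparent rate {r_apparent:.4g}/s does not exceed 1/T1b = {r1b:.4g}/s; "
            "unphysical T2,blood"
        )
    return 1.0 / r2


def t2_to_yv(t2_blood: float, hct: float, calib: CalibrationModel | None = None) -> float:
    """Invert the blood calibration for venous saturation Yv.

    Solves C*(1-Y)^2 + B*(1-Y) + (A - 1/T2b) = 0 on the physiologic branch
    (the root with the smaller (1-Y), where the forward map is monotone) and
    requires Y within the calibration's validity range.
    """
    calib = calib or CalibrationModel()
    if t2_blood <= 0:
        raise ValueError("T2,blood must be positive")
    a, b, c = calib.coefficients(hct)
    rhs = 1.0 / t2_blood - a
    if c == 0:
        if b == 0:
            raise ValueError("degenerate calibration (B = C = 0)")
        x = rhs / b
    else:
        disc = b * b + 4.0 * c * rhs
        if disc < 0:
            raise ValueError(
                f"T2,blood = {t2_blood:.4g} s outside the calibration's reachable range"
            )
        x = (-b + np.sqrt(disc)) / (2.0 * c)
    yv = 1.0 - x
    lo, hi = calib.y_range
    if not lo - 1e-9 <= yv <= hi + 1e-9:
        raise ValueError(
            f"inverted saturation {yv:.4f} outside calibration validity [{lo}, {hi}]"
        )
    return float(min(max(yv, lo), hi))


def compute_oef(ya: float, yv: float) -> tuple[float, bool]:
    """Oxygen extraction fraction (Ya - Yv) / Ya.

    Returns ``(oef, in_range)``; values outside [0, 1] are returned unclipped
    with the flag cleared rather than silently truncated.
    """
    if ya <= 0:
        raise ValueError("arterial saturation must be positive")
    oef = (ya - yv) / ya
    return float(oef), bool(0.0 <= oef <= 1.0)


def fit_trust(
    m: TrustMeasurement,
    hct: float,
    ya: float,
    calib: CalibrationModel | None = None,
    consts: KineticConstants | None = None,
) -> TrustFit:
    """Full chain: decay fit, T1 correction, calibration inversion, OEF."""
    s0, r_app, rmse = fit_apparent_decay(m)
    t2b = correct_for_t1(r_app, hct, consts)
    yv = t2_to_yv(t2b, hct, calib)
    oef, ok = compute_oef(ya, yv)
    return TrustFit(
        s0=s0, r_apparent=r_app, t2_blood=t2b, yv=yv, oef=oef, rmse=rmse, oef_in_range=ok
    )
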