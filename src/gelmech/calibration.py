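"""Instrument calibration: optical-lever sensitivity and spring constant.

The photodetector voltage is converted to metres of deflection through the
inverse optical lever sensitivity, obtained from the constant-compliance
region of force curves taken on a rigid (glass) substrate where deflection
tracks piezo travel 1:1. The cantilever spring constant is estimated from
the thermal fluctuation of the free lever via equipartition,
k = k_B * T / <d^2>.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datatypes import BOLTZMANN, Calibration, RawForceCurve

__all__ = ["fit_lever_sensitivity", "spring_constant_thermal", "calibrate", "SensitivityFit"]


@dataclass
class SensitivityFit:
    sensitivity: float  # m/V
    per_curve: np.ndarray  # m/V, accepted curves only
    cv: float  # relative spread across curves
    n_rejected: int


def _contact_slope(curve: RawForceCurve, compliance_fraction: float, min_r2: float):
    """Slope (V/m) of the constant-compliance region of one hard curve.

    Returns None when no contact region is found, the slope is non-positive,
    or the region is visibly non-linear.
    """
    app = curve.approach
    z, v = curve.z[app], curve.v[app]
    if z.size < 16:
        return None
    nb = max(8, int(0.2 * z.size))
    base = v[:nb]
    thr = base.mean() + 3.0 * base.std()
    above = np.nonzero(v > thr)[0]
    above = above[above >= nb]
    if above.size < 8:
        return None
    contact = np.arange(above[0], z.size)
    n_win = max(8, int(round(compliance_fraction * contact.size)))
    win = contact[-n_win:]
    slope, intercept = np.polyfit(z[win], v[win], 1)
    if slope <= 0:
        return None
    pred = slope * z[win] + intercept
    ss_res = np.sum((v[win] - pred) ** 2)
    ss_tot = np.sum((v[win] - v[win].mean()) ** 2)
    if ss_tot > 0 and 1.0 - ss_res / ss_tot < min_r2:
        return None
    return slope


def fit_lever_sensitivity(
    hard_curves: list[RawForceCurve],
    compliance_fraction: float = 0.3,
    min_r2: float = 0.9,
) -> SensitivityFit:
    """Optical-lever sensitivity from curves acquired on a rigid substrate.

    Each curve contributes the least-squares slope (V/m) of the last
    ``compliance_fraction`` of its contact region; the returned sensitivity
    is the reciprocal of the mean slope. Curves with non-positive or clearly
    non-linear compliance are rejected; rejecting all curves is an error.
    """
    if not hard_curves:
        raise ValueError("at least one hard-substrate curve is required")
    slopes = []
    for c in hard_curves:
        s = _contact_slope(c, compliance_fraction, min_r2)
        if s is not None:
            slopes.append(s)
    if not slopes:
        raise ValueError("all hard-substrate curves were rejected")
    slopes = np.asarray(slopes)
    sens_each = 1.0 / slopes
    sens = 1.0 / slopes.mean()
    cv = float(sens_each.std() / sens_each.mean()) if len(slopes) > 1 else 0.0
    return SensitivityFit(
        sensitivity=float(sens),
        per_curve=sens_each,
        cv=cv,
        n_rejected=len(hard_curves) - len(slopes),
    )


def spring_constant_thermal(
    deflection: np.ndarray,
    temperature: float = 298.0,
    mode_correction: float = 1.0,
) -> float:
    """Spring constant from a thermal deflection series via equipartition.

    k = mode_correction * k_B * T / <d^2>, where <d^2> is the mean-square
    deflection of the linearly detrended series. ``mode_correction`` defaults
    to 1 (raw equipartition); the first-flexural-mode shape factor (~0.971)
    can be supplied by callers who want it.
    """
    d = np.asarray(deflection, dtype=float)
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if d.size < 1000:
        warnings.warn("thermal series shorter than 1000 samples; k estimate will be noisy")
    # remove mean and any slow linear drift
    t = np.arange(d.size, dtype=float)
    coef = np.polyfit(t, d, 1)
    resid = d - np.polyval(coef, t)
    msd = float(np.mean(resid**2))
    if msd <= 0:
        raise ValueError("zero mean-square deflection; cannot estimate spring constant")
    return mode_correction * BOLTZMANN * temperature / msd


def calibrate(
    hard_curves: list[RawForceCurve],
    thermal_deflection: np.ndarray,
    temperature: float = 298.0,
    mode_correction: float = 1.0,
) -> Calibration:
    """Full calibration: sensitivity from hard curves, k from thermal noise."""
    fit = fit_lever_sensitivity(hard_curves)
    k = spring_constant_thermal(thermal_deflection, temperature, mode_correction)
    return Calibration(
        sensitivity=fit.sensitivity,
        spring_constant=k,
        temperature=temperature,
        n_hard_curves=len(fit.per_curve),
        sensitivity_cv=fit.cv,
    )
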