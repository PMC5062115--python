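"""Raw-curve processing: voltage -> load, contact detection, QC.

The chain mirrors standard force-spectroscopy practice:

1. ``convert_to_load``: deflection d = v * sensitivity, baseline-corrected by
   a robust linear fit to the pre-contact portion of the approach; load
   P = k * d.
2. ``detect_contact_point``: threshold crossing of the approach load above
   the baseline noise (mean + c*sigma, persistent for w samples), refined by
   back-extrapolating a power-law contact fit to zero load. The refinement
   fits P = a * x**p with x = (z - z0) - P/k (piezo travel past contact minus
   cantilever deflection, i.e. the indentation implied by candidate z0) and
   minimises the residual over z0, first on the sample grid, then
   continuously. p defaults to 2, the conical-contact exponent.
3. ``to_load_indentation``: h = (z - z0) - d for samples past contact.
4. ``qc_filter``: drops curves whose contact point could not be detected,
   whose baseline is excessively noisy, or whose approach load is grossly
   non-monotone, and reports the discarded fraction.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
from scipy import optimize, stats

from .datatypes import (
    Calibration,
    ContactPoint,
    ForceDisplacementCurve,
    LoadIndentationCurve,
    RawForceCurve,
)

__all__ = [
    "convert_to_load",
    "detect_contact_point",
    "to_load_indentation",
    "preprocess_curve",
    "qc_filter",
]


def convert_to_load(
    raw: RawForceCurve,
    cal: Calibration,
    baseline_fraction: float = 0.2,
    baseline_method: str = "theil",
) -> ForceDisplacementCurve:
    """Convert photodetector voltage to baseline-corrected load.

    The baseline (offset and optional linear tilt) is estimated on the first
    ``baseline_fraction`` of the approach segment with a robust Theil-Sen fit
    (``baseline_method='ols'`` switches to ordinary least squares) and
    subtracted from both segments.
    """
    if cal is None:
        raise ValueError("calibration is required")
    d = raw.v * cal.sensitivity
    app = raw.approach
    z_app, d_app = raw.z[app], d[app]
    nb = max(8, int(baseline_fraction * z_app.size))
    zb, db = z_app[:nb], d_app[:nb]
    if baseline_method == "theil":
        slope, intercept, _, _ = stats.theilslopes(db, zb)
    elif baseline_method == "ols":
        slope, intercept = np.polyfit(zb, db, 1)
    else:
        raise ValueError(f"unknown baseline method {baseline_method!r}")
    d_corr = d - (slope * raw.z + intercept)
    load = cal.spring_constant * d_corr
    baseline_sd = float(np.std(db - (slope * zb + intercept)) * cal.spring_constant)
    meta = dict(raw.metadata)
    meta["baseline_slope_m_per_m"] = float(slope)
    meta["n_baseline"] = nb
    return ForceDisplacementCurve(
        z=raw.z.copy(),
        load=load,
        segment=raw.segment.copy(),
        baseline_sd=baseline_sd,
        metadata=meta,
    )


def _first_persistent_crossing(above: np.ndarray, w: int):
    """Index of the first run of >= w consecutive True values, or None."""
    if above.size < w:
        return None
    run = 0
    for i, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= w:
            return i - w + 1
    return None


def _contact_sse(z0, z, p, k, exponent):
    """Profile SSE of the piecewise model baseline + power-law contact.

    For a candidate contact point z0, fits P ~ b0 + b1*z + a*x**exponent with
    x = (z - z0) - P/k (the indentation implied by z0), linear in
    (b0, b1, a), and returns (SSE, a). Fitting the residual baseline offset
    and tilt jointly with the contact term uses the full pre-contact lever
    arm, which is what makes z0 identifiable at low signal-to-noise.
    """
    x = np.clip((z - z0) - p / k, 0.0, None)
    t = x**exponent
    if float(t @ t) <= 0:
        return float(p @ p), 0.0, (0.0, 0.0)
    m = np.column_stack([np.ones_like(z), z - z[0], t])
    scale = np.sqrt((m * m).sum(axis=0))  # unit-norm columns: the raw design
    m = m / scale  # spans ~14 orders of magnitude and would lose the contact column
    coef, *_ = np.linalg.lstsq(m, p, rcond=None)
    coef = coef / scale
    a = float(coef[2])
    if a < 0:
        return float(p @ p), 0.0, (0.0, 0.0)
    r = p - a * t - coef[0] - coef[1] * (z - z[0])
    return float(r @ r), a, (float(coef[0]), float(coef[1]))


def detect_contact_point(
    curve: ForceDisplacementCurve,
    c: float = 3.0,
    w: int = 5,
    exponent: float = 2.0,
    fit_fraction: float = 1.0,
) -> ContactPoint:
    """Locate the tip-surface contact on the approach segment.

    The crossing of load above baseline mean + ``c`` * sigma (persisting for
    ``w`` samples) establishes that contact exists and bounds its location;
    the contact fit baseline + a*x^exponent (x = travel past contact minus
    deflection) is then back-extrapolated to zero load by minimising its
    residual over z0 — a grid scan over the samples between the start of the
    curve and the crossing, refined continuously. ``fit_fraction`` limits the
    fit window to loads below that fraction of the maximum (1.0 uses the
    whole approach; reduce it if the material deviates from the assumed
    exponent at depth).
    """
    app = curve.approach
    z, p = curve.z[app], curve.load[app]
    nb = curve.metadata.get("n_baseline", max(8, int(0.2 * z.size)))
    sigma = curve.baseline_sd
    mu = float(np.mean(p[:nb]))
    thr = mu + c * sigma
    idx = _first_persistent_crossing(p > thr, w)
    if idx is None or idx <= nb:
        return ContactPoint(np.nan, 0.0, ok=False, reason="no_contact")
    p_max = float(p[-1])
    if p_max <= thr:
        return ContactPoint(np.nan, 0.0, ok=False, reason="no_contact")

    k = curve.metadata.get("spring_constant", None)
    if k is None:
        k = curve.metadata.get("spring_constant_true", np.inf)
    if fit_fraction < 1.0:
        past = np.nonzero(p[idx:] > fit_fraction * p_max)[0]
        j_hi = idx + int(past[0]) if past.size else z.size
        j_hi = min(max(j_hi, idx + w), z.size)
    else:
        j_hi = z.size
    zf, pf = z[:j_hi], p[:j_hi]

    # grid scan of candidate contact locations up to the threshold crossing,
    # then continuous refinement around the best grid point
    cand = z[max(nb // 2, 1) : idx + 1]
    if cand.size == 0:
        return ContactPoint(np.nan, 0.0, ok=False, reason="no_contact")
    sses = np.array([_contact_sse(z0, zf, pf, k, exponent)[0] for z0 in cand])
    best = int(np.argmin(sses))
    dz = float(np.median(np.diff(z)))
    lo, hi = cand[best] - 1.5 * dz, cand[best] + 1.5 * dz
    res = optimize.minimize_scalar(
        lambda z0: _contact_sse(z0, zf, pf, k, exponent)[0],
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": max(abs(hi - lo) * 1e-12, 1e-16)},
    )
    z0 = float(res.x)
    sse, a, (b0, b1) = _contact_sse(z0, zf, pf, k, exponent)
    ss_tot = float(np.sum((pf - pf.mean()) ** 2))
    conf = max(0.0, 1.0 - sse / ss_tot) if ss_tot > 0 else 0.0
    if a <= 0:
        return ContactPoint(np.nan, 0.0, ok=False, reason="degenerate_contact_fit")
    return ContactPoint(
        z0=z0, confidence=conf, ok=True, baseline_offset=b0, baseline_tilt=b1
    )


def to_load_indentation(
    curve: ForceDisplacementCurve,
    contact_z: float,
    cal: Calibration,
) -> LoadIndentationCurve:
    """Re-express a force-displacement curve as load vs indentation.

    Indentation h = (z - contact_z) - d, the piezo travel past contact minus
    the cantilever deflection d = P/k; samples before contact are dropped and
    small negative h from noise is clipped to zero. On a rigid substrate the
    deflection equals the travel and h is identically ~0; such degenerate
    curves are flagged rather than fitted.
    """
    if not np.isfinite(contact_z):
        raise ValueError("contact_z must be finite; run detect_contact_point first")
    keep = curve.z >= contact_z
    z, p, seg = curve.z[keep], curve.load[keep], curve.segment[keep]
    d = p / cal.spring_constant
    travel = z - contact_z
    h = np.clip(travel - d, 0.0, None)
    flag = "ok"
    in_contact = p > max(3.0 * curve.baseline_sd, 0.0)
    if in_contact.sum() >= 8:
        # stiff-substrate degenerate: deflection absorbs (almost) all travel
        ratio = np.median(h[in_contact] / np.maximum(travel[in_contact], 1e-18))
        if ratio < 0.02:
            flag = "discarded:rigid_contact"
    meta = dict(curve.metadata)
    meta["baseline_sd_N"] = curve.baseline_sd
    return LoadIndentationCurve(
        h=h, P=p, segment=seg, contact_z=float(contact_z), quality_flag=flag, metadata=meta
    )


def preprocess_curve(
    raw: RawForceCurve,
    cal: Calibration,
    c: float = 3.0,
    w: int = 5,
    exponent: float = 2.0,
    baseline_fraction: float = 0.2,
) -> LoadIndentationCurve:
    """Full per-curve chain: convert, detect contact, build P(h); never raises
    on bad curves — failures come back as discarded-flagged curves."""
    fd = convert_to_load(raw, cal, baseline_fraction=baseline_fraction)
    fd.metadata.setdefault("spring_constant", cal.spring_constant)
    cp = detect_contact_point(fd, c=c, w=w, exponent=exponent)
    if not cp.ok:
        return LoadIndentationCurve(
            h=np.array([]),
            P=np.array([]),
            segment=np.array([]),
            contact_z=np.nan,
            quality_flag=f"discarded:{cp.reason}",
            metadata=dict(fd.metadata),
        )
    # apply the residual baseline re-estimated jointly with the contact fit
    z_ref = fd.z[fd.approach][0]
    fd.load = fd.load - (cp.baseline_offset + cp.baseline_tilt * (fd.z - z_ref))
    out = to_load_indentation(fd, cp.z0, cal)
    out.metadata["contact_confidence"] = cp.confidence
    return out


def _approach_monotone_violation(curve: LoadIndentationCurve) -> float:
    """Largest drop of the smoothed in-contact approach load, vs its range.

    Only the portion where the smoothed load exceeds 20% of its maximum is
    examined: before contact the load is pure baseline noise, where apparent
    'drops' are meaningless.
    """
    app = curve.approach
    p = curve.P[app]
    if p.size < 16:
        return 0.0
    win = max(5, p.size // 20)
    kernel = np.ones(win) / win
    sm = np.convolve(p, kernel, mode="valid")
    sm = sm[sm > 0.2 * sm.max()]
    if sm.size < 4:
        return 0.0
    rng = sm.max() - sm.min()
    if rng <= 0:
        return 0.0
    running_max = np.maximum.accumulate(sm)
    return float((running_max - sm).max() / rng)


def qc_filter(
    curves: list[LoadIndentationCurve],
    max_baseline_sd_fraction: float = 0.3,
    max_monotone_violation: float = 0.2,
):
    """Partition curves into retained and discarded, with per-reason counts.

    A curve is discarded when (i) its contact point was not detected, (ii)
    its baseline noise exceeds ``max_baseline_sd_fraction`` of the maximum
    load, or (iii) its approach load is non-monotone beyond tolerance.
    Returns ``(retained, discard_fraction, reasons)``. Filtering the retained
    list again discards nothing (idempotence). All curves discarded is an
    error.
    """
    retained, reasons = [], Counter()
    for cu in curves:
        if not cu.ok:
            reasons[cu.quality_flag.split(":", 1)[-1]] += 1
            continue
        p_max = float(cu.P.max()) if len(cu.P) else 0.0
        sd = cu.metadata.get("baseline_sd_N", 0.0)
        if p_max <= 0 or sd > max_baseline_sd_fraction * p_max:
            cu.quality_flag = "discarded:noisy_baseline"
            reasons["noisy_baseline"] += 1
            continue
        if _approach_monotone_violation(cu) > max_monotone_violation:
            cu.quality_flag = "discarded:nonmonotone_approach"
            reasons["nonmonotone_approach"] += 1
            continue
        retained.append(cu)
    if curves and not retained:
        raise ValueError(f"all {len(curves)} curves discarded: {dict(reasons)}")
    frac = (len(curves) - len(retained)) / len(curves) if curves else 0.0
    return retained, frac, reasons
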