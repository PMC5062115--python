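"""Synthetic data generators with known ground truth.

Every downstream stage of the package (calibration, curve processing, the
Oliver-Pharr fit, morphometry) is exercised against data produced here, so
each generator records the exact truth it rasterised or simulated.

The forward contact model is Sneddon's solution for a rigid cone pressed
into an elastic half-space,

    P(h) = (2/pi) * tan(theta) * E / (1 - nu^2) * h^2,

mapped into instrument coordinates through the cantilever: the piezo travel
past contact splits into sample indentation h and cantilever deflection
d = P/k, and the photodetector reads v = d / sensitivity plus optional
linear baseline tilt and Gaussian noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .datatypes import (
    BOLTZMANN,
    AcquisitionSpec,
    Cantilever,
    ForceVolumeMap,
    GelSpec,
    RawForceCurve,
    TipSpec,
)

__all__ = [
    "sneddon_load",
    "simulate_force_curve",
    "simulate_force_volume",
    "simulate_thermal_noise",
    "simulate_hard_contact_curve",
    "ImageSpec",
    "ImageObject",
    "generate_cell_image",
]


def sneddon_load(h, young_modulus: float, poisson_ratio: float, tip: TipSpec):
    """Quasi-static load of a rigid cone at indentation depth h (closed form)."""
    if young_modulus <= 0:
        raise ValueError("young_modulus must be positive")
    h = np.asarray(h, dtype=float)
    c = (2.0 / np.pi) * tip.tan_theta * young_modulus / (1.0 - poisson_ratio**2)
    return c * np.clip(h, 0.0, None) ** 2


def _indentation_from_travel(delta_z, prefactor: float, k: float):
    """Solve h + P(h)/k = delta_z for the cone law P = prefactor * h**2.

    The positive root of (prefactor/k) h^2 + h - delta_z = 0; exact, so the
    noiseless simulated curve matches the closed-form law to round-off.
    """
    delta_z = np.clip(np.asarray(delta_z, dtype=float), 0.0, None)
    a = prefactor / k
    # numerically stable quadratic root: 2*dz / (1 + sqrt(1 + 4 a dz))
    return 2.0 * delta_z / (1.0 + np.sqrt(1.0 + 4.0 * a * delta_z))


def simulate_force_curve(
    gel: GelSpec,
    acq: AcquisitionSpec,
    tip: TipSpec = TipSpec(),
    cantilever: Cantilever = Cantilever(),
    rng: Optional[np.random.Generator] = None,
    position: tuple[float, float] = (0.0, 0.0),
) -> RawForceCurve:
    """Simulate one approach/retract force curve on a gel.

    Returns a :class:`RawForceCurve` in displacement/voltage space whose
    metadata records the ground-truth contact point, modulus and instrument
    constants. With ``plastic_residual_depth = 0`` and ``adhesion = 0`` the
    retract retraces the loading path exactly (before noise).
    """
    rng = np.random.default_rng(0) if rng is None else rng
    k = cantilever.spring_constant
    sens = cantilever.sensitivity
    n = acq.samples_per_curve
    h_max = acq.max_indentation
    prefactor = (2.0 / np.pi) * tip.tan_theta * gel.reduced_modulus

    p_max = prefactor * h_max**2
    travel_contact = h_max + p_max / k  # piezo travel needed past contact
    travel_pre = travel_contact * acq.pre_contact_fraction / (1.0 - acq.pre_contact_fraction)
    z0 = travel_pre
    z_total = travel_pre + travel_contact

    z_app = np.linspace(0.0, z_total, n)
    h_app = _indentation_from_travel(z_app - z0, prefactor, k)
    p_app = prefactor * h_app**2

    # Unloading branch: power law anchored at (h_max, P_max) with residual
    # depth h_f, i.e. P = P_max * ((h - h_f)/(h_max - h_f))^2.
    h_f = gel.plastic_residual_depth
    if h_f >= h_max:
        raise ValueError("plastic_residual_depth must be smaller than max_indentation")
    alpha_u = p_max / (h_max - h_f) ** 2
    z_ret = z_app[::-1].copy()
    dz_ret = np.clip(z_ret - z0, 0.0, None)
    g = _indentation_from_travel(np.clip(dz_ret - h_f, 0.0, None), alpha_u, k)
    p_ret = np.where(dz_ret > h_f, alpha_u * g**2, 0.0)
    if gel.adhesion > 0:
        p_ret = np.where(p_ret > 0, p_ret - gel.adhesion, p_ret)

    z = np.concatenate([z_app, z_ret])
    load = np.concatenate([p_app, p_ret])
    seg = np.array(["A"] * n + ["R"] * n)

    deflection = load / k
    v = deflection / sens + acq.baseline_tilt * z / sens
    if acq.deflection_noise_sd > 0:
        v = v + rng.normal(0.0, acq.deflection_noise_sd / sens, size=v.shape)

    meta = {
        "speed_m_per_s": acq.displacement_speed,
        "contact_z_true": z0,
        "young_modulus_true": gel.young_modulus,
        "poisson_ratio": gel.poisson_ratio,
        "spring_constant_true": k,
        "sensitivity_true": sens,
        "theta_deg": tip.half_angle_deg,
        "h_max_true": h_max,
        "position": position,
    }
    return RawForceCurve(z=z, v=v, segment=seg, metadata=meta)


def _noise_only_curve(acq: AcquisitionSpec, cantilever: Cantilever, rng) -> RawForceCurve:
    """A corrupted acquisition: detector noise with no tip-sample contact."""
    n = acq.samples_per_curve
    z_total = 2.5 * acq.max_indentation
    z_app = np.linspace(0.0, z_total, n)
    z = np.concatenate([z_app, z_app[::-1]])
    sd_v = max(acq.deflection_noise_sd, 0.5e-9) / cantilever.sensitivity
    v = rng.normal(0.0, sd_v, size=z.shape)
    seg = np.array(["A"] * n + ["R"] * n)
    meta = {"corrupted": True, "contact_z_true": np.nan}
    return RawForceCurve(z=z, v=v, segment=seg, metadata=meta)


def simulate_force_volume(
    gel_field: GelSpec | Callable[[float, float], GelSpec],
    acq: AcquisitionSpec,
    tip: TipSpec = TipSpec(),
    cantilever: Cantilever = Cantilever(),
    seed: int = 0,
    bad_curve_fraction: float = 0.0,
) -> ForceVolumeMap:
    """Simulate a force-volume map over a regular grid.

    ``gel_field`` is either a single :class:`GelSpec` (homogeneous gel) or a
    callable (x, y) -> GelSpec describing lateral heterogeneity.
    ``bad_curve_fraction`` replaces round(fraction * n) randomly chosen
    curves by contact-free noise, emulating acquisition artefacts; their
    locations are recorded in ``bad_mask``. Deterministic given ``seed``.
    """
    if not 0.0 <= bad_curve_fraction < 1.0:
        raise ValueError("bad_curve_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    nx, ny = acq.grid_nx, acq.grid_ny
    xs = np.linspace(0.0, acq.scan_area[0], nx)
    ys = np.linspace(0.0, acq.scan_area[1], ny)
    n_total = nx * ny
    n_bad = int(round(bad_curve_fraction * n_total))
    bad_idx = rng.choice(n_total, size=n_bad, replace=False) if n_bad else np.array([], int)
    bad_mask = np.zeros((ny, nx), dtype=bool)

    curves, positions, true_e = [], [], np.empty((ny, nx))
    i = 0
    for iy, y in enumerate(ys):
        for ix, x in enumerate(xs):
            gel = gel_field if isinstance(gel_field, GelSpec) else gel_field(x, y)
            true_e[iy, ix] = gel.young_modulus
            if i in bad_idx:
                curve = _noise_only_curve(acq, cantilever, rng)
                bad_mask[iy, ix] = True
            else:
                curve = simulate_force_curve(
                    gel, acq, tip, cantilever, rng=rng, position=(x, y)
                )
            curve.metadata["index"] = i
            curves.append(curve)
            positions.append((x, y))
            i += 1

    meta = {
        "seed": seed,
        "theta_deg": tip.half_angle_deg,
        "spring_constant_true": cantilever.spring_constant,
        "sensitivity_true": cantilever.sensitivity,
        "scan_area": acq.scan_area,
    }
    return ForceVolumeMap(
        curves=curves,
        positions=np.asarray(positions),
        grid_shape=(ny, nx),
        true_modulus=true_e,
        bad_mask=bad_mask,
        metadata=meta,
    )


def simulate_thermal_noise(
    spring_constant: float,
    temperature: float = 298.0,
    n: int = 100_000,
    seed: int = 0,
) -> np.ndarray:
    """Thermal deflection series of a cantilever in air (equipartition model).

    Draws i.i.d. Gaussian deflections with variance k_B * T / k, the
    mean-square amplitude of a simple harmonic oscillator at temperature T.
    """
    if spring_constant <= 0:
        raise ValueError("spring constant must be positive")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if n < 100:
        warnings.warn("fewer than 100 thermal-noise samples; variance estimate will be poor")
    rng = np.random.default_rng(seed)
    sd = np.sqrt(BOLTZMANN * temperature / spring_constant)
    return rng.normal(0.0, sd, size=n)


def simulate_hard_contact_curve(
    cantilever: Cantilever = Cantilever(),
    acq: AcquisitionSpec = AcquisitionSpec(),
    voltage_noise_sd: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> RawForceCurve:
    """Approach/retract curve on a rigid substrate (glass), for calibration.

    Past contact all piezo travel converts to deflection, so the voltage
    slope of the contact region is 1/sensitivity (the constant-compliance
    region used to calibrate the optical lever).
    """
    rng = np.random.default_rng(0) if rng is None else rng
    n = acq.samples_per_curve
    travel_contact = 100e-9  # deflection range exercised on glass
    z0 = travel_contact * acq.pre_contact_fraction / (1.0 - acq.pre_contact_fraction)
    z_app = np.linspace(0.0, z0 + travel_contact, n)
    d = np.clip(z_app - z0, 0.0, None)
    v_app = d / cantilever.sensitivity
    z = np.concatenate([z_app, z_app[::-1]])
    v = np.concatenate([v_app, v_app[::-1]])
    if voltage_noise_sd > 0:
        v = v + rng.normal(0.0, voltage_noise_sd, size=v.shape)
    seg = np.array(["A"] * n + ["R"] * n)
    meta = {
        "hard_substrate": True,
        "contact_z_true": z0,
        "sensitivity_true": cantilever.sensitivity,
        "spring_constant_true": cantilever.spring_constant,
    }
    return RawForceCurve(z=z, v=v, segment=seg, metadata=meta)


# ---------------------------------------------------------------------------
# Image generation (cells and spheroid-like clusters)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ImageObject:
    """One object to rasterise: an ellipse-shaped cell or a packed cluster.

    ``axes_um`` are the full major/minor axes of the ellipse footprint.
    For ``shape='cluster'`` the ellipse is filled with randomly packed cell
    disks until the foreground fraction reaches ``fill_density``.
    """

    shape: str  # 'ellipse' | 'cluster'
    center_um: tuple[float, float]
    axes_um: tuple[float, float]  # (major, minor), full lengths
    orientation_rad: float = 0.0
    fill_density: float = 1.0
    cell_radius_um: float = 6.0  # packing grain for clusters

    def __post_init__(self) -> None:
        if self.shape not in ("ellipse", "cluster"):
            raise ValueError(f"unknown object shape {self.shape!r}")
        if min(self.axes_um) <= 0:
            raise ValueError("axes must be positive")
        if not 0.0 <= self.fill_density <= 1.0:
            raise ValueError("fill_density must lie in [0, 1]")


@dataclass(frozen=True)
class ImageSpec:
    """Canvas, scale and content of a synthetic microscopy image.

    Cells render dark on a light background, as in thresholded histology
    images where cells are black and background white.
    """

    shape_px: tuple[int, int] = (512, 512)
    pixel_size_um: float = 1.0
    objects: tuple = ()
    noise_sd: float = 4.0  # 8-bit intensity units
    background: int = 230
    foreground: int = 25
    seed: int = 0


def _ellipse_mask(shape_px, center_px, semi_axes_px, orientation_rad):
    from skimage.draw import ellipse

    rr, cc = ellipse(
        center_px[0],
        center_px[1],
        semi_axes_px[0],
        semi_axes_px[1],
        shape=shape_px,
        rotation=orientation_rad,
    )
    mask = np.zeros(shape_px, dtype=bool)
    mask[rr, cc] = True
    return mask


def _ellipse_perimeter_um(a_um: float, b_um: float) -> float:
    # Ramanujan's second approximation; a, b are semi-axes.
    lam = (a_um - b_um) / (a_um + b_um)
    return np.pi * (a_um + b_um) * (1 + 3 * lam**2 / (10 + np.sqrt(4 - 3 * lam**2)))


def _pack_cluster(shape_px, region_mask, fill_density, cell_radius_px, rng):
    """Fill a region with random cell disks until the target fraction is hit."""
    from skimage.draw import disk

    target = fill_density * region_mask.sum()
    filled = np.zeros(shape_px, dtype=bool)
    rows, cols = np.nonzero(region_mask)
    if rows.size == 0 or target <= 0:
        return filled
    for _ in range(20000):
        if filled.sum() >= target:
            break
        j = rng.integers(rows.size)
        rr, cc = disk((rows[j], cols[j]), cell_radius_px, shape=shape_px)
        keep = region_mask[rr, cc]
        candidate = filled.copy()
        candidate[rr[keep], cc[keep]] = True
        if candidate.sum() <= target * 1.03:  # avoid large overshoot
            filled = candidate
    return filled


def generate_cell_image(spec: ImageSpec):
    """Rasterise the objects of ``spec`` into an 8-bit grayscale image.

    Returns ``(image, truth)`` where ``truth`` is a pandas DataFrame with one
    row per object: analytic area/perimeter/axes (µm), roundness, the
    realised foreground fill fraction, and an ``overlaps`` flag set when the
    object's footprint intersects a previously drawn one.
    """
    import pandas as pd

    rng = np.random.default_rng(spec.seed)
    px = spec.pixel_size_um
    canvas = np.zeros(spec.shape_px, dtype=bool)
    rows = []
    for obj_id, obj in enumerate(spec.objects):
        a_px = obj.axes_um[0] / 2.0 / px
        b_px = obj.axes_um[1] / 2.0 / px
        c_px = (obj.center_um[1] / px, obj.center_um[0] / px)  # (row, col)
        if max(c_px) < 0 or c_px[0] > spec.shape_px[0] or c_px[1] > spec.shape_px[1]:
            raise ValueError("object centre outside the canvas")
        # skimage.draw.ellipse rotates (row, col) axes; pass (minor, major)
        # as (r_radius, c_radius) so orientation measures the major axis
        # angle from the column (x) axis.
        region = _ellipse_mask(spec.shape_px, c_px, (b_px, a_px), obj.orientation_rad)
        if obj.shape == "ellipse":
            filled = region
            realised_fill = 1.0
        else:
            cell_r_px = max(obj.cell_radius_um / px, 1.5)
            filled = _pack_cluster(spec.shape_px, region, obj.fill_density, cell_r_px, rng)
            realised_fill = filled.sum() / max(region.sum(), 1)
        overlaps = bool((canvas & region).any())
        canvas |= filled
        major, minor = max(obj.axes_um), min(obj.axes_um)
        rows.append(
            {
                "object_id": obj_id,
                "shape": obj.shape,
                "area_um2": np.pi * (major / 2) * (minor / 2),
                "perimeter_um": _ellipse_perimeter_um(major / 2, minor / 2),
                "major_um": major,
                "minor_um": minor,
                "roundness": minor / major,
                "fill_density": realised_fill,
                "region_mask_area_px": int(region.sum()),
                "filled_area_px": int(filled.sum()),
                "overlaps": overlaps,
            }
        )

    img = np.full(spec.shape_px, float(spec.background))
    img[canvas] = float(spec.foreground)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    truth = pd.DataFrame(
        rows,
        columns=[
            "object_id", "shape", "area_um2", "perimeter_um", "major_um", "minor_um",
            "roundness", "fill_density", "region_mask_area_px", "filled_area_px", "overlaps",
        ],
    )
    truth.attrs["pixel_size_um"] = px
    return img, truth
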