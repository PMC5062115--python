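"""End-to-end orchestration: simulate -> calibrate -> preprocess -> fit -> stats,
and simulate-images -> morphometry -> clusters.

A single user seed fans out to per-stage sub-seeds through
``numpy.random.SeedSequence.spawn`` so stages are independently reproducible.
Reports are plain dicts (JSON-serialisable) carrying a schema version and a
hash of the generating configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np

from . import calibration as calib
from . import image_quant, map_statistics, processing, synthetic
from .datatypes import AcquisitionSpec, Calibration, Cantilever, GelSpec, TipSpec
from .oliver_pharr import fit_curve_set

__all__ = [
    "ConditionConfig",
    "MechanicsConfig",
    "ImagingConfig",
    "analyze_force_volume",
    "run_mechanics_pipeline",
    "run_imaging_pipeline",
]

log = logging.getLogger("gelmech")

SCHEMA_VERSION = 1


def _config_hash(cfg) -> str:
    payload = json.dumps(asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive n independent 31-bit sub-seeds from one user seed."""
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(n)]


@dataclass
class ConditionConfig:
    """One gel formulation in a simulated stiffness study."""

    label: str
    young_modulus_kpa: float
    alginate_pct: float | None = None
    cacl2_molarity: float | None = None


@dataclass
class MechanicsConfig:
    """All parameters of the mechanics pipeline, stated exactly once."""

    conditions: list = field(default_factory=list)  # list[ConditionConfig]
    n_maps: int = 3
    grid_nx: int = 16
    grid_ny: int = 16
    scan_area_um: float = 5.0
    max_indentation_nm: float = 100.0
    displacement_speed_um_s: float = 6.0
    samples_per_curve: int = 500
    deflection_noise_nm: float = 0.5
    bad_curve_fraction: float = 0.10
    theta_deg: float = 22.0
    nu: float = 0.5
    area_convention: str = "contact_depth"
    spring_constant: float = 0.1
    sensitivity_nm_per_v: float = 20.0
    temperature_K: float = 298.0
    thermal_samples: int = 200_000
    n_hard_curves: int = 5
    hard_curve_noise_v: float = 0.0
    contact_c: float = 3.0
    contact_w: int = 5
    fit_fraction: float = 0.8
    alpha: float = 0.05
    seed: int = 0


def analyze_force_volume(
    fv,
    cal: Calibration,
    tip: TipSpec = TipSpec(),
    nu: float = 0.5,
    area_convention: str = "contact_depth",
    contact_c: float = 3.0,
    contact_w: int = 5,
    fit_fraction: float = 0.8,
):
    """Preprocess + QC + Oliver-Pharr fit of every curve of one map.

    Returns ``(estimates_df, discard_fraction, reasons)`` where the DataFrame
    has one row per retained curve.
    """
    processed = [
        processing.preprocess_curve(cu, cal, c=contact_c, w=contact_w)
        for cu in fv.curves
    ]
    retained, frac, reasons = processing.qc_filter(processed)
    log.info("QC: retained %d/%d curves (%s)", len(retained), len(fv), dict(reasons))
    df = fit_curve_set(
        retained, tip=tip, nu=nu, area_convention=area_convention, fit_fraction=fit_fraction
    )
    return df, frac, reasons


def run_mechanics_pipeline(cfg: MechanicsConfig) -> dict:
    """Simulated multi-gel stiffness study, end to end.

    Per condition, ``n_maps`` force-volume maps are simulated and analysed
    with a calibration itself estimated from simulated thermal-noise and
    hard-substrate data; per-curve moduli are aggregated, conditions compared
    pairwise (Mann-Whitney) and merged into stiffness categories.
    Deterministic given ``cfg.seed``.
    """
    if not cfg.conditions:
        raise ValueError("config lists no gel conditions")
    tip = TipSpec(half_angle_deg=cfg.theta_deg)
    cant = Cantilever(
        spring_constant=cfg.spring_constant, sensitivity=cfg.sensitivity_nm_per_v * 1e-9
    )
    acq = AcquisitionSpec(
        grid_nx=cfg.grid_nx,
        grid_ny=cfg.grid_ny,
        scan_area=(cfg.scan_area_um * 1e-6, cfg.scan_area_um * 1e-6),
        max_indentation=cfg.max_indentation_nm * 1e-9,
        displacement_speed=cfg.displacement_speed_um_s * 1e-6,
        samples_per_curve=cfg.samples_per_curve,
        deflection_noise_sd=cfg.deflection_noise_nm * 1e-9,
    )
    seeds = _spawn_seeds(cfg.seed, 2 + len(cfg.conditions))

    # --- calibration stage (simulated thermal noise + hard-substrate curves)
    thermal = synthetic.simulate_thermal_noise(
        cant.spring_constant, cfg.temperature_K, n=cfg.thermal_samples, seed=seeds[0]
    )
    rng_hard = np.random.default_rng(seeds[1])
    hard = [
        synthetic.simulate_hard_contact_curve(
            cant, acq, voltage_noise_sd=cfg.hard_curve_noise_v, rng=rng_hard
        )
        for _ in range(cfg.n_hard_curves)
    ]
    cal = calib.calibrate(hard, thermal, temperature=cfg.temperature_K)
    log.info(
        "calibration: sens=%.4g nm/V (true %.4g), k=%.4g N/m (true %.4g)",
        cal.sensitivity * 1e9, cant.sensitivity * 1e9, cal.spring_constant, cant.spring_constant,
    )

    # --- per-condition acquisition and analysis
    conditions, condition_reports = [], []
    for cond_cfg, cond_seed in zip(cfg.conditions, seeds[2:]):
        gel = GelSpec(young_modulus=cond_cfg.young_modulus_kpa * 1e3, poisson_ratio=cfg.nu)
        map_seeds = _spawn_seeds(cond_seed, cfg.n_maps)
        estimates, discards = [], []
        for ms in map_seeds:
            fv = synthetic.simulate_force_volume(
                gel, acq, tip, cant, seed=ms, bad_curve_fraction=cfg.bad_curve_fraction
            )
            df, frac, _ = analyze_force_volume(
                fv, cal, tip=tip, nu=cfg.nu, area_convention=cfg.area_convention,
                contact_c=cfg.contact_c, contact_w=cfg.contact_w, fit_fraction=cfg.fit_fraction,
            )
            estimates.append(df["E_kPa"].dropna().to_numpy() * 1e3)
            discards.append(frac)
        e_all = np.concatenate(estimates)
        cond = map_statistics.GelCondition(
            label=cond_cfg.label,
            estimates=e_all,
            alginate_pct=cond_cfg.alginate_pct,
            cacl2_molarity=cond_cfg.cacl2_molarity,
            n_maps=cfg.n_maps,
        )
        conditions.append(cond)
        mean, sd, n = map_statistics.aggregate_condition(e_all)
        condition_reports.append(
            {
                "label": cond_cfg.label,
                "true_E_kPa": cond_cfg.young_modulus_kpa,
                "mean_E_kPa": mean / 1e3,
                "sd_E_kPa": sd / 1e3,
                "n_retained": n,
                "discard_fraction": float(np.mean(discards)),
            }
        )

    comparison = map_statistics.compare_conditions(conditions, alpha=cfg.alpha) \
        if len(conditions) >= 2 else None

    report = {
        "schema_version": SCHEMA_VERSION,
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "calibration": {
            "sensitivity_nm_per_V": cal.sensitivity * 1e9,
            "spring_constant_N_per_m": cal.spring_constant,
        },
        "conditions": condition_reports,
    }
    if comparison is not None:
        report["pairwise"] = comparison.pairwise.to_dict(orient="records")
        report["categories"] = [
            {"label": c.label, "range_kPa": [c.range_pa[0] / 1e3, c.range_pa[1] / 1e3],
             "members": c.members}
            for c in comparison.categories
        ]
    return report


@dataclass
class ImagingConfig:
    """Parameters of the imaging pipeline (morphometry + clusters)."""

    image_specs: list = field(default_factory=list)  # list[synthetic.ImageSpec]
    pixel_size_um: float = 1.0
    bins_preset: str = "default"
    min_area_px: int = 10
    dark_foreground: bool = True
    seed: int = 0


def run_imaging_pipeline(cfg: ImagingConfig) -> dict:
    """Generate images, segment, measure shapes, bin clusters, report.

    An image without detectable objects contributes empty tables, not an
    error. Every automatic threshold applied is logged and reported.
    """
    import pandas as pd

    all_shapes, cluster_rows, thresholds = [], [], []
    for img_i, spec in enumerate(cfg.image_specs):
        img, truth = synthetic.generate_cell_image(spec)
        try:
            mask, thr = image_quant.binarize(img, dark_foreground=cfg.dark_foreground)
        except ValueError:
            thresholds.append(None)
            continue
        thresholds.append(thr)
        log.info("image %d: Otsu threshold %.1f", img_i, thr)
        shapes = image_quant.measure_shapes(
            mask, pixel_size=spec.pixel_size_um, min_area_px=cfg.min_area_px
        )
        shapes.insert(0, "image_id", img_i)
        all_shapes.append(shapes)
        for _, obj in truth[truth["shape"] == "cluster"].iterrows():
            region = obj["region_mask_area_px"]
            true_dens = 100.0 * obj["filled_area_px"] / region if region else np.nan
            # measured density: thresholded foreground fraction inside the
            # cluster footprint, reconstructed from the generating spec
            o = spec.objects[int(obj["object_id"])]
            px = spec.pixel_size_um
            roi = synthetic._ellipse_mask(
                spec.shape_px,
                (o.center_um[1] / px, o.center_um[0] / px),
                (o.axes_um[1] / 2 / px, o.axes_um[0] / 2 / px),
                o.orientation_rad,
            )
            dens, thr_used = image_quant.cluster_density(
                img, roi=roi, dark_foreground=cfg.dark_foreground
            )
            cluster_rows.append(
                {
                    "image_id": img_i,
                    "object_id": int(obj["object_id"]),
                    "size_um": obj["major_um"],
                    "density_pct": dens,
                    "true_density_pct": true_dens,
                    "threshold": thr_used,
                }
            )

    shapes_df = (
        pd.concat(all_shapes, ignore_index=True)
        if all_shapes
        else pd.DataFrame(columns=["image_id", "object_id", "area_um2", "perimeter_um",
                                   "major_um", "minor_um", "circularity", "roundness"])
    )
    clusters_df = pd.DataFrame(cluster_rows)
    if not clusters_df.empty:
        bins = image_quant.bin_cluster_sizes(clusters_df["size_um"], preset=cfg.bins_preset)
    else:
        bins = pd.DataFrame(columns=["bin", "count", "percent"])

    return {
        "schema_version": SCHEMA_VERSION,
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "thresholds": thresholds,
        "shapes": shapes_df.to_dict(orient="records"),
        "cluster_bins": bins.to_dict(orient="records"),
        "clusters": clusters_df.to_dict(orient="records"),
    }
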