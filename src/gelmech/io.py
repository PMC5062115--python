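"""File formats: force-curve TSV dialect, HDF5 force-volume container, images.

TSV dialect (bit-exact round trip of the text):
    # k_N_per_m=0.1
    # sens_nm_per_V=20
    # theta_deg=22
    # speed_um_per_s=6
    z_nm<TAB>deflection_V<TAB>segment
with segment in {A, R}.

HDF5 container: datasets /curves/{i}/z_nm, /curves/{i}/deflection_V,
/curves/{i}/segment plus root attributes (k, sensitivity, theta, seed) and
optional /truth datasets for simulated maps.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .datatypes import Calibration, ForceVolumeMap, RawForceCurve

__all__ = [
    "write_curve_tsv",
    "read_curve_tsv",
    "write_force_volume_h5",
    "read_force_volume_h5",
    "write_calibration_json",
    "read_calibration_json",
    "write_image",
    "read_image",
]

_HEADER_KEYS = ("k_N_per_m", "sens_nm_per_V", "theta_deg", "speed_um_per_s")


def write_curve_tsv(curve: RawForceCurve, path) -> None:
    meta = curve.metadata
    header = {
        "k_N_per_m": meta.get("spring_constant_true", meta.get("k_N_per_m", "")),
        "sens_nm_per_V": _nm(meta.get("sensitivity_true", meta.get("sens_nm_per_V"))),
        "theta_deg": meta.get("theta_deg", ""),
        "speed_um_per_s": _um(meta.get("speed_m_per_s", meta.get("speed_um_per_s"))),
    }
    lines = [f"# {k}={header[k]}" for k in _HEADER_KEYS]
    lines.append("z_nm\tdeflection_V\tsegment")
    for z, v, s in zip(curve.z, curve.v, curve.segment):
        lines.append(f"{z * 1e9:.6f}\t{v:.9g}\t{s}")
    Path(path).write_text("\n".join(lines) + "\n")


def _nm(x):
    return "" if x is None else x * 1e9 if isinstance(x, float) else x


def _um(x):
    return "" if x is None else x * 1e6 if isinstance(x, float) else x


def read_curve_tsv(path) -> RawForceCurve:
    meta = {}
    z, v, seg = [], [], []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                try:
                    meta[key.strip()] = float(val)
                except ValueError:
                    meta[key.strip()] = val
                continue
            if line.startswith("z_nm"):
                continue
            z_s, v_s, s = line.split("\t")
            z.append(float(z_s) * 1e-9)
            v.append(float(v_s))
            seg.append(s)
    if "k_N_per_m" in meta:
        meta["spring_constant_true"] = meta["k_N_per_m"]
    if "sens_nm_per_V" in meta:
        meta["sensitivity_true"] = meta["sens_nm_per_V"] * 1e-9
    if "speed_um_per_s" in meta:
        meta["speed_m_per_s"] = meta["speed_um_per_s"] * 1e-6
    return RawForceCurve(
        z=np.array(z), v=np.array(v), segment=np.array(seg), metadata=meta
    )


def write_force_volume_h5(fv: ForceVolumeMap, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        g = f.create_group("curves")
        for i, cu in enumerate(fv.curves):
            gc = g.create_group(str(i))
            gc.create_dataset("z_nm", data=cu.z * 1e9)
            gc.create_dataset("deflection_V", data=cu.v)
            gc.create_dataset("segment", data=np.char.encode(cu.segment.astype("U1")))
            if np.isfinite(cu.metadata.get("contact_z_true", np.nan)):
                gc.attrs["contact_z_true_nm"] = cu.metadata["contact_z_true"] * 1e9
        f.attrs["grid_ny"], f.attrs["grid_nx"] = fv.grid_shape
        for key in ("seed", "theta_deg", "spring_constant_true", "sensitivity_true"):
            if key in fv.metadata:
                f.attrs[key] = fv.metadata[key]
        f.create_dataset("positions_m", data=fv.positions)
        if fv.true_modulus is not None:
            f.create_dataset("truth/E_Pa", data=fv.true_modulus)
        if fv.bad_mask is not None:
            f.create_dataset("truth/bad_mask", data=fv.bad_mask)


def read_force_volume_h5(path) -> ForceVolumeMap:
    import h5py

    with h5py.File(path, "r") as f:
        meta = {k: f.attrs[k] for k in f.attrs if k not in ("grid_ny", "grid_nx")}
        shape = (int(f.attrs["grid_ny"]), int(f.attrs["grid_nx"]))
        curves = []
        n = len(f["curves"])
        for i in range(n):
            gc = f["curves"][str(i)]
            cmeta = {
                "index": i,
                "theta_deg": meta.get("theta_deg"),
                "spring_constant_true": meta.get("spring_constant_true"),
                "sensitivity_true": meta.get("sensitivity_true"),
            }
            if "contact_z_true_nm" in gc.attrs:
                cmeta["contact_z_true"] = float(gc.attrs["contact_z_true_nm"]) * 1e-9
            curves.append(
                RawForceCurve(
                    z=gc["z_nm"][()] * 1e-9,
                    v=gc["deflection_V"][()],
                    segment=np.char.decode(gc["segment"][()]),
                    metadata=cmeta,
                )
            )
        positions = f["positions_m"][()]
        true_e = f["truth/E_Pa"][()] if "truth" in f and "E_Pa" in f["truth"] else None
        bad = f["truth/bad_mask"][()].astype(bool) if "truth" in f and "bad_mask" in f["truth"] else None
    return ForceVolumeMap(
        curves=curves, positions=positions, grid_shape=shape,
        true_modulus=true_e, bad_mask=bad, metadata=meta,
    )


def write_calibration_json(cal: Calibration, path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "sensitivity_m_per_V": cal.sensitivity,
                "spring_constant_N_per_m": cal.spring_constant,
                "temperature_K": cal.temperature,
                "n_hard_curves": cal.n_hard_curves,
                "sensitivity_cv": cal.sensitivity_cv,
            },
            indent=2,
        )
    )


def read_calibration_json(path) -> Calibration:
    d = json.loads(Path(path).read_text())
    return Calibration(
        sensitivity=d["sensitivity_m_per_V"],
        spring_constant=d["spring_constant_N_per_m"],
        temperature=d.get("temperature_K", 298.0),
        n_hard_curves=d.get("n_hard_curves", 0),
        sensitivity_cv=d.get("sensitivity_cv", 0.0),
    )


def write_image(image: np.ndarray, path) -> None:
    """8-bit grayscale image to TIFF or PNG, chosen by extension."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, image)
    else:
        from PIL import Image

        Image.fromarray(image).save(path)


def read_image(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        return tifffile.imread(path)
    from PIL import Image

    return np.asarray(Image.open(path))
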