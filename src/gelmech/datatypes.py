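"""Core data containers shared across the force-spectroscopy pipeline.

All mechanical quantities are stored in SI units (m, N, Pa, V). File formats
use the instrument-friendly units declared in their headers (nm, V, kPa).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

BOLTZMANN = 1.380649e-23  # J/K


@dataclass(frozen=True)
class TipSpec:
    """Geometry of the indenting AFM probe.

    Only conical tips are supported: the contact model used throughout
    (Sneddon loading law, Oliver-Pharr unloading analysis) is specific to a
    rigid cone of half-angle ``half_angle_deg``.
    """

    half_angle_deg: float = 22.0
    geometry: str = "cone"

    def __post_init__(self) -> None:
        if self.geometry != "cone":
            raise ValueError(f"unsupported tip geometry: {self.geometry!r}")
        if not 0.0 < self.half_angle_deg < 90.0:
            raise ValueError("cone half-angle must lie in (0, 90) degrees")

    @property
    def tan_theta(self) -> float:
        return float(np.tan(np.deg2rad(self.half_angle_deg)))


@dataclass(frozen=True)
class GelSpec:
    """Ground-truth material description of a simulated hydrogel.

    Parameters
    ----------
    young_modulus : float
        True Young's modulus in Pa.
    poisson_ratio : float
        Poisson's ratio; 0.5 models an incompressible rubber-like gel.
    plastic_residual_depth : float
        Residual indentation depth h_f (m) left after unloading; 0 means
        fully elastic (retract retraces the loading path).
    adhesion : float
        Constant pull force (N, >= 0) subtracted from the retract load while
        the tip is in contact; a minimal adhesion model.
    """

    young_modulus: float
    poisson_ratio: float = 0.5
    plastic_residual_depth: float = 0.0
    adhesion: float = 0.0

    def __post_init__(self) -> None:
        if self.young_modulus <= 0:
            raise ValueError("young_modulus must be positive")
        if not 0.0 <= self.poisson_ratio <= 0.5:
            raise ValueError("poisson_ratio must lie in [0, 0.5]")
        if self.plastic_residual_depth < 0:
            raise ValueError("plastic_residual_depth must be >= 0")
        if self.adhesion < 0:
            raise ValueError("adhesion must be >= 0")

    @property
    def reduced_modulus(self) -> float:
        """E/(1 - nu^2), the plane-strain modulus entering the contact law."""
        return self.young_modulus / (1.0 - self.poisson_ratio**2)


@dataclass(frozen=True)
class Cantilever:
    """Cantilever/detector constants of the simulated instrument.

    The defaults (k = 0.1 N/m, 20 nm/V) are package constants chosen as
    typical for soft sharp-tip probes; they are not measured values.
    """

    spring_constant: float = 0.1  # N/m
    sensitivity: float = 20e-9  # m of deflection per V

    def __post_init__(self) -> None:
        if self.spring_constant <= 0:
            raise ValueError("spring constant must be positive")
        if self.sensitivity <= 0:
            raise ValueError("sensitivity must be positive")


@dataclass(frozen=True)
class AcquisitionSpec:
    """Force-volume acquisition geometry and noise model.

    ``scan_area`` is (x, y) in metres; ``max_indentation`` the target sample
    deformation; ``deflection_noise_sd`` the additive Gaussian noise on the
    measured deflection (m); ``baseline_tilt`` a linear optical drift in m of
    apparent deflection per m of piezo travel. ``pre_contact_fraction`` sets
    how much of the approach ramp is spent off the surface.
    """

    grid_nx: int = 16
    grid_ny: int = 16
    scan_area: tuple[float, float] = (5e-6, 5e-6)
    max_indentation: float = 100e-9
    displacement_speed: float = 6e-6  # m/s
    samples_per_curve: int = 500  # per segment
    deflection_noise_sd: float = 0.5e-9  # m
    baseline_tilt: float = 0.0  # m deflection per m travel
    pre_contact_fraction: float = 0.45

    def __post_init__(self) -> None:
        if self.grid_nx < 1 or self.grid_ny < 1:
            raise ValueError("grid counts must be >= 1")
        if self.max_indentation <= 0:
            raise ValueError("max_indentation must be positive")
        if self.samples_per_curve < 16:
            raise ValueError("samples_per_curve must be >= 16")
        if not 0.2 <= self.pre_contact_fraction < 0.9:
            raise ValueError("pre_contact_fraction must lie in [0.2, 0.9)")


@dataclass
class RawForceCurve:
    """Instrument-level record: piezo displacement vs photodetector voltage.

    ``z`` increases towards the sample on approach. ``segment`` holds 'A'
    (approach) or 'R' (retract) per sample. ``metadata`` carries acquisition
    constants and, for simulated curves, the ground truth.
    """

    z: np.ndarray  # m
    v: np.ndarray  # V
    segment: np.ndarray  # '<U1', 'A' or 'R'
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.segment = np.asarray(self.segment)
        if not (self.z.shape == self.v.shape == self.segment.shape):
            raise ValueError("z, v and segment must have equal length")
        for seg in ("A", "R"):
            zs = self.z[self.segment == seg]
            if zs.size >= 2:
                d = np.diff(zs)
                if not (np.all(d > 0) or np.all(d < 0)):
                    raise ValueError(f"segment {seg!r} must be strictly monotone in z")

    @property
    def approach(self) -> np.ndarray:
        return self.segment == "A"

    @property
    def retract(self) -> np.ndarray:
        return self.segment == "R"


@dataclass
class ForceDisplacementCurve:
    """Calibrated curve: baseline-corrected load (N) vs piezo displacement."""

    z: np.ndarray  # m
    load: np.ndarray  # N
    segment: np.ndarray
    baseline_sd: float  # N, residual noise of the pre-contact baseline
    metadata: dict = field(default_factory=dict)

    @property
    def approach(self) -> np.ndarray:
        return self.segment == "A"

    @property
    def retract(self) -> np.ndarray:
        return self.segment == "R"


@dataclass
class ContactPoint:
    """Result of contact-point detection on a force-displacement curve."""

    z0: float  # m; nan when not found
    confidence: float  # 1 - SSE/variance of the local contact fit, in [0,1]
    ok: bool
    reason: str = ""
    baseline_offset: float = 0.0  # N, residual offset re-estimated in the fit
    baseline_tilt: float = 0.0  # N per m of z, relative to the first approach sample


@dataclass
class LoadIndentationCurve:
    """Load P (N) versus indentation h (m), the substrate of the model fit.

    ``quality_flag`` is 'ok' or 'discarded:<reason>'.
    """

    h: np.ndarray  # m, >= 0
    P: np.ndarray  # N
    segment: np.ndarray
    contact_z: float
    quality_flag: str = "ok"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.h) != len(self.P):
            raise ValueError("h and P must have equal length")
        if len(self.h) and np.nanmin(self.h) < -1e-15:
            raise ValueError("indentation must be non-negative")

    @property
    def ok(self) -> bool:
        return self.quality_flag == "ok"

    @property
    def approach(self) -> np.ndarray:
        return self.segment == "A"

    @property
    def retract(self) -> np.ndarray:
        return self.segment == "R"


@dataclass
class ForceVolumeMap:
    """A grid of force curves with per-pixel ground truth (when simulated)."""

    curves: list  # list[RawForceCurve], row-major over the grid
    positions: np.ndarray  # (n, 2) in m
    grid_shape: tuple[int, int]
    true_modulus: Optional[np.ndarray] = None  # Pa, grid-shaped
    bad_mask: Optional[np.ndarray] = None  # True where the curve is corrupted
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.curves)


@dataclass(frozen=True)
class Calibration:
    """Instrument calibration used to convert voltage to load."""

    sensitivity: float  # m/V
    spring_constant: float  # N/m
    temperature: float = 298.0  # K
    n_hard_curves: int = 0
    sensitivity_cv: float = 0.0  # relative spread across hard curves

    def __post_init__(self) -> None:
        if self.sensitivity <= 0:
            raise ValueError("sensitivity must be positive")
        if self.spring_constant <= 0:
            raise ValueError("spring constant must be positive")
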