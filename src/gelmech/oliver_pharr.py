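"""Oliver-Pharr analysis of conical nanoindentation unloading curves.

The unloading (retract) branch of a load-indentation curve is fitted with a
power law

    P = alpha * h**m            (m ~ 1.5-2 for a conical indenter),

giving the contact stiffness at maximum indentation

    S = dP/dh |_{h_max} = alpha * m * h_max**(m-1).

The Young's modulus of the sample follows from the rigid-indenter relation

    E = (1 - nu**2) * (sqrt(pi) / 2) * S / sqrt(A),

with A the projected contact area of the cone. Two area conventions are
offered: ``contact_depth`` evaluates A = pi * tan(theta)^2 * h_c^2 at the
contact depth h_c = h_max - eps * P_max / S with eps = 2*(pi-2)/pi (exact
for the Sneddon cone, and the package default); ``at_h_max`` evaluates
A = pi * tan(theta)^2 * h_max^2 at the maximum indentation itself, which for
an ideal cone understates E by a factor 2/pi because the contact radius at
depth h_max is smaller than the cone cross-section there.

`OliverPharrModel` / `OliverPharrResults` wrap this chain in the familiar
model/results idiom: the model is constructed from a
:class:`~gelmech.datatypes.LoadIndentationCurve`, ``fit()`` performs the
power-law regression and returns a results object carrying the estimates,
their standard errors and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize

from .datatypes import LoadIndentationCurve, TipSpec

__all__ = [
    "EPSILON_CONE",
    "PowerLawFit",
    "fit_unloading_power_law",
    "contact_stiffness",
    "projected_area",
    "youngs_modulus",
    "OliverPharrModel",
    "OliverPharrResults",
]

#: Oliver-Pharr geometric intercept factor for a conical indenter.
EPSILON_CONE = 2.0 * (np.pi - 2.0) / np.pi


@dataclass
class PowerLawFit:
    """P = alpha * (h - h_offset)**exponent fitted to the unloading branch."""

    alpha: float  # N / m**exponent
    exponent: float
    alpha_se: float
    exponent_se: float
    residual_rms: float  # N
    h_max: float  # m
    P_max: float  # N
    n_samples: int
    exponent_in_range: bool = True  # conical expectation m in [1, 3]


def fit_unloading_power_law(
    curve: LoadIndentationCurve,
    fit_fraction: float = 0.8,
    h_offset: float = 0.0,
    min_samples: int = 10,
) -> PowerLawFit:
    """Fit P = alpha * (h - h_offset)**m to the unloading segment.

    The fit uses the top ``fit_fraction`` of the retract force range (the
    portion dominated by elastic recovery), seeded by log-log linear
    regression and refined by nonlinear least squares. ``h_offset`` allows a
    known residual (plastic) depth to be subtracted; it defaults to 0 so the
    fit is performed on the raw indentation, matching the P = alpha*h^m
    parametrisation.
    """
    ret = curve.retract
    h = curve.h[ret] - h_offset
    p = curve.P[ret]
    if p.size == 0:
        raise ValueError("curve has no retract segment")
    p_max = float(p.max())
    if p_max <= 0:
        raise ValueError("non-positive loads dominate the retract segment")
    # window selection on a lightly smoothed load: selecting on the raw noisy
    # load correlates the cut with the noise and biases the exponent low
    win = max(3, min(31, p.size // 10)) | 1
    p_s = np.convolve(p, np.ones(win) / win, mode="same")
    sel = (p_s >= (1.0 - fit_fraction) * p_s.max()) & (h > 0) & (p > 0)
    h, p = h[sel], p[sel]
    if h.size < min_samples:
        raise ValueError(
            f"only {h.size} usable unloading samples (need >= {min_samples})"
        )
    # log-log seed
    b, loga = np.polyfit(np.log(h), np.log(p), 1)
    seed = (np.exp(loga), b)

    def model(hh, alpha, m):
        return alpha * hh**m

    popt, pcov = optimize.curve_fit(model, h, p, p0=seed, maxfev=10000)
    alpha, m = float(popt[0]), float(popt[1])
    if alpha <= 0:
        raise ValueError("fitted alpha is non-positive")
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    resid = p - model(h, *popt)
    h_max = float(h.max())
    return PowerLawFit(
        alpha=alpha,
        exponent=m,
        alpha_se=float(perr[0]),
        exponent_se=float(perr[1]),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        h_max=h_max,
        P_max=float(alpha * h_max**m),
        n_samples=int(h.size),
        exponent_in_range=bool(1.0 <= m <= 3.0),
    )


def contact_stiffness(fit: PowerLawFit) -> float:
    """Contact stiffness S = dP/dh at maximum indentation (N/m)."""
    if fit.h_max <= 0:
        raise ValueError("h_max must be positive")
    return fit.alpha * fit.exponent * fit.h_max ** (fit.exponent - 1.0)


def projected_area(
    h_max: float,
    P_max: float,
    S: float,
    tip: TipSpec,
    convention: str = "contact_depth",
) -> float:
    """Projected contact area of a conical tip (m^2).

    ``contact_depth``: A = pi tan^2(theta) h_c^2 with
    h_c = h_max - eps P_max / S, eps = 2(pi-2)/pi — the standard
    Oliver-Pharr correction, exact for the Sneddon cone.
    ``at_h_max``: A = pi tan^2(theta) h_max^2, the cone cross-section at the
    maximum indentation itself.
    """
    if min(h_max, P_max, S) <= 0:
        raise ValueError("h_max, P_max and S must be positive")
    if convention == "at_h_max":
        depth = h_max
    elif convention == "contact_depth":
        depth = h_max - EPSILON_CONE * P_max / S
        if depth <= 0:
            raise ValueError("contact depth h_c <= 0; curve too blunt for the cone model")
    else:
        raise ValueError(f"unknown area convention {convention!r}")
    return np.pi * tip.tan_theta**2 * depth**2


def youngs_modulus(S: float, A: float, nu: float = 0.5) -> float:
    """Young's modulus from unloading stiffness and projected contact area.

    E = (1 - nu^2) (sqrt(pi)/2) S / sqrt(A), assuming a rigid indenter (no
    tip-compliance term).
    """
    if S <= 0 or A <= 0:
        raise ValueError("S and A must be positive")
    if not 0.0 <= nu < 1.0:
        raise ValueError("nu must lie in [0, 1)")
    return (1.0 - nu**2) * (np.sqrt(np.pi) / 2.0) * S / np.sqrt(A)


class OliverPharrModel:
    """Oliver-Pharr elasticity model for one load-indentation curve.

    Parameters
    ----------
    curve : LoadIndentationCurve
        Pre-processed curve (contact already subtracted).
    tip : TipSpec
        Conical tip geometry.
    nu : float
        Poisson's ratio of the sample; 0.5 for an incompressible rubber-like
        hydrogel.
    area_convention : {'contact_depth', 'at_h_max'}
        How the projected contact area is evaluated (see module docstring).
    fit_fraction : float
        Fraction of the retract force range used in the power-law fit.
    h_offset : float
        Known residual depth subtracted before fitting (default 0).
    """

    def __init__(
        self,
        curve: LoadIndentationCurve,
        tip: TipSpec = TipSpec(),
        nu: float = 0.5,
        area_convention: str = "contact_depth",
        fit_fraction: float = 0.8,
        h_offset: float = 0.0,
    ):
        if area_convention not in ("contact_depth", "at_h_max"):
            raise ValueError(f"unknown area convention {area_convention!r}")
        self.curve = curve
        self.tip = tip
        self.nu = nu
        self.area_convention = area_convention
        self.fit_fraction = fit_fraction
        self.h_offset = h_offset

    def fit(self) -> "OliverPharrResults":
        plf = fit_unloading_power_law(
            self.curve, fit_fraction=self.fit_fraction, h_offset=self.h_offset
        )
        S = contact_stiffness(plf)
        A = projected_area(plf.h_max, plf.P_max, S, self.tip, self.area_convention)
        E = youngs_modulus(S, A, self.nu)
        return OliverPharrResults(model=self, power_law=plf, stiffness=S, contact_area=A, youngs_modulus=E)


@dataclass
class OliverPharrResults:
    """Estimates from an Oliver-Pharr fit of a single indentation curve."""

    model: OliverPharrModel
    power_law: PowerLawFit
    stiffness: float  # N/m
    contact_area: float  # m^2
    youngs_modulus: float  # Pa
    flags: list = field(default_factory=list)

    @property
    def alpha(self) -> float:
        return self.power_law.alpha

    @property
    def exponent(self) -> float:
        return self.power_law.exponent

    @property
    def youngs_modulus_se(self) -> float:
        """First-order (delta-method) standard error of E from the alpha SE.

        E is proportional to alpha for a fixed exponent, so the relative
        uncertainty of alpha propagates directly; exponent uncertainty is
        neglected (it is strongly correlated with alpha over a narrow h
        range).
        """
        rel = self.power_law.alpha_se / self.power_law.alpha
        return self.youngs_modulus * rel

    def summary(self) -> str:
        pl = self.power_law
        lines = [
            "Oliver-Pharr conical indentation fit",
            "=" * 52,
            f"unloading samples          {pl.n_samples:>12d}",
            f"h_max                      {pl.h_max * 1e9:>12.2f} nm",
            f"P_max                      {pl.P_max * 1e9:>12.4f} nN",
            f"alpha                      {pl.alpha:>12.4g} N/m^m (se {pl.alpha_se:.2g})",
            f"exponent m                 {pl.exponent:>12.4f} (se {pl.exponent_se:.2g})"
            + ("" if pl.exponent_in_range else "  [outside 1-3]"),
            f"residual rms               {pl.residual_rms * 1e9:>12.4g} nN",
            f"contact stiffness S        {self.stiffness:>12.4g} N/m",
            f"projected area A           {self.contact_area * 1e12:>12.4g} um^2"
            f"  ({self.model.area_convention})",
            f"Poisson ratio nu           {self.model.nu:>12.2f}",
            f"Young's modulus E          {self.youngs_modulus / 1e3:>12.2f} kPa"
            f" (se {self.youngs_modulus_se / 1e3:.2g})",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Plot the unloading data and the fitted power law."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        cu = self.model.curve
        ret = cu.retract
        ax.plot(cu.h[ret] * 1e9, cu.P[ret] * 1e9, ".", ms=2, label="unloading data")
        hh = np.linspace(0, self.power_law.h_max, 200)
        ax.plot(
            hh * 1e9,
            self.power_law.alpha * hh**self.power_law.exponent * 1e9,
            "-",
            label=f"fit m={self.power_law.exponent:.3f}",
        )
        ax.set_xlabel("indentation h (nm)")
        ax.set_ylabel("load P (nN)")
        ax.legend()
        return ax


def fit_curve_set(
    curves,
    tip: TipSpec = TipSpec(),
    nu: float = 0.5,
    area_convention: str = "contact_depth",
    fit_fraction: float = 0.8,
) -> "pd.DataFrame":
    """Fit a list of retained curves, returning a tidy per-curve table.

    Curves whose fit fails are reported with NaN estimates and an error flag
    rather than aborting the map.
    """
    import pandas as pd

    rows = []
    for i, cu in enumerate(curves):
        row = {
            "curve_id": cu.metadata.get("index", i),
            "alpha": np.nan,
            "m": np.nan,
            "h_max_nm": np.nan,
            "S_N_per_m": np.nan,
            "A_um2": np.nan,
            "E_kPa": np.nan,
            "flags": "",
        }
        try:
            res = OliverPharrModel(
                cu, tip=tip, nu=nu, area_convention=area_convention, fit_fraction=fit_fraction
            ).fit()
        except ValueError as exc:
            row["flags"] = f"fit_failed:{exc}"
        else:
            row.update(
                alpha=res.alpha,
                m=res.exponent,
                h_max_nm=res.power_law.h_max * 1e9,
                S_N_per_m=res.stiffness,
                A_um2=res.contact_area * 1e12,
                E_kPa=res.youngs_modulus / 1e3,
                flags="" if res.power_law.exponent_in_range else "exponent_out_of_range",
            )
        rows.append(row)
    return pd.DataFrame(rows)
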