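"""Core steady-state anisotropy math.

Fluorescence anisotropy is computed from the parallel and perpendicular
polarized emission intensities,

    r = (I_par - g * I_perp) / (I_par + 2 * g * I_perp),

where ``g`` corrects any polarization bias of the detection path and is
calibrated on an isotropic dye solution (r = 0 by assumption).  The same
denominator is the total fluorescence F_tot = I_par + 2 g I_perp, which is
proportional to the number of emitting fluorophores and therefore tracks
photoswitching.

High numerical-aperture objectives collect emission over a wide cone and mix
the polarization components.  Following Axelrod's treatment, the measured
channels are linear combinations of the cartesian emission components
(I_x, I_y, I_z) with angle-dependent coefficients K_a, K_b, K_c:

    I_par    = K_c I_z + K_b I_y + K_a I_x
    g I_perp = K_b I_z + K_c I_y + K_a I_x

With randomly oriented fluorophores (I_x = I_y) the system inverts in closed
form, giving the corrected anisotropy r = (I_z - I_y) / (I_z + 2 I_y).  The
collection half-angle follows from NA = n sin(theta).

All public angle arguments are in degrees; trigonometry is internal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
from scipy.optimize import curve_fit

from .errors import (
    CalibrationError,
    FitError,
    IllConditionedCorrectionError,
    NumericalError,
)

if TYPE_CHECKING:  # pragma: no cover
    from .image_io import ChannelTrace

__all__ = [
    "OpticsConfig",
    "KFactors",
    "ExpFit",
    "collection_angle",
    "k_factors",
    "anisotropy",
    "total_fluorescence",
    "fraction_switched",
    "estimate_g",
    "fit_exponential",
    "axelrod_unmix",
]

#: refuse the unmixing inversion when |D| falls below this times max(K_c^2, 1)
_D_TOLERANCE = 1e-9


def collection_angle(numerical_aperture: float, refractive_index: float) -> float:
    """Collection half-angle theta (degrees) from NA = n * sin(theta).

    Raises
    ------
    NumericalError
        If NA is non-positive or exceeds the refractive index.
    """
    if not 0.0 < numerical_aperture <= refractive_index:
        raise NumericalError(
            f"require 0 < NA <= n, got NA={numerical_aperture}, n={refractive_index}"
        )
    return math.degrees(math.asin(numerical_aperture / refractive_index))


@dataclass(frozen=True)
class KFactors:
    """Polarization mixing coefficients for a collection half-angle."""

    k_a: float
    k_b: float
    k_c: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.k_a, self.k_b, self.k_c)


def k_factors(theta_deg: float) -> KFactors:
    """Mixing coefficients K_a, K_b, K_c at collection half-angle ``theta_deg``.

    K_a = (2 - 3 cos t + cos^3 t) / 3
    K_b = (1 - 3 cos t + 3 cos^2 t - cos^3 t) / 12
    K_c = (5 - 3 cos t - cos^2 t - cos^3 t) / 4

    All three vanish as theta -> 0 and grow monotonically with theta.
    """
    c = math.cos(math.radians(theta_deg))
    k_a = (2.0 - 3.0 * c + c**3) / 3.0
    k_b = (1.0 - 3.0 * c + 3.0 * c**2 - c**3) / 12.0
    k_c = (5.0 - 3.0 * c - c**2 - c**3) / 4.0
    return KFactors(k_a, k_b, k_c)


@dataclass
class OpticsConfig:
    """Optical configuration of the polarization imaging path.

    Parameters
    ----------
    numerical_aperture, refractive_index
        Define the collection half-angle via NA = n sin(theta).
    g_factor
        Detection bias correction; the perpendicular channel is multiplied
        by g before any anisotropy arithmetic.
    apply_axelrod
        Whether the high-NA polarization mixing model is active.  In the
        analysis direction this enables the unmixing correction; in the
        simulation direction it enables the forward mixing.
    """

    numerical_aperture: float = 1.4
    refractive_index: float = 1.515
    g_factor: float = 1.0
    apply_axelrod: bool = False
    theta_deg: float = field(init=False)

    def __post_init__(self) -> None:
        self.theta_deg = collection_angle(self.numerical_aperture, self.refractive_index)
        if self.g_factor <= 0:
            raise NumericalError(f"g_factor must be positive, got {self.g_factor}")

    @property
    def kfactors(self) -> KFactors:
        return k_factors(self.theta_deg)


def anisotropy(i_par, i_perp, g: float = 1.0):
    """Anisotropy r = (I_par - g I_perp) / (I_par + 2 g I_perp).

    Accepts scalars or arrays.  For non-negative intensities r lies in
    [-0.5, 1]; photoselection of an isotropic immobile population bounds it
    further to [-0.2, 0.4].
    """
    i_par = np.asarray(i_par, dtype=float)
    i_perp = np.asarray(i_perp, dtype=float)
    denom = i_par + 2.0 * g * i_perp
    if np.any(denom == 0):
        raise NumericalError("anisotropy undefined: I_par + 2 g I_perp = 0")
    r = (i_par - g * i_perp) / denom
    return float(r) if r.ndim == 0 else r


def total_fluorescence(i_par, i_perp, g: float = 1.0):
    """Total fluorescence F_tot = I_par + 2 g I_perp."""
    out = np.asarray(i_par, dtype=float) + 2.0 * g * np.asarray(i_perp, dtype=float)
    return float(out) if out.ndim == 0 else out


def fraction_switched(f_tot) -> np.ndarray:
    """Fraction of fluorophores switched off, F(t) = (I(t0) - I(t)) / I(t0).

    The first frame defines t0, so F(0) = 0 exactly.  Noise can push later
    values slightly negative; they are preserved, not clipped.
    """
    f_tot = np.asarray(f_tot, dtype=float)
    if f_tot.ndim != 1 or f_tot.size < 1:
        raise NumericalError("fraction_switched expects a 1-D trace")
    i0 = f_tot[0]
    if i0 <= 0:
        raise NumericalError(f"initial total fluorescence must be positive, got {i0}")
    return (i0 - f_tot) / i0


def estimate_g(reference_trace: "ChannelTrace") -> float:
    """g-factor from an isotropic reference solution.

    A freely rotating dye (e.g. fluorescein) depolarizes completely within
    its fluorescence lifetime, so its true anisotropy is zero and any
    channel imbalance is instrumental:

        g = mean(I_par - bg_par) / mean(I_perp - bg_perp)

    With this g, the anisotropy of the reference evaluates to exactly zero.
    """
    par = np.mean(reference_trace.par_sub)
    perp = np.mean(reference_trace.perp_sub)
    if par <= 0 or perp <= 0:
        raise CalibrationError(
            "background-subtracted reference intensities must be positive "
            f"(got par={par:.4g}, perp={perp:.4g})"
        )
    return float(par / perp)


@dataclass(frozen=True)
class ExpFit:
    """Single-exponential-with-offset fit y = a exp(-b x) + c."""

    a: float
    b: float
    c: float
    degenerate: bool = False


def fit_exponential(time, f_tot) -> ExpFit:
    """Fit y = a exp(-b x) + c to a decaying total-fluorescence trace.

    Used as a descriptive model of the photoswitching drive.  A trace with
    no decay (relative range below 1e-9) is flagged degenerate with b = 0
    rather than raising.
    """
    x = np.asarray(time, dtype=float)
    y = np.asarray(f_tot, dtype=float)
    if x.size < 4:
        raise FitError("exponential fit needs at least 4 points")
    span = y.max() - y.min()
    if span <= 1e-9 * max(abs(y.max()), 1.0):
        return ExpFit(a=0.0, b=0.0, c=float(y.mean()), degenerate=True)

    # moment-based starting values: amplitude from the range, rate from the
    # time to decay to ~1/e of the range above the floor
    c0 = y.min()
    a0 = y[0] - c0
    target = c0 + a0 / math.e
    below = np.nonzero(y <= target)[0]
    tau = x[below[0]] - x[0] if below.size and below[0] > 0 else (x[-1] - x[0]) / 2
    b0 = 1.0 / max(tau, np.diff(x).min() if x.size > 1 else 1.0)

    def model(x, a, b, c):
        return a * np.exp(-b * x) + c

    try:
        popt, _ = curve_fit(model, x, y, p0=(a0, b0, c0), maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - rare with good p0
        raise FitError(f"exponential fit did not converge: {exc}") from exc
    return ExpFit(a=float(popt[0]), b=float(popt[1]), c=float(popt[2]))


def axelrod_unmix(i_par, g_i_perp, theta_deg: float):
    """Invert high-NA polarization mixing and return (I_z, I_y, r_corrected).

    Solves the mixing system (with I_x = I_y) for the cartesian components:

        I_y = (I_par K_b - g I_perp K_c) / D
        I_z = (g I_perp (K_b + K_a) - I_par (K_c + K_a)) / D
        D   = K_b^2 + K_a K_b - K_c^2 - K_a K_c

    and evaluates the corrected anisotropy r = (I_z - I_y)/(I_z + 2 I_y).
    At small angles D -> 0 and the inversion is refused; uncorrected
    analysis should be used instead.
    """
    ka, kb, kc = k_factors(theta_deg).as_tuple()
    d = kb * kb + ka * kb - kc * kc - ka * kc
    if abs(d) < _D_TOLERANCE * max(kc * kc, 1.0):
        raise IllConditionedCorrectionError(
            f"unmixing denominator |D|={abs(d):.3e} at theta={theta_deg:.3g} deg "
            "is ill-conditioned; analyze uncorrected instead"
        )
    i_par = np.asarray(i_par, dtype=float)
    g_i_perp = np.asarray(g_i_perp, dtype=float)
    i_y = (i_par * kb - g_i_perp * kc) / d
    i_z = (g_i_perp * (kb + ka) - i_par * (kc + ka)) / d
    r = anisotropy(i_z, i_y, g=1.0)
    if i_y.ndim == 0:
        return float(i_z), float(i_y), r
    return i_z, i_y, r
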