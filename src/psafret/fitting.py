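"""psAFRET estimation: anisotropy-vs-switching regression and drFRET.

During photoswitching the fraction of fluorophores still on decreases, so
fewer emitters have an on-state partner to transfer energy to and the
measured anisotropy climbs from its homo-FRET value toward the transfer-free
value.  Plotting r against x = 1 - F(t) (the fraction still on) gives an
approximately straight line; ordinary least squares then extrapolates to

    r_et1 = r(x=1)   anisotropy with every fluorophore on (full FRET)
    r_et0 = r(x=0)   anisotropy at complete photoswitching (no FRET)

and the anisotropy change delta_r = r_et0 - r_et1 converts into an
efficiency-like quantity

    drFRET = 6 (r_et0 - r_et1) / (1 + 8 r_et0 - 4 r_et1 + 4 r_et0 r_et1),

the fractional gain of perpendicular-channel signal caused by energy
transfer.  Unlike delta_r, drFRET is largely insensitive to the optical
configuration (objective NA, polarization mixing), which makes results
comparable across instruments.

Regression diagnostics follow the standard simple-linear-regression
formulas: residual standard error s = sqrt(SSE / (n - 2)), slope standard
error s_b1 = s / sqrt(SS_xx) with SS_xx = sum(x^2) - (sum x)^2 / n.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .anisotropy import (
    OpticsConfig,
    anisotropy,
    axelrod_unmix,
    fraction_switched,
    total_fluorescence,
)
from .errors import FitError, NumericalError
from .image_io import ChannelTrace

__all__ = [
    "AnisotropyTrace",
    "LinearFit",
    "PsafretResult",
    "compute_anisotropy_trace",
    "fit_anisotropy_line",
    "extrapolate",
    "drfret",
    "analyze_trace",
]


@dataclass
class AnisotropyTrace:
    """Per-frame anisotropy, total fluorescence and switching abscissa."""

    r: np.ndarray
    f_tot: np.ndarray
    fraction: np.ndarray  # F(t), 0 at the first frame
    corrected: bool = False

    @property
    def x(self) -> np.ndarray:
        """Fraction of fluorophores still on, x = 1 - F(t)."""
        return 1.0 - self.fraction


def compute_anisotropy_trace(trace: ChannelTrace, optics: OpticsConfig) -> AnisotropyTrace:
    """Background-subtracted channels -> per-frame anisotropy trace.

    The g-factor scales the perpendicular channel first; with
    ``optics.apply_axelrod`` the channel pair is unmixed through the
    collection-cone model before the anisotropy is formed.  F_tot (and
    hence F(t)) always uses the channel-domain I_par + 2 g I_perp.
    """
    par = trace.par_sub
    perp = trace.perp_sub
    g = optics.g_factor
    f_tot = total_fluorescence(par, perp, g)
    if optics.apply_axelrod:
        _, _, r = axelrod_unmix(par, g * perp, optics.theta_deg)
    else:
        r = anisotropy(par, perp, g)
    return AnisotropyTrace(
        r=np.asarray(r, dtype=float),
        f_tot=np.asarray(f_tot, dtype=float),
        fraction=fraction_switched(f_tot),
        corrected=optics.apply_axelrod,
    )


@dataclass
class LinearFit:
    """Simple linear regression r = a + b x with the textbook error terms."""

    a: float
    b: float
    s: float
    s_beta1: float
    ss_xx: float
    n_used: int
    mask: np.ndarray = field(repr=False, default=None)


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float, float]:
    n = x.size
    ss_xx = float(np.sum(x**2) - np.sum(x) ** 2 / n)
    if ss_xx <= 1e-12 * max(float(np.sum(x**2)), 1.0):
        raise FitError("degenerate abscissa: no spread in fraction photoswitched")
    ss_xy = float(np.sum(x * y) - np.sum(x) * np.sum(y) / n)
    b = ss_xy / ss_xx
    a = float(np.mean(y)) - b * float(np.mean(x))
    resid = y - (a + b * x)
    s = float(np.sqrt(np.sum(resid**2) / (n - 2))) if n > 2 else 0.0
    s_beta1 = s / np.sqrt(ss_xx)
    return a, b, s, s_beta1, ss_xx


def fit_anisotropy_line(
    trace: AnisotropyTrace,
    cutoff: float = 0.8,
    low_signal_frac: float = 0.05,
) -> LinearFit:
    """OLS of anisotropy on x = 1 - F(t), restricted to reliable frames.

    Frames beyond ``cutoff`` fraction photoswitched are excluded (anisotropy
    becomes very noisy once most fluorophores are off), as are frames whose
    total fluorescence has fallen below ``low_signal_frac`` of its initial
    value.  Excluded frames stay in the trace for plotting.
    """
    mask = (trace.fraction <= cutoff) & (trace.f_tot >= low_signal_frac * trace.f_tot[0])
    n = int(mask.sum())
    if n < 3:
        raise FitError(f"only {n} frames pass the cutoff; need >= 3 for the line fit")
    a, b, s, s_beta1, ss_xx = _ols(trace.x[mask], trace.r[mask])
    return LinearFit(a=a, b=b, s=s, s_beta1=s_beta1, ss_xx=ss_xx, n_used=n, mask=mask)


def extrapolate(fit: LinearFit) -> tuple[float, float, float]:
    """(r_et1, r_et0, delta_r) from the fitted line.

    x = 1 is the unswitched start (full homo-FRET), x = 0 the complete-
    photoswitching limit (no acceptors left), so r_et1 = a + b, r_et0 = a
    and delta_r = r_et0 - r_et1 = -b.
    """
    return fit.a + fit.b, fit.a, -fit.b


def drfret(r_et0: float, r_et1: float) -> float:
    """Convert the anisotropy pair to the drFRET efficiency.

    drFRET = 6 (r_et0 - r_et1) / (1 + 8 r_et0 - 4 r_et1 + 4 r_et0 r_et1);
    it equals the fractional increase of perpendicular-channel signal due to
    energy transfer, is zero when r_et1 = r_et0, and grows with delta_r.
    The denominator reduces to (1 + 2 r_et0)^2 at delta_r = 0 and stays
    positive whenever r_et1 <= r_et0 on the physical anisotropy range.
    Out-of-domain pairs raise rather than clamp; a negative result
    (r_et1 > r_et0) is returned with a warning.
    """
    if not -0.2 <= r_et0 <= 0.4:
        raise NumericalError(f"r_et0={r_et0} outside the photoselection range [-0.2, 0.4]")
    denom = 1.0 + 8.0 * r_et0 - 4.0 * r_et1 + 4.0 * r_et0 * r_et1
    if denom <= 0:
        raise NumericalError(
            f"drFRET denominator {denom:.4g} <= 0 for r_et0={r_et0}, r_et1={r_et1}"
        )
    value = 6.0 * (r_et0 - r_et1) / denom
    if value < 0:
        warnings.warn(
            f"negative drFRET ({value:.4g}): r_et1 > r_et0, anisotropy fell during switching",
            stacklevel=2,
        )
    return value


@dataclass
class PsafretResult:
    """Full psAFRET readout for one cell/ROI."""

    r_et1: float
    r_et0: float
    delta_r: float
    drfret: float
    cutoff_used: float
    corrected: bool
    fit: LinearFit
    trace: AnisotropyTrace | None = None

    def to_dict(self) -> dict:
        return {
            "r_et1": self.r_et1,
            "r_et0": self.r_et0,
            "delta_r": self.delta_r,
            "drfret": self.drfret,
            "slope": self.fit.b,
            "intercept": self.fit.a,
            "s": self.fit.s,
            "s_beta1": self.fit.s_beta1,
            "n_used": self.fit.n_used,
            "cutoff": self.cutoff_used,
            "corrected": self.corrected,
        }


def analyze_trace(
    trace: ChannelTrace,
    optics: OpticsConfig,
    cutoff: float = 0.8,
    low_signal_frac: float = 0.05,
) -> PsafretResult:
    """Run the full psAFRET pipeline on one channel trace.

    g-factor scaling, optional high-NA correction, total fluorescence and
    F(t), the linear fit up to the cutoff, extrapolation to the anisotropy
    endpoints, and the drFRET conversion.
    """
    if trace.has_negative:
        warnings.warn(
            "background-subtracted intensities contain negative values; "
            "low-signal frames may dominate",
            stacklevel=2,
        )
    atrace = compute_anisotropy_trace(trace, optics)
    fit = fit_anisotropy_line(atrace, cutoff=cutoff, low_signal_frac=low_signal_frac)
    n_excluded = atrace.r.size - fit.n_used
    if n_excluded:
        warnings.warn(
            f"{n_excluded} frame(s) excluded by the {cutoff:.2f} cutoff or low-signal guard",
            stacklevel=2,
        )
    r_et1, r_et0, delta_r = extrapolate(fit)
    return PsafretResult(
        r_et1=r_et1,
        r_et0=r_et0,
        delta_r=delta_r,
        drfret=drfret(r_et0, r_et1),
        cutoff_used=cutoff,
        corrected=atrace.corrected,
        fit=fit,
        trace=atrace,
    )
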