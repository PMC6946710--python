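"""Synthetic photoswitching-anisotropy data with known ground truth.

The generator models an ensemble of immobile oligomers, each carrying
``n_subunits`` copies of a photoswitchable fluorescent protein.  Polarized
excitation photoselects emitters (cos^2 weighting); energy transfer inside
an oligomer depolarizes the emission.  For a cluster with ``k`` fluorophores
in the on state and equal all-pairs coupling ``omega*tau`` (transfer rate
times lifetime), the steady-state anisotropy is

    r(k) = r_mono (1 + wt) / (1 + k wt) + r_et (k - 1) wt / (1 + k wt)

where ``r_mono`` is the anisotropy of directly excited emission and
``r_et`` that of FRET-sensitized emission (default 0: sensitized emission
carries no memory of the excitation polarization).  Coupling relates to the
chromophore separation through the Foerster radius, wt = (d/R0)^-6.

During photoswitching each on fluorophore turns off independently with a
fixed per-frame probability, so the on-fraction decays geometrically.  With
a fraction ``p`` of fluorophores on, the emitting population is a binomial
mixture over on-state compositions, giving the ensemble anisotropy

    r(p) = sum_j C(N-1, j) p^j (1-p)^(N-1-j) r(j+1)

(the j on-partners seen by a random on fluorophore).  For a dimer this is
exactly affine in p — the basis of the linear extrapolation used by the
analysis — while larger oligomers at tight separations (d <~ 0.8 R0) curve
upward.

Anisotropy and brightness are projected to the parallel/perpendicular
detection channels, optionally through the high-NA polarization mixing
model, and degraded with Poisson shot noise plus Gaussian read noise on a
camera baseline.  Every simulated dataset carries its ground truth
(r_et1, r_et0, drFRET) for end-to-end validation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import comb
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

from .anisotropy import OpticsConfig
from .errors import DataError, DegenerateOpticsError, NumericalError
from .fitting import drfret
from .image_io import ChannelTrace, ROISpec

__all__ = [
    "OligomerModel",
    "SwitchingParams",
    "CameraModel",
    "GroundTruth",
    "TraceScene",
    "SceneGeometry",
    "cluster_anisotropy",
    "ensemble_anisotropy",
    "project_to_channels",
    "simulate_scene",
    "simulate_trace",
    "render_stack",
]


@dataclass
class OligomerModel:
    """Ground-truth photophysics of one oligomer species.

    ``coupling`` is the pairwise transfer-rate x lifetime product
    (omega*tau >= 0).  If ``d_over_r0`` is given instead, coupling is
    derived from it as (d/R0)^-6; giving both requires consistency.
    """

    n_subunits: int = 2
    r_mono: float = 0.35
    r_et: float = 0.0
    coupling: float | None = None
    d_over_r0: float | None = None

    def __post_init__(self) -> None:
        if self.n_subunits < 1:
            raise NumericalError(f"n_subunits must be >= 1, got {self.n_subunits}")
        if not -0.2 < self.r_mono <= 0.4:
            raise NumericalError(f"r_mono={self.r_mono} outside (-0.2, 0.4]")
        if not -0.2 <= self.r_et <= 0.4:
            raise NumericalError(f"r_et={self.r_et} outside [-0.2, 0.4]")
        if self.d_over_r0 is not None:
            derived = float(self.d_over_r0) ** -6
            if self.coupling is None:
                self.coupling = derived
            elif abs(self.coupling - derived) > 1e-12:
                raise NumericalError(
                    f"coupling={self.coupling} inconsistent with d_over_r0="
                    f"{self.d_over_r0} (implies {derived})"
                )
        if self.coupling is None:
            self.coupling = 1.0
        if self.coupling < 0:
            raise NumericalError(f"coupling must be >= 0, got {self.coupling}")


@dataclass
class SwitchingParams:
    """Stochastic off-switching drive: geometric decay of the on-state."""

    p_off_per_frame: float = 0.08
    n_frames: int = 50
    reactivation: bool = False  # repeated on/off cycles are not modeled

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_off_per_frame <= 1.0:
            raise NumericalError("p_off_per_frame must lie in [0, 1]")
        if self.n_frames < 2:
            raise NumericalError("n_frames must be >= 2")
        if self.reactivation:
            raise NumericalError("reactivation cycles are not supported")

    def on_fraction(self) -> np.ndarray:
        """Expected on-fraction per frame, p(t) = (1 - p_off)^t."""
        t = np.arange(self.n_frames)
        return (1.0 - self.p_off_per_frame) ** t


@dataclass
class CameraModel:
    """Detector model: shot noise, Gaussian read noise, baseline, gain."""

    photons_per_fluor: float = 200.0
    read_noise_sd: float = 2.0
    offset: float = 100.0
    gain: float = 1.0
    shot_noise: bool = True

    def __post_init__(self) -> None:
        for name in ("photons_per_fluor", "read_noise_sd", "offset", "gain"):
            if getattr(self, name) < 0:
                raise NumericalError(f"{name} must be non-negative")


@dataclass
class GroundTruth:
    """True anisotropies and drFRET of a simulated dataset."""

    r_et1_true: float
    r_et0_true: float
    drfret_true: float
    p_trajectory: np.ndarray

    def to_dict(self) -> dict:
        return {
            "r_et1_true": self.r_et1_true,
            "r_et0_true": self.r_et0_true,
            "drfret_true": self.drfret_true,
            "p_trajectory": list(map(float, self.p_trajectory)),
        }


def cluster_anisotropy(k_on: int, model: OligomerModel) -> float:
    """Steady-state anisotropy of a cluster with ``k_on`` on-state fluorophores.

    Equal all-pairs coupling: the directly excited fluorophore keeps a
    fraction (1 + wt)/(1 + k wt) of the emission; the rest is sensitized.
    A lone fluorophore (k = 1) or zero coupling gives r_mono.
    """
    if not 1 <= k_on <= model.n_subunits:
        raise NumericalError(f"k_on={k_on} outside [1, {model.n_subunits}]")
    wt = model.coupling
    denom = 1.0 + k_on * wt
    return model.r_mono * (1.0 + wt) / denom + model.r_et * (k_on - 1) * wt / denom


def ensemble_anisotropy(p_on: float, model: OligomerModel) -> float:
    """Ensemble anisotropy when a fraction ``p_on`` of fluorophores is on.

    Intensity-weighted binomial mixture over the on-state composition of the
    N-1 potential partners of an emitting fluorophore (equal quantum yields).
    """
    if not 0.0 <= p_on <= 1.0:
        raise NumericalError(f"p_on={p_on} outside [0, 1]")
    n = model.n_subunits
    total = 0.0
    for j in range(n):
        w = comb(n - 1, j) * p_on**j * (1.0 - p_on) ** (n - 1 - j)
        total += w * cluster_anisotropy(j + 1, model)
    return total


def project_to_channels(r: float, f_total: float, optics: OpticsConfig):
    """Project (anisotropy, total intensity) onto the detection channels.

    Returns the pair (I_par, g*I_perp).  The cartesian emission components
    are I_z = F (1 + 2r)/3 and I_x = I_y = F (1 - r)/3; with
    ``optics.apply_axelrod`` the channels mix through the K factors of the
    collection cone, otherwise the ideal channels (I_z, I_y) are returned.
    """
    if f_total < 0:
        raise NumericalError(f"f_total must be >= 0, got {f_total}")
    f_total = float(f_total)
    i_z = f_total * (1.0 + 2.0 * r) / 3.0
    i_y = f_total * (1.0 - r) / 3.0
    if not optics.apply_axelrod:
        return i_z, i_y
    ka, kb, kc = optics.kfactors.as_tuple()
    if max(ka, kb, kc) < 1e-15:
        raise DegenerateOpticsError(
            f"collection angle {optics.theta_deg:.3g} deg gives vanishing mixing factors"
        )
    i_par = kc * i_z + kb * i_y + ka * i_y
    g_i_perp = kb * i_z + kc * i_y + ka * i_y
    return i_par, g_i_perp


@dataclass
class TraceScene:
    """Noise-free per-frame channel expectations plus the truth.

    ``exp_par`` / ``exp_perp`` are expected *detected photons* per frame for
    the whole emitting region (the instrumental g-factor is already folded
    into the perpendicular channel).
    """

    exp_par: np.ndarray
    exp_perp: np.ndarray
    camera: CameraModel
    optics: OpticsConfig
    truth: GroundTruth


def simulate_scene(
    model: OligomerModel,
    switching: SwitchingParams,
    camera: CameraModel,
    optics: OpticsConfig,
    n_oligomers: int,
    seed: int,
) -> TraceScene:
    """Realize the stochastic switching and compute noise-free channel traces.

    Each oligomer starts fully on; per frame every on fluorophore survives
    with probability 1 - p_off.  The realized population's exact ensemble
    anisotropy (intensity-weighted over cluster compositions) and total
    brightness are projected to the channels.  Camera noise is *not* added
    here; see :func:`simulate_trace` and :func:`render_stack`.
    """
    if n_oligomers < 1:
        raise NumericalError("n_oligomers must be >= 1")
    rng = np.random.default_rng(seed)
    n = model.n_subunits
    r_k = np.array([0.0] + [cluster_anisotropy(k, model) for k in range(1, n + 1)])

    k_on = np.full(n_oligomers, n, dtype=np.int64)
    exp_par = np.empty(switching.n_frames)
    exp_perp = np.empty(switching.n_frames)
    for t in range(switching.n_frames):
        if t > 0:
            k_on = rng.binomial(k_on, 1.0 - switching.p_off_per_frame)
        counts = np.bincount(k_on, minlength=n + 1)
        weights = counts * np.arange(n + 1)  # intensity ~ number of on fluorophores
        total_on = weights.sum()
        if total_on == 0:
            exp_par[t] = exp_perp[t] = 0.0
            continue
        r_frame = float(weights @ r_k) / total_on
        f_tot = float(total_on) * camera.photons_per_fluor
        i_par, g_i_perp = project_to_channels(r_frame, f_tot, optics)
        exp_par[t] = i_par
        exp_perp[t] = g_i_perp / optics.g_factor  # detected photons

    truth = ground_truth(model, switching)
    return TraceScene(exp_par=exp_par, exp_perp=exp_perp, camera=camera, optics=optics, truth=truth)


def ground_truth(model: OligomerModel, switching: SwitchingParams) -> GroundTruth:
    """Closed-form truth: r_et1 with everything on, r_et0 in the full-switching limit."""
    r_et1 = ensemble_anisotropy(1.0, model)
    r_et0 = model.r_mono
    return GroundTruth(
        r_et1_true=r_et1,
        r_et0_true=r_et0,
        drfret_true=drfret(r_et0, r_et1),
        p_trajectory=switching.on_fraction(),
    )


def _add_camera_noise(expected: np.ndarray, camera: CameraModel, rng: np.random.Generator):
    photons = rng.poisson(expected) if camera.shot_noise else expected
    counts = camera.gain * photons + camera.offset
    if camera.read_noise_sd > 0:
        counts = counts + rng.normal(0.0, camera.read_noise_sd, size=expected.shape)
    return counts


def simulate_trace(
    model: OligomerModel,
    switching: SwitchingParams,
    camera: CameraModel,
    optics: OpticsConfig,
    n_oligomers: int = 10_000,
    seed: int = 0,
) -> tuple[ChannelTrace, GroundTruth]:
    """Simulate one ROI-level photoswitching trace with camera noise.

    Returns a :class:`ChannelTrace` (background columns carry the camera
    baseline, as measured from a signal-free region) and the ground truth.
    Fully reproducible for a given seed.
    """
    scene = simulate_scene(model, switching, camera, optics, n_oligomers, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    par = _add_camera_noise(scene.exp_par, camera, rng)
    perp = _add_camera_noise(scene.exp_perp, camera, rng)
    trace = ChannelTrace(
        mean_par=par,
        mean_perp=perp,
        bg_par=np.full(switching.n_frames, camera.offset),
        bg_perp=np.full(switching.n_frames, camera.offset),
        n_pixels=1,
    )
    return trace, scene.truth


@dataclass
class SceneGeometry:
    """Layout of the rendered dual-view frame.

    The page is ``height x 2*half_width``: parallel half left, perpendicular
    half right.  ``cell_vertices`` and ``background_vertices`` are polygons
    in half-frame coordinates; ``channel_offset`` translates the cell region
    in the perpendicular half to exercise registration.
    """

    height: int = 64
    half_width: int = 64
    cell_vertices: Sequence[tuple[float, float]] = field(
        default_factory=lambda: [(16, 16), (16, 48), (48, 48), (48, 16)]
    )
    background_vertices: Sequence[tuple[float, float]] = field(
        default_factory=lambda: [(2, 2), (2, 12), (12, 12), (12, 2)]
    )
    channel_offset: tuple[int, int] = (0, 0)

    def cell_roi(self) -> ROISpec:
        return ROISpec("cell", self.cell_vertices, channel_offset=self.channel_offset)

    def background_roi(self) -> ROISpec:
        return ROISpec("background", self.background_vertices, channel_offset=self.channel_offset)


def render_stack(
    scene: TraceScene,
    geometry: SceneGeometry,
    seed: int,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Render a scene to a 16-bit dual-view TIFF plus ROI and truth JSON.

    The per-frame channel expectation is spread uniformly over the cell
    polygon; background pixels carry baseline and noise only.  Per-pixel
    Poisson shot noise and Gaussian read noise are drawn from ``seed``, so
    identical calls produce byte-identical files.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise DataError(f"cannot create output directory {out_dir}: {exc}") from exc

    rng = np.random.default_rng(seed)
    cam = scene.camera
    h, w = geometry.height, geometry.half_width
    shape = (h, w)
    cell = geometry.cell_roi()
    mask_par = cell.mask(shape)
    mask_perp = cell.mask(shape, shifted=True)
    n_pix = int(mask_par.sum())

    n_frames = scene.exp_par.size
    pages = np.empty((n_frames, h, 2 * w), dtype=np.uint16)
    for t in range(n_frames):
        page = np.zeros((h, 2 * w))
        lam_par = np.zeros(shape)
        lam_perp = np.zeros(shape)
        lam_par[mask_par] = scene.exp_par[t] / n_pix
        lam_perp[mask_perp] = scene.exp_perp[t] / n_pix
        page[:, :w] = _add_camera_noise(lam_par, cam, rng)
        page[:, w:] = _add_camera_noise(lam_perp, cam, rng)
        pages[t] = np.clip(np.rint(page), 0, 65535).astype(np.uint16)

    stack_path = out_dir / "stack.tif"
    roi_path = out_dir / "roi.json"
    truth_path = out_dir / "truth.json"
    tifffile.imwrite(stack_path, pages, photometric="minisblack")
    roi_path.write_text(
        json.dumps([cell.to_dict(), geometry.background_roi().to_dict()], indent=2)
    )
    truth_path.write_text(json.dumps(scene.truth.to_dict(), indent=2))
    return {"stack": stack_path, "roi": roi_path, "truth": truth_path}
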