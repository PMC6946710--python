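"""Dual-view TIFF input and ROI trace extraction.

A dual-view splitter projects the parallel and perpendicular polarized
images side by side on one camera chip, so each TIFF page holds both
channels.  This module splits and registers the halves, rasterizes polygon
ROIs, and reduces a stack to per-frame mean intensities with per-frame
background subtraction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage.draw import polygon2mask
from skimage.registration import phase_cross_correlation

from .errors import DataError

__all__ = [
    "ImageStack",
    "ROISpec",
    "ChannelTrace",
    "StackLayout",
    "read_stack",
    "extract_trace",
    "load_rois",
]


@dataclass
class ImageStack:
    """An ordered stack of equally sized 2-D intensity rasters."""

    pages: np.ndarray  # (frames, height, width), float64

    def __post_init__(self) -> None:
        self.pages = np.asarray(self.pages, dtype=float)
        if self.pages.ndim != 3:
            raise DataError(f"expected (frames, height, width), got shape {self.pages.shape}")

    @property
    def frame_count(self) -> int:
        return self.pages.shape[0]

    @property
    def height(self) -> int:
        return self.pages.shape[1]

    @property
    def width(self) -> int:
        return self.pages.shape[2]


@dataclass
class ROISpec:
    """Polygon region of interest in 0-based (row, col) pixel coordinates.

    ``channel_offset`` maps the parallel-half ROI onto its perpendicular
    counterpart (added to every vertex).  Pixel membership uses pixel-center
    containment via :func:`skimage.draw.polygon2mask`, which is deterministic
    and identical in both channels after the offset shift.
    """

    label: str
    vertices: Sequence[tuple[float, float]]
    channel_offset: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        self.vertices = [(float(r), float(c)) for r, c in self.vertices]
        if len(self.vertices) < 3:
            raise DataError(f"ROI '{self.label}' needs >= 3 vertices")

    def mask(self, shape: tuple[int, int], *, shifted: bool = False) -> np.ndarray:
        verts = np.asarray(self.vertices, dtype=float)
        if shifted:
            verts = verts + np.asarray(self.channel_offset, dtype=float)
        m = polygon2mask(shape, verts)
        if not m.any():
            raise DataError(f"ROI '{self.label}' covers no pixels in a {shape} image")
        return m

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "vertices": [list(v) for v in self.vertices],
            "channel_offset": list(self.channel_offset),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ROISpec":
        return cls(
            label=d["label"],
            vertices=[tuple(v) for v in d["vertices"]],
            channel_offset=tuple(d.get("channel_offset", (0, 0))),
        )


def load_rois(path: str | Path) -> list[ROISpec]:
    """Read a list of ROIs from a JSON file (single object or list)."""
    data = json.loads(Path(path).read_text())
    if isinstance(data, dict):
        data = [data]
    return [ROISpec.from_dict(d) for d in data]


@dataclass
class ChannelTrace:
    """Per-frame ROI mean intensities for both polarization channels.

    Raw means and per-frame background means are stored side by side; the
    ``par_sub`` / ``perp_sub`` properties give the background-subtracted
    values.  Negative subtracted values are preserved (never clipped) and
    reported by ``has_negative``.
    """

    mean_par: np.ndarray
    mean_perp: np.ndarray
    bg_par: np.ndarray
    bg_perp: np.ndarray
    n_pixels: int

    def __post_init__(self) -> None:
        self.mean_par = np.atleast_1d(np.asarray(self.mean_par, dtype=float))
        self.mean_perp = np.atleast_1d(np.asarray(self.mean_perp, dtype=float))
        self.bg_par = np.broadcast_to(
            np.asarray(self.bg_par, dtype=float), self.mean_par.shape
        ).copy()
        self.bg_perp = np.broadcast_to(
            np.asarray(self.bg_perp, dtype=float), self.mean_perp.shape
        ).copy()
        if self.mean_par.shape != self.mean_perp.shape:
            raise DataError("parallel and perpendicular traces differ in length")
        if self.n_pixels <= 0:
            raise DataError("n_pixels must be positive")

    @property
    def n_frames(self) -> int:
        return self.mean_par.size

    @property
    def par_sub(self) -> np.ndarray:
        return self.mean_par - self.bg_par

    @property
    def perp_sub(self) -> np.ndarray:
        return self.mean_perp - self.bg_perp

    @property
    def has_negative(self) -> bool:
        return bool(np.any(self.par_sub < 0) or np.any(self.perp_sub < 0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(self.n_frames),
                "mean_par": self.mean_par,
                "mean_perp": self.mean_perp,
                "bg_par": self.bg_par,
                "bg_perp": self.bg_perp,
                "n_pixels": self.n_pixels,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ChannelTrace":
        df = pd.read_csv(path)
        return cls(
            mean_par=df["mean_par"].to_numpy(),
            mean_perp=df["mean_perp"].to_numpy(),
            bg_par=df["bg_par"].to_numpy(),
            bg_perp=df["bg_perp"].to_numpy(),
            n_pixels=int(df["n_pixels"].iloc[0]),
        )


@dataclass
class StackLayout:
    """How the two polarization channels are arranged on disk.

    mode "side_by_side": each page holds parallel (left) and perpendicular
    (right) halves, split at ``split_col`` (default: the middle).
    mode "two_files": two pre-split stacks are given as a pair of paths.
    ``registration_offset`` is the (rows, cols) translation of the
    perpendicular half relative to the parallel half; registration shifts
    the perpendicular stack by its negative.  With ``refine_registration``
    a whole-pixel phase-correlation estimate from the first frame replaces
    the configured value.
    """

    mode: str = "side_by_side"
    split_col: int | None = None
    registration_offset: tuple[int, int] = (0, 0)
    refine_registration: bool = False
    recovered_offset: tuple[int, int] | None = field(default=None, init=False)


def _read_pages(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise DataError(f"{path}: expected a grayscale stack, got shape {arr.shape}")
    return arr.astype(float)


def read_stack(
    path: str | Path | tuple[str | Path, str | Path],
    layout: StackLayout | None = None,
) -> tuple[ImageStack, ImageStack]:
    """Read a dual-view stack and return registered (parallel, perpendicular).

    Raises
    ------
    DataError
        Odd page width in side-by-side mode without an explicit split
        column, or mismatched frame counts for two-file input.
    """
    layout = layout or StackLayout()
    if layout.mode == "two_files":
        if not (isinstance(path, tuple) and len(path) == 2):
            raise DataError("two_files layout requires a (parallel, perpendicular) path pair")
        par = _read_pages(path[0])
        perp = _read_pages(path[1])
        if par.shape[0] != perp.shape[0]:
            raise DataError(
                f"frame count mismatch: {par.shape[0]} parallel vs {perp.shape[0]} perpendicular"
            )
        if par.shape[1:] != perp.shape[1:]:
            raise DataError("parallel and perpendicular stacks differ in page size")
    elif layout.mode == "side_by_side":
        pages = _read_pages(path)
        width = pages.shape[2]
        split = layout.split_col
        if split is None:
            if width % 2:
                raise DataError(
                    f"page width {width} is odd; set split_col explicitly for side-by-side layout"
                )
            split = width // 2
        par = pages[:, :, :split]
        perp = pages[:, :, split : 2 * split] if 2 * split <= width else pages[:, :, split:]
        if par.shape != perp.shape:
            raise DataError("split halves have unequal shapes; check split_col")
    else:
        raise DataError(f"unknown layout mode {layout.mode!r}")

    offset = tuple(int(v) for v in layout.registration_offset)
    if layout.refine_registration:
        # phase_cross_correlation returns the shift registering perp onto
        # par, i.e. minus the displacement of perp relative to par
        shift, _, _ = phase_cross_correlation(par[0], perp[0], upsample_factor=1)
        offset = (-int(round(shift[0])), -int(round(shift[1])))
    layout.recovered_offset = offset
    if offset != (0, 0):
        perp = ndimage.shift(perp, (0, -offset[0], -offset[1]), order=0, mode="nearest")
    return ImageStack(par), ImageStack(perp)


def extract_trace(
    par: ImageStack,
    perp: ImageStack,
    roi: ROISpec,
    background_roi: ROISpec,
) -> ChannelTrace:
    """Per-frame ROI means in both channels with per-frame background.

    Background is taken from a no-signal region and subtracted frame by
    frame so that slow baseline drifts are tracked rather than averaged
    away.  Subtraction happens lazily in :class:`ChannelTrace`; negative
    results are preserved.
    """
    if par.pages.shape != perp.pages.shape:
        raise DataError("channel stacks differ in shape")
    shape = (par.height, par.width)
    m_roi_par = roi.mask(shape)
    m_roi_perp = roi.mask(shape, shifted=True)
    m_bg_par = background_roi.mask(shape)
    m_bg_perp = background_roi.mask(shape, shifted=True)

    return ChannelTrace(
        mean_par=par.pages[:, m_roi_par].mean(axis=1),
        mean_perp=perp.pages[:, m_roi_perp].mean(axis=1),
        bg_par=par.pages[:, m_bg_par].mean(axis=1),
        bg_perp=perp.pages[:, m_bg_perp].mean(axis=1),
        n_pixels=int(m_roi_par.sum()),
    )
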