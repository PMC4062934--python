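"""Per-pixel Stokes estimation and polarization maps.

A rotating linear analyzer measures, at orientation :math:`\\theta`,

.. math::  I(\\theta) = \\tfrac12\\,(S_0 + S_1 \\cos 2\\theta + S_2 \\sin 2\\theta),

so with at least three distinct analyzer angles (mod 180°) the linear Stokes
parameters :math:`(S_0, S_1, S_2)` of every pixel are recoverable by ordinary
least squares against the frame intensities. From these follow the angle of
polarization (AoP) :math:`\\varphi = \\tfrac12\\operatorname{atan2}(S_2, S_1)`,
an axial quantity reported in degrees on [0, 180), and the degree of linear
polarization (DoLP) :math:`d = \\sqrt{S_1^2+S_2^2}/S_0 \\in [0, 1]`.

:math:`S_3` (circular polarization) is not measurable with a rotating linear
analyzer alone and is not estimated; the degree reported here is strictly the
degree of *linear* polarization.

AoP convention: degrees counterclockwise from the image x-axis (columns),
period 180°. Circular statistics on AoP use the axial convention
throughout (angles doubled, averaged, halved).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
import tifffile
import imageio.v3 as iio
from matplotlib.colors import hsv_to_rgb

from .image_ingest import FrameStack, dark_subtract

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic_scene import ScenePattern

__all__ = [
    "StokesImage",
    "PolarizationMaps",
    "RingSummary",
    "estimate_stokes",
    "compute_maps",
    "false_color",
    "color_legend",
    "ring_summary",
    "axial_difference_deg",
    "axial_mean_deg",
    "write_maps",
    "write_false_color",
]


@dataclass
class StokesImage:
    """Per-pixel linear Stokes parameters plus fit diagnostics."""

    s0: np.ndarray
    s1: np.ndarray
    s2: np.ndarray
    residual_rms: np.ndarray
    valid: np.ndarray


@dataclass
class PolarizationMaps:
    """Per-pixel AoP (degrees, [0,180)) and DoLP ([0,1]) with validity mask."""

    aop_deg: np.ndarray
    dolp: np.ndarray
    valid: np.ndarray


@dataclass
class RingSummary:
    """Ring-wise polarization statistics for a bull's-eye target."""

    rings: pd.DataFrame  # index: region; columns: aop_deg, dolp, n_pixels
    inter_ring_aop_difference_deg: float


def _design_matrix(angles_deg: np.ndarray) -> np.ndarray:
    two_theta = 2.0 * np.deg2rad(angles_deg)
    return 0.5 * np.column_stack(
        [np.ones_like(two_theta), np.cos(two_theta), np.sin(two_theta)]
    )


def estimate_stokes(stack: FrameStack) -> StokesImage:
    """Least-squares Stokes parameters for every pixel of an analyzer stack.

    Fits ``I(theta) = 0.5 * (S0 + S1 cos 2theta + S2 sin 2theta)`` to the N
    frame intensities per pixel. One pseudoinverse of the shared N x 3 design
    matrix is reused across all pixels. If the stack still carries a dark
    frame it is subtracted first (see :func:`image_ingest.dark_subtract`).

    Raises if the analyzer angle set is rank deficient (fewer than three
    distinct angles mod 180°).
    """
    if stack.dark is not None:
        stack = dark_subtract(stack)
    A = _design_matrix(stack.angles_deg)
    if np.linalg.matrix_rank(A) < 3:
        raise ValueError("analyzer angle set is rank deficient for Stokes fitting")
    n, h, w = stack.frames.shape
    intensities = stack.frames.reshape(n, -1)
    pinv = np.linalg.pinv(A)
    s = pinv @ intensities
    resid = A @ s - intensities
    residual_rms = np.sqrt(np.mean(resid**2, axis=0)).reshape(h, w)
    valid = stack.valid.copy()
    if stack.saturated is not None:
        valid &= ~np.any(stack.saturated, axis=0)
    return StokesImage(
        s0=s[0].reshape(h, w),
        s1=s[1].reshape(h, w),
        s2=s[2].reshape(h, w),
        residual_rms=residual_rms,
        valid=valid,
    )


def compute_maps(
    stokes: StokesImage,
    *,
    dolp_min: float = 0.05,
    s0_min: float | None = None,
    dark_noise_sd: float | None = None,
) -> PolarizationMaps:
    """AoP/DoLP maps from Stokes parameters with validity thresholding.

    AoP is numerically meaningless where almost no light (S0 below
    ``s0_min``) or almost no polarized light (DoLP below ``dolp_min``)
    reaches the pixel; those pixels are flagged invalid, never NaN. If
    ``s0_min`` is not given it defaults to ``5 * dark_noise_sd`` when a dark
    noise estimate is supplied, else 0.
    """
    if s0_min is None:
        s0_min = 5.0 * dark_noise_sd if dark_noise_sd is not None else 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        amplitude = np.hypot(stokes.s1, stokes.s2)
        dolp = np.where(stokes.s0 > 0, amplitude / np.where(stokes.s0 > 0, stokes.s0, 1.0), 0.0)
    dolp = np.clip(dolp, 0.0, 1.0)
    aop = (0.5 * np.degrees(np.arctan2(stokes.s2, stokes.s1))) % 180.0
    # float remainder of a tiny negative angle can land on 180.0 itself;
    # fold onto 0 so the codomain stays [0, 180)
    aop = np.where(aop >= 180.0 - 1e-9, 0.0, aop)
    valid = stokes.valid & (stokes.s0 > s0_min) & (dolp >= dolp_min)
    return PolarizationMaps(aop_deg=aop, dolp=dolp, valid=valid)


def false_color(maps: PolarizationMaps, mode: str = "aop_weighted") -> np.ndarray:
    """Render polarization maps as an 8-bit RGB image.

    Modes: ``aop`` — cyclic hue over [0°, 180°) at full brightness;
    ``dolp`` — grayscale, black (0) to white (100% polarization);
    ``aop_weighted`` — hue from AoP, brightness weighted by DoLP.
    Invalid pixels render black in every mode.
    """
    if mode not in ("aop", "dolp", "aop_weighted"):
        raise ValueError(f"unknown false-color mode {mode!r}")
    if mode == "dolp":
        gray = np.where(maps.valid, maps.dolp, 0.0)
        rgb = np.repeat(gray[..., None], 3, axis=-1)
    else:
        hue = (maps.aop_deg % 180.0) / 180.0
        value = maps.dolp if mode == "aop_weighted" else np.ones_like(hue)
        value = np.where(maps.valid, value, 0.0)
        hsv = np.stack([hue, np.ones_like(hue), value], axis=-1)
        rgb = hsv_to_rgb(hsv)
    return (np.clip(rgb, 0, 1) * 255).round().astype(np.uint8)


def color_legend(mode: str = "aop", width: int = 256, height: int = 24) -> np.ndarray:
    """Color-bar strip for a false-color rendering (0–180° hue or 0–100% DoLP)."""
    ramp = np.linspace(0.0, 1.0, width)
    if mode in ("aop", "aop_weighted"):
        hsv = np.stack([ramp, np.ones(width), np.ones(width)], axis=-1)
        row = hsv_to_rgb(hsv)
    elif mode == "dolp":
        row = np.repeat(ramp[:, None], 3, axis=1)
    else:
        raise ValueError(f"unknown false-color mode {mode!r}")
    strip = np.broadcast_to(row, (height, width, 3))
    return (strip * 255).round().astype(np.uint8)


def axial_mean_deg(angles_deg: np.ndarray) -> float:
    """Circular mean of axial (period-180°) angles, in [0, 180)."""
    angles_deg = np.asarray(angles_deg, dtype=float)
    if angles_deg.size == 0:
        raise ValueError("empty angle set")
    doubled = np.deg2rad(2.0 * angles_deg)
    mean = np.arctan2(np.mean(np.sin(doubled)), np.mean(np.cos(doubled)))
    out = (0.5 * np.degrees(mean)) % 180.0
    return float(0.0 if out >= 180.0 - 1e-9 else out)


def axial_difference_deg(a_deg: float, b_deg: float) -> float:
    """Axial distance between two polarization angles, in [0°, 90°]."""
    d = abs(a_deg - b_deg) % 180.0
    return float(min(d, 180.0 - d))


def ring_summary(maps: PolarizationMaps, pattern: "ScenePattern") -> RingSummary:
    """Per-ring circular-mean AoP, mean DoLP and pixel counts for a target.

    The quantitative check of the target configuration: for a "contrast"
    bull's-eye the inner and outer polarizer rings should come out 90° apart
    (axial distance), for a "plain" one 0°.
    """
    masks = pattern.region_masks(maps.aop_deg.shape)
    rows = {}
    for region in ("inner", "outer"):
        mask = masks[region] & maps.valid
        if not mask.any():
            raise ValueError(f"no valid pixels in {region} ring mask")
        rows[region] = {
            "aop_deg": axial_mean_deg(maps.aop_deg[mask]),
            "dolp": float(np.mean(maps.dolp[mask])),
            "n_pixels": int(mask.sum()),
        }
    rings = pd.DataFrame(rows).T
    diff = axial_difference_deg(rows["inner"]["aop_deg"], rows["outer"]["aop_deg"])
    return RingSummary(rings=rings, inter_ring_aop_difference_deg=diff)


def write_maps(directory: str | Path, stokes: StokesImage, maps: PolarizationMaps) -> None:
    """Write S0/S1/S2 and AoP/DoLP as 32-bit float TIFFs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, img in (
        ("s0", stokes.s0),
        ("s1", stokes.s1),
        ("s2", stokes.s2),
        ("aop_deg", maps.aop_deg),
        ("dolp", maps.dolp),
    ):
        tifffile.imwrite(directory / f"{name}.tiff", img.astype(np.float32))
    tifffile.imwrite(directory / "valid.tiff", maps.valid.astype(np.uint8))


def write_false_color(path: str | Path, maps: PolarizationMaps, mode: str = "aop_weighted") -> None:
    """Write a false-color rendering as an 8-bit RGB PNG."""
    iio.imwrite(Path(path), false_color(maps, mode))
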