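"""Frame preparation for rotating-analyzer polarimetry.

Takes raw frames — real acquisitions or synthetic renders — and produces an
aligned, dark-corrected :class:`FrameStack` ready for Stokes estimation:
Bayer channel separation, linear 16-bit TIFF I/O, dark-frame subtraction with
saturation masking, and translation-only stack registration.

All images are linear in exposure (integer counts or floats on the same
scale); no gamma or tone curve is applied anywhere. Coordinates are row-major
with the origin at the top-left; shifts are reported as (row, col).
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.filters import sobel
from skimage.registration import phase_cross_correlation

import tifffile

__all__ = [
    "MosaicFrame",
    "FrameStack",
    "BAYER_LAYOUTS",
    "split_bayer",
    "merge_bayer",
    "select_channel",
    "dark_subtract",
    "register_stack",
    "write_stack",
    "read_stack",
]

# (row, col) offset of each channel inside a 2x2 Bayer tile. G1 is the
# first green site in row-major order, G2 the second.
BAYER_LAYOUTS: dict[str, dict[str, tuple[int, int]]] = {
    "RGGB": {"R": (0, 0), "G1": (0, 1), "G2": (1, 0), "B": (1, 1)},
    "BGGR": {"B": (0, 0), "G1": (0, 1), "G2": (1, 0), "R": (1, 1)},
    "GRBG": {"G1": (0, 0), "R": (0, 1), "B": (1, 0), "G2": (1, 1)},
    "GBRG": {"G1": (0, 0), "B": (0, 1), "R": (1, 0), "G2": (1, 1)},
}


@dataclass
class MosaicFrame:
    """A raw single-sensor Bayer mosaic, linear with exposure."""

    data: np.ndarray
    layout: str = "RGGB"
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("mosaic must be a 2-D array")
        h, w = self.data.shape
        if h % 2 or w % 2:
            raise ValueError(f"mosaic dimensions must be even, got {h}x{w}")
        if self.layout not in BAYER_LAYOUTS:
            raise ValueError(f"unknown Bayer layout {self.layout!r}")
        full_scale = 2**self.bit_depth - 1
        if self.data.min() < 0 or self.data.max() > full_scale:
            raise ValueError("mosaic values outside [0, full scale]")


@dataclass
class FrameStack:
    """Aligned single-channel frames with their analyzer angles.

    Parameters
    ----------
    frames : (N, H, W) array
        Non-dark frames, one per analyzer orientation, linear counts.
    angles_deg : (N,) array
        Analyzer angle of each frame, degrees.
    dark : (H, W) array, optional
        Dark frame (lens cap on) to subtract before Stokes estimation.
    saturated : (N, H, W) bool array, optional
        Pixels at full scale in the raw data; propagate as invalid.
    valid : (H, W) bool array, optional
        Pixels usable in every frame (e.g. not shifted in from outside
        the field during registration). Defaults to all True.
    bit_depth : int
        Bit depth of the originating sensor; full scale is 2**bit_depth - 1.
    """

    frames: np.ndarray
    angles_deg: np.ndarray
    dark: np.ndarray | None = None
    saturated: np.ndarray | None = None
    valid: np.ndarray | None = None
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (N, H, W) array")
        if len(self.angles_deg) != len(self.frames):
            raise ValueError("one analyzer angle required per frame")
        n_distinct = len(np.unique(np.round(self.angles_deg % 180.0, 6)))
        if len(self.frames) < 3 or n_distinct < 3:
            raise ValueError(
                "need >= 3 frames with >= 3 distinct analyzer angles mod 180"
            )
        if self.dark is not None:
            self.dark = np.asarray(self.dark, dtype=float)
            if self.dark.shape != self.frames.shape[1:]:
                raise ValueError("dark frame shape mismatch")
        if self.valid is None:
            self.valid = np.ones(self.frames.shape[1:], dtype=bool)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def full_scale(self) -> float:
        return float(2**self.bit_depth - 1)


def split_bayer(frame: MosaicFrame) -> dict[str, np.ndarray]:
    """Separate a Bayer mosaic into its four half-resolution channels.

    Pure subsampling — exact integer passthrough, no interpolation. The
    inverse is :func:`merge_bayer`.
    """
    offsets = BAYER_LAYOUTS[frame.layout]
    return {
        name: frame.data[dr::2, dc::2].copy() for name, (dr, dc) in offsets.items()
    }


def merge_bayer(channels: dict[str, np.ndarray], layout: str = "RGGB") -> np.ndarray:
    """Re-interleave four channels into a mosaic (inverse of split_bayer)."""
    if layout not in BAYER_LAYOUTS:
        raise ValueError(f"unknown Bayer layout {layout!r}")
    offsets = BAYER_LAYOUTS[layout]
    h, w = channels["R"].shape
    out = np.empty((2 * h, 2 * w), dtype=channels["R"].dtype)
    for name, (dr, dc) in offsets.items():
        out[dr::2, dc::2] = channels[name]
    return out


def select_channel(channels: dict[str, np.ndarray], which: str = "G1") -> np.ndarray:
    """Pick one Bayer channel for analysis; ``Gmean`` averages G1 and G2."""
    if which == "Gmean":
        return (np.asarray(channels["G1"], dtype=float) + channels["G2"]) / 2.0
    if which not in ("R", "G1", "G2", "B"):
        raise ValueError(f"unknown channel selector {which!r}")
    return channels[which]


def dark_subtract(stack: FrameStack, *, allow_missing_dark: bool = False) -> FrameStack:
    """Subtract the dark frame from every analyzer frame, clamping at zero.

    Saturated pixels (at full scale in the *raw* frames) are recorded in the
    output's ``saturated`` mask. The dark frame is consumed: the returned
    stack has ``dark=None``. A stack without a dark frame is an error unless
    ``allow_missing_dark=True`` is passed explicitly.
    """
    if stack.dark is None:
        if not allow_missing_dark:
            raise ValueError(
                "stack has no dark frame; pass allow_missing_dark=True to skip"
            )
        return replace(stack, dark=None)
    saturated = stack.frames >= stack.full_scale
    if stack.saturated is not None:
        saturated |= stack.saturated
    frames = np.maximum(stack.frames - stack.dark[None], 0.0)
    return FrameStack(
        frames=frames,
        angles_deg=stack.angles_deg,
        dark=None,
        saturated=saturated,
        valid=stack.valid.copy(),
        bit_depth=stack.bit_depth,
    )


def _estimate_shift(
    reference: np.ndarray, moving: np.ndarray, upsample_factor: int
) -> tuple[np.ndarray, bool]:
    """Translation from `moving` to `reference` by phase correlation.

    Correlates Sobel gradient magnitudes, not raw intensities: frames taken
    through different analyzer orientations change region brightness (ring
    contrast can even invert), while edge magnitude stays put.
    """
    if np.ptp(moving) == 0 or np.ptp(reference) == 0:
        return np.zeros(2), False
    shift, _, _ = phase_cross_correlation(
        sobel(reference), sobel(moving), upsample_factor=upsample_factor,
        normalization=None,
    )
    return np.asarray(shift, dtype=float), True


def register_stack(
    stack: FrameStack,
    reference_index: int = 0,
    *,
    subpixel: bool = False,
    upsample_factor: int = 10,
) -> tuple[FrameStack, np.ndarray]:
    """Align every frame to the reference frame by pure translation.

    Returns the aligned stack and the per-frame estimated shifts
    ``(N, 2)`` in (row, col) pixels, i.e. the translation that was applied
    to each frame. Pixels shifted in from outside the field are removed from
    the stack's ``valid`` mask. A featureless (all-constant) frame cannot be
    registered; it is left untouched with a warning and zero shift.

    Registration is integer-translation by default; ``subpixel=True``
    refines via Fourier upsampling.
    """
    if stack.n_frames < 2:
        raise ValueError("need at least 2 frames to register")
    factor = upsample_factor if subpixel else 1
    ref = stack.frames[reference_index]
    shifts = np.zeros((stack.n_frames, 2))
    frames = stack.frames.copy()
    saturated = None if stack.saturated is None else stack.saturated.copy()
    valid = stack.valid.copy()
    for k in range(stack.n_frames):
        if k == reference_index:
            continue
        shift, ok = _estimate_shift(ref, stack.frames[k], factor)
        if not ok:
            warnings.warn(
                f"frame {k} is constant; correlation undefined, assuming zero shift",
                stacklevel=2,
            )
            continue
        shifts[k] = shift
        if np.any(shift):
            order = 1 if subpixel and np.any(shift != np.round(shift)) else 0
            frames[k] = ndimage.shift(stack.frames[k], shift, order=order, cval=0.0)
            if saturated is not None:
                saturated[k] = (
                    ndimage.shift(
                        stack.saturated[k].astype(float), shift, order=0, cval=1.0
                    )
                    > 0.5
                )
            valid &= (
                ndimage.shift(np.ones(stack.shape), shift, order=0, cval=0.0) > 0.5
            )
    aligned = FrameStack(
        frames=frames,
        angles_deg=stack.angles_deg,
        dark=None if stack.dark is None else stack.dark.copy(),
        saturated=saturated,
        valid=valid,
        bit_depth=stack.bit_depth,
    )
    return aligned, shifts


# ---------------------------------------------------------------------------
# TIFF + manifest I/O


def write_stack(directory: str | Path, stack: FrameStack) -> Path:
    """Write a stack as uncompressed 16-bit grayscale TIFFs plus angles.csv.

    Values are rounded to integer counts and clipped to the sensor full
    scale; the manifest has columns filename, angle_deg, is_dark.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    full_scale = stack.full_scale
    rows = []
    for k, (frame, angle) in enumerate(zip(stack.frames, stack.angles_deg)):
        name = f"frame_{k:03d}.tiff"
        data = np.clip(np.round(frame), 0, full_scale).astype(np.uint16)
        tifffile.imwrite(directory / name, data, compression=None)
        rows.append((name, float(angle), 0))
    if stack.dark is not None:
        data = np.clip(np.round(stack.dark), 0, full_scale).astype(np.uint16)
        tifffile.imwrite(directory / "dark.tiff", data, compression=None)
        rows.append(("dark.tiff", float("nan"), 1))
    manifest = directory / "angles.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "angle_deg", "is_dark"])
        writer.writerows(rows)
    return manifest


def read_stack(directory: str | Path, *, bit_depth: int = 16) -> FrameStack:
    """Read a stack written by :func:`write_stack` (or any conforming dir)."""
    directory = Path(directory)
    manifest = directory / "angles.csv"
    if not manifest.exists():
        raise FileNotFoundError(f"no angles.csv manifest in {directory}")
    frames, angles = [], []
    dark = None
    with open(manifest, newline="") as fh:
        for row in csv.DictReader(fh):
            img = tifffile.imread(directory / row["filename"]).astype(float)
            if int(row["is_dark"]):
                dark = img
            else:
                frames.append(img)
                angles.append(float(row["angle_deg"]))
    return FrameStack(
        frames=np.stack(frames),
        angles_deg=np.asarray(angles),
        dark=dark,
        bit_depth=bit_depth,
    )
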