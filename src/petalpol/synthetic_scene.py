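"""Synthetic bull's-eye polarization targets and forager choice sequences.

Renders analyzer-image stacks of artificial "flower" targets with known
per-pixel polarization state, so the whole polarimetry pipeline is testable
without a camera, and simulates differential-conditioning choice records
with between-bee heterogeneity, so the behavioral analysis is testable
without bees.

The target is a bull's-eye of two concentric linear-polarizer regions — an
inner disk (24 mm outer diameter) and an outer annulus (38 mm outer
diameter) — over an unpolarized background. In a "contrast" target the two
regions' polarization axes are perpendicular; in a "plain" target they are
parallel. Acquisition is modelled as a rotating ideal linear analyzer: at
analyzer angle :math:`\\theta` a pixel with radiance :math:`R`, degree of
linear polarization :math:`d` and polarization angle :math:`\\varphi`
produces

.. math:: I(\\theta) = \\tfrac12 R\\,(1 + d \\cos 2(\\theta - \\varphi)) + \\mathrm{dark},

the ideal-polarizer Malus response (the 1/2 means an unpolarized pixel
transmits half its radiance at every angle, so the recovered Stokes
:math:`S_0` equals :math:`R`; AoP and DoLP are scale-invariant either way).
Optional per-frame integer jitter, Gaussian read noise, Poisson shot noise
and clipping to the sensor full scale emulate a real acquisition. With all
noise off, frames are exact evaluations of the forward model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .behavior import TrialLayout, random_layout, shuffle_layout
from .image_ingest import FrameStack
from .polarimetry import PolarizationMaps

__all__ = [
    "RingSpec",
    "ScenePattern",
    "AcquisitionConfig",
    "make_target_pattern",
    "render_stack",
    "ground_truth_maps",
    "simulate_choices",
    "DEFAULT_ANGLES_DEG",
    "PX_PER_MM",
]

#: Default analyzer angles: seven frames in 20° increments.
DEFAULT_ANGLES_DEG: tuple[float, ...] = (0.0, 20.0, 40.0, 60.0, 80.0, 100.0, 120.0)

#: Default scale used to map the physical 38/24 mm ring diameters to pixels.
PX_PER_MM: float = 10.0


@dataclass
class RingSpec:
    """Polarization and radiance of one target region."""

    aop_deg: float
    dolp: float
    radiance: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.dolp <= 1.0:
            raise ValueError("dolp must lie in [0, 1]")
        if self.radiance <= 0:
            raise ValueError("radiance must be positive")
        self.aop_deg = float(self.aop_deg) % 180.0


@dataclass
class ScenePattern:
    """Geometry and polarization state of one bull's-eye target.

    Radii are in pixels; ``inner`` is a disk of radius
    ``inner_outer_radius_px``, ``outer`` an annulus between
    ``outer_inner_radius_px`` and ``outer_outer_radius_px``; everything else
    is unpolarized background. ``intensity_factors`` are neutral-density
    multipliers per region (the DFIC intensity-contrast overlay).
    """

    image_size: tuple[int, int]
    center: tuple[float, float]
    inner_outer_radius_px: float
    outer_inner_radius_px: float
    outer_outer_radius_px: float
    inner: RingSpec
    outer: RingSpec
    background_radiance: float
    intensity_factors: dict[str, float] = field(
        default_factory=lambda: {"inner": 1.0, "outer": 1.0, "background": 1.0}
    )

    def __post_init__(self) -> None:
        r_in, r_gap, r_out = (
            self.inner_outer_radius_px,
            self.outer_inner_radius_px,
            self.outer_outer_radius_px,
        )
        if not (0 < r_in < r_gap <= r_out):
            raise ValueError(
                "radii must be positive and nested: inner disk < outer annulus"
            )
        if self.background_radiance <= 0:
            raise ValueError("background radiance must be positive")
        for factor in self.intensity_factors.values():
            if factor <= 0:
                raise ValueError("intensity factors must be positive")

    def region_masks(
        self, shape: tuple[int, int] | None = None, center: tuple[float, float] | None = None
    ) -> dict[str, np.ndarray]:
        """Boolean masks for inner disk, outer annulus and background."""
        shape = self.image_size if shape is None else shape
        cy, cx = self.center if center is None else center
        rows, cols = np.ogrid[: shape[0], : shape[1]]
        r = np.hypot(rows - cy, cols - cx)
        inner = r <= self.inner_outer_radius_px
        outer = (r >= self.outer_inner_radius_px) & (r <= self.outer_outer_radius_px)
        return {"inner": inner, "outer": outer, "background": ~(inner | outer)}

    def field_maps(
        self, center: tuple[float, float] | None = None
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-pixel (radiance, dolp, aop_deg) maps, intensity factors applied."""
        masks = self.region_masks(center=center)
        f = self.intensity_factors
        radiance = np.full(self.image_size, self.background_radiance * f.get("background", 1.0))
        dolp = np.zeros(self.image_size)
        aop = np.zeros(self.image_size)
        for name, spec in (("inner", self.inner), ("outer", self.outer)):
            m = masks[name]
            radiance[m] = spec.radiance * f.get(name, 1.0)
            dolp[m] = spec.dolp
            aop[m] = spec.aop_deg
        return radiance, dolp, aop


@dataclass
class AcquisitionConfig:
    """Acquisition model: analyzer angles, dark level, noise, jitter.

    ``frame_jitter_px`` gives one integer (row, col) translation per analyzer
    frame (default: all zero). ``gain`` is counts per photon for the Poisson
    shot-noise model. With ``read_noise_sd=0``, ``shot_noise=False`` and zero
    jitter, rendering is an exact, deterministic evaluation of the forward
    model (no quantization).
    """

    analyzer_angles_deg: tuple[float, ...] = DEFAULT_ANGLES_DEG
    dark_level: float = 200.0
    read_noise_sd: float = 0.0
    shot_noise: bool = False
    gain: float = 1.0
    frame_jitter_px: tuple[tuple[int, int], ...] | None = None
    bit_depth: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        angles = np.asarray(self.analyzer_angles_deg, dtype=float)
        if len(angles) < 3 or len(np.unique(np.round(angles % 180.0, 6))) < 3:
            raise ValueError("need >= 3 distinct analyzer angles mod 180")
        if self.dark_level < 0 or self.read_noise_sd < 0 or self.gain <= 0:
            raise ValueError("dark level / noise parameters must be non-negative")
        if self.frame_jitter_px is not None and len(self.frame_jitter_px) != len(angles):
            raise ValueError("need one jitter offset per analyzer frame")


def make_target_pattern(
    kind: str,
    *,
    image_size: tuple[int, int] | None = None,
    px_per_mm: float = PX_PER_MM,
    outer_aop_deg: float = 0.0,
    dolp: float = 1.0,
    radiance: float = 40000.0,
    background_radiance: float | None = None,
    intensity_factors: dict[str, float] | None = None,
) -> ScenePattern:
    """Build a "contrast" or "plain" bull's-eye target pattern.

    ``contrast``: the inner disk's polarization axis is perpendicular to the
    outer annulus's (90° apart, axially). ``plain``: both regions share the
    same axis. Geometry defaults to the physical target — 24 mm inner and
    38 mm outer ring diameters — at ``px_per_mm`` scale, with a 1 px gap
    between the regions and an unpolarized background at a quarter of the
    ring radiance.
    """
    if kind not in ("contrast", "plain"):
        raise ValueError(f"kind must be 'contrast' or 'plain', got {kind!r}")
    r_inner = 12.0 * px_per_mm  # 24 mm outer diameter
    r_outer = 19.0 * px_per_mm  # 38 mm outer diameter
    if image_size is None:
        side = 2 * int(math.ceil(r_outer)) + 40
        image_size = (side, side)
    center = ((image_size[0] - 1) / 2.0, (image_size[1] - 1) / 2.0)
    outer_aop = float(outer_aop_deg) % 180.0
    inner_aop = (outer_aop + 90.0) % 180.0 if kind == "contrast" else outer_aop
    if background_radiance is None:
        background_radiance = radiance / 4.0
    pattern = ScenePattern(
        image_size=image_size,
        center=center,
        inner_outer_radius_px=r_inner,
        outer_inner_radius_px=r_inner + 1.0,
        outer_outer_radius_px=r_outer,
        inner=RingSpec(aop_deg=inner_aop, dolp=dolp, radiance=radiance),
        outer=RingSpec(aop_deg=outer_aop, dolp=dolp, radiance=radiance),
        background_radiance=background_radiance,
    )
    if intensity_factors is not None:
        pattern = replace(pattern, intensity_factors=dict(intensity_factors))
    return pattern


def render_stack(pattern: ScenePattern, config: AcquisitionConfig | None = None) -> FrameStack:
    """Render an analyzer-image stack (plus dark frame) of a target pattern.

    Evaluates the Malus forward model per pixel at each analyzer angle,
    applies per-frame jitter as a shift of the target center, then shot
    noise, read noise and clipping to the sensor full scale as configured.
    The dark frame is the dark level plus read noise. Fully deterministic
    and bit-reproducible given ``config.seed``.
    """
    config = AcquisitionConfig() if config is None else config
    rng = np.random.default_rng(config.seed)
    angles = np.asarray(config.analyzer_angles_deg, dtype=float)
    jitter = config.frame_jitter_px or ((0, 0),) * len(angles)
    full_scale = float(2**config.bit_depth - 1)
    noisy = config.shot_noise or config.read_noise_sd > 0

    frames = np.empty((len(angles), *pattern.image_size))
    base_center = pattern.center
    field_cache: dict[tuple[int, int], tuple] = {}
    for k, (theta, (dy, dx)) in enumerate(zip(angles, jitter)):
        key = (int(dy), int(dx))
        if key not in field_cache:
            center = (base_center[0] + dy, base_center[1] + dx)
            field_cache[key] = pattern.field_maps(center=center)
        radiance, dolp, aop = field_cache[key]
        signal = 0.5 * radiance * (
            1.0 + dolp * np.cos(2.0 * np.deg2rad(theta - aop))
        )
        if config.shot_noise:
            signal = rng.poisson(signal / config.gain) * config.gain
        frame = signal + config.dark_level
        if config.read_noise_sd > 0:
            frame = frame + rng.normal(0.0, config.read_noise_sd, frame.shape)
        frames[k] = np.clip(frame, 0.0, full_scale) if noisy else frame
    dark = np.full(pattern.image_size, float(config.dark_level))
    if config.read_noise_sd > 0:
        dark = np.clip(
            dark + rng.normal(0.0, config.read_noise_sd, dark.shape), 0.0, full_scale
        )
    return FrameStack(
        frames=frames, angles_deg=angles, dark=dark, bit_depth=config.bit_depth
    )


def ground_truth_maps(
    pattern: ScenePattern, image_size: tuple[int, int] | None = None
) -> PolarizationMaps:
    """The true per-pixel AoP/DoLP maps a perfect polarimeter would recover.

    Background pixels carry DoLP 0 and are flagged invalid (AoP is undefined
    where nothing is polarized).
    """
    if image_size is not None and image_size != pattern.image_size:
        pattern = replace(pattern, image_size=image_size)
    _, dolp, aop = pattern.field_maps()
    valid = pattern.region_masks()["background"] == False  # noqa: E712 — ring pixels only
    return PolarizationMaps(aop_deg=aop, dolp=dolp, valid=valid)


def simulate_choices(
    *,
    beta0: float = 0.0,
    beta1: float = math.log(3.0),
    sigma_b: float = 0.5,
    sigma_s: float = 0.5,
    n_bees: int = 9,
    n_trials: int = 100,
    seed: int = 0,
    dfic: bool = False,
    bout_length: int = 5,
    treatment: str | None = None,
) -> pd.DataFrame:
    """Simulate differential-conditioning choice sequences.

    Each bee i makes ``n_trials`` binary choices with

    ``P(correct at trial t) = logistic((beta0 + b_i) + (beta1 + s_i) * x_t)``,

    where ``x_t = (t-1)/(n_trials-1)`` and ``b_i ~ N(0, sigma_b^2)``,
    ``s_i ~ N(0, sigma_s^2)`` capture between-bee differences in ability and
    learning rate. Defaults: chance performance at the first trial rising to
    ~75% correct by trial 100 for the average bee, with substantial
    heterogeneity — nine bees of one hundred trials each.

    With ``dfic=True`` every trial carries a condition label 1-4 drawn from a
    4x4 Latin-square target layout that is re-shuffled (under the three
    rearrangement constraints) after every foraging bout of ``bout_length``
    choices; otherwise the condition column is the constant ``"pol"``.
    The condition never influences the response probability — intensity
    contrast is uninformative by design, as in the experiment.
    """
    if n_trials < 1 or n_bees < 1:
        raise ValueError("n_bees and n_trials must be >= 1")
    if sigma_b < 0 or sigma_s < 0:
        raise ValueError("variance components must be >= 0")
    rng = np.random.default_rng(seed)
    b = rng.normal(0.0, sigma_b, n_bees)
    s = rng.normal(0.0, sigma_s, n_bees)
    t = np.arange(1, n_trials + 1)
    x = (t - 1) / (n_trials - 1) if n_trials > 1 else np.zeros(1)
    logits = (beta0 + b)[:, None] + (beta1 + s)[:, None] * x[None, :]
    correct = rng.random((n_bees, n_trials)) < 1.0 / (1.0 + np.exp(-logits))

    if dfic:
        conditions = np.empty((n_bees, n_trials), dtype=int)
        for i in range(n_bees):
            layout = random_layout(rng=rng)
            for j in range(n_trials):
                if j > 0 and j % bout_length == 0:
                    layout = shuffle_layout(layout, rng=rng)
                cell = rng.integers(16)
                conditions[i, j] = layout.grid[cell // 4, cell % 4]
        condition_col = conditions.ravel()
    else:
        condition_col = np.full(n_bees * n_trials, "pol", dtype=object)

    table = pd.DataFrame(
        {
            "bee_id": np.repeat([f"bee{i:02d}" for i in range(n_bees)], n_trials),
            "trial": np.tile(t, n_bees),
            "condition": condition_col,
            "correct": correct.ravel().astype(int),
        }
    )
    table.attrs["treatment"] = treatment or ("DFIC" if dfic else "synthetic")
    return table
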