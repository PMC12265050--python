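"""Ground-truthed synthetic data for the sptPALM / morphometry / UPLC pipeline.

Every downstream stage of the package (localization, tracking, mobility
statistics, cell morphometry, chromatogram quantification) can be
exercised and validated against data generated here, where the truth is
known by construction:

* single-particle trajectories as a two-state mixture — *immobile*
  particles (a fixed anchor plus Gaussian localization noise, the
  signature of an enzyme bound to the peptidoglycan sacculus) and
  *mobile* particles undergoing free 2D Brownian motion with per-step
  Gaussian increments of variance ``2 D dt`` per axis;
* photoactivated-fluorophore movies rendered from those trajectories
  with a pixel-integrated Gaussian PSF, Poisson shot noise and Gaussian
  read noise, mimicking sparse PAmCherry activation and bleaching;
* label images of rod / sphere / spherocylinder cells with known
  length, width and L/W aspect ratio;
* UPLC-like chromatograms built as sums of labelled Gaussian peaks on a
  drifting baseline.

Brownian steps are exact Gaussian increments (no spatial grid), which is
exact for free diffusion at any frame interval.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import ndtr

from .movie import MovieStack
from .muropeptide import Chromatogram

__all__ = [
    "SimulationConfig",
    "GroundTruthTrajectory",
    "CellShapeSpec",
    "ChromPeakSpec",
    "ChromatogramSpec",
    "MOBILITY_PRESETS",
    "simulate_trajectories",
    "trajectories_to_dataframe",
    "render_movie",
    "simulate_cell_images",
    "cells_intensity_image",
    "simulate_chromatogram",
]


# Mobility scenario presets: (immobile_fraction, D_mobile um^2/s) for
# PAmCherry-tagged lytic transglycosylases in M. xanthus, by protein and
# time after glycerol induction of sporulation.
MOBILITY_PRESETS: dict[str, tuple[float, float]] = {
    "ltgA-vegetative": (0.239, 2.62e-2),
    "ltgB-vegetative": (0.182, 2.80e-2),
    "ltgA-1min": (0.210, 2.53e-2),
    "ltgB-1min": (0.280, 2.17e-2),
    "ltgA-30min": (0.315, 1.80e-2),
    "ltgB-30min": (0.102, 2.87e-2),
}


@dataclass
class SimulationConfig:
    """Parameters of a two-state single-particle trajectory simulation.

    Attributes
    ----------
    n_particles
        Number of trajectories to draw.
    immobile_fraction
        Probability that a particle is immobile (PG-bound); labels are
        Bernoulli draws, so realized counts fluctuate binomially.
    d_mobile
        Diffusion coefficient of the mobile state, um^2/s.
    frame_interval
        Time between frames, s (default 0.1 s = 10 Hz).
    pixel_size
        Camera pixel size, um (default 0.16).
    loc_noise_sd
        Per-axis Gaussian localization noise, um, applied to immobile
        particles (and, if ``mobile_loc_noise``, added to mobile ones).
        Default 0.015 um, a typical PALM localization precision.
    track_length_frames
        Fixed number of frames per track, used when ``bleach_prob`` is
        None.
    bleach_prob
        Per-frame bleaching probability; when set, track lengths are
        geometric (clipped to >= 2 frames).
    field_size
        Field of view in pixels, (height, width).
    activation_spacing_frames
        Spacing between successive activation (start) frames; 0 starts
        every track at frame 0, > 0 staggers activations so only a few
        particles are fluorescent at once, as in sparse photoactivation.
    seed
        Seed for the generator; fixed seed gives bit-identical output.
    """

    n_particles: int
    immobile_fraction: float = 0.0
    d_mobile: float = 2.62e-2
    frame_interval: float = 0.1
    pixel_size: float = 0.16
    loc_noise_sd: float = 0.015
    track_length_frames: int = 12
    bleach_prob: float | None = None
    field_size: tuple[int, int] = (64, 64)
    activation_spacing_frames: float = 0.0
    mobile_loc_noise: bool = False
    seed: int | None = None

    def validate(self) -> None:
        if not (isinstance(self.n_particles, (int, np.integer)) and self.n_particles >= 1):
            raise ValueError("n_particles must be an integer >= 1")
        for name in ("immobile_fraction", "d_mobile", "frame_interval",
                     "pixel_size", "loc_noise_sd"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite")
        if not 0.0 <= self.immobile_fraction <= 1.0:
            raise ValueError("immobile_fraction must lie in [0, 1]")
        if self.d_mobile < 0:
            raise ValueError("d_mobile must be >= 0")
        if self.frame_interval <= 0 or self.pixel_size <= 0:
            raise ValueError("frame_interval and pixel_size must be > 0")
        if self.loc_noise_sd < 0:
            raise ValueError("loc_noise_sd must be >= 0")
        if self.bleach_prob is None:
            if self.track_length_frames < 2:
                raise ValueError("track_length_frames must be >= 2")
        elif not 0.0 < self.bleach_prob < 1.0:
            raise ValueError("bleach_prob must lie in (0, 1)")
        if len(self.field_size) != 2 or any(s < 1 for s in self.field_size):
            raise ValueError("field_size must be two counts >= 1")


@dataclass
class GroundTruthTrajectory:
    """One simulated track with its generating truth attached."""

    track_id: int
    true_class: str                 # "immobile" | "mobile"
    true_d: float                   # um^2/s; 0 for immobile
    start_frame: int
    xy: np.ndarray                  # (n, 2) positions, um
    frame_interval: float = 0.1

    @property
    def n_frames(self) -> int:
        return self.xy.shape[0]

    @property
    def frames(self) -> np.ndarray:
        return self.start_frame + np.arange(self.n_frames)

    @property
    def times(self) -> np.ndarray:
        return self.frames * self.frame_interval


@dataclass
class CellShapeSpec:
    """Geometry of one synthetic cell/spore.

    ``length >= width > 0``; a sphere has ``length == width``. The rod
    shape is a plain rectangle, the spherocylinder a rectangle with
    hemispherical caps (total tip-to-tip length = ``length``).
    """

    shape: str                      # "rod" | "sphere" | "spherocylinder"
    length: float                   # um
    width: float                    # um
    orientation: float = 0.0        # radians, CCW from +x
    center: tuple[float, float] | None = None   # (x, y) um; None = place randomly

    def validate(self) -> None:
        if self.shape not in ("rod", "sphere", "spherocylinder"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if not (self.length >= self.width > 0):
            raise ValueError("require length >= width > 0")
        if self.shape == "sphere" and not math.isclose(self.length, self.width):
            raise ValueError("sphere requires length == width")


@dataclass
class ChromPeakSpec:
    species_label: str
    center: float                   # retention time, min
    sd: float                       # Gaussian width, min
    area: float                     # absorbance * min


@dataclass
class ChromatogramSpec:
    """A chromatogram as labelled Gaussian peaks over a drifting baseline.

    The default 0-25 min window matches a standard UPLC muropeptide run.
    """

    peaks: Sequence[ChromPeakSpec]
    baseline_offset: float = 0.0
    baseline_slope: float = 0.0     # absorbance / min
    noise_sd: float = 0.0
    sampling_rate: float = 100.0    # points / min
    t_start: float = 0.0
    t_end: float = 25.0
    sample_id: str = "sample"
    biomass_norm: float = 1.0

    def validate(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError("t_end must exceed t_start")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for p in self.peaks:
            if not self.t_start <= p.center <= self.t_end:
                raise ValueError(f"peak {p.species_label!r} outside run window")
            if p.sd <= 0 or p.area <= 0:
                raise ValueError(f"peak {p.species_label!r} needs sd > 0 and area > 0")


# ---------------------------------------------------------------------------
# trajectories


def _reflect_into(spec: CellShapeSpec, xy: np.ndarray) -> np.ndarray:
    """Fold a point back inside a cell outline (reflecting boundary)."""
    cx, cy = spec.center if spec.center is not None else (0.0, 0.0)
    d = xy - (cx, cy)
    c, s = math.cos(spec.orientation), math.sin(spec.orientation)
    u = c * d[0] + s * d[1]
    v = -s * d[0] + c * d[1]
    r = spec.width / 2.0
    if spec.shape == "rod":
        h = spec.length / 2.0
        for _ in range(8):
            if u > h:
                u = 2 * h - u
            elif u < -h:
                u = -2 * h - u
            if v > r:
                v = 2 * r - v
            elif v < -r:
                v = -2 * r - v
            if abs(u) <= h and abs(v) <= r:
                break
    else:
        half = max((spec.length - spec.width) / 2.0, 0.0)
        for _ in range(8):
            ua = np.clip(u, -half, half)
            dv = math.hypot(u - ua, v)
            if dv <= r:
                break
            # fold radially about the cap/side boundary
            scale = (2 * r - dv) / dv
            u = ua + (u - ua) * scale
            v = v * scale
    x = c * u - s * v + cx
    y = s * u + c * v + cy
    return np.array([x, y])


def simulate_trajectories(
    config: SimulationConfig,
    confine: CellShapeSpec | None = None,
) -> list[GroundTruthTrajectory]:
    """Draw a mixture of immobile and Brownian single-particle tracks.

    Mobile steps are i.i.d. Gaussian per axis with variance
    ``2 * d_mobile * frame_interval``; immobile positions are one fixed
    anchor plus i.i.d. Gaussian noise of sd ``loc_noise_sd`` per axis.
    With ``confine`` given, mobile steps reflect at the cell outline.

    Returns exactly ``config.n_particles`` trajectories, reproducibly
    for a fixed ``config.seed``.
    """
    config.validate()
    if confine is not None:
        confine.validate()
    rng = np.random.default_rng(config.seed)
    dt = config.frame_interval
    step_sd = math.sqrt(2.0 * config.d_mobile * dt)
    h, w = config.field_size
    margin = 3.0 * config.pixel_size
    xmax = w * config.pixel_size
    ymax = h * config.pixel_size

    out: list[GroundTruthTrajectory] = []
    for i in range(config.n_particles):
        immobile = rng.random() < config.immobile_fraction
        if config.bleach_prob is not None:
            n = max(2, int(rng.geometric(config.bleach_prob)))
        else:
            n = int(config.track_length_frames)
        if confine is not None:
            # rejection-sample a start inside the outline
            while True:
                p0 = rng.uniform((0.0, 0.0), (xmax, ymax))
                if np.allclose(_reflect_into(confine, p0), p0, atol=1e-12):
                    break
        else:
            lo = min(margin, xmax / 4), min(margin, ymax / 4)
            p0 = rng.uniform(lo, (xmax - lo[0], ymax - lo[1]))
        if immobile:
            xy = p0 + rng.normal(0.0, config.loc_noise_sd, size=(n, 2))
            true_d = 0.0
            cls = "immobile"
        else:
            steps = rng.normal(0.0, step_sd, size=(n - 1, 2))
            if confine is None:
                xy = p0 + np.vstack([np.zeros(2), np.cumsum(steps, axis=0)])
            else:
                xy = np.empty((n, 2))
                xy[0] = p0
                for k in range(1, n):
                    xy[k] = _reflect_into(confine, xy[k - 1] + steps[k - 1])
            if config.mobile_loc_noise and config.loc_noise_sd > 0:
                xy = xy + rng.normal(0.0, config.loc_noise_sd, size=xy.shape)
            true_d = config.d_mobile
            cls = "mobile"
        start = int(round(i * config.activation_spacing_frames))
        out.append(GroundTruthTrajectory(
            track_id=i, true_class=cls, true_d=true_d,
            start_frame=start, xy=xy, frame_interval=dt,
        ))
    return out


def trajectories_to_dataframe(trajs: Sequence[GroundTruthTrajectory]) -> pd.DataFrame:
    """Long-format ground-truth table (one row per localization)."""
    rows = []
    for t in trajs:
        for f, (x, y) in zip(t.frames, t.xy):
            rows.append((t.track_id, int(f), x, y, t.true_class, t.true_d))
    return pd.DataFrame(
        rows, columns=["track_id", "frame", "x_um", "y_um", "true_class", "true_D_um2_s"]
    )


# ---------------------------------------------------------------------------
# movie rendering


def _integrated_psf(center_px: float, lo: int, hi: int, sigma_px: float) -> np.ndarray:
    """Per-pixel integral of a unit 1D Gaussian over pixels lo..hi-1."""
    edges = np.arange(lo, hi + 1, dtype=float)
    cdf = ndtr((edges - center_px) / sigma_px)
    return np.diff(cdf)


def render_movie(
    trajectories: Sequence[GroundTruthTrajectory],
    psf_sigma: float = 0.13,
    photons_per_spot: float = 400.0,
    background: float = 10.0,
    read_noise_sd: float = 2.0,
    offset: float = 100.0,
    field_size: tuple[int, int] = (64, 64),
    pixel_size: float = 0.16,
    frame_interval: float = 0.1,
    shot_noise: bool = True,
    n_frames: int | None = None,
    seed: int | None = None,
) -> MovieStack:
    """Render trajectories into a camera movie.

    Each active particle deposits ``photons_per_spot`` photons per frame
    as a symmetric Gaussian PSF of width ``psf_sigma`` (um), integrated
    over each pixel. Photon counts (signal + uniform ``background``)
    receive Poisson shot noise when ``shot_noise``; Gaussian read noise
    of sd ``read_noise_sd`` and a constant camera ``offset`` are then
    added. Particles outside the field are clipped with a warning.
    """
    h, w = field_size
    if n_frames is None:
        n_frames = max((t.start_frame + t.n_frames for t in trajectories), default=1)
    rng = np.random.default_rng(seed)
    sigma_px = psf_sigma / pixel_size
    signal = np.zeros((n_frames, h, w), dtype=float)
    clipped = False
    for t in trajectories:
        for f, (x, y) in zip(t.frames, t.xy):
            if f >= n_frames:
                break
            # pixel (i, j) center sits at ((j+0.5)*px, (i+0.5)*px)
            cx = x / pixel_size
            cy = y / pixel_size
            if not (0 <= cx <= w and 0 <= cy <= h):
                clipped = True
            r = max(3, int(math.ceil(4 * sigma_px)))
            jlo = max(0, int(math.floor(cx)) - r)
            jhi = min(w, int(math.floor(cx)) + r + 1)
            ilo = max(0, int(math.floor(cy)) - r)
            ihi = min(h, int(math.floor(cy)) + r + 1)
            if jlo >= jhi or ilo >= ihi:
                continue
            gx = _integrated_psf(cx, jlo, jhi, sigma_px)
            gy = _integrated_psf(cy, ilo, ihi, sigma_px)
            signal[f, ilo:ihi, jlo:jhi] += photons_per_spot * np.outer(gy, gx)
    if clipped:
        warnings.warn("some particle positions fall outside the field; "
                      "their intensity is clipped", stacklevel=2)
    expected = signal + background
    if shot_noise:
        counts = rng.poisson(expected).astype(float)
    else:
        counts = expected
    if read_noise_sd > 0:
        counts = counts + rng.normal(0.0, read_noise_sd, size=counts.shape)
    frames = counts + offset
    return MovieStack(frames=frames, pixel_size=pixel_size,
                      frame_interval=frame_interval)


# ---------------------------------------------------------------------------
# cell images


def _rasterize(spec: CellShapeSpec, pixel_size: float,
               shape: tuple[int, int]) -> np.ndarray:
    h, w = shape
    jj, ii = np.meshgrid(np.arange(w), np.arange(h))
    x = (jj + 0.5) * pixel_size
    y = (ii + 0.5) * pixel_size
    cx, cy = spec.center
    c, s = math.cos(spec.orientation), math.sin(spec.orientation)
    u = c * (x - cx) + s * (y - cy)
    v = -s * (x - cx) + c * (y - cy)
    r = spec.width / 2.0
    if spec.shape == "sphere":
        return u ** 2 + v ** 2 <= r ** 2
    if spec.shape == "rod":
        return (np.abs(u) <= spec.length / 2.0) & (np.abs(v) <= r)
    half = (spec.length - spec.width) / 2.0
    du = np.maximum(np.abs(u) - half, 0.0)
    return du ** 2 + v ** 2 <= r ** 2


def simulate_cell_images(
    specs: Sequence[CellShapeSpec],
    pixel_size: float = 0.16,
    image_shape: tuple[int, int] = (256, 256),
    seed: int | None = None,
    max_retries: int = 50,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Rasterize non-overlapping cells into a label image.

    Specs without a fixed center are placed uniformly at random,
    re-sampling up to ``max_retries`` times on overlap (one blank pixel
    of separation is enforced); a spec with an explicit overlapping
    placement raises. Returns the uint16 label image and a ground-truth
    table (cell_id, shape, length_um, width_um, lw_ratio).
    """
    rng = np.random.default_rng(seed)
    h, w = image_shape
    labels = np.zeros(image_shape, dtype=np.uint16)
    occupied = np.zeros(image_shape, dtype=bool)
    rows = []
    for k, given in enumerate(specs, start=1):
        given.validate()
        spec = dataclasses.replace(given)    # never mutate the caller's spec
        fixed = spec.center is not None
        placed = False
        for _ in range(1 if fixed else max_retries):
            if not fixed:
                m = spec.length / 2.0 + pixel_size
                spec.center = tuple(rng.uniform(
                    (m, m), (w * pixel_size - m, h * pixel_size - m)))
            mask = _rasterize(spec, pixel_size, image_shape)
            if not mask.any():
                raise ValueError(f"cell {k} rasterizes to an empty mask")
            if not (ndimage.binary_dilation(mask) & occupied).any():
                placed = True
                break
            if fixed:
                break
        if not placed:
            raise ValueError(f"could not place cell {k} without overlap")
        labels[mask] = k
        occupied |= mask
        rows.append((k, spec.shape, spec.length, spec.width,
                     spec.length / spec.width))
    truth = pd.DataFrame(
        rows, columns=["cell_id", "shape", "length_um", "width_um", "lw_ratio"])
    return labels, truth


def cells_intensity_image(
    labels: np.ndarray,
    foreground: float = 200.0,
    background: float = 20.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Turn a label image into a simple bright-cells-on-dark intensity image."""
    rng = np.random.default_rng(seed)
    img = np.where(labels > 0, foreground, background).astype(float)
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, size=img.shape)
    return img


# ---------------------------------------------------------------------------
# chromatograms


def simulate_chromatogram(spec: ChromatogramSpec, seed: int | None = None) -> Chromatogram:
    """Sum of Gaussian peaks on a linear baseline, uniformly sampled.

    ``signal(t) = offset + slope*t + sum_k area_k * N(t; center_k, sd_k)
    + Gaussian noise`` over the run window.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    n = int(round((spec.t_end - spec.t_start) * spec.sampling_rate)) + 1
    t = np.linspace(spec.t_start, spec.t_end, n)
    signal = spec.baseline_offset + spec.baseline_slope * t
    for p in spec.peaks:
        signal = signal + p.area * np.exp(
            -0.5 * ((t - p.center) / p.sd) ** 2) / (p.sd * math.sqrt(2 * math.pi))
    if spec.noise_sd > 0:
        signal = signal + rng.normal(0.0, spec.noise_sd, size=n)
    return Chromatogram(time=t, signal=signal, sample_id=spec.sample_id,
                        biomass_norm=spec.biomass_norm)
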