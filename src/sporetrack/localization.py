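"""Sub-pixel particle localization by symmetric 2D Gaussian fitting.

Candidate spots are local intensity maxima standing above the frame's
robust background by a signal-to-noise threshold; each candidate is then
refined by least-squares fitting of a symmetric Gaussian PSF, integrated
over the pixel area, plus a constant background over a small window.
The fitted center is the particle position.

Coordinate convention (shared across the package): the origin is the
top-left corner of the frame, x runs along columns, y along rows, and
the center of pixel ``(i, j)`` is at ``((j + 0.5) * pixel_size,
(i + 0.5) * pixel_size)``.

Fits are rejected (``fit_ok = False``) when the optimizer fails, the
fitted sigma leaves [0.5, 4] px, or the center leaves the fit window;
this implicitly discards blurry out-of-focus background objects (such
as fast cytoplasmic fluorophores), which do not fit a narrow PSF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from scipy.special import ndtr

from .movie import MovieStack

__all__ = ["Localization", "detect_spots", "fit_gaussian_2d", "localize_movie"]

SIGMA_BOUNDS_PX = (0.5, 4.0)


@dataclass
class Localization:
    """One fitted particle position in one frame."""

    frame_index: int
    x: float                    # um
    y: float                    # um
    amplitude: float            # photons (total, integrated over the PSF)
    psf_sigma_fit: float        # um
    background: float
    fit_ok: bool
    residual: float             # RMS of fit residuals
    window_clipped: bool = False


def detect_spots(
    frame: np.ndarray,
    min_snr: float = 6.0,
    min_separation_px: int = 3,
) -> np.ndarray:
    """Candidate spot pixels: local maxima above background + SNR * noise.

    Background is the frame median and the noise scale is the median
    absolute deviation (scaled to Gaussian sd). Non-maximum suppression
    uses a square window of half-width ``min_separation_px``.

    Returns an ``(n, 2)`` integer array of (row, col) positions.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0 or not np.isfinite(frame).all():
        return np.empty((0, 2), dtype=int)
    bg = np.median(frame)
    noise = 1.4826 * np.median(np.abs(frame - bg))
    threshold = bg + min_snr * noise
    size = 2 * int(min_separation_px) + 1
    is_max = frame == ndimage.maximum_filter(frame, size=size, mode="nearest")
    cand = is_max & (frame > threshold)
    return np.argwhere(cand)


def _model(params, xc, yc):
    amp, x0, y0, sigma, bg = params
    gx = ndtr((xc + 0.5 - x0) / sigma) - ndtr((xc - 0.5 - x0) / sigma)
    gy = ndtr((yc + 0.5 - y0) / sigma) - ndtr((yc - 0.5 - y0) / sigma)
    return amp * gy[:, None] * gx[None, :] + bg


def fit_gaussian_2d(
    frame: np.ndarray,
    candidate: tuple[int, int],
    window_halfwidth_px: int = 3,
    pixel_size: float = 0.16,
    frame_index: int = 0,
) -> Localization:
    """Fit one spot with a pixel-integrated symmetric 2D Gaussian.

    The model is ``amplitude * G(x - x0) * G(y - y0) + background``
    where G is a unit Gaussian of width sigma integrated over each
    pixel, fitted by least squares over a ``(2h+1)**2`` window centered
    on the candidate pixel. Windows clipped by the frame edge are fitted
    over the reduced window and flagged.
    """
    frame = np.asarray(frame, dtype=float)
    h, w = frame.shape
    r0, c0 = int(candidate[0]), int(candidate[1])
    hw = int(window_halfwidth_px)
    ilo, ihi = max(0, r0 - hw), min(h, r0 + hw + 1)
    jlo, jhi = max(0, c0 - hw), min(w, c0 + hw + 1)
    clipped = (ihi - ilo != 2 * hw + 1) or (jhi - jlo != 2 * hw + 1)
    win = frame[ilo:ihi, jlo:jhi]
    # coordinates of pixel centers within the window, in pixel units
    xc = np.arange(jlo, jhi) + 0.5
    yc = np.arange(ilo, ihi) + 0.5

    if np.ptp(win) == 0:
        # structureless window: nothing to fit
        return Localization(
            frame_index=frame_index, x=(c0 + 0.5) * pixel_size,
            y=(r0 + 0.5) * pixel_size, amplitude=0.0,
            psf_sigma_fit=0.0, background=float(win.mean()),
            fit_ok=False, residual=0.0, window_clipped=clipped)

    bg0 = float(win.min())
    amp0 = max(float(win.sum() - bg0 * win.size), 1e-6)
    weights = np.clip(win - bg0, 0, None)
    wsum = weights.sum()
    if wsum > 0:
        x_init = float((weights.sum(axis=0) * xc).sum() / wsum)
        y_init = float((weights.sum(axis=1) * yc).sum() / wsum)
    else:
        x_init, y_init = c0 + 0.5, r0 + 0.5
    p0 = np.array([amp0, x_init, y_init, 1.2, bg0])

    def resid(p):
        return (_model(p, xc, yc) - win).ravel()

    ok = True
    try:
        sol = optimize.least_squares(
            resid, p0,
            bounds=([0.0, xc[0] - 1, yc[0] - 1, 0.2, -np.inf],
                    [np.inf, xc[-1] + 1, yc[-1] + 1, 8.0, np.inf]),
            method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=300,
        )
        amp, x0, y0, sigma, bg = sol.x
        if not sol.success:
            ok = False
    except Exception:
        amp, x0, y0, sigma, bg = p0
        ok = False
    rms = float(np.sqrt(np.mean(resid([amp, x0, y0, sigma, bg]) ** 2)))
    if not (SIGMA_BOUNDS_PX[0] <= sigma <= SIGMA_BOUNDS_PX[1]):
        ok = False
    if not (xc[0] - 0.5 <= x0 <= xc[-1] + 0.5 and yc[0] - 0.5 <= y0 <= yc[-1] + 0.5):
        ok = False
    if amp <= 0:
        ok = False
    return Localization(
        frame_index=frame_index,
        x=float(x0 * pixel_size),
        y=float(y0 * pixel_size),
        amplitude=float(amp),
        psf_sigma_fit=float(sigma * pixel_size),
        background=float(bg),
        fit_ok=ok,
        residual=rms,
        window_clipped=clipped,
    )


def localize_movie(
    movie: MovieStack,
    min_snr: float = 6.0,
    min_separation_px: int = 3,
    window_halfwidth_px: int = 3,
) -> pd.DataFrame:
    """Detect and fit all spots in every frame.

    Returns a localizations table (frame, x_um, y_um, amplitude,
    sigma_px, background, residual) keeping only successful fits;
    deterministic for a fixed input movie.
    """
    rows = []
    for f in range(movie.n_frames):
        frame = movie.frames[f]
        for cand in detect_spots(frame, min_snr=min_snr,
                                 min_separation_px=min_separation_px):
            loc = fit_gaussian_2d(frame, cand, window_halfwidth_px,
                                  pixel_size=movie.pixel_size, frame_index=f)
            if loc.fit_ok:
                rows.append((f, loc.x, loc.y, loc.amplitude,
                             loc.psf_sigma_fit / movie.pixel_size,
                             loc.background, loc.residual))
    return pd.DataFrame(
        rows, columns=["frame", "x_um", "y_um", "amplitude",
                       "sigma_px", "background", "residual"])
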