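"""Movie container and TIFF I/O.

A :class:`MovieStack` is the in-memory form of a single-channel
fluorescence time-lapse: a ``(T, H, W)`` array plus the two pieces of
calibration metadata every downstream step needs, the physical pixel
size (default 0.16 um, a typical EMCCD effective pixel at 100x) and
the frame interval (default 0.1 s, i.e. 10 Hz acquisition).

On disk a movie is a multi-page TIFF with a small YAML sidecar
(``<stem>.meta.yaml``) carrying ``pixel_size_um`` and
``frame_interval_s``; TIFF tags are deliberately not used for
calibration so the sidecar stays human-editable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

__all__ = ["MovieStack", "read_movie", "write_movie"]


@dataclass
class MovieStack:
    """Time-ordered stack of single-channel frames with calibration.

    Parameters
    ----------
    frames
        Array of shape ``(T, H, W)``; any numeric dtype.
    pixel_size
        Physical size of one pixel, um.
    frame_interval
        Time between consecutive frames, s.
    """

    frames: np.ndarray
    pixel_size: float = 0.16
    frame_interval: float = 0.1
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")
        if not (self.pixel_size > 0):
            raise ValueError("pixel_size must be > 0")
        if not (self.frame_interval > 0):
            raise ValueError("frame_interval must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(H, W) of a single frame."""
        return self.frames.shape[1:]

    def __len__(self) -> int:
        return self.n_frames

    def __getitem__(self, i: int) -> np.ndarray:
        return self.frames[i]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix("").with_suffix(".meta.yaml")


def write_movie(movie: MovieStack, path: str | Path) -> Path:
    """Write a multi-page TIFF plus a YAML metadata sidecar."""
    path = Path(path)
    frames = movie.frames
    if frames.dtype.kind == "f":
        frames = np.clip(np.rint(frames), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, frames)
    meta = {
        "pixel_size_um": float(movie.pixel_size),
        "frame_interval_s": float(movie.frame_interval),
    }
    meta.update(movie.meta)
    sidecar = _sidecar_path(path)
    sidecar.write_text(yaml.safe_dump(meta, sort_keys=True))
    return path


def read_movie(path: str | Path) -> MovieStack:
    """Read a multi-page TIFF written by :func:`write_movie`.

    Calibration comes from the sidecar when present; otherwise the
    10 Hz / 160 nm defaults apply.
    """
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    sidecar = _sidecar_path(path)
    meta: dict = {}
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text()) or {}
    return MovieStack(
        frames=frames,
        pixel_size=float(meta.get("pixel_size_um", 0.16)),
        frame_interval=float(meta.get("frame_interval_s", 0.1)),
        meta={k: v for k, v in meta.items()
              if k not in ("pixel_size_um", "frame_interval_s")},
    )
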