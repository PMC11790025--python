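"""ROI-grid fluorescence extraction from time-lapse movies.

A recording is reduced to an ROI-by-frame table of mean fluorescence:
the field of view is tiled with non-overlapping square ROIs (56 x 56 px,
i.e. 11 x 11 um at the default pixel size, slightly larger than one
cell), and the mean pixel intensity inside each ROI is taken at every
frame.  All downstream event and wave analysis operates on this table.

Conventions
-----------
* Pixel indices are 0-based; an ROI box is the half-open square
  ``[x0, x0 + size) x [y0, y0 + size)``.
* The tiling is anchored at the top-left corner; partial tiles at the
  right/bottom edges are dropped, so a ``1400 x 728`` frame yields
  ``25 * 13 = 325`` ROIs of 56 px.
* Physical ROI coordinates are box centers in micrometres.
* The time axis is ``t_j = j * frame_interval`` with frame 0 at t = 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

#: default ROI edge length in pixels (11 um at the default pixel size)
DEFAULT_ROI_SIZE_PX = 56
#: default pixel size in um/px (56 px spans 11 um)
DEFAULT_PIXEL_SIZE = 11.0 / 56.0


@dataclass(frozen=True)
class Movie:
    """A single-channel fluorescence stack with physical calibration.

    Parameters
    ----------
    data
        Intensity array of shape ``(n_frames, height, width)``.
    pixel_size
        Lateral calibration in um/px.
    frame_interval
        Time between successive frames in seconds.
    """

    data: np.ndarray
    pixel_size: float = DEFAULT_PIXEL_SIZE
    frame_interval: float = 2.0

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"movie must be 3-D (frames, h, w); got shape {data.shape}")
        if data.shape[0] < 2:
            raise ValueError("movie needs at least 2 frames")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be positive")
        object.__setattr__(self, "data", data)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def height(self) -> int:
        return self.data.shape[1]

    @property
    def width(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


@dataclass(frozen=True)
class RoiGrid:
    """A row-major tiling of square ROIs over a frame."""

    roi_size_px: int
    pixel_size: float
    n_cols: int
    n_rows: int
    width_px: int
    height_px: int

    @property
    def n_rois(self) -> int:
        return self.n_cols * self.n_rows

    @property
    def boxes(self) -> np.ndarray:
        """Top-left ``(x0, y0)`` pixel of each box, row-major order."""
        cols = np.arange(self.n_cols) * self.roi_size_px
        rows = np.arange(self.n_rows) * self.roi_size_px
        xx, yy = np.meshgrid(cols, rows)
        return np.column_stack([xx.ravel(), yy.ravel()])

    @property
    def centers_um(self) -> np.ndarray:
        """Box centers in um, shape ``(n_rois, 2)`` as (x, y)."""
        half = self.roi_size_px / 2.0
        return (self.boxes + half) * self.pixel_size

    @property
    def pitch_um(self) -> float:
        """Center-to-center distance of adjacent ROIs in um."""
        return self.roi_size_px * self.pixel_size

    def roi_index(self, x_um: float, y_um: float) -> int:
        """ROI containing the physical point ``(x_um, y_um)``.

        Raises ``ValueError`` for points outside the tiled area.
        """
        col = int(np.floor(x_um / self.pixel_size / self.roi_size_px))
        row = int(np.floor(y_um / self.pixel_size / self.roi_size_px))
        if not (0 <= col < self.n_cols and 0 <= row < self.n_rows):
            raise ValueError(f"point ({x_um}, {y_um}) um lies outside the ROI grid")
        return row * self.n_cols + col

    def to_json(self, path) -> None:
        payload = {
            "roi_size_px": self.roi_size_px,
            "pixel_size": self.pixel_size,
            "n_cols": self.n_cols,
            "n_rows": self.n_rows,
            "width_px": self.width_px,
            "height_px": self.height_px,
            "boxes": self.boxes.tolist(),
            "centers_um": self.centers_um.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "RoiGrid":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            roi_size_px=d["roi_size_px"],
            pixel_size=d["pixel_size"],
            n_cols=d["n_cols"],
            n_rows=d["n_rows"],
            width_px=d["width_px"],
            height_px=d["height_px"],
        )


@dataclass
class TraceMatrix:
    """ROI-by-frame mean fluorescence bound to a grid and time base."""

    values: np.ndarray  # (n_rois, n_frames)
    grid: RoiGrid
    frame_interval: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("trace matrix must be 2-D (rois, frames)")
        if self.values.shape[0] != self.grid.n_rois:
            raise ValueError(
                f"{self.values.shape[0]} rows but grid has {self.grid.n_rois} ROIs"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace matrix contains non-finite entries")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    @property
    def duration(self) -> float:
        return self.n_frames * self.frame_interval

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns roi, frame, time_s, F."""
        n_r, n_f = self.values.shape
        return pd.DataFrame(
            {
                "roi": np.repeat(np.arange(n_r), n_f),
                "frame": np.tile(np.arange(n_f), n_r),
                "time_s": np.tile(self.times, n_r),
                "F": self.values.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, grid: RoiGrid, frame_interval: float) -> "TraceMatrix":
        wide = df.pivot(index="roi", columns="frame", values="F").sort_index()
        return cls(values=wide.to_numpy(), grid=grid, frame_interval=frame_interval)


def make_roi_grid(
    width_px: int,
    height_px: int,
    roi_size_px: int = DEFAULT_ROI_SIZE_PX,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
) -> RoiGrid:
    """Tile a frame with non-overlapping square ROIs.

    The tiling starts at the top-left corner; partial tiles at the right
    and bottom edges are dropped, so the count is
    ``floor(width/size) * floor(height/size)``.
    """
    if roi_size_px <= 0:
        raise ValueError("roi_size_px must be positive")
    if roi_size_px > min(width_px, height_px):
        raise ValueError("roi_size_px exceeds the frame dimensions")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    return RoiGrid(
        roi_size_px=int(roi_size_px),
        pixel_size=float(pixel_size),
        n_cols=width_px // roi_size_px,
        n_rows=height_px // roi_size_px,
        width_px=int(width_px),
        height_px=int(height_px),
    )


def extract_traces(movie: Movie, grid: RoiGrid) -> TraceMatrix:
    """Mean fluorescence of every ROI at every frame.

    Entry ``(i, j)`` is the arithmetic mean of the ``roi_size**2`` pixels
    of box *i* in frame *j*.
    """
    if grid.width_px != movie.width or grid.height_px != movie.height:
        raise ValueError(
            f"grid built for {grid.width_px}x{grid.height_px} px but movie is "
            f"{movie.width}x{movie.height} px"
        )
    s = grid.roi_size_px
    cropped = movie.data[:, : grid.n_rows * s, : grid.n_cols * s].astype(float)
    t = movie.n_frames
    block = cropped.reshape(t, grid.n_rows, s, grid.n_cols, s)
    means = block.mean(axis=(2, 4))  # (t, n_rows, n_cols)
    values = means.reshape(t, grid.n_rois).T
    return TraceMatrix(values=values, grid=grid, frame_interval=movie.frame_interval)


def read_movie(path, pixel_size: float, frame_interval: float) -> Movie:
    """Load a single-channel multi-page TIFF as a :class:`Movie`."""
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None, ...]
    return Movie(data=data, pixel_size=pixel_size, frame_interval=frame_interval)


def write_movie(path, movie: Movie) -> None:
    """Write a movie as a 16-bit multi-page TIFF (values clipped to uint16)."""
    data = np.clip(np.round(movie.data), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(path, data, photometric="minisblack")
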