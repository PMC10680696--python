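"""Spatial data structures: windows, multitype point patterns, pixel rasters.

Coordinates are real-valued microns.  The observation window is a closed
axis-aligned rectangle; points on the boundary count as inside.  A
multitype point pattern is a set of located points each carrying a
categorical cell-type label.  A :class:`PixelImage` is a gridded surface
over the window used for spatial covariates (e.g. distance to the nearest
blood vessel) and predicted intensity maps.

Raster conventions: row index increases with y, column index with x;
lookups use the nearest-pixel convention (no interpolation), so covariates
are piecewise constant and binary masks stay binary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

DEFAULT_GRID = (128, 128)


@dataclass(frozen=True)
class Window:
    """Closed rectangular observation window, in microns."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float

    def __post_init__(self):
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError("window must satisfy x_max > x_min and y_max > y_min")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def diagonal(self) -> float:
        return float(np.hypot(self.width, self.height))

    def contains(self, x, y) -> np.ndarray:
        """Vectorized closed-rectangle membership test."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (
            (x >= self.x_min) & (x <= self.x_max)
            & (y >= self.y_min) & (y <= self.y_max)
        )


class MultitypePointPattern:
    """Typed cell locations in a rectangular window.

    Parameters
    ----------
    coords : (n, 2) array of x, y in microns
    types : length-n sequence of string labels
    window : Window
    type_set : optional explicit label ordering.  By default the ordering
        is first-appearance order of the labels, fixed thereafter
        (parameter matrices are indexed by it).  Labels are case-sensitive.
    """

    def __init__(self, coords, types, window: Window, type_set=None):
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        if coords.size == 0:
            coords = coords.reshape(0, 2)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValueError("coords must be an (n, 2) array")
        types = np.asarray([str(t) for t in types], dtype=object)
        if len(types) != len(coords):
            raise ValueError("coords and types must have the same length")
        inside = window.contains(coords[:, 0], coords[:, 1])
        if not np.all(inside):
            bad = int(np.flatnonzero(~inside)[0])
            raise ValueError(
                f"point {bad} at ({coords[bad, 0]}, {coords[bad, 1]}) lies "
                "outside the window"
            )
        if type_set is None:
            type_set = list(dict.fromkeys(types.tolist()))
        else:
            type_set = [str(t) for t in type_set]
            unknown = set(types.tolist()) - set(type_set)
            if unknown:
                raise ValueError(f"labels {sorted(unknown)} not in type_set")
        self.coords = coords
        self.types = types
        self.window = window
        self.type_set = type_set

    # -- basic queries ---------------------------------------------------
    @property
    def n_points(self) -> int:
        return len(self.coords)

    def __len__(self) -> int:
        return self.n_points

    def counts(self) -> dict:
        """Number of points per label in ``type_set``, including zeros."""
        return {t: int(np.sum(self.types == t)) for t in self.type_set}

    def type_indices(self) -> np.ndarray:
        """Integer label codes, indexed by position in ``type_set``."""
        lut = {t: i for i, t in enumerate(self.type_set)}
        return np.array([lut[t] for t in self.types], dtype=np.intp)

    def points_of_type(self, label: str) -> np.ndarray:
        if label not in self.type_set:
            raise ValueError(f"unknown type label {label!r}")
        return self.coords[self.types == label]

    # -- derived patterns ------------------------------------------------
    def subset(self, keep_types) -> "MultitypePointPattern":
        """Pattern restricted to the given labels (type_set order kept)."""
        keep = [t for t in self.type_set if t in set(keep_types)]
        mask = np.isin(self.types, keep)
        return MultitypePointPattern(
            self.coords[mask], self.types[mask], self.window, type_set=keep
        )

    def add_point(self, x: float, y: float, label: str) -> "MultitypePointPattern":
        type_set = self.type_set if label in self.type_set else self.type_set + [label]
        return MultitypePointPattern(
            np.vstack([self.coords, [[x, y]]]),
            np.append(self.types, label),
            self.window,
            type_set=type_set,
        )

    def remove_point(self, index: int) -> "MultitypePointPattern":
        return MultitypePointPattern(
            np.delete(self.coords, index, axis=0),
            np.delete(self.types, index),
            self.window,
            type_set=self.type_set,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"x": self.coords[:, 0], "y": self.coords[:, 1], "type": self.types}
        )

    def __repr__(self) -> str:
        return (
            f"MultitypePointPattern(n={self.n_points}, "
            f"types={self.type_set}, window=[{self.window.x_min}, "
            f"{self.window.x_max}]x[{self.window.y_min}, {self.window.y_max}])"
        )


# -- file I/O -----------------------------------------------------------


def read_pattern_csv(path, window="auto") -> MultitypePointPattern:
    """Read a point pattern from a CSV with header columns ``x,y,type``.

    Extra columns (e.g. ``image_id``, ``patient_id``) are ignored here and
    consumed by the cohort layer.  With ``window="auto"`` the window is the
    bounding box of the points (error on an empty file, where no bounding
    box exists).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in ("x", "y", "type") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    for col in ("x", "y"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() & df[col].notna()]
        if len(bad) or (df[col].isna().any()):
            row = int((df.index[df[col].isna()] if df[col].isna().any() else bad)[0])
            raise ValueError(f"{path}: non-numeric or missing {col!r} at data row {row}")
        df[col] = vals
    if isinstance(window, str) and window == "auto":
        if len(df) == 0:
            raise ValueError(f"{path}: empty file; an explicit window is required")
        window = Window(
            float(df["x"].min()), float(df["x"].max()),
            float(df["y"].min()), float(df["y"].max()),
        )
    inside = window.contains(df["x"].to_numpy(), df["y"].to_numpy())
    if not np.all(inside):
        row = int(np.flatnonzero(~inside)[0])
        raise ValueError(
            f"{path}: point at data row {row} "
            f"({df['x'].iloc[row]}, {df['y'].iloc[row]}) is outside the window"
        )
    return MultitypePointPattern(
        df[["x", "y"]].to_numpy(float), df["type"].astype(str).tolist(), window
    )


def write_pattern_csv(pattern: MultitypePointPattern, path, extra_columns=None) -> None:
    """Write ``x,y,type`` CSV (full float precision round trip)."""
    df = pattern.to_dataframe()
    if extra_columns:
        for name, value in extra_columns.items():
            df[name] = value
    df.to_csv(path, index=False, float_format="%.17g")


# -- pixel rasters ------------------------------------------------------


@dataclass
class PixelImage:
    """Gridded spatial surface over a window.

    ``values`` has shape ``(n_rows, n_cols)``; row 0 is the bottom
    (smallest y) strip of the window.
    """

    window: Window
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("raster values must be finite")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def pixel_width(self) -> float:
        return self.window.width / self.n_cols

    @property
    def pixel_height(self) -> float:
        return self.window.height / self.n_rows

    def pixel_centers(self):
        """(xs, ys) 1-D arrays of pixel-center coordinates."""
        xs = self.window.x_min + (np.arange(self.n_cols) + 0.5) * self.pixel_width
        ys = self.window.y_min + (np.arange(self.n_rows) + 0.5) * self.pixel_height
        return xs, ys

    def lookup(self, x, y):
        """Nearest-pixel value(s) at location(s) inside the window."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        inside = self.window.contains(x, y)
        if not np.all(inside):
            raise ValueError("location outside the raster window")
        col = np.clip(
            ((x - self.window.x_min) / self.pixel_width).astype(int), 0, self.n_cols - 1
        )
        row = np.clip(
            ((y - self.window.y_min) / self.pixel_height).astype(int), 0, self.n_rows - 1
        )
        out = self.values[row, col]
        return float(out) if out.ndim == 0 else out


def lookup(image: PixelImage, location) -> float:
    """Value of the pixel containing ``location`` (nearest-pixel convention)."""
    x, y = location
    return image.lookup(x, y)


def _grid_centers(window: Window, grid) -> np.ndarray:
    n_rows, n_cols = grid
    xs = window.x_min + (np.arange(n_cols) + 0.5) * window.width / n_cols
    ys = window.y_min + (np.arange(n_rows) + 0.5) * window.height / n_rows
    gx, gy = np.meshgrid(xs, ys)
    return np.column_stack([gx.ravel(), gy.ravel()])


def distance_map(pattern: MultitypePointPattern, ref_type: str,
                 grid=DEFAULT_GRID) -> PixelImage:
    """Distance (microns) from each pixel center to the nearest point of
    ``ref_type``.

    This builds the "distance to nearest blood vessel"-style spatial
    covariate when ``ref_type`` is the vasculature label.
    """
    ref = pattern.points_of_type(ref_type)
    if len(ref) == 0:
        raise ValueError(
            f"no points of type {ref_type!r}: distance covariate undefined"
        )
    centers = _grid_centers(pattern.window, grid)
    dist, _ = cKDTree(ref).query(centers)
    return PixelImage(pattern.window, dist.reshape(grid))


def empty_region_mask(pattern: MultitypePointPattern, grid=DEFAULT_GRID,
                      threshold: float = 30.0) -> PixelImage:
    """Binary mask of regions devoid of cells.

    A pixel is 1 iff the distance from its center to the nearest cell of
    *any* type exceeds ``threshold`` (microns).  Default threshold 30 µm,
    the short-range interaction radius.
    """
    if pattern.n_points == 0:
        raise ValueError("empty pattern: empty-region mask undefined")
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    centers = _grid_centers(pattern.window, grid)
    dist, _ = cKDTree(pattern.coords).query(centers)
    return PixelImage(pattern.window, (dist > threshold).astype(float).reshape(grid))


# -- raster file round trip ---------------------------------------------


def save_raster(image: PixelImage, path) -> None:
    """Write a raster as a plain-text grid plus a JSON sidecar.

    The sidecar ``<path>.json`` records the window and grid shape; values
    are written with 17 significant digits so the round trip is bit-exact.
    """
    path = Path(path)
    np.savetxt(path, image.values, fmt="%.17g")
    sidecar = {
        "window": [image.window.x_min, image.window.x_max,
                   image.window.y_min, image.window.y_max],
        "shape": [image.n_rows, image.n_cols],
    }
    path.with_name(path.name + ".json").write_text(json.dumps(sidecar))


def load_raster(path) -> PixelImage:
    path = Path(path)
    sidecar = json.loads(path.with_name(path.name + ".json").read_text())
    values = np.loadtxt(path, ndmin=2)
    if list(values.shape) != sidecar["shape"]:
        raise ValueError(f"{path}: grid shape does not match sidecar")
    return PixelImage(Window(*sidecar["window"]), values)
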