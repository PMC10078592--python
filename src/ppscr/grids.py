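"""Rectangular window grids for habitat and detection regions.

A study region is tiled by non-overlapping axis-aligned rectangular windows,
each carrying a vector of spatial covariates that is constant within the
window.  Two grids appear in a spatial capture-recapture (SCR) analysis:

* the *habitat* grid, covering the full region where activity centers may
  lie (it tiles its bounding rectangle exactly), and
* the *detection* grid, covering the searched sub-region where detections
  can occur.  It need not tile the habitat extent — the uncovered margin is
  the buffer — but its windows must not overlap each other.

Coordinates are continuous planar kilometres in a projected system;
latitude/longitude input is not supported.

Window membership is half-open, ``[lower, upper)`` in each coordinate, with
points on the global upper boundary absorbed by the last window of the row
or column, so every point of the extent belongs to exactly one window.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("ppscr")

__all__ = [
    "Window",
    "WindowGrid",
    "GridError",
    "OutOfDomainError",
    "build_grid",
    "locate_window",
    "read_grid",
    "write_grid",
]


class GridError(ValueError):
    """Invalid grid geometry or malformed grid input."""


class OutOfDomainError(GridError):
    """A query point lies outside the grid extent."""


@dataclass(frozen=True)
class Window:
    """One rectangular window with its covariate vector."""

    lower: tuple[float, float]
    upper: tuple[float, float]
    covariates: np.ndarray

    def __post_init__(self) -> None:
        if not (self.upper[0] > self.lower[0] and self.upper[1] > self.lower[1]):
            raise GridError(f"window upper {self.upper} must exceed lower {self.lower}")

    @property
    def area(self) -> float:
        return (self.upper[0] - self.lower[0]) * (self.upper[1] - self.lower[1])

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return (self.lower[0], self.lower[1], self.upper[0], self.upper[1])

    @property
    def center(self) -> tuple[float, float]:
        return (
            0.5 * (self.lower[0] + self.upper[0]),
            0.5 * (self.lower[1] + self.upper[1]),
        )


@dataclass
class _RegularLayout:
    """Lattice structure of a grid whose windows form a regular rectangular
    array, enabling O(1) point location and separable kernel integrals."""

    origin: tuple[float, float]
    resolution: tuple[float, float]
    shape: tuple[int, int]  # (nx, ny)
    index_map: np.ndarray = field(repr=False)  # (nx, ny) -> window index


class WindowGrid:
    """Ordered collection of non-overlapping rectangular windows.

    Parameters
    ----------
    lower, upper : (H, 2) arrays
        Window corner coordinates in km.
    covariates : (H, C) array
        One row per window, one column per named covariate.
    covariate_names : sequence of str
    role : "habitat" or "detection"
        Habitat grids must tile their bounding rectangle exactly; detection
        grids may leave parts of it uncovered (the buffer) but must still be
        overlap-free.
    """

    def __init__(
        self,
        lower: np.ndarray,
        upper: np.ndarray,
        covariates: np.ndarray | None = None,
        covariate_names: tuple[str, ...] = (),
        role: str = "habitat",
        validate: bool = True,
    ) -> None:
        self.lower = np.atleast_2d(np.asarray(lower, dtype=float))
        self.upper = np.atleast_2d(np.asarray(upper, dtype=float))
        if self.lower.shape != self.upper.shape or self.lower.shape[1] != 2:
            raise GridError("lower/upper must both be (H, 2) arrays")
        n = self.lower.shape[0]
        if covariates is None:
            covariates = np.zeros((n, len(covariate_names)))
        self.covariates = np.asarray(covariates, dtype=float).reshape(n, -1)
        self.covariate_names = tuple(covariate_names)
        if self.covariates.shape[1] != len(self.covariate_names):
            raise GridError(
                f"covariate matrix has {self.covariates.shape[1]} columns but "
                f"{len(self.covariate_names)} names were given"
            )
        if role not in ("habitat", "detection"):
            raise GridError(f"unknown grid role {role!r}")
        self.role = role
        if np.any(self.upper <= self.lower):
            bad = int(np.argmax(np.any(self.upper <= self.lower, axis=1)))
            raise GridError(f"window {bad} has upper <= lower")
        self._layout = self._infer_regular_layout()
        if validate:
            self._validate()

    # -- basic properties ---------------------------------------------------

    @property
    def n_windows(self) -> int:
        return self.lower.shape[0]

    @property
    def areas(self) -> np.ndarray:
        return np.prod(self.upper - self.lower, axis=1)

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """Bounding rectangle (xmin, ymin, xmax, ymax)."""
        return (
            float(self.lower[:, 0].min()),
            float(self.lower[:, 1].min()),
            float(self.upper[:, 0].max()),
            float(self.upper[:, 1].max()),
        )

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.lower + self.upper)

    @property
    def is_regular(self) -> bool:
        return self._layout is not None

    @property
    def windows(self) -> list[Window]:
        return [
            Window(tuple(self.lower[h]), tuple(self.upper[h]), self.covariates[h])
            for h in range(self.n_windows)
        ]

    def __len__(self) -> int:
        return self.n_windows

    def __repr__(self) -> str:
        return (
            f"WindowGrid(role={self.role!r}, n_windows={self.n_windows}, "
            f"extent={self.extent}, covariates={list(self.covariate_names)})"
        )

    # -- structure ----------------------------------------------------------

    def _infer_regular_layout(self) -> _RegularLayout | None:
        xs = np.unique(self.lower[:, 0])
        ys = np.unique(self.lower[:, 1])
        nx, ny = len(xs), len(ys)
        if nx * ny != self.n_windows:
            return None
        if nx > 1 and not np.allclose(np.diff(xs), xs[1] - xs[0], rtol=1e-9, atol=1e-9):
            return None
        if ny > 1 and not np.allclose(np.diff(ys), ys[1] - ys[0], rtol=1e-9, atol=1e-9):
            return None
        rx = xs[1] - xs[0] if nx > 1 else self.upper[0, 0] - self.lower[0, 0]
        ry = ys[1] - ys[0] if ny > 1 else self.upper[0, 1] - self.lower[0, 1]
        if not (
            np.allclose(self.upper[:, 0] - self.lower[:, 0], rx, rtol=1e-9)
            and np.allclose(self.upper[:, 1] - self.lower[:, 1], ry, rtol=1e-9)
        ):
            return None
        ix = np.rint((self.lower[:, 0] - xs[0]) / rx).astype(int)
        iy = np.rint((self.lower[:, 1] - ys[0]) / ry).astype(int)
        if not (
            np.allclose(self.lower[:, 0], xs[0] + ix * rx, atol=1e-9 * max(rx, 1.0))
            and np.allclose(self.lower[:, 1], ys[0] + iy * ry, atol=1e-9 * max(ry, 1.0))
        ):
            return None
        index_map = np.full((nx, ny), -1, dtype=int)
        index_map[ix, iy] = np.arange(self.n_windows)
        if np.any(index_map < 0):
            return None
        return _RegularLayout(
            origin=(float(xs[0]), float(ys[0])),
            resolution=(float(rx), float(ry)),
            shape=(nx, ny),
            index_map=index_map,
        )

    def _validate(self) -> None:
        # pairwise overlap: open rectangles must be disjoint (tolerance
        # absorbs floating-point noise in abutting edges)
        lo, up = self.lower, self.upper
        tol = 1e-9 * max(float(np.max(up - lo)), 1.0)
        ox = (lo[:, None, 0] < up[None, :, 0] - tol) & (
            up[:, None, 0] > lo[None, :, 0] + tol
        )
        oy = (lo[:, None, 1] < up[None, :, 1] - tol) & (
            up[:, None, 1] > lo[None, :, 1] + tol
        )
        overlap = ox & oy
        np.fill_diagonal(overlap, False)
        if overlap.any():
            i, j = map(int, np.argwhere(overlap)[0])
            raise GridError(f"windows {i} and {j} overlap")
        if self.role == "habitat":
            xmin, ymin, xmax, ymax = self.extent
            extent_area = (xmax - xmin) * (ymax - ymin)
            if not np.isclose(self.total_area, extent_area, rtol=1e-9):
                raise GridError(
                    "habitat grid does not tile its bounding rectangle "
                    f"(window area {self.total_area}, extent area {extent_area})"
                )

    # -- point location -----------------------------------------------------

    def locate(self, points: np.ndarray, strict: bool = True) -> np.ndarray:
        """Window index for each point; half-open membership with the global
        upper boundary absorbed by the last row/column.

        Points outside the grid get index -1 (``strict=False``) or raise
        :class:`OutOfDomainError`.  For a detection grid whose windows do
        not cover the whole bounding box, points in the gaps also count as
        outside.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        xmin, ymin, xmax, ymax = self.extent
        if self._layout is not None:
            (ox, oy) = self._layout.origin
            (rx, ry) = self._layout.resolution
            (nx, ny) = self._layout.shape
            ix = np.floor((pts[:, 0] - ox) / rx).astype(int)
            iy = np.floor((pts[:, 1] - oy) / ry).astype(int)
            # absorb the global upper boundary into the last row/column
            ix[(ix == nx) & (pts[:, 0] <= xmax)] = nx - 1
            iy[(iy == ny) & (pts[:, 1] <= ymax)] = ny - 1
            inside = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
            idx = np.full(len(pts), -1, dtype=int)
            idx[inside] = self._layout.index_map[ix[inside], iy[inside]]
        else:
            ge = (pts[:, None, 0] >= self.lower[None, :, 0]) & (
                pts[:, None, 1] >= self.lower[None, :, 1]
            )
            ltx = (pts[:, None, 0] < self.upper[None, :, 0]) | (
                (pts[:, None, 0] == self.upper[None, :, 0])
                & (self.upper[None, :, 0] == xmax)
            )
            lty = (pts[:, None, 1] < self.upper[None, :, 1]) | (
                (pts[:, None, 1] == self.upper[None, :, 1])
                & (self.upper[None, :, 1] == ymax)
            )
            member = ge & ltx & lty
            idx = np.where(member.any(axis=1), member.argmax(axis=1), -1)
        if strict and np.any(idx < 0):
            bad = pts[np.argmax(idx < 0)]
            raise OutOfDomainError(f"point {tuple(bad)} is outside the grid")
        if np.asarray(points).ndim == 1:
            return idx[0]
        return idx

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points lying in some window of the grid."""
        idx = self.locate(points, strict=False)
        return np.atleast_1d(idx) >= 0


def build_grid(
    extent: tuple[float, float, float, float],
    resolution: float | tuple[float, float],
    covariates: pd.DataFrame | np.ndarray | None = None,
    covariate_names: tuple[str, ...] | None = None,
    role: str = "habitat",
) -> WindowGrid:
    """Tile ``extent`` = (xmin, ymin, xmax, ymax) with square/rectangular
    windows of the given resolution (km), in row-major order: window index
    ``h = iy * nx + ix`` with x varying fastest.

    ``covariates`` may be a DataFrame (optionally indexed / keyed by a
    ``window_id`` column) or a plain (H, C) array.  Missing rows are an
    error naming the window.
    """
    xmin, ymin, xmax, ymax = map(float, extent)
    rx, ry = (resolution, resolution) if np.isscalar(resolution) else resolution
    if rx <= 0 or ry <= 0:
        raise GridError("resolution must be positive")
    nxf, nyf = (xmax - xmin) / rx, (ymax - ymin) / ry
    nx, ny = int(round(nxf)), int(round(nyf))
    if nx < 1 or ny < 1 or not (
        np.isclose(nxf, nx, atol=1e-9) and np.isclose(nyf, ny, atol=1e-9)
    ):
        raise GridError(
            f"extent sides ({xmax - xmin}, {ymax - ymin}) are not positive "
            f"multiples of resolution ({rx}, {ry})"
        )
    iy, ix = np.divmod(np.arange(nx * ny), nx)
    lower = np.column_stack([xmin + ix * rx, ymin + iy * ry])
    upper = lower + [rx, ry]

    n = nx * ny
    if covariates is None:
        cov = None
        names: tuple[str, ...] = tuple(covariate_names or ())
        if names:
            raise GridError("covariate names given without covariate values")
    elif isinstance(covariates, pd.DataFrame):
        df = covariates
        if "window_id" in df.columns:
            df = df.set_index("window_id")
        names = tuple(covariate_names or df.columns)
        missing = sorted(set(range(n)) - set(int(i) for i in df.index))
        if missing:
            raise GridError(f"covariate table is missing window {missing[0]}")
        cov = df.loc[np.arange(n), list(names)].to_numpy(dtype=float)
    else:
        cov = np.asarray(covariates, dtype=float).reshape(n, -1)
        names = tuple(
            covariate_names or (f"cov{i}" for i in range(cov.shape[1]))
        )
    grid = WindowGrid(lower, upper, cov, names, role=role)
    logger.info(
        "built %s grid: %d windows (%dx%d) over extent %s",
        role, grid.n_windows, nx, ny, grid.extent,
    )
    return grid


def locate_window(grid: WindowGrid, point) -> int:
    """Index of the window containing ``point`` (raises if outside)."""
    return int(grid.locate(np.asarray(point, dtype=float)))


# -- I/O ---------------------------------------------------------------------

_CSV_FIXED = ["window_id", "xmin", "ymin", "xmax", "ymax"]


def write_grid(grid: WindowGrid, path, format: str = "csv") -> None:
    if format == "csv":
        df = pd.DataFrame(
            {
                "window_id": np.arange(grid.n_windows),
                "xmin": grid.lower[:, 0],
                "ymin": grid.lower[:, 1],
                "xmax": grid.upper[:, 0],
                "ymax": grid.upper[:, 1],
            }
        )
        for j, name in enumerate(grid.covariate_names):
            df[name] = grid.covariates[:, j]
        df.to_csv(path, index=False)
    elif format == "geojson":
        features = []
        for h in range(grid.n_windows):
            (x0, y0), (x1, y1) = grid.lower[h], grid.upper[h]
            props = {"window_id": int(h)}
            props.update(
                {
                    name: float(grid.covariates[h, j])
                    for j, name in enumerate(grid.covariate_names)
                }
            )
            features.append(
                {
                    "type": "Feature",
                    "geometry": {
                        "type": "Polygon",
                        "coordinates": [
                            [[x0, y0], [x1, y0], [x1, y1], [x0, y1], [x0, y0]]
                        ],
                    },
                    "properties": props,
                }
            )
        with open(path, "w") as fh:
            json.dump(
                {
                    "type": "FeatureCollection",
                    "features": features,
                    "properties": {"role": grid.role},
                },
                fh,
            )
    else:
        raise GridError(f"unknown grid format {format!r}")
    logger.info("wrote %s grid (%d windows) to %s", grid.role, grid.n_windows, path)


def read_grid(path, format: str = "csv", role: str = "habitat") -> WindowGrid:
    """Read a grid written by :func:`write_grid`; ``write ∘ read`` round-trips
    exactly, preserving window order."""
    if format == "csv":
        df = pd.read_csv(path)
        missing = [c for c in _CSV_FIXED if c not in df.columns]
        if missing:
            raise GridError(f"grid CSV {path} lacks columns {missing}")
        df = df.sort_values("window_id")
        names = tuple(c for c in df.columns if c not in _CSV_FIXED)
        grid = WindowGrid(
            df[["xmin", "ymin"]].to_numpy(float),
            df[["xmax", "ymax"]].to_numpy(float),
            df[list(names)].to_numpy(float) if names else None,
            names,
            role=role,
        )
    elif format == "geojson":
        from shapely.geometry import box, shape

        with open(path) as fh:
            gj = json.load(fh)
        if gj.get("type") != "FeatureCollection":
            raise GridError(f"{path}: expected a GeoJSON FeatureCollection")
        rows = []
        for k, feat in enumerate(gj.get("features", [])):
            try:
                geom = shape(feat["geometry"])
            except Exception as exc:  # malformed geometry
                raise GridError(f"{path}: feature {k} has malformed geometry: {exc}")
            rect = box(*geom.bounds)
            if geom.geom_type != "Polygon" or (
                geom.symmetric_difference(rect).area > 1e-9 * max(rect.area, 1.0)
            ):
                raise GridError(
                    f"{path}: feature {k} is not an axis-aligned rectangle"
                )
            props = dict(feat.get("properties", {}))
            wid = int(props.pop("window_id", k))
            rows.append((wid, geom.bounds, props))
        rows.sort(key=lambda r: r[0])
        names = tuple(rows[0][2].keys()) if rows else ()
        lower = np.array([[b[0], b[1]] for _, b, _ in rows])
        upper = np.array([[b[2], b[3]] for _, b, _ in rows])
        cov = np.array([[p[n] for n in names] for _, _, p in rows]) if names else None
        grid = WindowGrid(lower, upper, cov, names,
                          role=gj.get("properties", {}).get("role", role))
    else:
        raise GridError(f"unknown grid format {format!r}")
    logger.info("read %s grid (%d windows) from %s", grid.role, grid.n_windows, path)
    return grid
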