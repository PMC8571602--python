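"""Raster data model and neutral-landscape covariate generators.

A :class:`Grid` is a single rectangular raster layer with shared geometry
(rows, cols, cell size, lower-left origin).  Cell centers sit at
``(x0 + (j + 0.5) * cell_size, y0 + (i + 0.5) * cell_size)`` with 0-based
indices and row 0 at the *bottom* of the map.  A :class:`CovariateStack` is a
named set of co-registered grids — the environment every model in this
package sees.

The generators (`make_distance_grid`, `make_cluster_grid`,
`make_gaussian_field`, `make_correlated_gradient`) build the synthetic
landscapes used by the simulation study: distance-to-feature surfaces,
clustered binary habitat layers, an autocorrelated elevation field, and a
gradient constructed to have a prescribed Pearson correlation with another
layer.  All of them are pure functions of their parameters and a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "Grid",
    "CovariateStack",
    "make_distance_grid",
    "make_cluster_grid",
    "make_gaussian_field",
    "make_correlated_gradient",
    "rescale01",
    "read_raster",
    "write_raster",
]


@dataclass
class Grid:
    """One raster layer: a 2-D float array plus its geometry.

    Parameters
    ----------
    values
        Array of shape ``(nrows, ncols)``; row 0 is the bottom row.
    cell_size
        Side length of a (square) cell in map units.
    origin
        ``(x0, y0)`` of the lower-left corner of the lower-left cell.
    nodata_mask
        Optional boolean array, True where the cell holds no data.
    """

    values: np.ndarray
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    nodata_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise ValueError("grid values must be a non-empty 2-D array")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.nodata_mask is not None:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.values.shape:
                raise ValueError("nodata_mask shape mismatch")
        valid = self.values if self.nodata_mask is None else self.values[~self.nodata_mask]
        if valid.size and not np.all(np.isfinite(valid)):
            raise ValueError("grid values must be finite wherever data is present")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def geometry(self) -> tuple[int, int, float, tuple[float, float]]:
        return (self.nrows, self.ncols, self.cell_size, tuple(self.origin))

    def same_geometry(self, other: "Grid") -> bool:
        """Two grids are co-registered iff all geometry fields are equal."""
        return self.geometry() == other.geometry()

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) arrays of cell-center coordinates, shape (nrows, ncols)."""
        x0, y0 = self.origin
        xs = x0 + (np.arange(self.ncols) + 0.5) * self.cell_size
        ys = y0 + (np.arange(self.nrows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def cell_index(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices of the cells containing points (x, y).

        Points exactly on the upper/right edge are assigned to the last
        cell.  Raises if any point falls outside the grid extent.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        x0, y0 = self.origin
        j = np.floor((x - x0) / self.cell_size).astype(int)
        i = np.floor((y - y0) / self.cell_size).astype(int)
        # points on the far edge belong to the outermost cell
        j = np.where((j == self.ncols) & np.isclose(x, x0 + self.ncols * self.cell_size), self.ncols - 1, j)
        i = np.where((i == self.nrows) & np.isclose(y, y0 + self.nrows * self.cell_size), self.nrows - 1, i)
        bad = (i < 0) | (i >= self.nrows) | (j < 0) | (j >= self.ncols)
        if np.any(bad):
            idx = np.flatnonzero(bad)
            raise ValueError(f"points outside grid extent at indices {idx.tolist()[:20]}")
        return i, j

    def value_at(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        i, j = self.cell_index(x, y)
        return self.values[i, j]

    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid."""
        x0, y0 = self.origin
        return (x0, y0, x0 + self.ncols * self.cell_size, y0 + self.nrows * self.cell_size)


class CovariateStack:
    """Named, co-registered set of :class:`Grid` layers."""

    def __init__(self, layers: Mapping[str, Grid] | None = None):
        self._layers: dict[str, Grid] = {}
        if layers:
            for name, grid in layers.items():
                self.add(name, grid)

    def add(self, name: str, grid: Grid) -> None:
        if name in self._layers:
            raise ValueError(f"duplicate layer name {name!r}")
        if self._layers:
            ref_name = next(iter(self._layers))
            if not self._layers[ref_name].same_geometry(grid):
                raise ValueError(
                    f"layer {name!r} is not co-registered with layer {ref_name!r}: "
                    f"{grid.geometry()} vs {self._layers[ref_name].geometry()}"
                )
        self._layers[name] = grid

    def __getitem__(self, name: str) -> Grid:
        if name not in self._layers:
            raise KeyError(f"missing covariate layer {name!r}; have {sorted(self._layers)}")
        return self._layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self._layers

    def __iter__(self):
        return iter(self._layers)

    def __len__(self) -> int:
        return len(self._layers)

    @property
    def names(self) -> list[str]:
        return list(self._layers)

    @property
    def geometry_grid(self) -> Grid:
        """Any layer, as the carrier of the shared geometry."""
        return next(iter(self._layers.values()))

    def require(self, names: Iterable[str]) -> None:
        missing = [n for n in names if n not in self._layers]
        if missing:
            raise KeyError(f"missing covariate layers: {missing}; have {sorted(self._layers)}")

    def items(self):
        return self._layers.items()


def _like(ref: Grid | tuple, values: np.ndarray) -> Grid:
    if isinstance(ref, Grid):
        return Grid(values, ref.cell_size, ref.origin)
    nrows, ncols = ref[:2]
    cell_size = ref[2] if len(ref) > 2 else 1.0
    origin = ref[3] if len(ref) > 3 else (0.0, 0.0)
    if values.shape != (nrows, ncols):
        raise ValueError("shape mismatch")
    return Grid(values, cell_size, origin)


def _geometry(shape: Grid | tuple) -> Grid:
    """Accept a Grid or a (nrows, ncols[, cell_size[, origin]]) tuple."""
    if isinstance(shape, Grid):
        return shape
    nrows, ncols = shape[:2]
    cell_size = shape[2] if len(shape) > 2 else 1.0
    origin = shape[3] if len(shape) > 3 else (0.0, 0.0)
    return Grid(np.zeros((nrows, ncols)), cell_size, origin)


def make_distance_grid(shape: Grid | tuple, target) -> Grid:
    """Euclidean distance from each cell center to the nearest point of *target*.

    *target* is a point ``(x, y)``, or a polyline given as a sequence of
    vertices ``[(x1, y1), (x2, y2), ...]`` (a single segment is the 2-vertex
    case).  Distances are computed exactly per cell against every segment.
    """
    ref = _geometry(shape)
    target = np.atleast_2d(np.asarray(target, dtype=float))
    if target.size == 0:
        raise ValueError("distance target is empty")
    if target.shape[1] != 2:
        raise ValueError("target must be (x, y) pairs")
    X, Y = ref.cell_centers()
    px = X.ravel()
    py = Y.ravel()
    dist = np.full(px.shape, np.inf)
    if len(target) == 1:
        dist = np.hypot(px - target[0, 0], py - target[0, 1])
    else:
        for a, b in zip(target[:-1], target[1:]):
            ab = b - a
            denom = float(ab @ ab)
            if denom == 0.0:
                d = np.hypot(px - a[0], py - a[1])
            else:
                t = np.clip(((px - a[0]) * ab[0] + (py - a[1]) * ab[1]) / denom, 0.0, 1.0)
                d = np.hypot(px - (a[0] + t * ab[0]), py - (a[1] + t * ab[1]))
            dist = np.minimum(dist, d)
    return _like(ref, dist.reshape(ref.shape))


def make_cluster_grid(shape: Grid | tuple, proportion: float, clumping: float = 0.5,
                      seed: int | np.random.Generator = 0) -> Grid:
    """Clustered binary (0/1) landscape covering roughly *proportion* of cells.

    Modified-random-clusters style: a fraction *clumping* of cells is marked
    by percolation seeding, connected clusters are grown and assigned to the
    1-class largest-first until the target proportion is met, then remaining
    unassigned cells take the class of their nearest assigned neighbour.
    The realized fraction of 1s is within ±0.05 of *proportion*.
    """
    if not 0.0 <= proportion <= 1.0:
        raise ValueError("proportion must lie in [0, 1]")
    ref = _geometry(shape)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    nrows, ncols = ref.shape
    if proportion == 0.0:
        return _like(ref, np.zeros(ref.shape))
    if proportion == 1.0:
        return _like(ref, np.ones(ref.shape))

    # percolation seeding: mark cells, find 4-connected clusters
    marked = rng.random((nrows, ncols)) < clumping
    from scipy import ndimage

    labels, nlab = ndimage.label(marked)
    order = rng.permutation(np.arange(1, nlab + 1))
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, order)
    # split the *marked* cells by the target proportion; the nearest-neighbour
    # fill of unmarked cells then carries that proportion to the whole grid
    target = proportion * marked.sum()
    out = np.full((nrows, ncols), -1, dtype=int)  # -1 = unassigned
    filled = 0.0
    for lab, size in zip(order, sizes):
        cls = 1 if filled < target else 0
        out[labels == lab] = cls
        if cls == 1:
            filled += size
    # unmarked cells: nearest assigned neighbour
    unassigned = out < 0
    if np.any(unassigned):
        _, (ir, jc) = ndimage.distance_transform_edt(unassigned, return_indices=True)
        out = out[ir, jc]
    # nudge toward the target by flipping random boundary cells if badly off
    frac = out.mean()
    tol = 0.02
    attempts = 0
    while abs(frac - proportion) > tol and attempts < 50:
        need_ones = frac < proportion
        grown = ndimage.binary_dilation(out == 1) & (out == 0) if need_ones else \
            ndimage.binary_dilation(out == 0) & (out == 1)
        cand = np.flatnonzero(grown.ravel())
        if cand.size == 0:
            break
        n_flip = min(cand.size, max(1, int(abs(frac - proportion) * out.size)))
        flip = rng.choice(cand, size=n_flip, replace=False)
        out.ravel()[flip] = 1 if need_ones else 0
        frac = out.mean()
        attempts += 1
    return _like(ref, out.astype(float))


def make_gaussian_field(shape: Grid | tuple, mean: float = 0.0, sd: float = 1.0,
                        autocorr_range: float = 10.0,
                        seed: int | np.random.Generator = 0) -> Grid:
    """Spatially autocorrelated Gaussian random field.

    White noise is smoothed with a Gaussian kernel of scale
    ``autocorr_range`` (in cells) and restandardized to the requested mean
    and standard deviation, giving a stationary field with an approximately
    Gaussian correlogram.
    """
    if sd < 0:
        raise ValueError("sd must be non-negative")
    ref = _geometry(shape)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if sd == 0:
        return _like(ref, np.full(ref.shape, float(mean)))
    from scipy import ndimage

    noise = rng.standard_normal(ref.shape)
    smooth = ndimage.gaussian_filter(noise, sigma=autocorr_range, mode="wrap")
    smooth = (smooth - smooth.mean()) / smooth.std()
    return _like(ref, mean + sd * smooth)


def make_correlated_gradient(base: Grid, target_correlation: float,
                             seed: int | np.random.Generator = 0,
                             autocorr_range: float = 10.0) -> Grid:
    """Layer with a prescribed Pearson correlation to *base*, rescaled to [0, 1].

    Constructed as ``r * standardized(base) + sqrt(1 - r^2) * noise`` with
    spatially smooth noise orthogonalized against the base, so the empirical
    correlation matches ``target_correlation`` to high precision; the final
    [0, 1] rescale is affine and leaves the correlation unchanged.
    """
    if not -1.0 < target_correlation < 1.0:
        raise ValueError("target_correlation must lie strictly in (-1, 1)")
    vals = base.values.ravel()
    if np.ptp(vals) == 0:
        raise ValueError("base grid is constant; correlation undefined")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    z = (vals - vals.mean()) / vals.std()
    noise = make_gaussian_field(base, 0.0, 1.0, autocorr_range, rng).values.ravel()
    # orthogonalize the noise against the base so the mix hits r exactly
    noise = noise - (noise @ z) / (z @ z) * z
    nstd = noise.std()
    if nstd == 0:  # degenerate noise draw; fall back to white noise
        noise = rng.standard_normal(vals.shape)
        noise = noise - (noise @ z) / (z @ z) * z
        nstd = noise.std()
    noise = (noise - noise.mean()) / nstd
    r = target_correlation
    mix = r * z + np.sqrt(1.0 - r * r) * noise
    out = rescale01(mix.reshape(base.shape))
    return _like(base, out)


def rescale01(values: np.ndarray) -> np.ndarray:
    """Affine rescale of an array to [0, 1]; constant input maps to 0."""
    values = np.asarray(values, dtype=float)
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# Raster I/O
#
# Two formats: single-band float32 TIFF with geometry and nodata carried in a
# JSON ImageDescription tag (.tif/.tiff), and ESRI ASCII grid (.asc), a plain
# text header + whitespace-separated values.  TIFF round-trips float32
# bit-exactly; the ASCII writer prints full double precision (%.17g).
# ---------------------------------------------------------------------------

_NODATA = -9999.0


def write_raster(grid: Grid, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        data = np.asarray(grid.values, dtype=np.float32)
        # TIFF rows run top-to-bottom; our row 0 is the bottom row
        data = data[::-1].copy()
        if grid.nodata_mask is not None:
            data[grid.nodata_mask[::-1]] = np.float32(_NODATA)
        meta = {
            "cell_size": grid.cell_size,
            "origin": list(grid.origin),
            "nodata": _NODATA if grid.nodata_mask is not None else None,
        }
        tifffile.imwrite(path, data, description=json.dumps(meta))
    elif path.suffix.lower() == ".asc":
        vals = grid.values.copy()
        if grid.nodata_mask is not None:
            vals[grid.nodata_mask] = _NODATA
        header = (
            f"ncols {grid.ncols}\n"
            f"nrows {grid.nrows}\n"
            f"xllcorner {grid.origin[0]!r}\n"
            f"yllcorner {grid.origin[1]!r}\n"
            f"cellsize {grid.cell_size!r}\n"
            f"NODATA_value {_NODATA}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, vals[::-1], fmt="%.17g")
    else:
        raise ValueError(f"unsupported raster format: {path.suffix!r} (use .tif or .asc)")


def read_raster(path: str | Path) -> Grid:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            data = page.asarray().astype(float)[::-1]
            desc = page.tags.get("ImageDescription")
            meta = json.loads(desc.value) if desc is not None else {}
        cell_size = float(meta.get("cell_size", 1.0))
        origin = tuple(meta.get("origin", (0.0, 0.0)))
        nodata = meta.get("nodata")
        mask = None
        if nodata is not None:
            mask = data == nodata
            data = np.where(mask, 0.0, data)
            if not mask.any():
                mask = None
        return Grid(data, cell_size, origin, mask)
    if path.suffix.lower() == ".asc":
        header: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                header[key.lower()] = float(val)
            data = np.loadtxt(fh)
        data = np.atleast_2d(data)[::-1]
        nodata = header.get("nodata_value")
        mask = None
        if nodata is not None:
            mask = data == nodata
            data = np.where(mask, 0.0, data)
            if not mask.any():
                mask = None
        return Grid(
            data,
            cell_size=header["cellsize"],
            origin=(header["xllcorner"], header["yllcorner"]),
            nodata_mask=mask,
        )
    raise ValueError(f"unsupported raster format: {path.suffix!r} (use .tif or .asc)")


def read_stack(directory: str | Path, names: Iterable[str] | None = None) -> CovariateStack:
    """Read every raster in *directory* into a stack keyed by file stem."""
    directory = Path(directory)
    paths = sorted(p for p in directory.iterdir() if p.suffix.lower() in {".tif", ".tiff", ".asc"})
    if names is not None:
        wanted = set(names)
        paths = [p for p in paths if p.stem in wanted]
    stack = CovariateStack()
    for p in paths:
        stack.add(p.stem, read_raster(p))
    return stack
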