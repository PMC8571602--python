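"""Availability-point generation: MCP home range, uniform and bias-corrected sampling.

In use–availability habitat models the "availability" sample defines what
the animal could have chosen.  Here the availability domain is the minimum
convex polygon (MCP, the 100% convex hull) around the telemetry locations,
optionally buffered.  Uniform sampling inside the MCP is the conventional
choice; the bias-corrected variant instead draws availability points with
probability proportional to the observer model's predicted accessibility,
so that use and availability share the same observer bias and the bias
cancels out of the selection coefficients.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint, Point, Polygon
from shapely.prepared import prep

from .grids import CovariateStack
from .observer import LogisticFit, predict_observer_probability

__all__ = [
    "compute_mcp",
    "buffer_polygon",
    "sample_random_availability",
    "sample_corrected_availability",
    "polygon_vertices",
]


def compute_mcp(points: pd.DataFrame) -> Polygon:
    """Minimum convex polygon (100% convex hull) of a point set.

    Requires at least 3 non-collinear points; degenerate inputs raise
    rather than being silently buffered into a sliver.
    """
    if len(points) < 3:
        raise ValueError(f"MCP needs >= 3 points, got {len(points)}")
    hull = MultiPoint(list(zip(points["x"], points["y"]))).convex_hull
    if not isinstance(hull, Polygon) or hull.area == 0:
        raise ValueError("points are collinear; MCP is degenerate")
    return hull


def polygon_vertices(poly: Polygon) -> np.ndarray:
    """Exterior vertices, counter-clockwise, closed (first == last)."""
    coords = np.asarray(poly.exterior.coords)
    # shapely's convex_hull is CCW already; enforce it via the shoelace sign
    area2 = np.sum(coords[:-1, 0] * coords[1:, 1] - coords[1:, 0] * coords[:-1, 1])
    if area2 < 0:
        coords = coords[::-1]
    return coords

def buffer_polygon(poly: Polygon, distance: float) -> Polygon:
    """Minkowski dilation of the polygon; distance 0 is the identity."""
    if distance < 0:
        raise ValueError("buffer distance must be non-negative")
    if distance == 0:
        return poly
    return poly.buffer(distance)


def sample_random_availability(poly: Polygon, n: int,
                               seed: int | np.random.Generator = 0,
                               source: str = "availability") -> pd.DataFrame:
    """*n* points uniform over the polygon interior (bounding-box rejection)."""
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    minx, miny, maxx, maxy = poly.bounds
    prepared = prep(poly)
    xs: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    got = 0
    # acceptance rate = area ratio; oversample accordingly
    rate = max(poly.area / ((maxx - minx) * (maxy - miny)), 1e-6)
    while got < n:
        m = int((n - got) / rate * 1.2) + 16
        cx = rng.uniform(minx, maxx, m)
        cy = rng.uniform(miny, maxy, m)
        ok = np.fromiter((prepared.contains(Point(x, y)) for x, y in zip(cx, cy)),
                         dtype=bool, count=m)
        xs.append(cx[ok])
        ys.append(cy[ok])
        got += int(ok.sum())
    x = np.concatenate(xs)[:n]
    y = np.concatenate(ys)[:n]
    return pd.DataFrame({"x": x, "y": y, "source": source})


def sample_corrected_availability(poly: Polygon, fit: LogisticFit, stack: CovariateStack,
                                  n_out: int, n_candidates: int = 100_000,
                                  seed: int | np.random.Generator = 0,
                                  source: str = "availability",
                                  weighting: str = "odds") -> pd.DataFrame:
    """Availability points weighted by predicted observer accessibility.

    Draws ``n_candidates`` uniform points inside the polygon, evaluates the
    observer model at each, and samples ``n_out`` of them without
    replacement with probability proportional to the model's prediction
    (exponential-key weighted reservoir method).  The output then follows
    the observer model's "use distribution" within the availability domain.

    ``weighting`` selects the prediction scale: ``"odds"`` (default) uses
    ``exp(linear predictor)``, the opportunistic-vs-telemetry density
    ratio, which is the accessibility surface up to a constant and is
    invariant to the arbitrary case–control ratio the model was fitted
    with; ``"probability"`` uses the fitted probability itself, which is
    proportional to the odds only where records are sparse and compresses
    the surface where the fitted probabilities saturate.
    """
    if n_out > n_candidates:
        raise ValueError("n_out cannot exceed n_candidates")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    candidates = sample_random_availability(poly, n_candidates, rng, source=source)
    # clip candidates to the raster extent: a buffered polygon may overhang it
    xmin, ymin, xmax, ymax = stack.geometry_grid.extent()
    inside = (
        (candidates["x"] >= xmin) & (candidates["x"] <= xmax)
        & (candidates["y"] >= ymin) & (candidates["y"] <= ymax)
    )
    candidates = candidates[inside].reset_index(drop=True)
    if len(candidates) < n_out:
        raise ValueError("too few candidates fall inside the covariate rasters")
    if weighting == "odds":
        from .observer import extract_covariates

        table = extract_covariates(candidates, stack, fit.terms)
        eta = fit.linear_predictor(table)
        w = np.exp(eta - eta.max())  # proportional to exp(eta); overflow-safe
    elif weighting == "probability":
        w = predict_observer_probability(fit, candidates, stack)
    else:
        raise ValueError("weighting must be 'odds' or 'probability'")
    if np.all(w <= 0):
        raise ValueError("all predicted observer probabilities are zero")
    # Efraimidis–Spirakis: keep the n_out largest u^(1/w), i.e. smallest -log(u)/w
    keys = np.full(len(w), np.inf)
    pos = w > 0
    keys[pos] = rng.exponential(size=int(pos.sum())) / w[pos]
    chosen = np.argsort(keys)[:n_out]
    return candidates.iloc[np.sort(chosen)].reset_index(drop=True)
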