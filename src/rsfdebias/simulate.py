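"""Simulation of species presence, observer accessibility, and opportunistic records.

The simulation places a virtual species and virtual citizen-science
observers on a synthetic landscape.  Per grid cell,

* ``pi`` is the probability of species presence,
  ``logit(pi) = intercept + sum_k beta_k * covariate_k``;
* ``alpha`` is the probability of an observer being present,
  ``logit(alpha) = sum_k gamma_k * covariate_k`` (no intercept); and
* ``psi = alpha * pi`` is the probability of an opportunistic record.

Telemetry locations are sampled proportionally to ``pi`` (an unbiased view
of space use); opportunistic records proportionally to ``psi`` (space use
filtered through observer accessibility).  Downstream, a resource selection
function fitted naively to the opportunistic points against uniform
availability absorbs the observer bias; the correction re-samples
availability from the fitted observer surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import (
    CovariateStack,
    Grid,
    make_cluster_grid,
    make_correlated_gradient,
    make_distance_grid,
    make_gaussian_field,
    rescale01,
)

__all__ = [
    "SimulationParams",
    "ProbabilityGrids",
    "make_landscape",
    "species_probability",
    "observer_probability",
    "opportunistic_probability",
    "sample_points",
    "run_observation_simulation",
]

#: species-presence coefficients: a forest dweller at low altitude, far from
#: roads, attracted by a hidden gradient correlated with distance-to-roads
DEFAULT_SPECIES_BETAS = {
    "forest": 2.5,
    "altitude": -2.0,
    "d_roads": 4.5,
    "other_gradient": 3.0,
}

#: observer-accessibility coefficients: observers stay near roads and towns
#: and favour nice viewpoints
DEFAULT_OBSERVER_BETAS = {
    "d_roads": -6.0,
    "d_urb": -3.0,
    "nice_viewpoints": 1.0,
}


@dataclass
class SimulationParams:
    """Everything the observation simulation needs, including the seed.

    Covariates named in the beta dictionaries must exist as layers in the
    covariate stack.  ``n_telemetry``/``n_opportunistic`` are the fixed
    numbers of points drawn per replicate.
    """

    species_intercept: float = -7.0
    species_betas: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SPECIES_BETAS))
    observer_betas: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_OBSERVER_BETAS))
    n_telemetry: int = 500
    n_opportunistic: int = 300
    n_replicates: int = 1
    grid_shape: tuple[int, int] = (200, 200)
    forest_proportion: float = 0.3
    viewpoint_proportion: float = 0.1
    gradient_correlation: float = -0.80
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_telemetry <= 0:
            raise ValueError("n_telemetry must be positive")
        if self.n_opportunistic <= 0:
            raise ValueError("n_opportunistic must be positive")


@dataclass
class ProbabilityGrids:
    """Per-cell presence (pi), observer (alpha), and record (psi) probabilities."""

    pi: Grid
    alpha: Grid
    psi: Grid

    def __post_init__(self) -> None:
        for name in ("pi", "alpha", "psi"):
            g = getattr(self, name)
            if np.any((g.values < 0) | (g.values > 1)):
                raise ValueError(f"{name} has values outside [0, 1]")
        if not np.array_equal(self.psi.values, self.alpha.values * self.pi.values):
            raise ValueError("psi must equal alpha * pi elementwise")


def make_landscape(shape: tuple[int, int] = (200, 200), seed: int | np.random.Generator = 0,
                   forest_proportion: float = 0.3, viewpoint_proportion: float = 0.1,
                   gradient_correlation: float = -0.80) -> CovariateStack:
    """Synthetic landscape for the simulation study.

    Layers (continuous ones rescaled to [0, 1] so that O(1) coefficients
    yield non-degenerate probabilities):

    - ``d_urb``       distance to a settlement at the upper-left corner
    - ``d_roads``     distance to a road segment crossing the landscape
    - ``other_gradient`` hidden gradient correlated with d_roads at the
      requested Pearson r (default −0.80)
    - ``forest``, ``nice_viewpoints``  clustered binary layers
    - ``altitude``    Gaussian random field (mean 1, sd 1) rescaled to [0, 1]
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    nrows, ncols = shape
    geom = Grid(np.zeros(shape))
    xmax, ymax = float(ncols), float(nrows)

    d_urb = make_distance_grid(geom, (0.0, ymax))  # upper-left corner
    # road: a segment across the landscape, due diagonal-ish with random offset
    off = rng.uniform(0.25, 0.75)
    road = [(0.0, ymax * off), (xmax, ymax * (1.0 - off))]
    d_roads = make_distance_grid(geom, road)

    stack = CovariateStack()
    stack.add("d_urb", Grid(rescale01(d_urb.values)))
    d_roads01 = Grid(rescale01(d_roads.values))
    stack.add("d_roads", d_roads01)
    stack.add("other_gradient", make_correlated_gradient(d_roads01, gradient_correlation, rng))
    stack.add("forest", make_cluster_grid(geom, forest_proportion, 0.5, rng))
    stack.add("nice_viewpoints", make_cluster_grid(geom, viewpoint_proportion, 0.5, rng))
    alt = make_gaussian_field(geom, mean=1.0, sd=1.0, autocorr_range=min(shape) / 10, seed=rng)
    stack.add("altitude", Grid(rescale01(alt.values)))
    return stack


def _linear_predictor(stack: CovariateStack, betas: dict[str, float], intercept: float) -> np.ndarray:
    stack.require(betas)
    geom = stack.geometry_grid
    lp = np.full(geom.shape, float(intercept))
    for name, beta in betas.items():
        lp += beta * stack[name].values
    return lp


def _inv_logit(x: np.ndarray) -> np.ndarray:
    from scipy.special import expit

    return expit(x)


def species_probability(stack: CovariateStack, params: SimulationParams) -> Grid:
    """Presence probability surface pi = inverse-logit(intercept + X @ beta)."""
    lp = _linear_predictor(stack, params.species_betas, params.species_intercept)
    geom = stack.geometry_grid
    return Grid(_inv_logit(lp), geom.cell_size, geom.origin)


def observer_probability(stack: CovariateStack, params: SimulationParams) -> Grid:
    """Observer probability surface alpha (zero-intercept linear predictor)."""
    lp = _linear_predictor(stack, params.observer_betas, 0.0)
    geom = stack.geometry_grid
    return Grid(_inv_logit(lp), geom.cell_size, geom.origin)


def opportunistic_probability(pi: Grid, alpha: Grid) -> Grid:
    """psi = alpha * pi, elementwise, on co-registered grids."""
    if not pi.same_geometry(alpha):
        raise ValueError("pi and alpha are not co-registered")
    return Grid(alpha.values * pi.values, pi.cell_size, pi.origin)


def sample_points(prob: Grid, n: int, seed: int | np.random.Generator = 0,
                  source: str = "sample", jitter: bool = True) -> pd.DataFrame:
    """Draw *n* point locations with probability proportional to cell value.

    Cells are drawn by weighted multinomial sampling with replacement; each
    point is placed at its cell center and (by default) jittered uniformly
    within the cell so that geometric operations never see exactly
    coincident or collinear points.  Deterministic given the seed.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    vals = prob.values.ravel()
    if np.any(vals < 0):
        raise ValueError("probability grid has negative values")
    total = vals.sum()
    if total == 0:
        raise ValueError("cannot sample from an all-zero probability grid")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    idx = rng.choice(vals.size, size=n, replace=True, p=vals / total)
    i, j = np.unravel_index(idx, prob.shape)
    x0, y0 = prob.origin
    cs = prob.cell_size
    if jitter:
        dx = rng.uniform(0.0, 1.0, size=n)
        dy = rng.uniform(0.0, 1.0, size=n)
    else:
        dx = dy = np.full(n, 0.5)
    x = x0 + (j + dx) * cs
    y = y0 + (i + dy) * cs
    return pd.DataFrame({"x": x, "y": y, "source": source, "row": i, "col": j})


def run_observation_simulation(stack: CovariateStack, params: SimulationParams,
                               seed: int | np.random.Generator | None = None
                               ) -> tuple[pd.DataFrame, pd.DataFrame, ProbabilityGrids]:
    """Simulate one replicate of telemetry and opportunistic point sets.

    Telemetry points are drawn from the presence surface pi, opportunistic
    records from psi = alpha * pi.  Returns the two labelled point tables
    and the probability surfaces.
    """
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    pi = species_probability(stack, params)
    alpha = observer_probability(stack, params)
    psi = opportunistic_probability(pi, alpha)
    grids = ProbabilityGrids(pi=pi, alpha=alpha, psi=psi)
    telemetry = sample_points(pi, params.n_telemetry, rng, source="telemetry")
    opportunistic = sample_points(psi, params.n_opportunistic, rng, source="opportunistic")
    return telemetry, opportunistic, grids
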