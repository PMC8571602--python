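"""Resource selection functions by infinitely weighted logistic regression.

An RSF compares covariates at locations an animal used with covariates at
locations available to it; the exponentiated linear predictor is
proportional to relative selection strength.  Following the
point-process-equivalence argument for use–availability designs, the
logistic likelihood is fitted with a large weight (default 100) on every
availability row, which approximates the limit of an infinite availability
sample and makes the slope estimates insensitive to the background size.

Skewed covariates (distances, intensities) conventionally enter
log-transformed — all terms except slope-like ones — with a small
scale-aware epsilon guarding zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from shapely import contains_xy as _poly_contains
from shapely.geometry import Polygon

from .grids import CovariateStack, Grid
from .observer import (
    LogisticFit,
    default_epsilons,
    extract_covariates,
    fit_logistic,
    log_transform_columns,
)

__all__ = [
    "RSFDesign",
    "SuitabilityMap",
    "build_design",
    "fit_weighted_rsf",
    "fit_three_models",
    "predict_suitability",
    "map_correlation",
]

DEFAULT_BACKGROUND_WEIGHT = 100.0


@dataclass
class RSFDesign:
    """Design matrix for a use–availability logistic fit.

    ``response`` is 1 for use rows (telemetry or opportunistic points) and
    0 for availability rows; ``weights`` are 1 for use rows and the
    background weight for availability rows.
    """

    X: pd.DataFrame
    response: np.ndarray
    weights: np.ndarray
    transform_log: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.response = np.asarray(self.response, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if not (len(self.X) == len(self.response) == len(self.weights)):
            raise ValueError("X, response and weights must have equal length")
        if not set(np.unique(self.response)) <= {0.0, 1.0}:
            raise ValueError("response must be binary")


@dataclass
class SuitabilityMap:
    """Per-cell log-odds habitat suitability, masked to the prediction polygon."""

    grid: Grid
    fit: LogisticFit
    mask: Polygon | None = None

    @property
    def values(self) -> np.ndarray:
        return self.grid.values


def build_design(use: pd.DataFrame, availability: pd.DataFrame, stack: CovariateStack,
                 covariates: Sequence[str],
                 transform_log: dict[str, float] | None = None,
                 background_weight: float = DEFAULT_BACKGROUND_WEIGHT) -> RSFDesign:
    """Stack use (1) and availability (0) rows with extracted covariates.

    ``transform_log`` maps term name to the epsilon used in ``log(x + eps)``;
    pass :func:`rsfdebias.observer.default_epsilons` output for skewed
    empirical covariates, or None/{} to fit on the raw scale.
    """
    if len(use) == 0:
        raise ValueError("use point set is empty")
    if len(availability) == 0:
        raise ValueError("availability point set is empty")
    X_use = extract_covariates(use, stack, covariates)
    X_av = extract_covariates(availability, stack, covariates)
    X = pd.concat([X_use, X_av], ignore_index=True)
    transform_log = dict(transform_log or {})
    X = log_transform_columns(X, transform_log)
    y = np.concatenate([np.ones(len(X_use)), np.zeros(len(X_av))])
    w = np.concatenate([np.ones(len(X_use)), np.full(len(X_av), float(background_weight))])
    return RSFDesign(X=X, response=y, weights=w, transform_log=transform_log)


def fit_weighted_rsf(design: RSFDesign, ridge_penalty: float = 0.0) -> LogisticFit:
    """Weighted maximum-likelihood logistic fit of the RSF design."""
    if np.ptp(design.response) == 0:
        raise ValueError("response is constant; cannot fit")
    w_bg = design.weights[design.response == 0]
    scheme = f"use=1, availability weight={w_bg[0]:g}" if w_bg.size else "use only"
    fit = fit_logistic(design.X, design.response, design.weights,
                       ridge_penalty=ridge_penalty, weight_scheme=scheme)
    fit.transform_log = dict(design.transform_log)
    return fit


def fit_three_models(telemetry: pd.DataFrame, opportunistic: pd.DataFrame,
                     availability_random_tel: pd.DataFrame,
                     availability_random_opp: pd.DataFrame,
                     availability_corrected: pd.DataFrame,
                     stack: CovariateStack, covariates: Sequence[str],
                     transform_log: dict[str, float] | None = None,
                     background_weight: float = DEFAULT_BACKGROUND_WEIGHT,
                     ridge_penalty: float = 0.0) -> dict[str, LogisticFit]:
    """The three-way comparison at the heart of the method.

    - ``telemetry``: telemetry use points vs uniform availability — the
      (approximately) unbiased reference;
    - ``naive``: opportunistic use points vs uniform availability — absorbs
      the observer bias into the selection coefficients;
    - ``corrected``: opportunistic use points vs availability sampled from
      the observer model's accessibility surface.

    All three share the covariate list and term ordering.
    """
    kw = dict(transform_log=transform_log, background_weight=background_weight)
    fits = {
        "telemetry": fit_weighted_rsf(
            build_design(telemetry, availability_random_tel, stack, covariates, **kw),
            ridge_penalty),
        "naive": fit_weighted_rsf(
            build_design(opportunistic, availability_random_opp, stack, covariates, **kw),
            ridge_penalty),
        "corrected": fit_weighted_rsf(
            build_design(opportunistic, availability_corrected, stack, covariates, **kw),
            ridge_penalty),
    }
    return fits


def predict_suitability(fit: LogisticFit, stack: CovariateStack,
                        mask: Polygon | None = None) -> SuitabilityMap:
    """Per-cell linear predictor (log-odds suitability) over the stack.

    Cells whose centers fall outside *mask* are set to nodata.
    """
    stack.require(fit.terms)
    geom = stack.geometry_grid
    table = pd.DataFrame({name: stack[name].values.ravel() for name in fit.terms})
    lp = fit.linear_predictor(table).reshape(geom.shape)
    nodata = None
    if mask is not None:
        X, Y = geom.cell_centers()
        inside = _poly_contains(mask, X, Y)
        nodata = ~inside
        lp = np.where(nodata, 0.0, lp)
    grid = Grid(lp, geom.cell_size, geom.origin, nodata_mask=nodata)
    return SuitabilityMap(grid=grid, fit=fit, mask=mask)


def map_correlation(a: SuitabilityMap, b: SuitabilityMap) -> float:
    """Pearson correlation between two suitability maps over jointly valid cells."""
    ga, gb = a.grid, b.grid
    if not ga.same_geometry(gb):
        raise ValueError("maps are not co-registered")
    valid = np.ones(ga.shape, dtype=bool)
    if ga.nodata_mask is not None:
        valid &= ~ga.nodata_mask
    if gb.nodata_mask is not None:
        valid &= ~gb.nodata_mask
    va = ga.values[valid]
    vb = gb.values[valid]
    if va.size < 2:
        raise ValueError("fewer than 2 jointly valid cells")
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        raise ValueError("zero variance in a map; correlation undefined")
    return float(np.corrcoef(va, vb)[0, 1])
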