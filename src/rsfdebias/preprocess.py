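"""Empirical-style data cleaning for telemetry and opportunistic records.

Telemetry tracks are temporally thinned (one fix per minimum interval) and
restricted to a season and daily activity window so they are comparable to
when citizen scientists are in the field.  Opportunistic records are
filtered on coordinate uncertainty, purged of "super-observers" (single
contributors dominating the dataset, typically professionals), and clipped
to a buffered home-range polygon around the telemetry data.

All filters are pure selections: they never modify surviving rows, and
applying a filter twice equals applying it once.

A fixture generator (:func:`make_empirical_fixture`) produces synthetic
tables with the full empirical schema — multiple animals and observers,
timestamps across years, an injected super-observer, uncertainties
straddling the cutoff — so the whole empirical pipeline is exercisable
without any external download.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from shapely import contains_xy
from shapely.geometry import Polygon

from .grids import CovariateStack
from .sampling import buffer_polygon, compute_mcp
from .simulate import SimulationParams, make_landscape, run_observation_simulation

__all__ = [
    "thin_telemetry",
    "filter_season_hours",
    "filter_opportunistic",
    "buffer_filter",
    "make_empirical_fixture",
    "normalize_darwin_core",
]

#: GBIF / DarwinCore column aliases mapped onto the package schema on ingest
DARWIN_CORE_ALIASES = {
    "decimalLongitude": "x",
    "decimalLatitude": "y",
    "coordinateUncertaintyInMeters": "coord_uncertainty",
    "recordedBy": "observer_id",
    "eventDate": "timestamp",
}


def normalize_darwin_core(records: pd.DataFrame) -> pd.DataFrame:
    """Rename DarwinCore-style columns to the package's x/y/observer schema."""
    present = {k: v for k, v in DARWIN_CORE_ALIASES.items() if k in records.columns}
    return records.rename(columns=present)


def thin_telemetry(records: pd.DataFrame, min_interval_hours: float) -> pd.DataFrame:
    """Keep at most one fix per ``min_interval_hours`` within each animal.

    Greedy earliest-first scan: the first fix is always kept, then a fix is
    kept iff it falls at least the interval after the last kept fix.
    """
    if "timestamp" not in records.columns or records["timestamp"].isna().any():
        bad = (records.index[records["timestamp"].isna()].tolist()
               if "timestamp" in records.columns else "all")
        raise ValueError(f"telemetry thinning needs timestamps; missing at rows {bad}")
    ts = pd.to_datetime(records["timestamp"])
    interval = pd.Timedelta(hours=min_interval_hours)
    group_key = records["animal_id"] if "animal_id" in records.columns else pd.Series(0, index=records.index)
    keep = pd.Series(False, index=records.index)
    for _, grp in ts.groupby(group_key):
        grp = grp.sort_values(kind="stable")
        last = None
        for idx, t in grp.items():
            if last is None or t - last >= interval:
                keep.loc[idx] = True
                last = t
    return records[keep]


def filter_season_hours(records: pd.DataFrame,
                        season: tuple[tuple[int, int], tuple[int, int]] = ((6, 22), (9, 22)),
                        hours: tuple[int, int] = (8, 22)) -> pd.DataFrame:
    """Keep records within a seasonal date window and daily hour window.

    Defaults retain summer (Jun 22 – Sep 22, inclusive, any year) during
    normal human activity hours (08–22 inclusive).
    """
    ts = pd.to_datetime(records["timestamp"])
    (m0, d0), (m1, d1) = season
    key = ts.dt.month * 100 + ts.dt.day
    in_season = (key >= m0 * 100 + d0) & (key <= m1 * 100 + d1)
    in_hours = (ts.dt.hour >= hours[0]) & (ts.dt.hour <= hours[1])
    return records[in_season & in_hours]


def filter_opportunistic(records: pd.DataFrame, max_uncertainty: float = 400.0,
                         super_observer_fraction: float = 0.5) -> pd.DataFrame:
    """Coordinate-uncertainty and super-observer filters for opportunistic data.

    Drops records with coordinate uncertainty >= ``max_uncertainty`` (or
    missing — the rule cannot be verified for them); then drops every record
    of any observer contributing strictly more than
    ``super_observer_fraction`` of the *remaining* records.
    """
    out = records
    if "coord_uncertainty" in out.columns:
        unc = pd.to_numeric(out["coord_uncertainty"], errors="coerce")
        out = out[unc.notna() & (unc < max_uncertainty)]
    if "observer_id" in out.columns and len(out):
        shares = out["observer_id"].value_counts(normalize=True)
        supers = shares.index[shares > super_observer_fraction]
        out = out[~out["observer_id"].isin(supers)]
    if len(out) == 0:
        warnings.warn("all opportunistic records removed by filters", stacklevel=2)
    return out


def buffer_filter(records: pd.DataFrame, reference: pd.DataFrame,
                  buffer: float = 10_000.0) -> pd.DataFrame:
    """Keep records inside the buffered MCP of the reference (telemetry) points."""
    poly: Polygon = buffer_polygon(compute_mcp(reference), buffer)
    inside = contains_xy(poly, records["x"].to_numpy(float), records["y"].to_numpy(float))
    # boundary points count as inside (covers, not strict containment)
    if not inside.all():
        from shapely import dwithin, points

        border = ~inside
        pts = points(records.loc[border, "x"].to_numpy(float),
                     records.loc[border, "y"].to_numpy(float))
        inside[border] = dwithin(poly, pts, 1e-9)
    return records[inside]


def make_empirical_fixture(config: dict | None = None, seed: int = 0
                           ) -> tuple[pd.DataFrame, pd.DataFrame, CovariateStack]:
    """Synthetic telemetry and opportunistic tables with the empirical schema.

    Built on a simulated landscape: telemetry fixes are hourly tracks for
    several animals over two summers (so 5-h thinning bites), with some
    fixes outside the season/hour windows; opportunistic records carry
    observer ids (one injected super-observer), event timestamps, and
    coordinate uncertainties straddling the 400 m cutoff.  Deterministic
    given the seed.
    """
    config = dict(config or {})
    rng = np.random.default_rng(seed)
    shape = config.get("grid_shape", (60, 60))
    n_animals = config.get("n_animals", 4)
    n_observers = config.get("n_observers", 6)
    params = SimulationParams(
        grid_shape=shape,
        n_telemetry=config.get("n_telemetry", 400),
        n_opportunistic=config.get("n_opportunistic", 150),
        seed=seed,
    )
    stack = make_landscape(shape, rng, params.forest_proportion,
                           params.viewpoint_proportion, params.gradient_correlation)
    telemetry, opportunistic, _ = run_observation_simulation(stack, params, rng)

    # telemetry: assign animals and hourly timestamps over two summers,
    # deliberately spilling outside the season and hour windows
    n_tel = len(telemetry)
    telemetry = telemetry.drop(columns=["row", "col"]).copy()
    telemetry["animal_id"] = [f"animal_{k % n_animals}" for k in range(n_tel)]
    starts = pd.to_datetime(["2019-06-10 00:00", "2020-06-10 00:00"])
    t0 = starts[rng.integers(0, 2, n_tel)]
    telemetry["timestamp"] = t0 + pd.to_timedelta(rng.integers(0, 110 * 24, n_tel), unit="h")
    telemetry = telemetry.sort_values(["animal_id", "timestamp"]).reset_index(drop=True)

    # opportunistic: observer ids with one super-observer holding ~60% of
    # records, daytime summer timestamps, uncertainty straddling 400 m
    n_opp = len(opportunistic)
    opportunistic = opportunistic.drop(columns=["row", "col"]).copy()
    obs = np.array([f"observer_{k}" for k in range(1, n_observers)])
    observer_id = np.where(rng.random(n_opp) < 0.6, "observer_0",
                           obs[rng.integers(0, len(obs), n_opp)])
    opportunistic["observer_id"] = observer_id
    days = rng.integers(0, 90, n_opp)
    hour = rng.integers(8, 21, n_opp)
    opportunistic["timestamp"] = (pd.Timestamp("2020-06-22")
                                  + pd.to_timedelta(days, unit="D")
                                  + pd.to_timedelta(hour, unit="h"))
    opportunistic["coord_uncertainty"] = rng.choice(
        [10.0, 50.0, 100.0, 250.0, 400.0, 800.0], size=n_opp,
        p=[0.25, 0.25, 0.2, 0.1, 0.1, 0.1])
    return telemetry, opportunistic, stack
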