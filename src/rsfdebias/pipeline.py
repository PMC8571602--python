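"""End-to-end orchestration: simulation experiment and empirical pipeline.

The simulation experiment replays the whole method many times on freshly
generated landscapes: simulate presence and observation → fit the observer
model → sample uniform and bias-corrected availability → fit the naive and
corrected RSFs → record each coefficient next to the value used to simulate
the species.  Averaging over replicates shows whether the correction
recovers the truth where the naive model cannot — most strikingly for
distance to roads, where observer preference for roadsides drives the naive
coefficient to the wrong sign.

The empirical pipeline applies the cleaning filters, fits the telemetry,
naive and corrected models on user-supplied tables and rasters, and writes
coefficient tables, suitability maps and map correlations.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import preprocess
from .grids import CovariateStack, write_raster
from .observer import default_epsilons, fit_observer_model
from .rsf import fit_three_models, map_correlation, predict_suitability
from .sampling import (
    buffer_polygon,
    compute_mcp,
    sample_corrected_availability,
    sample_random_availability,
)
from .simulate import SimulationParams, make_landscape, run_observation_simulation

__all__ = ["run_simulation_experiment", "run_empirical_pipeline", "replicate_summary"]

log = logging.getLogger(__name__)

#: covariates entering the simulated RSFs — the species drivers of the
#: presence surface (observer covariates are deliberately excluded, as the
#: ecologist fitting the RSF would not include pure accessibility terms)
SIM_RSF_COVARIATES = ("forest", "altitude", "d_roads", "other_gradient")
#: covariates entering the simulated observer model — accessibility drivers
SIM_OBSERVER_COVARIATES = ("d_roads", "d_urb", "nice_viewpoints")


def run_simulation_replicate(params: SimulationParams, seed: int,
                             availability_factor_naive: int = 10,
                             availability_factor_corrected: int = 3,
                             n_candidates: int = 100_000,
                             rsf_covariates: Sequence[str] = SIM_RSF_COVARIATES,
                             observer_covariates: Sequence[str] = SIM_OBSERVER_COVARIATES,
                             ) -> pd.DataFrame:
    """One replicate of the simulation experiment; returns a tidy estimate table."""
    rng = np.random.default_rng(seed)
    stack = make_landscape(params.grid_shape, rng, params.forest_proportion,
                           params.viewpoint_proportion, params.gradient_correlation)
    telemetry, opportunistic, _ = run_observation_simulation(stack, params, rng)
    log.info("replicate seed=%s: %d telemetry, %d opportunistic points",
             seed, len(telemetry), len(opportunistic))

    obs_fit = fit_observer_model(opportunistic, telemetry, stack, observer_covariates)

    mcp_tel = compute_mcp(telemetry)
    # naive availability domain: MCP around all observed locations (pooled),
    # so naive and corrected differ only in how availability is weighted
    mcp_all = compute_mcp(pd.concat([telemetry[["x", "y"]], opportunistic[["x", "y"]]],
                                    ignore_index=True))
    av_tel = sample_random_availability(mcp_tel, availability_factor_naive * len(telemetry), rng)
    av_opp = sample_random_availability(mcp_all, availability_factor_naive * len(opportunistic), rng)
    av_cor = sample_corrected_availability(
        mcp_tel, obs_fit, stack,
        n_out=availability_factor_corrected * len(opportunistic),
        n_candidates=n_candidates, seed=rng)
    log.info("replicate seed=%s: availability tel=%d naive=%d corrected=%d",
             seed, len(av_tel), len(av_opp), len(av_cor))

    fits = fit_three_models(telemetry, opportunistic, av_tel, av_opp, av_cor,
                            stack, rsf_covariates)

    truth = {**params.species_betas}
    rows = []
    for model, fit in fits.items():
        for term in fit.terms:
            rows.append({
                "model": model,
                "term": term,
                "estimate": fit.coef(term),
                "se": fit.se(term),
                "truth": truth.get(term, np.nan),
                "seed": seed,
            })
    for name, beta in zip(obs_fit.terms, obs_fit.coefficients):
        rows.append({
            "model": "observer",
            "term": name,
            "estimate": float(beta),
            "se": obs_fit.se(name),
            "truth": params.observer_betas.get(name, np.nan),
            "seed": seed,
        })
    return pd.DataFrame(rows)


def run_simulation_experiment(params: SimulationParams | None = None,
                              n_replicates: int | None = None,
                              seed: int | None = None,
                              **replicate_kwargs) -> pd.DataFrame:
    """Run the replicated simulation experiment.

    Returns a table with one row per (replicate, model, term):
    columns replicate, model, term, estimate, se, truth, seed.  Fully
    deterministic given the master seed; a failed replicate is recorded
    (model = 'error') and the run continues.
    """
    params = params or SimulationParams()
    n_replicates = n_replicates if n_replicates is not None else params.n_replicates
    master = np.random.default_rng(params.seed if seed is None else seed)
    rep_seeds = master.integers(0, 2**31 - 1, size=n_replicates)
    frames = []
    for r, s in enumerate(rep_seeds):
        try:
            tab = run_simulation_replicate(params, int(s), **replicate_kwargs)
        except Exception as exc:  # record and continue
            log.warning("replicate %d (seed %d) failed: %s", r, s, exc)
            tab = pd.DataFrame([{"model": "error", "term": str(exc), "estimate": np.nan,
                                 "se": np.nan, "truth": np.nan, "seed": int(s)}])
        tab.insert(0, "replicate", r)
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)


def replicate_summary(results: pd.DataFrame) -> pd.DataFrame:
    """Mean, spread and error summaries per (model, term) across replicates."""
    ok = results[results["model"] != "error"]
    g = ok.groupby(["model", "term"])
    out = g.agg(
        mean_estimate=("estimate", "mean"),
        sd_estimate=("estimate", "std"),
        q05=("estimate", lambda v: v.quantile(0.05)),
        q95=("estimate", lambda v: v.quantile(0.95)),
        truth=("truth", "first"),
        n_replicates=("estimate", "size"),
    ).reset_index()
    out["mean_abs_error"] = (
        ok.assign(err=(ok["estimate"] - ok["truth"]).abs())
        .groupby(["model", "term"])["err"].mean().values
    )
    return out


def run_empirical_pipeline(telemetry: pd.DataFrame, opportunistic: pd.DataFrame,
                           stack: CovariateStack, config: dict | None = None,
                           out_dir: str | Path | None = None) -> dict:
    """Clean, fit the three models, and compare suitability maps.

    ``config`` keys (all optional): rsf_covariates, observer_covariates,
    thin_interval_hours (5), season/hours windows, max_uncertainty (400),
    buffer (10 km in map units), availability factors, background_weight,
    log_transform (True) and slope_like terms excluded from it, seed.

    Returns a dict with the fits, the correlation table, the suitability
    maps, and the cleaned tables; optionally writes coefficients (CSV),
    fits (JSON), maps (GeoTIFF-style .tif) and the correlation table to
    ``out_dir``.
    """
    cfg = dict(config or {})
    rng = np.random.default_rng(cfg.get("seed", 0))
    rsf_cov = list(cfg.get("rsf_covariates", SIM_RSF_COVARIATES))
    obs_cov = list(cfg.get("observer_covariates", SIM_OBSERVER_COVARIATES))

    telemetry = preprocess.normalize_darwin_core(telemetry)
    opportunistic = preprocess.normalize_darwin_core(opportunistic)

    n0_tel, n0_opp = len(telemetry), len(opportunistic)
    if "timestamp" in telemetry.columns:
        telemetry = preprocess.thin_telemetry(telemetry, cfg.get("thin_interval_hours", 5))
        telemetry = preprocess.filter_season_hours(
            telemetry, cfg.get("season", ((6, 22), (9, 22))), cfg.get("hours", (8, 22)))
    opportunistic = preprocess.filter_opportunistic(
        opportunistic, cfg.get("max_uncertainty", 400.0), cfg.get("super_observer_fraction", 0.5))
    opportunistic = preprocess.buffer_filter(opportunistic, telemetry, cfg.get("buffer", 10_000.0))
    log.info("preprocess: telemetry %d -> %d, opportunistic %d -> %d",
             n0_tel, len(telemetry), n0_opp, len(opportunistic))
    if len(opportunistic) < 3:
        raise ValueError("too few opportunistic records survive filtering")

    transform = None
    if cfg.get("log_transform", True):
        slope_like = set(cfg.get("slope_like", ("slope",)))
        transform = default_epsilons(stack, [t for t in set(rsf_cov) | set(obs_cov)
                                             if t not in slope_like])

    obs_transform = {k: v for k, v in (transform or {}).items() if k in obs_cov} or None
    obs_fit = fit_observer_model(opportunistic, telemetry, stack, obs_cov,
                                 transform_log=obs_transform,
                                 ridge_penalty=cfg.get("ridge_penalty", 0.0))

    mcp_tel = compute_mcp(telemetry)
    poly = buffer_polygon(mcp_tel, cfg.get("buffer", 10_000.0))
    f_naive = cfg.get("availability_factor_naive", 10)
    f_corr = cfg.get("availability_factor_corrected", 3)
    av_tel = sample_random_availability(mcp_tel, f_naive * len(telemetry), rng)
    mcp_all = compute_mcp(pd.concat([telemetry[["x", "y"]], opportunistic[["x", "y"]]],
                                    ignore_index=True))
    av_opp = sample_random_availability(mcp_all, f_naive * len(opportunistic), rng)
    av_cor = sample_corrected_availability(poly, obs_fit, stack,
                                           n_out=f_corr * len(opportunistic),
                                           n_candidates=cfg.get("n_candidates", 100_000),
                                           seed=rng)

    rsf_transform = {k: v for k, v in (transform or {}).items() if k in rsf_cov} or None
    fits = fit_three_models(telemetry, opportunistic, av_tel, av_opp, av_cor, stack, rsf_cov,
                            transform_log=rsf_transform,
                            background_weight=cfg.get("background_weight", 100.0),
                            ridge_penalty=cfg.get("ridge_penalty", 0.0))

    maps = {name: predict_suitability(fit, stack, mask=mcp_tel) for name, fit in fits.items()}
    correlations = pd.DataFrame([
        {"pair": "telemetry_vs_naive",
         "pearson_r": map_correlation(maps["telemetry"], maps["naive"])},
        {"pair": "telemetry_vs_corrected",
         "pearson_r": map_correlation(maps["telemetry"], maps["corrected"])},
    ])

    coef_rows = []
    for model, fit in {**fits, "observer": obs_fit}.items():
        for term in fit.terms:
            lo, hi = fit.wald_interval(term)
            coef_rows.append({"model": model, "term": term, "estimate": fit.coef(term),
                              "se": fit.se(term), "ci95_low": lo, "ci95_high": hi})
    coefficients = pd.DataFrame(coef_rows)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        coefficients.to_csv(out_dir / "coefficients.csv", index=False)
        correlations.to_csv(out_dir / "map_correlations.csv", index=False)
        obs_fit.to_json(out_dir / "observer_fit.json")
        for name, fit in fits.items():
            fit.to_json(out_dir / f"{name}_fit.json")
            write_raster(maps[name].grid, out_dir / f"suitability_{name}.tif")

    return {
        "observer_fit": obs_fit,
        "fits": fits,
        "maps": maps,
        "correlations": correlations,
        "coefficients": coefficients,
        "telemetry": telemetry,
        "opportunistic": opportunistic,
    }
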