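"""The observer model: where do citizen scientists record observations?

Opportunistic occurrence records are conditional on an observer being
present; telemetry locations are not.  Contrasting the two with a logistic
regression — record type coded 1 for opportunistic, 0 for telemetry — on
accessibility and visibility covariates (distance to roads, distance to
settlements, viewpoints, forest cover, ...) therefore estimates the spatial
footprint of the observation process itself.  A negative distance-to-roads
coefficient, for instance, says opportunistic records sit closer to roads
than the animals' actual space use.

The fitted model predicts, for any location, the relative probability that
a citizen scientist would have produced a record there; those predictions
drive the bias-corrected availability sample (see :mod:`rsfdebias.sampling`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .grids import CovariateStack

__all__ = [
    "LogisticFit",
    "SeparationError",
    "extract_covariates",
    "fit_logistic",
    "fit_observer_model",
    "predict_observer_probability",
    "log_transform_columns",
]


class SeparationError(RuntimeError):
    """Raised when a logistic fit encounters (quasi-)complete separation."""


@dataclass
class LogisticFit:
    """A fitted logistic regression: coefficients, uncertainty, metadata.

    ``coefficients`` excludes the intercept and is ordered like ``terms``.
    ``vcov`` covers ``[intercept] + terms``.  ``transform_log`` records which
    terms entered the model log-transformed (with the epsilons used), so
    prediction applies the same transform.
    """

    terms: list[str]
    intercept: float
    coefficients: np.ndarray
    standard_errors: np.ndarray
    vcov: np.ndarray
    n_cases: int
    n_controls: int
    converged: bool
    transform_log: dict[str, float] = field(default_factory=dict)
    weight_scheme: str = "unweighted"

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.standard_errors = np.asarray(self.standard_errors, dtype=float)
        self.vcov = np.asarray(self.vcov, dtype=float)
        if len(self.coefficients) != len(self.terms):
            raise ValueError("coefficient and term counts differ")
        if self.vcov.shape != (len(self.terms) + 1, len(self.terms) + 1):
            raise ValueError("vcov must cover intercept + terms")
        if not np.allclose(self.vcov, self.vcov.T, atol=1e-8):
            raise ValueError("vcov must be symmetric")

    def coef(self, term: str) -> float:
        return float(self.coefficients[self.terms.index(term)])

    def se(self, term: str) -> float:
        return float(self.standard_errors[self.terms.index(term)])

    def wald_interval(self, term: str, level: float = 0.95) -> tuple[float, float]:
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2)
        est, se = self.coef(term), self.se(term)
        return est - z * se, est + z * se

    def linear_predictor(self, table: pd.DataFrame) -> np.ndarray:
        """Intercept + X @ beta on a design table, applying stored transforms."""
        X = log_transform_columns(table[self.terms], self.transform_log)
        return self.intercept + X.to_numpy(dtype=float) @ self.coefficients

    def predict_probability(self, table: pd.DataFrame) -> np.ndarray:
        from scipy.special import expit

        return expit(self.linear_predictor(table))

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "terms": self.terms,
            "intercept": self.intercept,
            "coefficients": self.coefficients.tolist(),
            "standard_errors": self.standard_errors.tolist(),
            "vcov": self.vcov.tolist(),
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
            "converged": self.converged,
            "transform_log": self.transform_log,
            "weight_scheme": self.weight_scheme,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "LogisticFit":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(
            terms=list(d["terms"]),
            intercept=float(d["intercept"]),
            coefficients=np.asarray(d["coefficients"]),
            standard_errors=np.asarray(d["standard_errors"]),
            vcov=np.asarray(d["vcov"]),
            n_cases=int(d["n_cases"]),
            n_controls=int(d["n_controls"]),
            converged=bool(d["converged"]),
            transform_log=dict(d.get("transform_log", {})),
            weight_scheme=d.get("weight_scheme", "unweighted"),
        )


def log_transform_columns(table: pd.DataFrame, transform_log: dict[str, float]) -> pd.DataFrame:
    """Return a copy with ``log(x + eps)`` applied to the named columns."""
    if not transform_log:
        return table
    out = table.copy()
    for name, eps in transform_log.items():
        if name in out.columns:
            out[name] = np.log(out[name].to_numpy(dtype=float) + eps)
    return out


def default_epsilons(stack: CovariateStack, terms: Iterable[str]) -> dict[str, float]:
    """Scale-aware epsilons for log transforms: half the cell size for layers
    spanning more than one cell-size unit (distance-like), else half the
    smallest positive value."""
    eps = {}
    for name in terms:
        grid = stack[name]
        vals = grid.values
        pos = vals[vals > 0]
        if pos.size == 0:
            eps[name] = grid.cell_size / 2
        elif vals.max() > grid.cell_size:
            eps[name] = grid.cell_size / 2
        else:
            eps[name] = float(pos.min()) / 2
    return eps


def extract_covariates(points: pd.DataFrame, stack: CovariateStack,
                       covariates: Sequence[str] | None = None) -> pd.DataFrame:
    """Covariate value of the containing cell for each point, rows in input order."""
    names = list(covariates) if covariates is not None else stack.names
    stack.require(names)
    x = points["x"].to_numpy(dtype=float)
    y = points["y"].to_numpy(dtype=float)
    out = {}
    for name in names:
        out[name] = stack[name].value_at(x, y)
    return pd.DataFrame(out, index=points.index)


def fit_logistic(X: pd.DataFrame, y: np.ndarray, weights: np.ndarray | None = None,
                 ridge_penalty: float = 0.0, weight_scheme: str = "unweighted") -> LogisticFit:
    """Maximum-likelihood (weighted) logistic regression with Wald uncertainty.

    Weights multiply each row's log-likelihood contribution (frequency
    weights), the scheme used for infinitely weighted RSF likelihoods.
    Degenerate columns (zero variance) are dropped with coefficient 0.
    Raises :class:`SeparationError` on (quasi-)complete separation unless a
    ridge penalty is supplied.
    """
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    terms = list(X.columns)
    keep = [t for t in terms if np.ptp(X[t].to_numpy(dtype=float)) > 0]
    dropped = [t for t in terms if t not in keep]
    Xk = X[keep].to_numpy(dtype=float)
    design = sm.add_constant(Xk, has_constant="add")
    if weights is None:
        weights = np.ones(len(y))
    weights = np.asarray(weights, dtype=float)

    if ridge_penalty > 0:
        params, vcov, converged = _ridge_logistic(design, y, weights, ridge_penalty)
        scheme = f"{weight_scheme}, ridge={ridge_penalty}"
    else:
        import warnings

        from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

        model = sm.GLM(y, design, family=sm.families.Binomial(), freq_weights=weights)
        try:
            with np.errstate(all="ignore"), warnings.catch_warnings():
                warnings.simplefilter("error", PerfectSeparationWarning)
                res = model.fit(maxiter=200)
        except (PerfectSeparationWarning, Exception) as exc:
            raise SeparationError(
                "logistic fit failed (likely complete separation); "
                "retry with ridge_penalty > 0 for a penalized fit"
            ) from exc
        params = np.asarray(res.params)
        vcov = np.asarray(res.cov_params())
        converged = bool(res.converged)
        if converged and (np.abs(params).max() > 50 or not np.all(np.isfinite(vcov))):
            raise SeparationError(
                "fitted coefficients diverged, indicating quasi-complete separation; "
                "retry with ridge_penalty > 0 for a penalized fit"
            )
        scheme = weight_scheme

    se = np.sqrt(np.clip(np.diag(vcov), 0, None))

    # re-expand dropped constant columns with zero coefficients
    full_coefs = np.zeros(len(terms))
    full_se = np.zeros(len(terms))
    full_vcov = np.zeros((len(terms) + 1, len(terms) + 1))
    pos = {t: i for i, t in enumerate(keep)}
    full_vcov[0, 0] = vcov[0, 0]
    for t in keep:
        i = terms.index(t)
        full_coefs[i] = params[1 + pos[t]]
        full_se[i] = se[1 + pos[t]]
        full_vcov[0, 1 + i] = full_vcov[1 + i, 0] = vcov[0, 1 + pos[t]]
        for u in keep:
            full_vcov[1 + i, 1 + terms.index(u)] = vcov[1 + pos[t], 1 + pos[u]]

    return LogisticFit(
        terms=terms,
        intercept=float(params[0]),
        coefficients=full_coefs,
        standard_errors=full_se,
        vcov=full_vcov,
        n_cases=int(np.sum(y == 1)),
        n_controls=int(np.sum(y == 0)),
        converged=bool(converged),
        weight_scheme=scheme + (f" (dropped constant terms: {dropped})" if dropped else ""),
    )


def _ridge_logistic(design: np.ndarray, y: np.ndarray, weights: np.ndarray,
                    penalty: float, maxiter: int = 200, tol: float = 1e-10):
    """IRLS with an L2 penalty on the slopes (intercept unpenalized)."""
    from scipy.special import expit

    p = design.shape[1]
    pen = np.full(p, penalty)
    pen[0] = 0.0
    beta = np.zeros(p)
    converged = False
    for _ in range(maxiter):
        eta = design @ beta
        mu = expit(eta)
        w = weights * mu * (1 - mu)
        H = design.T @ (design * w[:, None]) + np.diag(pen)
        g = design.T @ (weights * (y - mu)) - pen * beta
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    eta = design @ beta
    mu = expit(eta)
    w = weights * mu * (1 - mu)
    H = design.T @ (design * w[:, None]) + np.diag(pen)
    vcov = np.linalg.inv(H)
    return beta, vcov, converged


def fit_observer_model(opportunistic: pd.DataFrame, telemetry: pd.DataFrame,
                       stack: CovariateStack, bias_covariates: Sequence[str],
                       transform_log: dict[str, float] | None = None,
                       ridge_penalty: float = 0.0) -> LogisticFit:
    """Fit the observer model: opportunistic (1) vs telemetry (0) locations.

    Parameters
    ----------
    bias_covariates
        Layer names describing observer accessibility/visibility.
    transform_log
        Optional ``{term: epsilon}`` mapping; named terms enter as
        ``log(x + eps)``.  Pass e.g. ``default_epsilons(stack, terms)`` for
        skewed empirical distance covariates; simulation-scale covariates
        are typically left untransformed.
    """
    if len(opportunistic) == 0 or len(telemetry) == 0:
        raise ValueError("both point sets must be non-empty")
    X_opp = extract_covariates(opportunistic, stack, bias_covariates)
    X_tel = extract_covariates(telemetry, stack, bias_covariates)
    X = pd.concat([X_opp, X_tel], ignore_index=True)
    y = np.concatenate([np.ones(len(X_opp)), np.zeros(len(X_tel))])
    transform_log = dict(transform_log or {})
    X = log_transform_columns(X, transform_log)
    fit = fit_logistic(X, y, ridge_penalty=ridge_penalty,
                       weight_scheme="observer contrast (opportunistic=1, telemetry=0)")
    fit.transform_log = transform_log
    return fit


def predict_observer_probability(fit: LogisticFit, points: pd.DataFrame,
                                 stack: CovariateStack) -> np.ndarray:
    """Predicted probability that each location would carry an opportunistic record."""
    if not fit.converged:
        raise ValueError("observer model did not converge; refusing to predict")
    table = extract_covariates(points, stack, fit.terms)
    return fit.predict_probability(table)
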