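"""Nonlinear calibration of growth laws to confluency time series.

Gompertz and generalized-logistic closed forms are fitted by least squares
(scipy ``least_squares``, trust-region reflective, deterministic multistart)
to (time, confluency) series; fits are compared with the least-squares AIC

    AIC = n_obs * ln(RSS / n_obs) + 2 * (k + 1)

(the +1 counts the error variance).  The Gompertz law only identifies the
composite rate g = lam*omega_bar, so its fit exposes g; separate lam and
omega estimates come from the generalized-logistic fit.  The death rate
delta is fixed (default 0) unless explicitly requested, keeping at most
three free parameters.

The AIC ratio AIC_gompertz / AIC_genlogistic is the relative goodness-of-fit
summary: with both AICs negative, values above 1 mean the Gompertz fit is an
improvement once the extra generalized-logistic parameter is penalized.  A
sign mismatch makes the ratio non-interpretable and is flagged.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import least_squares

from .laws import GrowthParams, TimeSeries, closed_form

__all__ = [
    "FitResult",
    "ExperimentSet",
    "AICRatio",
    "LinearFit",
    "fit_growth_law",
    "aic_score",
    "normalized_aic",
    "confluence_aic_regression",
    "lambda_omega_regression",
]

_RSS_FLOOR = 1e-30

# deterministic multistart grids (best RSS wins; ties -> first found)
_GENLOG_STARTS = [(lam, om) for lam in (0.01, 0.1, 1.0) for om in (0.5, 2.0, 8.0)]
_GOMPERTZ_STARTS = [0.01, 0.1, 1.0]


@dataclass
class FitResult:
    """Estimates and diagnostics of one least-squares growth-law fit."""

    law: str
    estimates: dict
    rss: float
    n_obs: int
    k: int
    aic: float = np.nan
    converged: bool = False
    rss_floored: bool = False
    cov: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "law": self.law,
            "estimates": {k: float(v) for k, v in self.estimates.items()},
            "rss": float(self.rss),
            "n_obs": int(self.n_obs),
            "k": int(self.k),
            "aic": float(self.aic),
            "converged": bool(self.converged),
        }


@dataclass
class ExperimentSet:
    """A collection of confluency series: DataFrame with columns
    (cell_line, u0, replicate, time, confluency), plus an optional manifest
    of ground-truth parameters per cell line (for synthetic data)."""

    data: pd.DataFrame
    manifest: dict = field(default_factory=dict)

    REQUIRED = ("cell_line", "u0", "replicate", "time", "confluency")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"missing required columns: {missing}")

    def series(self) -> Iterable[tuple[tuple, TimeSeries]]:
        """Iterate (key, TimeSeries) per (cell_line, u0, replicate)."""
        for key, grp in self.data.groupby(["cell_line", "u0", "replicate"], sort=True):
            grp = grp.sort_values("time")
            yield key, TimeSeries(
                grp["time"].to_numpy(),
                grp["confluency"].to_numpy(),
                condition=str(key[0]),
                replicate=int(key[2]),
                meta={"u0": float(key[1])},
            )


def _model_curve(law: str, t: np.ndarray, x: np.ndarray, delta: float,
                 fit_delta: bool) -> np.ndarray:
    if fit_delta:
        delta = x[-1]
    if law == "gen_logistic":
        p = GrowthParams("gen_logistic", lam=x[0], omega_bar=x[1],
                         delta=delta, u0=x[2])
    else:
        p = GrowthParams("gompertz", lam=x[0], omega_bar=1.0,
                         delta=delta, u0=x[1])
    return closed_form(p, t)


def fit_growth_law(
    ts: TimeSeries,
    law: str,
    delta: float = 0.0,
    fit_delta: bool = False,
    max_omega: float = 100.0,
) -> FitResult:
    """Fit ``gen_logistic`` (free: lam, omega_bar, u0) or ``gompertz``
    (free: g, u0) to a confluency series by least squares on the closed-form
    solution; ``delta`` is held fixed unless ``fit_delta`` is set.

    Non-convergence is flagged on the result, not raised.  Observations must
    lie in (0, 1].
    """
    if law not in ("gen_logistic", "gompertz"):
        raise ValueError(f"fitting supports gen_logistic/gompertz, got {law!r}")
    t = ts.times
    u = ts.values
    if np.any(u <= 0) or np.any(u > 1.0):
        raise ValueError("confluency observations must lie in (0, 1]")
    k = (3 if law == "gen_logistic" else 2) + (1 if fit_delta else 0)
    if len(ts) < k + 1:
        raise ValueError(f"need at least {k + 1} observations for {law}")
    u0_start = float(np.clip(u[0], 1e-4, 0.999))

    def residuals(x):
        with np.errstate(over="ignore", invalid="ignore"):
            model = _model_curve(law, t, x, delta, fit_delta)
        return np.nan_to_num(model, nan=1e3, posinf=1e3) - u

    if law == "gen_logistic":
        starts = [np.array([lam, om, u0_start]) for lam, om in _GENLOG_STARTS]
        lo = [delta + 1e-9 if not fit_delta else 1e-9, 1e-3, 1e-6]
        hi = [50.0, max_omega, 1.0]
        names = ["lam", "omega_bar", "u0"]
    else:
        starts = [np.array([g, u0_start]) for g in _GOMPERTZ_STARTS]
        lo = [1e-9, 1e-6]
        hi = [50.0, 1.0]
        names = ["g", "u0"]
    if fit_delta:
        starts = [np.append(x, max(delta, 1e-4)) for x in starts]
        lo = lo + [0.0]
        hi = hi + [10.0]
        names = names + ["delta"]

    best = None
    for x0 in starts:
        x0 = np.clip(x0, lo, hi)
        try:
            res = least_squares(residuals, x0, bounds=(lo, hi), method="trf")
        except Exception:
            continue
        rss = float(2.0 * res.cost)
        if best is None or rss < best[0] - 1e-15:
            best = (rss, res)
    if best is None:
        est = dict(zip(names, starts[0]))
        return FitResult(law, est, np.inf, len(ts), k, np.nan, converged=False)
    rss, res = best
    est = dict(zip(names, res.x))
    if not fit_delta:
        est["delta"] = delta
    fit = FitResult(
        law=law,
        estimates=est,
        rss=rss,
        n_obs=len(ts),
        k=k,
        converged=bool(res.status > 0),
    )
    fit.aic = aic_score(fit)
    return fit


def aic_score(fit: FitResult) -> float:
    """Least-squares AIC: n*ln(RSS/n) + 2(k+1).  A zero RSS is floored at a
    tiny epsilon and flagged on the fit."""
    if not np.isfinite(fit.rss):
        return np.nan
    rss = fit.rss
    if rss < _RSS_FLOOR:
        rss = _RSS_FLOOR
        fit.rss_floored = True
    return fit.n_obs * math.log(rss / fit.n_obs) + 2.0 * (fit.k + 1)


class AICRatio(NamedTuple):
    ratio: float
    interpretable: bool


def normalized_aic(fit_gompertz: FitResult, fit_genlog: FitResult) -> AICRatio:
    """AIC_gompertz / AIC_genlogistic.

    With both AICs negative (the typical case for good fits), values above
    1.0 mean Gompertz improves on generalized logistic after the parameter
    penalty.  Any non-negative AIC makes the ratio non-interpretable on that
    scale; the flag records this.
    """
    if not (fit_gompertz.converged and fit_genlog.converged):
        raise ValueError("both fits must have converged")
    if fit_genlog.aic == 0.0:
        raise ZeroDivisionError("generalized-logistic AIC is zero")
    ratio = fit_gompertz.aic / fit_genlog.aic
    interpretable = fit_gompertz.aic < 0.0 and fit_genlog.aic < 0.0
    return AICRatio(ratio, interpretable)


class LinearFit(NamedTuple):
    slope: float
    intercept: float
    r2_adj: float
    n: int


def _ols(x: np.ndarray, y: np.ndarray) -> LinearFit:
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return LinearFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r2_adj=float(model.rsquared_adj),
        n=int(len(y)),
    )


def confluence_aic_regression(
    experiments: Sequence[tuple] | pd.DataFrame,
    grouping: str | None = "cell_line",
) -> dict:
    """OLS of the AIC ratio on initial confluence u0: pooled and per group.

    ``experiments`` is a DataFrame with columns (u0, ratio[, cell_line]) or a
    sequence of (u0, ratio) / (u0, ratio, cell_line) tuples.  Each regression
    requires at least 3 points and non-constant u0.  Returns
    ``{"pooled": LinearFit, "per_group": {name: LinearFit}}``.
    """
    if isinstance(experiments, pd.DataFrame):
        df = experiments.copy()
    else:
        rows = list(experiments)
        if rows and len(rows[0]) == 3:
            df = pd.DataFrame(rows, columns=["u0", "ratio", "cell_line"])
        else:
            df = pd.DataFrame(rows, columns=["u0", "ratio"])
    if "u0" not in df.columns or "ratio" not in df.columns:
        raise ValueError("need columns u0 and ratio")

    def _fit_block(block: pd.DataFrame) -> LinearFit:
        if len(block) < 3:
            raise ValueError("regression requires at least 3 points")
        if block["u0"].nunique() < 2:
            raise ValueError("degenerate regression: u0 is constant")
        return _ols(block["u0"].to_numpy(float), block["ratio"].to_numpy(float))

    out = {"pooled": _fit_block(df), "per_group": {}}
    if grouping and grouping in df.columns:
        for name, block in df.groupby(grouping, sort=True):
            out["per_group"][name] = _fit_block(block)
    return out


class PowerLawFit(NamedTuple):
    slope: float
    intercept: float
    n_used: int


def lambda_omega_regression(
    fits: Sequence[FitResult] | Sequence[tuple[float, float]],
) -> PowerLawFit:
    """OLS of ln(omega_bar) on ln(lam) across fits.

    Under an exact constraint lam*omega_bar = C the slope is -1 and the
    intercept ln(C).  Accepts FitResult objects from generalized-logistic
    fits or raw (lam, omega) pairs; nonpositive estimates are excluded with
    a warning.
    """
    pairs = []
    for f in fits:
        if isinstance(f, FitResult):
            lam = f.estimates.get("lam")
            om = f.estimates.get("omega_bar")
        else:
            lam, om = f
        if lam is None or om is None or lam <= 0 or om <= 0:
            warnings.warn("excluding fit with nonpositive lam or omega")
            continue
        pairs.append((lam, om))
    if len(pairs) < 2:
        raise ValueError("need at least 2 fits with positive lam and omega")
    arr = np.asarray(pairs, dtype=float)
    fit = _ols(np.log(arr[:, 0]), np.log(arr[:, 1]))
    return PowerLawFit(fit.slope, fit.intercept, fit.n)
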