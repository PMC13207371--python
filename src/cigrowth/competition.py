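"""Two-subpopulation competition under shared-space contact inhibition.

Both subpopulations inhabit the same lattice/dish, so saturation is driven by
the *total* confluency u = u1 + u2 while each subpopulation keeps its own
birth rate lam_i and birth-neighborhood size omega_i:

    gen_logistic:  du_i/dt = lam_i * u_i * (1 - u**omega_i) - delta * u_i
    gompertz:      du_i/dt = -lam_i * omega_i * u_i * ln(u) - delta * u_i

A larger birth neighborhood lets a subpopulation keep dividing at higher
total crowding, so it can invade and take over despite a lower intrinsic
birth rate.  :func:`invasion_outcome` classifies the asymptotic share of the
invader and :func:`invasion_landscape` scans the (lam2, omega2) plane for
the takeover threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .laws import TimeSeries

__all__ = [
    "CompetitionParams",
    "competition_rhs",
    "solve_competition",
    "invasion_outcome",
    "invasion_landscape",
    "InvasionResult",
]

_STEADY_TOL = 1e-9


@dataclass(frozen=True)
class CompetitionParams:
    """Rates, neighborhood sizes and initial confluencies of the two
    subpopulations; ``delta`` is shared."""

    law: str
    lam1: float
    lam2: float
    omega1: float
    omega2: float
    delta: float = 0.0
    u1_0: float = 0.1
    u2_0: float = 0.01

    def __post_init__(self) -> None:
        if self.law not in ("gen_logistic", "gompertz"):
            raise ValueError("law must be gen_logistic or gompertz")
        if min(self.lam1, self.lam2, self.omega1, self.omega2, self.delta) < 0:
            raise ValueError("rates and neighborhood sizes must be >= 0")
        if self.u1_0 < 0 or self.u2_0 < 0 or self.u1_0 + self.u2_0 > 1:
            raise ValueError("initial confluencies must be >= 0 with sum <= 1")

    def swapped(self) -> "CompetitionParams":
        return replace(
            self,
            lam1=self.lam2,
            lam2=self.lam1,
            omega1=self.omega2,
            omega2=self.omega1,
            u1_0=self.u2_0,
            u2_0=self.u1_0,
        )


def competition_rhs(params: CompetitionParams, u1: float, u2: float):
    """(du1/dt, du2/dt) at state (u1, u2); the Gompertz coupling needs total
    u = u1 + u2 > 0."""
    if u1 < 0 or u2 < 0:
        raise ValueError("confluencies must be nonnegative")
    u = u1 + u2
    if params.law == "gen_logistic":
        d1 = params.lam1 * u1 * (1.0 - u**params.omega1) - params.delta * u1
        d2 = params.lam2 * u2 * (1.0 - u**params.omega2) - params.delta * u2
    else:
        if u <= 0:
            raise ValueError("gompertz competition undefined at total u = 0")
        lnu = np.log(u)
        d1 = -params.lam1 * params.omega1 * u1 * lnu - params.delta * u1
        d2 = -params.lam2 * params.omega2 * u2 * lnu - params.delta * u2
    return d1, d2


def _rhs_vec(params: CompetitionParams):
    def rhs(_t, y):
        u1 = max(y[0], 0.0)
        u2 = max(y[1], 0.0)
        if params.law == "gompertz" and u1 + u2 <= 0:
            return [0.0, 0.0]
        return list(competition_rhs(params, u1, u2))

    return rhs


def solve_competition(
    params: CompetitionParams, times: Sequence[float]
) -> tuple[TimeSeries, TimeSeries]:
    """Integrate both subpopulations on a strictly increasing time grid."""
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2 or not np.all(np.diff(times) > 0):
        raise ValueError("times must be a strictly increasing 1-d grid")
    sol = solve_ivp(
        _rhs_vec(params),
        (times[0], times[-1]),
        [params.u1_0, params.u2_0],
        t_eval=times,
        method="LSODA",
        rtol=1e-10,
        atol=1e-12,
    )
    if not sol.success:
        raise RuntimeError(f"competition integration failed: {sol.message}")
    u1 = np.clip(sol.y[0], 0.0, None)
    u2 = np.clip(sol.y[1], 0.0, None)
    return (
        TimeSeries(times, u1, condition="subpop1"),
        TimeSeries(times, u2, condition="subpop2"),
    )


class InvasionResult(NamedTuple):
    outcome: str
    share: float
    equilibrated: bool
    u1: float
    u2: float


def invasion_outcome(
    params: CompetitionParams,
    horizon: float = 5e4,
    tol: float = 1e-3,
) -> InvasionResult:
    """Integrate until the system is (numerically) stationary and classify
    the invader's asymptotic share u2/(u1+u2): below ``tol`` the resident
    retains, above 1 - ``tol`` the invader takes over, otherwise the two
    coexist.  A run that hits the horizon before stationarity is flagged
    ``equilibrated=False``."""
    if params.u2_0 <= 0:
        raise ValueError("invader must be present: u2_0 > 0")

    rhs = _rhs_vec(params)

    def steady(t, y):
        d1, d2 = rhs(t, y)
        return max(abs(d1), abs(d2)) - _STEADY_TOL

    steady.terminal = True
    steady.direction = -1
    sol = solve_ivp(
        rhs,
        (0.0, horizon),
        [params.u1_0, params.u2_0],
        method="LSODA",
        rtol=1e-10,
        atol=1e-13,
        events=steady,
        dense_output=False,
    )
    if not sol.success:
        raise RuntimeError(f"invasion integration failed: {sol.message}")
    u1 = max(float(sol.y[0, -1]), 0.0)
    u2 = max(float(sol.y[1, -1]), 0.0)
    equilibrated = bool(sol.t_events[0].size > 0)
    total = u1 + u2
    share = u2 / total if total > 0 else 0.0
    if share < tol:
        outcome = "resident_retains"
    elif share > 1.0 - tol:
        outcome = "invader_takes_over"
    else:
        outcome = "coexistence"
    return InvasionResult(outcome, share, equilibrated, u1, u2)


def invasion_landscape(
    base: CompetitionParams,
    lam2_grid: Sequence[float],
    omega2_grid: Sequence[float],
    horizon: float = 5e4,
    tol: float = 1e-3,
) -> pd.DataFrame:
    """Invasion outcome over a (lam2, omega2) grid; per fixed omega2 the set
    of lam2 giving takeover has threshold (up-set) structure."""
    lam2_grid = np.asarray(lam2_grid, dtype=float)
    omega2_grid = np.asarray(omega2_grid, dtype=float)
    if np.any(lam2_grid <= 0) or np.any(omega2_grid <= 0):
        raise ValueError("grids must be positive")
    if not (np.all(np.diff(lam2_grid) > 0) and np.all(np.diff(omega2_grid) > 0)):
        raise ValueError("grids must be sorted increasing")
    rows = []
    for om2 in omega2_grid:
        for lam2 in lam2_grid:
            p = replace(base, lam2=float(lam2), omega2=float(om2))
            res = invasion_outcome(p, horizon=horizon, tol=tol)
            rows.append(
                (float(lam2), float(om2), res.outcome, res.share, res.equilibrated)
            )
    return pd.DataFrame(
        rows, columns=["lam2", "omega2", "outcome", "final_share", "equilibrated"]
    )
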