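"""Mean-field growth laws derived from contact inhibition of division.

Starting from the master growth equation du/dt = u*lam*(1 - E[P(omega|n)]) -
u*delta, different assumptions about migration and neighborhood geometry give
different expressions for the expected blocked probability E[P(omega|n)], and
hence different classical growth laws:

===========================  ==========================================
law                          du/dt (density u) or dn/dt (count n)
===========================  ==========================================
``gen_logistic``             lam*u*(1 - u**omega_bar) - delta*u
``gompertz``                 -lam*omega_bar*u*ln(u) - delta*u
``gen_logistic_corrected``   lam*u*(1 - u**omega_bar*(1 + sigma^2 (ln u)^2 / 2)) - delta*u
``gompertz_corrected``       -lam*u*(omega_bar*ln u + (sigma^2+omega_bar^2)(ln u)^2/2) - delta*u
``exponential_saturating``   lam*u*(1 - I[u >= 1]) - delta*u
``radial``                   lam*d*n**((d-1)/d) - delta*n        (count space)
``fractal``                  lam*a*n**(D/d) - delta*n            (count space)
===========================  ==========================================

The generalized logistic (Richards) law arises in the well-mixed regime with
a tightly distributed birth-neighborhood size omega_bar; the Gompertz law is
its omega_bar -> 0 limit at fixed composite rate g = lam*omega_bar, valid when
the population is not too sparse (see :func:`gompertz_condition_margin`).
Radial and fractal laws arise without migration, where only surface cells can
divide; they are kept in count space ``n`` (a density version divides by l
and carries an explicit l**(-1/d) factor).

The Gompertz law is parametrized internally by the composite rate
``g = lam * omega_bar`` because lam and omega_bar are not separately
identifiable from a Gompertz curve; :class:`GrowthParams` accepts either
``lam`` together with ``omega_bar`` or the product directly via ``lam`` with
``omega_bar=1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "DENSITY_LAWS",
    "COUNT_LAWS",
    "GrowthParams",
    "TimeSeries",
    "growth_rhs",
    "closed_form",
    "solve_growth",
    "steady_state",
    "gompertz_condition_margin",
]

DENSITY_LAWS = (
    "exponential_saturating",
    "gen_logistic",
    "gompertz",
    "gen_logistic_corrected",
    "gompertz_corrected",
)
COUNT_LAWS = ("radial", "fractal")
_ALL_LAWS = DENSITY_LAWS + COUNT_LAWS


@dataclass(frozen=True)
class GrowthParams:
    """Parameter bundle for one growth law.

    Each law reads only the parameters it needs: ``lam`` (intrinsic birth
    rate, 1/time) and ``delta`` (death rate, 1/time) always; ``omega_bar``
    (mean birth-neighborhood size) and optionally ``sigma_omega`` for the
    well-mixed laws; ``d`` (embedding dimension), ``D`` (fractal dimension,
    d-1 < D <= d) and ``a`` (length constant) for the spatial laws; ``u0``
    the initial density (or count, for the count-space laws).
    """

    law: str
    lam: float = 0.0
    delta: float = 0.0
    omega_bar: float | None = None
    sigma_omega: float = 0.0
    d: int | None = None
    D: float | None = None
    a: float = 1.0
    u0: float | None = None

    def __post_init__(self) -> None:
        if self.law not in _ALL_LAWS:
            raise ValueError(f"unknown law {self.law!r}; expected one of {_ALL_LAWS}")
        if self.lam < 0 or self.delta < 0 or self.sigma_omega < 0:
            raise ValueError("rates and sigma_omega must be nonnegative")
        if self.law in ("gen_logistic", "gompertz", "gen_logistic_corrected",
                        "gompertz_corrected"):
            if self.omega_bar is None or self.omega_bar <= 0:
                raise ValueError(f"{self.law} requires omega_bar > 0")
        if self.law in COUNT_LAWS:
            if self.d is None or self.d < 1:
                raise ValueError(f"{self.law} requires embedding dimension d >= 1")
        if self.law == "fractal":
            # D = d-1 is the non-fractal boundary where the law reduces to radial
            if self.D is None or not (self.d - 1 <= self.D <= self.d):
                raise ValueError("fractal law requires d-1 <= D <= d")
            if self.a <= 0:
                raise ValueError("fractal length constant a must be > 0")

    @property
    def g(self) -> float:
        """Composite Gompertz rate g = lam * omega_bar."""
        return self.lam * (self.omega_bar if self.omega_bar is not None else 1.0)


@dataclass
class TimeSeries:
    """A (time, value) trajectory with optional condition/replicate labels.

    ``values`` are densities in [0, 1] for density-space laws or counts for
    count-space laws; ``times`` must be strictly increasing.
    """

    times: np.ndarray
    values: np.ndarray
    condition: str = ""
    replicate: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be 1-d arrays of equal length")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("values must be nonnegative")

    def __len__(self) -> int:
        return self.times.size


def growth_rhs(params: GrowthParams, u):
    """Right-hand side du/dt (or dn/dt for count-space laws) at state ``u``.

    Vectorized over ``u``.  The Gompertz variants require u > 0.
    """
    u = np.asarray(u, dtype=float)
    if np.any(u < 0):
        raise ValueError("state must be nonnegative")
    lam, dl = params.lam, params.delta
    law = params.law
    if law == "gen_logistic":
        out = lam * u * (1.0 - u ** params.omega_bar) - dl * u
    elif law == "gompertz":
        if np.any(u == 0):
            raise ValueError("gompertz rhs undefined at u=0 (ln 0)")
        out = -params.g * u * np.log(u) - dl * u
    elif law == "gen_logistic_corrected":
        with np.errstate(divide="ignore", invalid="ignore"):
            lnu2 = np.where(u > 0, np.log(np.where(u > 0, u, 1.0)) ** 2, 0.0)
        sat = u ** params.omega_bar * (1.0 + 0.5 * params.sigma_omega**2 * lnu2)
        out = lam * u * (1.0 - sat) - dl * u
    elif law == "gompertz_corrected":
        if np.any(u == 0):
            raise ValueError("gompertz rhs undefined at u=0 (ln 0)")
        lnu = np.log(u)
        ob, so = params.omega_bar, params.sigma_omega
        out = -lam * u * (ob * lnu + 0.5 * (so**2 + ob**2) * lnu**2) - dl * u
    elif law == "exponential_saturating":
        out = lam * u * (u < 1.0) - dl * u
    elif law == "radial":
        d = params.d
        out = lam * d * u ** ((d - 1) / d) - dl * u
    elif law == "fractal":
        out = lam * params.a * u ** (params.D / params.d) - dl * u
    else:  # pragma: no cover - guarded by GrowthParams
        raise ValueError(f"unknown law {law!r}")
    return out if out.ndim else float(out)


def _genlog_closed(t, lam, omega_bar, u0, delta):
    """Closed-form generalized-logistic solution, overflow-safe.

    The substitution w = u**(-omega_bar) linearizes the Bernoulli equation:
    w(t) = A + (u0**(-omega_bar) - A) e^{-c t} with A = lam/(lam-delta) and
    c = omega_bar*(lam-delta).  For lam > delta the two contributions
    A(1-e^{-ct}) and e^{q0-ct} (q0 = -omega_bar ln u0) are both positive and
    the log is assembled with logaddexp, so u0**(-omega_bar) never overflows.
    """
    t = np.asarray(t, dtype=float)
    if u0 <= 0 or u0 > 1:
        raise ValueError("gen_logistic closed form requires u0 in (0, 1]")
    om = omega_bar
    if abs(lam - delta) < 1e-14 * max(lam, delta, 1.0):
        # lam == delta limiting branch: du/dt = -lam u^{om+1}
        w = u0 ** (-om) + om * lam * t
        return w ** (-1.0 / om)
    c = om * (lam - delta)
    A = lam / (lam - delta)
    q0 = -om * math.log(u0)
    if lam > delta:
        with np.errstate(divide="ignore"):
            bulk = math.log(A) + np.log1p(-np.exp(-c * t))  # -inf at t=0
        lnw = np.logaddexp(bulk, q0 - c * t)
        return np.exp(-lnw / om)
    # decaying branch (lam < delta): direct evaluation is safe since c < 0
    w = A + (math.exp(q0) - A) * np.exp(-c * t)
    return w ** (-1.0 / om)


def _gompertz_closed(t, g, u0, delta):
    t = np.asarray(t, dtype=float)
    if u0 <= 0 or u0 > 1:
        raise ValueError("gompertz closed form requires u0 in (0, 1]")
    if g <= 0:
        raise ValueError("gompertz closed form requires g = lam*omega_bar > 0")
    v = (math.log(u0) + delta / g) * np.exp(-g * t) - delta / g
    return np.exp(v)


def closed_form(params: GrowthParams, t):
    """Analytic solution u(t) (or n(t)) where one exists.

    Supported: ``gen_logistic`` (any delta != lam, plus the lam == delta
    limit), ``gompertz`` (any delta), ``radial`` with d=2 and delta=0, and
    ``exponential_saturating`` (piecewise exact for any delta).
    """
    if params.u0 is None:
        raise ValueError("closed_form requires u0 in params")
    t = np.asarray(t, dtype=float)
    law = params.law
    if law == "gen_logistic":
        return _genlog_closed(t, params.lam, params.omega_bar, params.u0, params.delta)
    if law == "gompertz":
        return _gompertz_closed(t, params.g, params.u0, params.delta)
    if law == "radial":
        if params.d != 2 or params.delta != 0:
            raise ValueError("radial closed form implemented for d=2, delta=0")
        return (math.sqrt(params.u0) + params.lam * t) ** 2
    if law == "exponential_saturating":
        # below saturation: u' = (lam-delta) u; at u=1 the indicator switches
        # and the exact solution slides along u=1 while lam > delta
        lam, dl, u0 = params.lam, params.delta, params.u0
        if u0 > 1:
            raise ValueError("exponential_saturating requires u0 <= 1")
        r = lam - dl
        u = u0 * np.exp(r * t)
        if r > 0 and u0 < 1:
            t_hit = math.log(1.0 / u0) / r
            u = np.where(t >= t_hit, 1.0, u)
        elif u0 >= 1:
            u = np.where(lam >= dl, 1.0, np.exp(-dl * t))
        return np.minimum(u, 1.0)
    raise ValueError(f"no closed form for law {law!r}")


def solve_growth(
    params: GrowthParams,
    times: Sequence[float],
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> TimeSeries:
    """Numerical trajectory of the selected law on a strictly increasing time
    grid, by adaptive integration (LSODA).  Where a closed form exists the two
    agree to <= 1e-6 in sup-norm.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2 or not np.all(np.diff(times) > 0):
        raise ValueError("times must be a strictly increasing 1-d grid")
    if params.u0 is None:
        raise ValueError("solve_growth requires u0 in params")
    if params.law == "exponential_saturating":
        # indicator rhs is discontinuous at u=1; the piecewise analytic
        # solution is exact and avoids integrator chatter on the sliding mode
        vals = closed_form(params, times)
        return TimeSeries(times, np.asarray(vals))

    u_floor = 1e-300 if params.law.startswith("gompertz") else 0.0

    def rhs(_t, y):
        u = max(y[0], u_floor) if u_floor else max(y[0], 0.0)
        return [growth_rhs(params, u)]

    sol = solve_ivp(
        rhs,
        (times[0], times[-1]),
        [params.u0],
        t_eval=times,
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"integration failed for {params.law}: {sol.message}")
    vals = np.clip(sol.y[0], 0.0, None)
    return TimeSeries(times, vals, condition=params.law)


def steady_state(params: GrowthParams) -> float:
    """Nontrivial fixed point of the density-space laws (0 on extinction,
    i.e. when delta >= lam for the saturating laws)."""
    lam, dl = params.lam, params.delta
    if params.law == "gen_logistic":
        if dl >= lam:
            return 0.0
        return (1.0 - dl / lam) ** (1.0 / params.omega_bar)
    if params.law == "gompertz":
        # -g u ln u = delta u  =>  u* = exp(-delta/g); positive for any delta
        if params.g <= 0:
            return 0.0
        return math.exp(-dl / params.g)
    if params.law == "exponential_saturating":
        return 1.0 if lam > dl else 0.0
    raise ValueError(f"steady_state not defined for law {params.law!r}")


def gompertz_condition_margin(
    omega_bar: float,
    sigma_omega: float,
    u: float,
    strictness_factor: float = 10.0,
) -> tuple[float, bool]:
    """Margin of the Gompertz validity condition
    ``2*omega_bar/(sigma_omega**2 + omega_bar**2) >> |ln u|``.

    The ``>>`` is operationalized as a multiplicative ``strictness_factor``
    (default 10): margin = 2*ob/(so^2+ob^2) - factor*|ln u|, satisfied iff the
    margin is positive.  The condition fails at low density (|ln u| large),
    which is why Gompertz fits are poor for sparse populations.
    """
    if omega_bar <= 0:
        raise ValueError("omega_bar must be > 0")
    if sigma_omega < 0:
        raise ValueError("sigma_omega must be >= 0")
    if not 0 < u <= 1:
        raise ValueError("u must be in (0, 1]")
    margin = 2.0 * omega_bar / (sigma_omega**2 + omega_bar**2)
    margin -= strictness_factor * abs(math.log(u))
    return margin, margin > 0


def gompertz_equivalent(params: GrowthParams) -> GrowthParams:
    """The Gompertz law with the same composite rate g = lam*omega_bar, death
    rate and initial condition as a generalized-logistic parameter set."""
    return replace(
        params, law="gompertz", lam=params.g, omega_bar=1.0, sigma_omega=0.0
    )
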