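"""Exact stochastic simulation of the well-mixed birth-death chain.

The population size n follows a continuous-time Markov chain with per-capita
birth rate lam*(1 - (n/l)**omega) — the well-mixed blocked probability in its
large-l limit — and per-capita death rate delta.  Its deterministic (l -> oo)
limit is the generalized-logistic law; the drift and diffusion coefficients
of the density u = n/l are a(u) = (lam(u) - delta)*u and
b(u) = (lam(u) + delta)*u/l, which :func:`empirical_drift_diffusion`
estimates from ensembles of runs for consistency checks against the
mean-field equation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GillespieTrajectory",
    "wellmixed_gillespie",
    "density_on_grid",
    "empirical_drift_diffusion",
]


@dataclass
class GillespieTrajectory:
    """Event-time record of one run: n(t) is piecewise constant, jumping at
    the recorded times."""

    times: np.ndarray
    n: np.ndarray
    l: int
    meta: dict = field(default_factory=dict)

    @property
    def density(self) -> np.ndarray:
        return self.n / self.l


def wellmixed_gillespie(
    l: int,
    omega: int,
    lam: float,
    delta: float,
    n0: int,
    horizon: float,
    seed: int,
) -> GillespieTrajectory:
    """Exact event-driven simulation up to time ``horizon``.

    Birth is impossible at n = l (the density factor vanishes) and n = 0 is
    absorbing, so the run ends early if either no event can occur or the
    population dies out.
    """
    if not 1 <= n0 <= l:
        raise ValueError("need 1 <= n0 <= l")
    if omega < 0 or lam < 0 or delta < 0 or horizon <= 0:
        raise ValueError("invalid rates or horizon")
    rng = np.random.default_rng(seed)
    t = 0.0
    n = int(n0)
    times = [0.0]
    counts = [n]
    while t < horizon and n > 0:
        u = n / l
        birth = lam * (1.0 - u**omega) * n
        death = delta * n
        total = birth + death
        if total <= 0.0:
            break  # e.g. full lattice with no death: frozen forever
        t += rng.exponential(1.0 / total)
        if t > horizon:
            break
        if rng.random() < birth / total:
            n += 1
        else:
            n -= 1
        times.append(t)
        counts.append(n)
    return GillespieTrajectory(
        times=np.asarray(times),
        n=np.asarray(counts, dtype=np.int64),
        l=l,
        meta={"omega": omega, "lam": lam, "delta": delta, "n0": n0, "seed": seed},
    )


def density_on_grid(traj: GillespieTrajectory, grid: np.ndarray) -> np.ndarray:
    """Density u sampled on an arbitrary time grid (piecewise-constant
    interpolation between events)."""
    grid = np.asarray(grid, dtype=float)
    idx = np.searchsorted(traj.times, grid, side="right") - 1
    idx = np.clip(idx, 0, traj.n.size - 1)
    return traj.n[idx] / traj.l


def empirical_drift_diffusion(
    ensemble: list[GillespieTrajectory],
    u_bins: np.ndarray,
    dt_window: float,
) -> pd.DataFrame:
    """Binned drift/diffusion estimates from density increments.

    For each run, densities are sampled on a uniform grid of spacing
    ``dt_window``; each increment du over a window is assigned to the bin of
    its starting density.  Per bin the estimates are drift = mean(du)/dt,
    diffusion = var(du)/dt, with the drift standard error
    sd(du)/(sqrt(count)*dt).  Bins with no observations are reported as
    missing (NaN), not zero.
    """
    u_bins = np.asarray(u_bins, dtype=float)
    if u_bins.ndim != 1 or u_bins.size < 2 or not np.all(np.diff(u_bins) > 0):
        raise ValueError("u_bins must be increasing bin edges")
    if dt_window <= 0:
        raise ValueError("dt_window must be > 0")
    starts: list[np.ndarray] = []
    incs: list[np.ndarray] = []
    for tr in ensemble:
        grid = np.arange(0.0, tr.times[-1] + 0.5 * dt_window, dt_window)
        if grid.size < 2:
            continue
        u = density_on_grid(tr, grid)
        starts.append(u[:-1])
        incs.append(np.diff(u))
    if not starts:
        raise ValueError("ensemble contains no usable windows")
    u0 = np.concatenate(starts)
    du = np.concatenate(incs)
    which = np.digitize(u0, u_bins) - 1
    rows = []
    for b in range(u_bins.size - 1):
        sel = du[which == b]
        mid = 0.5 * (u_bins[b] + u_bins[b + 1])
        if sel.size == 0:
            rows.append(
                (u_bins[b], u_bins[b + 1], mid, np.nan, np.nan, np.nan, np.nan, 0)
            )
            continue
        u_mean = u0[which == b].mean()
        drift = sel.mean() / dt_window
        if sel.size > 1:
            sd = sel.std(ddof=1)
            diff = sd**2 / dt_window
            se = sd / (np.sqrt(sel.size) * dt_window)
        else:
            diff = np.nan
            se = np.nan
        rows.append((u_bins[b], u_bins[b + 1], mid, u_mean, drift, se, diff, sel.size))
    return pd.DataFrame(
        rows,
        columns=[
            "u_lo",
            "u_hi",
            "u_mid",
            "u_mean",
            "drift",
            "drift_se",
            "diffusion",
            "count",
        ],
    )
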