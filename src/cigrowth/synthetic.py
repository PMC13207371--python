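"""Synthetic datasets with the statistical structure the fitting pipeline
assumes.

Two generators:

* :func:`generate_invitro_dataset` emulates plate-reader confluency
  experiments — several "cell lines" with line-specific growth parameters,
  each seeded at several initial confluencies with replicates, observed on a
  fixed time grid with multiplicative Gaussian measurement noise
  (u_obs = u_true*(1+eps), eps ~ N(0, CV^2), clipped to (floor, 1]).

* :func:`generate_abm_dataset` emulates the in-silico design: lattice ABM
  growth curves across birth-neighborhood sizes with the product lam*omega
  held fixed, under a chosen migration mode, averaged over seeds.

Defaults: 7 cell lines, initial confluencies {0.01, 0.05, 0.1, 0.2, 0.4},
3 replicates, 50 samples over 240 h, CV = 0.02.  Line birth rates are
log-spaced over 0.02-0.06 /h (doubling times roughly 12-35 h, typical of
cultured cancer lines) and paired with neighborhood sizes descending from 8
to 1, mirroring the inverse lam-omega relationship the fitting pipeline is
meant to detect.  Ground-truth parameters are recorded in the manifest so
recovery can be tested end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .abm import ABMParams, LatticeState, NeighborhoodSpec, run_abm
from .fitting import ExperimentSet
from .laws import GrowthParams, closed_form

__all__ = [
    "SyntheticDesign",
    "generate_invitro_dataset",
    "generate_abm_dataset",
    "ABMGrowthData",
]

_OMEGA_TO_KIND = {4: "von_neumann", 8: "moore", 12: "von_neumann2", 24: "moore2"}


def _default_line_params(n_lines: int) -> list[dict]:
    lams = np.geomspace(0.02, 0.06, n_lines)
    omegas = np.geomspace(8.0, 1.0, n_lines)
    return [
        {
            "law": "gen_logistic",
            "lam": float(lam),
            "omega_bar": float(om),
            "delta": 0.0,
        }
        for lam, om in zip(lams, omegas)
    ]


@dataclass
class SyntheticDesign:
    """Design of an in-vitro-like confluency experiment; ``seed`` is
    mandatory and fully determines the dataset."""

    seed: int
    n_cell_lines: int = 7
    u0_levels: tuple[float, ...] = (0.01, 0.05, 0.1, 0.2, 0.4)
    replicates: int = 3
    times: np.ndarray = field(default_factory=lambda: np.linspace(0.0, 240.0, 50))
    cv: float = 0.02
    floor: float = 1e-6
    line_params: list[dict] | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.cv < 0:
            raise ValueError("CV must be >= 0")
        if not all(0 < u < 1 for u in self.u0_levels):
            raise ValueError("u0 levels must lie in (0, 1)")
        if self.replicates < 1 or self.n_cell_lines < 1:
            raise ValueError("need at least one replicate and one cell line")
        if self.line_params is None:
            self.line_params = _default_line_params(self.n_cell_lines)
        elif len(self.line_params) != self.n_cell_lines:
            raise ValueError("line_params length must equal n_cell_lines")


def generate_invitro_dataset(design: SyntheticDesign) -> ExperimentSet:
    """Noisy saturating growth curves per (cell line, u0, replicate).

    Deterministic given ``design.seed``; the manifest stores each line's
    true law and parameters for recovery tests.
    """
    rng = np.random.default_rng(design.seed)
    rows = []
    manifest: dict = {"seed": design.seed, "cv": design.cv, "lines": {}}
    for i, lp in enumerate(design.line_params):
        line = f"line{i + 1:02d}"
        manifest["lines"][line] = dict(lp)
        for u0 in design.u0_levels:
            params = GrowthParams(
                law=lp["law"],
                lam=lp["lam"],
                omega_bar=lp.get("omega_bar"),
                delta=lp.get("delta", 0.0),
                u0=u0,
            )
            u_true = np.asarray(closed_form(params, design.times))
            for rep in range(1, design.replicates + 1):
                eps = rng.normal(0.0, design.cv, size=u_true.shape)
                u_obs = np.clip(u_true * (1.0 + eps), design.floor, 1.0)
                for t, v in zip(design.times, u_obs):
                    rows.append((line, u0, rep, t, v))
    df = pd.DataFrame(
        rows, columns=["cell_line", "u0", "replicate", "time", "confluency"]
    )
    return ExperimentSet(df, manifest=manifest)


@dataclass
class ABMGrowthData:
    """Per-neighborhood-size ABM growth curves: mean density over seeds plus
    the per-seed curves, with the birth rate lam = product/omega used."""

    omega: int
    lam: float
    delta: float
    times: np.ndarray
    mean_density: np.ndarray
    per_seed: np.ndarray  # (n_seeds, n_times)
    seeds: list[int]


def generate_abm_dataset(
    omega_list: tuple[int, ...] = (4, 8, 12, 24),
    lam_omega_product: float = 0.1,
    delta: float = 0.001,
    migration_mode: str = "full_domain",
    lattice_dims: tuple[int, int] = (64, 64),
    n_seeds: int = 10,
    horizon: int = 1500,
    u0: float = 0.01,
    dt: float = 1.0,
    seed: int = 0,
) -> dict[int, ABMGrowthData]:
    """ABM growth curves across birth-neighborhood sizes at fixed
    lam*omega.

    Each omega uses its named lattice neighborhood and lam = product/omega;
    ``migration_mode`` is ``"full_domain"`` (m*dt = 1, well-mixed) or
    ``"none"``.  Initial state is a uniformly random configuration at
    density ``u0``.  Replicate seeds are derived deterministically from
    ``seed``.
    """
    if lam_omega_product <= 0:
        raise ValueError("lam*omega product must be > 0")
    if migration_mode not in ("full_domain", "none"):
        raise ValueError("migration_mode must be 'full_domain' or 'none'")
    w, h = lattice_dims
    ss = np.random.SeedSequence(seed)
    out: dict[int, ABMGrowthData] = {}
    for omega in omega_list:
        if omega not in _OMEGA_TO_KIND:
            raise ValueError(f"no named neighborhood with omega={omega}")
        lam = lam_omega_product / omega
        if lam * dt > 1.0:
            raise ValueError(
                f"per-step birth probability lam*dt={lam * dt} > 1 for omega={omega}"
            )
        child_seeds = [int(s) for s in ss.spawn(1)[0].generate_state(n_seeds) % 2**31]
        curves = []
        times = None
        for sd in child_seeds:
            init = LatticeState.random(w, h, u0, seed=sd)
            params = ABMParams(
                lam=lam,
                delta=delta,
                m=1.0 if migration_mode == "full_domain" else 0.0,
                dt=dt,
                birth_nbhd=NeighborhoodSpec(_OMEGA_TO_KIND[omega]),
                migration_nbhd=NeighborhoodSpec("full_domain")
                if migration_mode == "full_domain"
                else NeighborhoodSpec("moore"),
                seed=sd,
            )
            traj = run_abm(w, h, params, init=init, horizon=horizon)
            curves.append(traj.density)
            times = traj.times
        per_seed = np.vstack(curves)
        out[omega] = ABMGrowthData(
            omega=omega,
            lam=lam,
            delta=delta,
            times=times,
            mean_density=per_seed.mean(axis=0),
            per_seed=per_seed,
            seeds=child_seeds,
        )
    return out
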