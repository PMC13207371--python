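"""Neighborhood-occupancy probabilities for on-lattice cell populations.

A focal cell in a population of ``n`` cells on a lattice of ``l`` sites is
*blocked* from dividing when all ``omega`` sites of its birth neighborhood are
occupied.  Under the well-mixed (exchangeable-positions) assumption the number
of occupied neighbor sites ``X`` is hypergeometric: the ``n - 1`` non-focal
cells are placed uniformly without replacement on the ``l - 1`` non-focal
sites, of which ``omega`` form the neighborhood,

    P(X = x | n) = C(omega, x) * C(l - omega - 1, n - x - 1) / C(l - 1, n - 1).

Under strict spatial localization (no migration, radially growing cluster) the
blocked fraction follows instead from a surface/bulk partition of the cluster,
giving ``(1 - n**(-1/d))**d`` in embedding dimension ``d``.  These expressions
are the bridge between the microscopic exclusion process simulated in
:mod:`cigrowth.abm` and the mean-field growth laws in :mod:`cigrowth.laws`.

All quantities are dimensionless probabilities.  Every closed form here has an
independent brute-force oracle (:func:`oracle_blocked_prob`) used by the test
suite.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import stats

__all__ = [
    "OccupancyQuery",
    "RadialGeometry",
    "occupancy_pmf",
    "blocked_prob_wellmixed",
    "blocked_prob_radial",
    "blocked_prob_full_neighborhood",
    "oracle_blocked_prob",
]

#: largest enumeration size accepted by the exhaustive oracle
_MAX_ENUMERATION = 10**6


@dataclass(frozen=True)
class OccupancyQuery:
    """A single occupancy question: ``x`` occupied sites out of an
    ``omega``-site neighborhood, given ``n`` cells on ``l`` sites."""

    n: int
    l: int
    omega: int
    x: int

    def __post_init__(self) -> None:
        _validate_nlo(self.n, self.l, self.omega)
        if not 0 <= self.x <= self.omega:
            raise ValueError(f"x={self.x} outside [0, omega={self.omega}]")

    def pmf(self, exact: bool = False):
        return occupancy_pmf(self.n, self.l, self.omega, self.x, exact=exact)


@dataclass(frozen=True)
class RadialGeometry:
    """Geometry of a compact radially growing cluster of ``n`` cells in
    embedding dimension ``d``; the cell/cluster length-scale ratio is
    ``r/R = n**(-1/d)``."""

    d: int
    n: int

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError("embedding dimension d must be >= 1")
        if self.n < 1:
            raise ValueError("cell count n must be >= 1")

    @property
    def r_over_R(self) -> float:
        return self.n ** (-1.0 / self.d)

    def blocked_prob(self, mode: str = "exact") -> float:
        return blocked_prob_radial(self.n, self.d, mode=mode)


def _validate_nlo(n: int, l: int, omega: int) -> None:
    if n < 1:
        raise ValueError(f"need at least the focal cell: n={n}")
    if l < n:
        raise ValueError(f"lattice cannot hold the population: n={n} > l={l}")
    if not 0 <= omega <= l - 1:
        raise ValueError(f"omega={omega} outside [0, l-1={l - 1}]")


def occupancy_pmf(n: int, l: int, omega: int, x: int, *, exact: bool = False):
    """Probability of observing exactly ``x`` occupied sites in an
    ``omega``-site neighborhood of a focal cell, in a well-mixed population of
    ``n`` cells on ``l`` sites.

    Parameters
    ----------
    exact
        If True, return an exact :class:`fractions.Fraction` (bit-exact for
        any size, intended as the oracle path for small lattices).  Otherwise
        return a float computed through the log-gamma form, safe for ``l`` up
        to at least ``10**6``.

    Infeasible placements (e.g. more leftover cells than leftover sites)
    return probability 0 rather than raising, so the pmf is total over
    ``x = 0..omega``.
    """
    _validate_nlo(n, l, omega)
    if not 0 <= x <= omega:
        raise ValueError(f"x={x} outside [0, omega={omega}]")
    if n - x - 1 < 0 or n - x - 1 > l - omega - 1:
        return Fraction(0) if exact else 0.0
    if exact:
        num = math.comb(omega, x) * math.comb(l - omega - 1, n - x - 1)
        return Fraction(num, math.comb(l - 1, n - 1))
    # hypergeometric with population l-1, omega marked sites, n-1 draws
    return float(stats.hypergeom.pmf(x, l - 1, omega, n - 1))


def blocked_prob_wellmixed(
    n: int, l: int, omega: int, mode: str = "exact", *, rational: bool = False
):
    """Probability that a focal cell's whole ``omega``-site neighborhood is
    occupied, in a well-mixed population of ``n`` cells on ``l`` sites.

    ``mode="exact"`` evaluates the hypergeometric tail point
    ``P(X = omega | n)``, equal to the running product
    ``prod_{j=0}^{omega-1} (n-1-j)/(l-1-j)``; ``mode="limit"`` returns the
    large-``l`` factorized limit ``(n/l)**omega``.  With ``rational=True`` the
    exact mode returns a :class:`~fractions.Fraction`.
    """
    _validate_nlo(n, l, omega)
    if mode == "limit":
        return (n / l) ** omega
    if mode != "exact":
        raise ValueError(f"unknown mode {mode!r}")
    if rational:
        p = Fraction(1)
        for j in range(omega):
            p *= Fraction(n - 1 - j, l - 1 - j)
            if p == 0:
                break
        return p
    p = 1.0
    for j in range(omega):
        p *= (n - 1 - j) / (l - 1 - j)
        if p == 0.0:
            break
    return p


def blocked_prob_radial(n: int, d: int, mode: str = "exact") -> float:
    """Blocked probability of a compact radially growing cluster: the bulk
    fraction ``n0/n = (1 - n**(-1/d))**d``, or its first-order expansion
    ``1 - d*n**(-1/d)`` (clamped at 0; the expansion assumes ``n >> 1``)."""
    if d < 1:
        raise ValueError("embedding dimension d must be >= 1")
    if n < 1:
        raise ValueError("cell count n must be >= 1")
    if mode == "exact":
        return (1.0 - n ** (-1.0 / d)) ** d
    if mode == "firstorder":
        return max(0.0, 1.0 - d * n ** (-1.0 / d))
    raise ValueError(f"unknown mode {mode!r}")


def blocked_prob_full_neighborhood(n: int, l: int) -> int:
    """Blocked probability when the birth neighborhood spans the whole lattice
    (``omega = l - 1``): the indicator ``1 if n >= l else 0``.  Division is
    never blocked until the lattice is literally full, so growth is
    exponential up to saturation rather than logistic."""
    if l < 1:
        raise ValueError("need at least one lattice site")
    if n < 0:
        raise ValueError("cell count cannot be negative")
    return int(n >= l)


def oracle_blocked_prob(
    n: int,
    l: int,
    omega: int,
    method: str = "enumerate",
    reps: int | None = None,
    seed: int | None = None,
):
    """Brute-force estimate of the well-mixed blocked probability.

    Places the ``n - 1`` non-focal cells on the ``l - 1`` non-focal sites of
    an abstract site set whose first ``omega`` sites form the designated
    neighborhood, and measures the fraction of configurations in which all
    ``omega`` neighborhood sites are filled.

    ``method="enumerate"`` iterates every configuration (requires
    ``C(l-1, n-1) <= 10**6``) and returns an exact Fraction.
    ``method="sample"`` draws ``reps`` uniform configurations with the given
    ``seed`` and returns ``(estimate, standard_error)``.

    This function is deliberately independent of the closed forms above; it is
    the test oracle.
    """
    _validate_nlo(n, l, omega)
    if method == "enumerate":
        total = math.comb(l - 1, n - 1)
        if total > _MAX_ENUMERATION:
            raise ValueError(
                f"enumeration size C({l - 1},{n - 1})={total} exceeds {_MAX_ENUMERATION}"
            )
        hood = set(range(omega))
        hits = 0
        for config in itertools.combinations(range(l - 1), n - 1):
            if hood.issubset(config):
                hits += 1
        return Fraction(hits, total)
    if method == "sample":
        if reps is None or reps < 1:
            raise ValueError("sample mode requires reps >= 1")
        if seed is None:
            raise ValueError("sample mode requires a seed")
        rng = np.random.default_rng(seed)
        base = np.zeros(l - 1, dtype=np.uint8)
        base[: n - 1] = 1
        hits = 0
        chunk = 20_000
        done = 0
        while done < reps:
            k = min(chunk, reps - done)
            mats = rng.permuted(np.tile(base, (k, 1)), axis=1)
            hits += int(np.sum(mats[:, :omega].sum(axis=1) == omega))
            done += k
        p = hits / reps
        se = math.sqrt(max(p * (1.0 - p), 1.0 / reps) / reps)
        return p, se
    raise ValueError(f"unknown method {method!r}")
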