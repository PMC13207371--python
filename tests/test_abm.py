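"""Lattice birth-death-migration simulator: rules, estimators, regimes."""

import numpy as np
import pytest

from cigrowth import abm, occupancy
from cigrowth.abm import ABMParams, LatticeState, NeighborhoodSpec


def _params(**kw):
    kw.setdefault("lam", 0.1)
    kw.setdefault("seed", 1)
    return ABMParams(**kw)


class TestNeighborhoods:
    def test_von_neumann_exact_offsets(self):
        offs = set(abm.neighborhood_offsets("von_neumann"))
        assert offs == {(-1, 0), (1, 0), (0, -1), (0, 1)}

    @pytest.mark.parametrize(
        "kind,omega", [("von_neumann", 4), ("moore", 8), ("von_neumann2", 12),
                       ("moore2", 24)]
    )
    def test_sizes(self, kind, omega):
        spec = NeighborhoodSpec(kind)
        assert spec.omega == omega
        assert len(set(spec.offsets)) == omega

    def test_von_neumann2_is_manhattan_radius_2(self):
        for dr, dc in NeighborhoodSpec("von_neumann2").offsets:
            assert 1 <= abs(dr) + abs(dc) <= 2

    def test_moore2_is_chebyshev_radius_2(self):
        for dr, dc in NeighborhoodSpec("moore2").offsets:
            assert 1 <= max(abs(dr), abs(dc)) <= 2

    def test_custom_validation(self):
        with pytest.raises(ValueError):
            NeighborhoodSpec("custom", offsets=((0, 0), (1, 0)))
        with pytest.raises(ValueError):
            NeighborhoodSpec("custom", offsets=((1, 0), (1, 0)))
        with pytest.raises(ValueError):
            NeighborhoodSpec("hexagonal")

    def test_full_domain_has_no_offsets(self):
        spec = NeighborhoodSpec("full_domain")
        assert spec.is_full_domain and spec.omega is None
        with pytest.raises(ValueError):
            abm.neighborhood_offsets(spec)


class TestRunAbm:
    def test_identical_seed_identical_trajectory(self):
        p = _params(delta=0.01, m=0.3, seed=99)
        a = abm.run_abm(32, 32, p, horizon=80)
        b = abm.run_abm(32, 32, p, horizon=80)
        assert np.array_equal(a.n, b.n)
        assert np.array_equal(a.blocked, b.blocked)
        assert np.array_equal(a.surface, b.surface)

    def test_no_rates_no_change(self):
        init = LatticeState.random(24, 24, 0.3, seed=5)
        tr = abm.run_abm(24, 24, _params(lam=0.0, delta=0.0, m=0.7), init=init,
                         horizon=40)
        assert np.all(tr.n == init.n)

    def test_full_lattice_stays_full_and_blocked(self):
        tr = abm.run_abm(16, 16, _params(lam=0.1, delta=0.0, m=0.0),
                         init=LatticeState.full(16, 16), horizon=25)
        assert np.all(tr.n == 256)
        assert np.all(tr.blocked == 256)
        assert np.all(tr.surface == 0)

    def test_exclusion_and_monotone_growth(self):
        tr = abm.run_abm(32, 32, _params(lam=0.3, m=0.2), horizon=200)
        assert np.all(tr.n <= 1024)
        assert np.all(np.diff(tr.n) >= 0)  # delta = 0

    def test_empty_lattice_stays_empty(self):
        init = LatticeState(np.zeros((8, 8), dtype=np.uint8))
        tr = abm.run_abm(8, 8, _params(lam=0.5), init=init, horizon=10)
        assert np.all(tr.n == 0)

    def test_early_growth_matches_branching_process(self):
        """Before crowding, each cell divides independently with probability
        lam*dt, so E[n(t)] = (1 + lam*dt)**t (Galton-Watson mean)."""
        lam, t_check, n_seeds = 0.1, 15, 60
        finals = []
        for s in range(n_seeds):
            tr = abm.run_abm(
                64, 64,
                _params(lam=lam, seed=3000 + s, birth_nbhd=NeighborhoodSpec("moore")),
                horizon=t_check,
            )
            finals.append(tr.n[-1])
        finals = np.array(finals, dtype=float)
        expected = (1 + lam) ** t_check
        se = finals.std(ddof=1) / np.sqrt(n_seeds)
        assert abs(finals.mean() - expected) <= 4 * se

    def test_snapshots_recorded(self):
        tr = abm.run_abm(16, 16, _params(), horizon=20, snapshot_steps=[0, 10, 20])
        assert sorted(tr.snapshots) == [0, 10, 20]
        assert tr.snapshots[0].sum() == 1
        for step, grid in tr.snapshots.items():
            assert grid.sum() == tr.n[step]

    def test_invalid_horizon(self):
        with pytest.raises(ValueError):
            abm.run_abm(8, 8, _params(), horizon=0)


class TestBlockedFraction:
    def test_full_lattice(self):
        st = LatticeState.full(10, 10)
        vn = NeighborhoodSpec("von_neumann")
        assert abm.blocked_fraction(st, vn) == 1.0
        assert abm.blocked_fraction(st, vn, "per_lattice") == 1.0

    def test_single_isolated_cell(self):
        st = LatticeState.single_center_cell(11, 11)
        vn = NeighborhoodSpec("von_neumann")
        assert abm.blocked_fraction(st, vn) == 0.0
        assert abm.blocked_fraction(st, vn, "per_lattice") == 0.0
        assert abm.surface_cell_count(st, vn) == 1

    def test_per_cell_on_empty_lattice_rejected(self):
        st = LatticeState(np.zeros((4, 4), dtype=np.uint8))
        with pytest.raises(ValueError):
            abm.blocked_fraction(st, NeighborhoodSpec("von_neumann"))

    def test_wellmixed_matches_hypergeometric(self):
        """On uniformly random configurations the per-cell blocked fraction
        estimates the exact exchangeable-occupancy probability."""
        l, u, omega = 4096, 0.5, 4
        n = int(u * l)
        exact = occupancy.blocked_prob_wellmixed(n, l, omega)
        vn = NeighborhoodSpec("von_neumann")
        vals = [
            abm.blocked_fraction(LatticeState.random(64, 64, u, seed=s), vn)
            for s in range(20)
        ]
        vals = np.array(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - exact) <= 3 * se

    def test_kernel_and_numpy_estimators_agree(self):
        p = _params(lam=0.2, m=0.1, seed=11, birth_nbhd=NeighborhoodSpec("moore"))
        tr = abm.run_abm(24, 24, p, horizon=60, snapshot_steps=[60])
        st = LatticeState(tr.snapshots[60])
        blocked = abm.blocked_fraction(st, NeighborhoodSpec("moore")) * st.n
        assert int(round(blocked)) == tr.blocked[-1]
        assert abm.surface_cell_count(st, NeighborhoodSpec("moore")) == tr.surface[-1]


class TestSurfaceAndFractal:
    def test_solid_block_perimeter(self):
        st = LatticeState(np.zeros((40, 40), dtype=np.uint8))
        st.occupancy[10:20, 10:20] = 1
        assert abm.surface_cell_count(st, NeighborhoodSpec("von_neumann")) == 36

    def test_full_periodic_lattice_has_no_surface(self):
        st = LatticeState.full(12, 12)
        assert abm.surface_cell_count(st, NeighborhoodSpec("moore")) == 0

    def test_fractal_dimension_all_surface(self):
        assert abm.fractal_dimension_estimate(50, 50, 2) == pytest.approx(2.0)
        assert abm.fractal_dimension_estimate(50, 50, 3) == pytest.approx(3.0)

    def test_fractal_dimension_block_value(self):
        assert abm.fractal_dimension_estimate(100, 36, 2) == pytest.approx(
            2 * np.log(36) / np.log(100)
        )

    def test_fractal_dimension_of_discs_decreases_toward_surface_dim(self):
        """Compact discs of growing radius: D_hat falls toward d - 1 = 1."""
        vn = NeighborhoodSpec("von_neumann")
        dhats = []
        for radius in (5, 10, 20, 35, 50):
            size = 2 * radius + 8
            occ = np.zeros((size, size), dtype=np.uint8)
            yy, xx = np.mgrid[0:size, 0:size]
            occ[(yy - size // 2) ** 2 + (xx - size // 2) ** 2 <= radius**2] = 1
            st = LatticeState(occ)
            dhats.append(
                abm.fractal_dimension_estimate(
                    st.n, abm.surface_cell_count(st, vn), 2
                )
            )
        assert all(b < a for a, b in zip(dhats, dhats[1:]))
        assert 1.0 < dhats[-1] < dhats[0] < 2.0

    def test_fractal_dimension_domain_errors(self):
        with pytest.raises(ValueError):
            abm.fractal_dimension_estimate(1, 1, 2)
        with pytest.raises(ValueError):
            abm.fractal_dimension_estimate(10, 0, 2)


class TestEnsemble:
    def test_identical_trajectories_zero_sd(self):
        p = _params(seed=5)
        trs = [abm.run_abm(16, 16, p, horizon=30) for _ in range(3)]
        _, mean, sd = abm.ensemble_summary(trs)
        assert np.all(sd == 0)
        assert np.array_equal(mean, trs[0].n)

    def test_hand_mean_and_sd(self):
        t = np.arange(5, dtype=float)
        a = abm.Trajectory(t, t.copy(), np.zeros(5), t.copy(), l=100)
        b = abm.Trajectory(t, t + 2, np.zeros(5), t + 2, l=100)
        _, mean, sd = abm.ensemble_summary([a, b])
        np.testing.assert_allclose(mean, t + 1)
        np.testing.assert_allclose(sd, np.sqrt(2.0))

    def test_mismatched_grids_rejected(self):
        t = np.arange(5, dtype=float)
        a = abm.Trajectory(t, t, np.zeros(5), t, l=100)
        b = abm.Trajectory(t[:4], t[:4], np.zeros(4), t[:4], l=100)
        with pytest.raises(ValueError):
            abm.ensemble_summary([a, b])


class TestRegimes:
    """Qualitative growth-regime properties of the simulator."""

    @staticmethod
    def _mean_final_n(omega_kind, m, seeds, horizon=150, mig="moore"):
        finals = []
        for s in seeds:
            p = _params(
                lam=0.1, m=m, seed=s,
                birth_nbhd=NeighborhoodSpec(omega_kind),
                migration_nbhd=NeighborhoodSpec(mig),
            )
            finals.append(abm.run_abm(64, 64, p, horizon=horizon).n[-1])
        return np.array(finals, dtype=float)

    def test_larger_birth_neighborhood_grows_faster_without_migration(self):
        seeds = range(4000, 4010)
        small = self._mean_final_n("von_neumann", 0.0, seeds)
        large = self._mean_final_n("moore2", 0.0, seeds)
        assert large.mean() > small.mean()

    def test_migration_accelerates_growth(self):
        seeds = range(5000, 5010)
        none = self._mean_final_n("moore", 0.0, seeds)
        fast = self._mean_final_n("moore", 1.0, seeds)
        assert fast.mean() > none.mean()

    def test_neighborhood_irrelevant_under_full_mixing(self):
        """With full-domain migration every step, growth curves for omega = 4
        and omega = 24 coincide within the ensemble SD band."""
        seeds = list(range(6000, 6010))
        curves = {}
        for kind in ("von_neumann", "moore2"):
            mat = []
            for s in seeds:
                p = _params(
                    lam=0.1, m=1.0, seed=s,
                    birth_nbhd=NeighborhoodSpec(kind),
                    migration_nbhd=NeighborhoodSpec("full_domain"),
                )
                mat.append(abm.run_abm(64, 64, p, horizon=150).n)
            curves[kind] = np.vstack(mat).astype(float)
        m1 = curves["von_neumann"].mean(axis=0)
        m2 = curves["moore2"].mean(axis=0)
        sd = np.maximum(
            curves["von_neumann"].std(axis=0, ddof=1),
            curves["moore2"].std(axis=0, ddof=1),
        )
        mid = slice(20, 140)
        assert np.all(np.abs(m1[mid] - m2[mid]) <= np.maximum(sd[mid], 5.0))
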