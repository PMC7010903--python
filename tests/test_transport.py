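"""The straight-line CSDA engine: deposition kernel, S values, sweeps."""
import numpy as np
import pytest

from celldose.geometry import (
    CYTOPLASM,
    GOLGI,
    MEMBRANE,
    NUCLEUS,
    SphereCell,
    TruncatedConeCell,
    WellGeometry,
    build_well,
    layout_monolayer,
)
from celldose.transport import KEV_TO_J, TransportEngine, exponential_fit_r2


class TestDepositionKernel:
    def test_miss_deposits_nothing(self, engine, reference_cell):
        # ray pointing straight away from the nucleus
        dep = engine.deposit_along_ray(
            [0.0, -14.0, 2.0], [0.0, -1.0, 0.0], 300.0, reference_cell
        )
        assert dep == 0.0

    def test_stopper_deposits_residual_entry_energy(self, engine, reference_cell):
        """An electron whose range ends inside the nucleus leaves all the
        energy it still carried at the entry point."""
        origin = np.array([0.0, -12.0, reference_cell.nucleus_center[2]])
        direction = np.array([0.0, 1.0, 0.0])
        energy = 20.0  # range ~ 9 um: enters the nucleus and stops inside
        t1, _ = reference_cell.nucleus_entry_exit(origin[None], direction[None])
        total_range = float(engine.material.csda_range(energy))
        assert t1[0, 0] < total_range  # really enters
        expected = engine.material.residual_energy(total_range - t1[0, 0])
        dep = engine.deposit_along_ray(origin, direction, energy, reference_cell)
        assert dep == pytest.approx(float(expected), rel=1e-9)

    def test_partial_traversal_matches_fine_step_integration(self, engine, reference_cell):
        """Chord deposit agrees with 1e4-step integration of dE/ds = -S(E)."""
        origin = np.array([0.0, -12.0, reference_cell.nucleus_center[2]])
        direction = np.array([0.0, 1.0, 0.0])
        energy = 300.0
        t1, t2 = reference_cell.nucleus_entry_exit(origin[None], direction[None])
        # independent oracle: explicit Euler on the stopping-power ODE
        s_grid = np.linspace(0.0, float(t2[0, 0]), 10_001)
        e = energy
        dep_oracle = 0.0
        for a, b in zip(s_grid[:-1], s_grid[1:]):
            de = float(engine.material.stopping_power(e)) * (b - a)
            if a >= t1[0, 0]:
                dep_oracle += de
            e -= de
        dep = engine.deposit_along_ray(origin, direction, energy, reference_cell)
        assert dep == pytest.approx(dep_oracle, rel=1e-3)

    def test_full_path_deposits_all_energy(self, engine):
        """Energy conservation: a chord covering the whole path returns E."""
        energies = np.array([10.0, 50.0, 200.0, 497.0])
        ranges = np.asarray(engine.material.csda_range(energies))
        dep = engine.chord_deposit(ranges, np.zeros(4), ranges * 2)
        np.testing.assert_allclose(dep, energies, rtol=1e-6)


class TestSelfSValue:
    def test_full_absorption_limit(self, engine):
        """Source in a nucleus far larger than any range: S -> Delta / m."""
        cell = SphereCell(6.0e6, 5.0e6)
        sv = engine.self_s_value(cell, NUCLEUS, 1_000_000, seed=11)
        mass_kg = cell.nucleus_volume * 1e-15
        expected = engine.spectrum.delta_kev * KEV_TO_J / mass_kg
        assert abs(sv.value - expected) < 2 * sv.stderr + 1e-3 * expected

    def test_stderr_scales_inverse_sqrt(self, engine, reference_cell):
        a = engine.self_s_value(reference_cell, CYTOPLASM, 20_000, seed=3)
        b = engine.self_s_value(reference_cell, CYTOPLASM, 80_000, seed=3)
        assert a.stderr / b.stderr == pytest.approx(2.0, rel=0.25)

    def test_seeded_determinism(self, engine, reference_cell):
        a = engine.self_s_value(reference_cell, CYTOPLASM, 5_000, seed=9)
        b = engine.self_s_value(reference_cell, CYTOPLASM, 5_000, seed=9)
        assert a.value == b.value and a.stderr == b.stderr

    def test_shrinking_cell_raises_cytoplasm_self_dose(self, engine):
        """1900 vs 3500 um^3: printed increase 56% (checked within 15 pts)."""
        small = TruncatedConeCell.scaled_to_volume(1900.0)
        avg = TruncatedConeCell.scaled_to_volume(3500.0)
        s_small = engine.self_s_value(small, CYTOPLASM, 100_000, seed=4)
        s_avg = engine.self_s_value(avg, CYTOPLASM, 100_000, seed=5)
        increase = 100.0 * (s_small.value / s_avg.value - 1.0)
        assert 41.0 <= increase <= 71.0

    def test_zero_nucleus_volume_rejected(self, engine, reference_cell):
        class Broken:
            nucleus_volume = 0.0

        with pytest.raises(ValueError):
            engine.self_s_value(Broken(), CYTOPLASM)

    def test_sphere_exceeds_flat_cone(self, engine, reference_cell):
        """Compact spheres concentrate cytoplasm near the nucleus."""
        r_c = (3 * 3500 / (4 * np.pi)) ** (1 / 3)
        r_n = (3 * reference_cell.nucleus_volume / (4 * np.pi)) ** (1 / 3)
        sphere = SphereCell(r_c, r_n)
        s_sphere = engine.self_s_value(sphere, CYTOPLASM, 60_000, seed=6)
        s_cone = engine.self_s_value(reference_cell, CYTOPLASM, 60_000, seed=6)
        assert s_sphere.value > s_cone.value


class TestCrossSValue:
    def test_additivity_over_neighbors(self, engine, reference_cell):
        lay = layout_monolayer(reference_cell, gap=0.0, cutoff_um=120.0)
        sv = engine.cross_s_value(reference_cell, lay, CYTOPLASM, 20_000, seed=2)
        assert sv.meta["per_neighbor"].sum() == pytest.approx(sv.value, rel=1e-12)

    def test_first_ring_symmetry(self, engine, reference_cell):
        lay = layout_monolayer(reference_cell, gap=0.0, cutoff_um=280.0)
        sv = engine.cross_s_value(reference_cell, lay, CYTOPLASM, 60_000, seed=3)
        d = np.hypot(lay.positions[:, 0], lay.positions[:, 1])
        ring = sv.meta["per_neighbor"][d < lay.pitch * 1.01]
        assert ring.size == 6
        spread = ring.max() - ring.min()
        assert spread < 0.25 * ring.mean()  # ~3 sigma at this history count

    def test_empty_layout_gives_zero(self, engine, reference_cell):
        from celldose.geometry import MonolayerLayout

        lay = MonolayerLayout(np.empty((0, 3)), 30.0, 0.0, 0.0)
        sv = engine.cross_s_value(reference_cell, lay, CYTOPLASM, 100, seed=0)
        assert sv.value == 0.0

    def test_source_location_does_not_change_cross(self, engine, reference_cell):
        """Published finding: total cross-dose is source-location independent."""
        lay = layout_monolayer(reference_cell, gap=0.0, cutoff_um=280.0)
        cy = engine.cross_s_value(reference_cell, lay, CYTOPLASM, 60_000, seed=4)
        cs = engine.cross_s_value(reference_cell, lay, MEMBRANE, 60_000, seed=5)
        sigma = np.hypot(cy.stderr, cs.stderr)
        assert abs(cy.value - cs.value) < 3 * sigma


class TestMediumSValue:
    def test_empty_medium_zero(self, engine, reference_cell):
        well = WellGeometry(radius_mm=11.05, volume_ml=0.0)
        sv = engine.medium_s_value(reference_cell, well, 100, seed=0)
        assert sv.value == 0.0

    def test_orders_of_magnitude_below_cytoplasm(self, engine, reference_cell):
        sv = engine.medium_s_value(reference_cell, build_well(1.0), 100_000, seed=1)
        s_cy = engine.self_s_value(reference_cell, CYTOPLASM, 50_000, seed=1)
        orders = np.log10(s_cy.value / sv.value)
        assert 6.0 <= orders <= 8.0

    def test_half_space_equilibrium(self, engine, reference_cell):
        """Cell on the floor of a range-thick medium: S = Delta/(2 rho V)."""
        well = WellGeometry(radius_mm=5.0, volume_ml=np.pi * 25 * 6 / 1000)
        sv = engine.medium_s_value(reference_cell, well, 300_000, seed=2)
        expected = 0.5 * engine.spectrum.delta_kev * KEV_TO_J / (well.volume_um3 * 1e-15)
        assert sv.value == pytest.approx(expected, rel=0.05)


class TestParameterSweep:
    def test_volume_sweep_monotone_exponential(self, engine):
        volumes = [1900.0, 2800.0, 3500.0, 4500.0, 5500.0]
        df = engine.parameter_sweep("volume", volumes, CYTOPLASM, n_histories=20_000, seed=0)
        s = df["value"].to_numpy()
        assert np.all(np.diff(s) < 0)
        _, rate, r2 = exponential_fit_r2(np.array(volumes), s)
        assert rate > 0 and r2 > 0.9

    def test_nucleus_shift_reduces_golgi_dose(self, engine):
        """1-3 um shifts away from the Golgi: printed 15-36% (+-10 pts)."""
        base = engine.self_s_value(
            TruncatedConeCell.wide_variant(), GOLGI, 60_000, seed=9
        )
        df = engine.parameter_sweep(
            "nucleus_shift", [(1.0, 0.0), (3.0, 0.0)], GOLGI, n_histories=60_000, seed=9
        )
        reductions = 100.0 * (1.0 - df["value"].to_numpy() / base.value)
        assert np.all(reductions >= 5.0) and np.all(reductions <= 46.0)

    def test_unknown_sweep_rejected(self, engine):
        with pytest.raises(ValueError):
            engine.parameter_sweep("bogus", [1])
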