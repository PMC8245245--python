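import math

import numpy as np
import pytest

import mupool as mp


def make_fiber(x=0.0, y=0.0, z_iz=0.0, d=55.0, semilength=50.0, unit=1):
    return mp.Fiber(
        unit_index=unit, x=x, y=y, diameter_um=d,
        velocity_m_s=mp.conduction_velocity(d),
        z_iz=z_iz, z_left=-semilength, z_right=semilength,
    )


ELECTRODE = (0.0, 10.5, 25.0)
FS = 4000.0


class TestInnervationAllocation:
    def test_default_muscle(self):
        counts = mp.allocate_innervation(120, 70_000, 100)
        assert counts[0] == 28
        assert counts.sum() == 70_000
        assert np.all(np.diff(counts) >= 0)

    def test_uniform_degenerate(self):
        assert np.array_equal(mp.allocate_innervation(2, 30, 1.0), [15, 15])

    def test_exponential_shape(self):
        counts = mp.allocate_innervation(120, 70_000, 100)
        # ~100-fold spread survives rounding
        assert counts[-1] / counts[0] == pytest.approx(100, rel=0.06)

    def test_infeasible(self):
        with pytest.raises(ValueError):
            mp.allocate_innervation(10, 5, 100)


class TestConductionVelocity:
    def test_linear_map(self):
        assert mp.conduction_velocity(55.0) == pytest.approx(3.7)
        assert mp.conduction_velocity(25.0) == pytest.approx(2.2)

    def test_monotone_and_equal_inputs(self):
        assert mp.conduction_velocity(60.0) > mp.conduction_velocity(50.0)
        v = mp.conduction_velocity(np.array([55.0, 55.0]))
        assert v[0] == v[1]

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            mp.conduction_velocity(0.0)


class TestTerritories:
    def test_radius_from_density(self, rng, small_geometry):
        counts = np.array([28, 2728])
        centers, radii, fibers = mp.place_territories(counts, small_geometry, rng)
        assert radii[0] == pytest.approx(math.sqrt(28 / (20 * math.pi)), rel=1e-9)
        assert radii[1] == pytest.approx(math.sqrt(2728 / (20 * math.pi)), rel=1e-9)
        assert radii[1] < small_geometry.muscle_radius_mm

    def test_fibers_inside_muscle_and_density(self, rng, small_geometry):
        counts = mp.allocate_innervation(12, 700, 100)
        centers, radii, fibers = mp.place_territories(counts, small_geometry, rng)
        for (cx, cy), r, pos in zip(centers, radii, fibers):
            assert np.all(np.hypot(pos[:, 0], pos[:, 1]) <= small_geometry.muscle_radius_mm + 1e-9)
            assert np.all(np.hypot(pos[:, 0] - cx, pos[:, 1] - cy) <= r + 1e-9)
        dens = counts[-1] / (math.pi * radii[-1] ** 2)
        assert dens == pytest.approx(20.0, abs=1.0)


class TestFiberActionPotential:
    def test_decays_faster_than_monopole(self):
        f = make_fiber()
        near = mp.fiber_action_potential(f, (0.0, 20.0, 25.0), FS)
        far = mp.fiber_action_potential(f, (0.0, 40.0, 25.0), FS)
        assert np.abs(far).max() < np.abs(near).max() / 2

    def test_mirror_symmetry_about_iz_plane(self):
        """A centered fiber is invariant under z -> -z (the two tripoles swap),
        so electrodes at +z and -z record identical waveforms."""
        f = make_fiber()
        right = mp.fiber_action_potential(f, (0.0, 10.5, 25.0), FS)
        left = mp.fiber_action_potential(f, (0.0, 10.5, -25.0), FS)
        assert np.allclose(right, left, rtol=1e-12, atol=1e-15)

    def test_summation_linearity(self):
        f = make_fiber()
        single = mp.muap_template([f], ELECTRODE, FS)
        double = mp.muap_template([f, f], ELECTRODE, FS)
        assert np.allclose(double, 2 * single)

    def test_electrode_inside_muscle_rejected(self):
        with pytest.raises(ValueError):
            mp.MuscleGeometry(electrode_xyz=(0.0, 0.0, 25.0))


class TestMuapTemplate:
    def test_single_fiber_unit(self):
        f = make_fiber()
        assert np.allclose(
            mp.muap_template([f], ELECTRODE, FS),
            mp.fiber_action_potential(f, ELECTRODE, FS),
        )

    def test_amplitude_decreases_with_depth(self, rng):
        """Peak-to-peak falls monotonically as the same unit sits deeper."""
        offsets = rng.uniform(-0.5, 0.5, size=(20, 2))
        p2p = []
        for depth in (6.0, 4.0, 2.0, 0.0, -2.0):  # y of territory center, skin at +10.5
            fibers = [make_fiber(x=dx, y=depth + dy) for dx, dy in offsets]
            w = mp.muap_template(fibers, ELECTRODE, FS)
            p2p.append(w.max() - w.min())
        assert np.all(np.diff(p2p) < 0)

    def test_bigger_unit_bigger_template(self, rng):
        pos = rng.uniform(-1, 1, size=(60, 2))
        small = [make_fiber(x=x, y=y) for x, y in pos[:6]]
        big = [make_fiber(x=x, y=y) for x, y in pos]
        p2p = lambda w: w.max() - w.min()
        assert p2p(mp.muap_template(big, ELECTRODE, FS)) > p2p(mp.muap_template(small, ELECTRODE, FS))


class TestComposeEmg:
    def test_single_spike_is_delayed_template(self):
        tmpl = np.array([0.0, 1.0, -2.0, 0.5])
        x = mp.compose_emg([np.array([0.5])], [tmpl], fs=100.0, t_end=1.0)
        assert np.allclose(x[50:54], tmpl)
        assert np.all(x[:50] == 0) and np.all(x[54:] == 0)

    def test_no_spikes_zero(self):
        x = mp.compose_emg([np.empty(0)], [np.ones(5)], fs=100.0, t_end=1.0)
        assert np.all(x == 0)

    def test_linearity_in_templates(self, rng):
        trains = [np.sort(rng.uniform(0, 1, 5)), np.sort(rng.uniform(0, 1, 7))]
        tmpls = [rng.normal(size=20), rng.normal(size=20)]
        x1 = mp.compose_emg(trains, tmpls, 1000.0, 1.0)
        x3 = mp.compose_emg(trains, [3 * t for t in tmpls], 1000.0, 1.0)
        assert np.allclose(x3, 3 * x1)

    def test_coincident_spikes_sum(self):
        a, b = np.ones(4), -0.25 * np.ones(4)
        x = mp.compose_emg([np.array([0.1]), np.array([0.1])], [a, b], 100.0, 0.5)
        assert np.allclose(x[10:14], 0.75)

    def test_arv_monotone_in_discharge_count(self):
        """Adding discharges never lowers expected rectified amplitude (3-sigma)."""
        tmpl = mp.muap_template([make_fiber()], ELECTRODE, FS)
        diffs = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            sparse = np.sort(r.uniform(0, 5, 40))
            dense = np.sort(np.concatenate([sparse, r.uniform(0, 5, 40)]))
            arv = lambda tr: mp.emg_arv(mp.compose_emg([tr], [tmpl], FS, 5.0))
            diffs.append(arv(dense) - arv(sparse))
        diffs = np.array(diffs)
        assert diffs.mean() > 3 * diffs.std() / math.sqrt(diffs.size)


class TestBuildMuscle:
    def test_bookkeeping(self, rng, small_geometry):
        counts = mp.allocate_innervation(12, 700, 100)
        muscle = mp.build_muscle(counts, small_geometry, rng)
        assert len(muscle.templates) == 12
        assert muscle.counts.sum() == 700
        L = {t.size for t in muscle.templates}
        assert len(L) == 1  # common padded length
        p2p = [t.max() - t.min() for t in muscle.templates]
        assert np.argmax(p2p) >= 6  # big units dominate the surface signal
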