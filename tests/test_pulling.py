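"""Steered pulls, restraint schedules and contact statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import gatekeeper as gk
from gatekeeper.pulling import (ContactFrequencyTable, PullTrajectory,
                                correction_factor, correction_factors,
                                mean_table)


def default_schedule(z_init=1.5):
    return gk.RestraintSchedule().resolve(z_init=z_init)


class TestRestraintState:
    def test_stage_endpoints(self):
        sched = default_schedule(z_init=1.5)
        assert gk.restraint_state(sched, 0) == (1.5, 1000.0)
        assert gk.restraint_state(sched, 5_000_000) == (0.2, 0.0)

    def test_midpoint_interpolation(self):
        center, kappa = gk.restraint_state(default_schedule(), 4_750_000)
        assert center == pytest.approx(0.2)
        assert kappa == pytest.approx(500.0)

    def test_held_beyond_last_stage(self):
        assert gk.restraint_state(default_schedule(), 6_000_000) == (0.2, 0.0)

    def test_kappa_inheritance_and_validation(self):
        sched = gk.RestraintSchedule(stages=((0, 0.5, 100.0), (10, 1.0, None)))
        resolved = sched.resolve()
        assert resolved.stages[1][2] == 100.0
        with pytest.raises(ValueError):
            gk.RestraintSchedule(stages=())
        with pytest.raises(ValueError):
            gk.RestraintSchedule(stages=((0, 0.0, 1.0), (0, 0.1, 1.0)))


class TestConstantVelocityPull:
    def test_center_kinematics(self):
        flat = gk.make_landscape("flat")
        pull = gk.PullConfig(force_constant=100.0, velocity=10.0)
        n = 50_000
        traj = gk.run_constant_velocity_pull(flat, pull, zones=[], z_start=-1.0,
                                             n_steps=n, seed=1)
        dt = gk.LangevinParams().timestep
        assert traj.restraint_center[-1] == pytest.approx(
            -1.0 + 10.0 * 1e-3 * n * dt)
        # center advances linearly
        np.testing.assert_allclose(np.diff(traj.restraint_center),
                                   np.diff(traj.restraint_center)[0], rtol=1e-9)

    def test_zero_force_constant_free_diffusion(self):
        flat = gk.make_landscape("flat")
        pull = gk.PullConfig(force_constant=0.0, velocity=10.0)
        traj = gk.run_constant_velocity_pull(flat, pull, zones=[], z_start=0.0,
                                             n_steps=10_000, seed=2)
        assert np.all(traj.pull_force == 0.0)

    def test_stiff_spring_tracks_center(self):
        flat = gk.make_landscape("flat")
        pull = gk.PullConfig(force_constant=5000.0, velocity=2.0)
        traj = gk.run_constant_velocity_pull(flat, pull, zones=[], z_start=-1.0,
                                             n_steps=400_000, seed=3,
                                             frame_spacing=0.1)
        assert abs(np.mean(traj.z - traj.restraint_center)) < 0.005
        assert abs(traj.pull_force.mean()) < 1.0

    def test_contacts_are_zone_membership(self):
        flat = gk.make_landscape("flat")
        zones = [gk.ResidueZone("A100", 0.0, 0.2), gk.ResidueZone("B200", 2.0, 0.1)]
        pull = gk.PullConfig(force_constant=5000.0, velocity=10.0)
        traj = gk.run_constant_velocity_pull(flat, pull, zones=zones, z_start=0.0,
                                             n_steps=20_000, seed=4)
        expected = np.abs(traj.z - 0.0) <= 0.2
        assert np.array_equal(traj.contacts[0], expected)

    def test_duplicate_zone_labels_rejected(self):
        flat = gk.make_landscape("flat")
        zones = [gk.ResidueZone("X1", 0.0), gk.ResidueZone("X1", 1.0)]
        with pytest.raises(ValueError):
            gk.run_constant_velocity_pull(flat, gk.PullConfig(), zones=zones,
                                          z_start=0.0, n_steps=10, seed=0)


class TestCorrectionFactor:
    def test_hand_computed_window(self):
        f = np.array([2.0, 1.0, -1.0])
        assert correction_factor(f, 1, window=10, frame_spacing=1.0) == pytest.approx(0.5)

    def test_all_positive_and_all_zero(self):
        assert correction_factor(np.ones(5), 2) == 1.0
        assert correction_factor(np.zeros(5), 2) == 0.0

    def test_vectorized_matches_scalar_with_truncation(self):
        rng = np.random.default_rng(0)
        f = rng.normal(size=57)
        vec = correction_factors(f, window=5, frame_spacing=1.0)
        scal = [correction_factor(f, i, window=5, frame_spacing=1.0)
                for i in range(f.size)]
        np.testing.assert_allclose(vec, scal, atol=1e-12)

    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=40),
           st.integers(1, 15))
    def test_antisymmetry_and_bounds(self, forces, w):
        f = np.asarray(forces)
        cf = correction_factors(f, window=w, frame_spacing=1.0)
        cf_neg = correction_factors(-f, window=w, frame_spacing=1.0)
        np.testing.assert_allclose(cf_neg, -cf, atol=1e-12)
        assert np.all(cf <= 1.0 + 1e-12) and np.all(cf >= -1.0 - 1e-12)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            correction_factor(np.array([1.0, np.nan]), 0)


def toy_trajectory(contacts, forces, zones=None):
    contacts = np.atleast_2d(np.asarray(contacts, dtype=bool))
    forces = np.asarray(forces, dtype=float)
    n = forces.size
    zones = zones or [gk.ResidueZone(f"R{i+1}", 0.0) for i in range(contacts.shape[0])]
    return PullTrajectory(time=np.arange(1.0, n + 1), z=np.zeros(n),
                          restraint_center=np.zeros(n), pull_force=forces,
                          contacts=contacts, zones=zones, frame_spacing=1.0,
                          seed=0)


class TestAdjustedContactFrequencies:
    def test_always_in_contact_all_positive_forces(self):
        traj = toy_trajectory(np.ones(8), np.ones(8))
        t = gk.adjusted_contact_frequencies(traj).table
        assert t.raw_frequency[0] == 1.0
        assert t.adjusted_frequency[0] == 1.0

    def test_never_in_contact(self):
        traj = toy_trajectory(np.zeros(8), np.ones(8))
        t = gk.adjusted_contact_frequencies(traj).table
        assert t.raw_frequency[0] == 0.0
        assert t.adjusted_frequency[0] == 0.0

    def test_hand_computed_half_contact(self):
        """Contact on half the frames with cf = 0.5 there -> adjusted 0.25."""
        # window of 0 extra frames: cf(t) depends on frame t alone
        contacts = [1, 0, 1, 0]
        # window of 1 frame each side: frame 0 sees (+3,-1) -> 0.5,
        # frame 2 sees (-1,+3,0) -> 0.5
        forces = np.array([3.0, -1.0, 3.0, 0.0])
        traj = toy_trajectory(contacts, forces)
        t = gk.adjusted_contact_frequencies(traj, window=1.0).table
        # oracle by hand: frames 0,2 in contact
        cf = correction_factors(forces, window=1.0, frame_spacing=1.0)
        expected = (cf[0] + cf[2]) / 4
        assert cf[0] == pytest.approx(0.5)
        assert t.raw_frequency[0] == pytest.approx(0.5)
        assert t.adjusted_frequency[0] == pytest.approx(expected)
        assert t.adjusted_frequency[0] == pytest.approx(0.25)

    @given(st.integers(0, 2**31 - 1))
    def test_adjusted_bounded_by_raw(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        contacts = rng.random((3, n)) < 0.4
        forces = rng.normal(size=n)
        traj = toy_trajectory(contacts, forces,
                              zones=[gk.ResidueZone(f"Z{i}", 0.0) for i in range(3)])
        t = gk.adjusted_contact_frequencies(traj, window=4.0).table
        assert np.all(np.abs(t.adjusted_frequency) <= t.raw_frequency + 1e-12)
        assert np.all(t.raw_frequency <= 1.0)

    def test_replicate_average_equals_concatenation(self):
        """With a single-frame window, replicate-mean tables equal the
        table of the concatenated frames (linearity)."""
        rng = np.random.default_rng(1)
        zones = [gk.ResidueZone("Z1", 0.0), gk.ResidueZone("Z2", 0.0)]
        parts = []
        for _ in range(3):
            c = rng.random((2, 20)) < 0.5
            f = rng.normal(size=20)
            parts.append((c, f))
        tables = [gk.adjusted_contact_frequencies(toy_trajectory(c, f, zones), window=0.4)
                  for c, f in parts]
        avg = mean_table(tables)
        cat = toy_trajectory(np.hstack([c for c, _ in parts]),
                             np.hstack([f for _, f in parts]), zones)
        cat_t = gk.adjusted_contact_frequencies(cat, window=0.4)
        np.testing.assert_allclose(avg.table.raw_frequency,
                                   cat_t.table.raw_frequency, atol=1e-12)
        np.testing.assert_allclose(avg.table.adjusted_frequency,
                                   cat_t.table.adjusted_frequency, atol=1e-12)

    def test_zero_length_rejected(self):
        traj = toy_trajectory(np.ones(1), np.ones(1))
        traj.time = np.empty(0)
        with pytest.raises(ValueError):
            gk.adjusted_contact_frequencies(traj)

    def test_bounds_validation_on_table(self):
        with pytest.raises(ValueError):
            ContactFrequencyTable(table=pd.DataFrame(
                {"residue": ["A"], "raw_frequency": [1.5],
                 "adjusted_frequency": [0.0]}))


class TestContactLocalization:
    def test_gate_zones_favor_substrate_landscape(self):
        """Gate-proximal zones catch more contacts on the downhill substrate
        profile than on the entry-barrier non-substrate profile."""
        from gatekeeper.synth import PROMOTE_RESIDUES, ZONE_CENTERS, _mechanistic_table, PanelSpec

        spec = PanelSpec()
        gate = [r for r in PROMOTE_RESIDUES if ZONE_CENTERS[r] > 1.3]
        means = {}
        for label in (1, 0):
            vals = []
            for s in range(4):
                df = _mechanistic_table(spec, label, 50 + s).table.set_index("residue")
                vals.append(df.loc[gate].raw_frequency.mean())
            means[label] = np.mean(vals)
        assert means[1] > means[0]
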