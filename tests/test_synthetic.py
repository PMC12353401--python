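"""Ground-truth contracts and determinism of the synthetic generators."""

import numpy as np
import pytest
from scipy import stats

import stretchlab as sl
from stretchlab.synthetic import (
    DeformationSchedule,
    gen_bead_series,
    gen_cell_labels,
    gen_drifting_acquisition,
    gen_filaments,
)


class TestDeformationSchedule:
    def test_grip_schedule_cumulates_to_150_percent(self):
        sched = DeformationSchedule.from_grip_displacement()
        assert sched.n_steps == 8
        assert sched.cumulative_eng() == pytest.approx(1.5, abs=1e-12)

    def test_constant_velocity_lengths(self):
        sched = DeformationSchedule.constant_velocity(
            l0_um=2000.0, velocity_um_min=40.0, interval_min=5.0, n_steps=3)
        # lengths 2000, 2200, 2400, 2600 -> cumulative 0.3
        assert sched.cumulative_eng() == pytest.approx(0.3, abs=1e-12)
        assert sched.times[-1] == 15.0

    def test_lateral_contraction_sign(self):
        sched = DeformationSchedule.uniform(2, 0.1, nu=0.27)
        assert np.allclose(sched.step_eps_yy, -0.027)

    def test_step_at_or_below_minus_one_rejected(self):
        with pytest.raises(ValueError):
            DeformationSchedule(np.array([0.1, -1.0]))


class TestBeadSeries:
    def test_zero_schedule_zero_noise_gives_identical_frames(self):
        sched = DeformationSchedule.uniform(3, 0.0)
        series = gen_bead_series(n_beads=50, image_size=(128, 128),
                                 noise_sd=0.0, schedule=sched, seed=4)
        for t in range(1, 4):
            assert np.array_equal(series.stack.frames[0],
                                  series.stack.frames[t])

    def test_advection_is_proportional_to_center_offset(self):
        sched = DeformationSchedule.uniform(1, 0.10, nu=0.0)
        series = gen_bead_series(n_beads=100, image_size=(401, 401),
                                 schedule=sched, seed=5)
        offsets = series.positions[0, :, 0] - 200.0  # center x of a 401-wide image
        moved = series.positions[1, :, 0] - series.positions[0, :, 0]
        assert np.allclose(moved, 0.10 * offsets, atol=1e-9)

    def test_deterministic_given_seed(self):
        kw = dict(n_beads=60, image_size=(96, 96),
                  schedule=DeformationSchedule.uniform(1, 0.05), seed=123)
        a = gen_bead_series(**kw)
        b = gen_bead_series(**kw)
        assert np.array_equal(a.stack.frames, b.stack.frames)
        assert np.array_equal(a.positions, b.positions)

    def test_truth_fields_carry_the_scheduled_strain(self):
        sched = DeformationSchedule.uniform(2, 0.08, nu=0.25)
        series = gen_bead_series(n_beads=40, image_size=(64, 64),
                                 schedule=sched, seed=6)
        for f in series.fields:
            strain = sl.strain_from_displacement(f)
            assert np.nanmax(np.abs(strain.eps_xx - 0.08)) < 1e-9
            assert np.nanmax(np.abs(strain.eps_yy + 0.02)) < 1e-9

    def test_infeasible_density_rejected(self):
        with pytest.raises(ValueError, match="density"):
            gen_bead_series(n_beads=100000, image_size=(32, 32), seed=0)


class TestCellLabels:
    def test_zero_noise_truth_equals_global_schedule(self):
        sched = DeformationSchedule.uniform(2, 0.15)
        series = gen_cell_labels(n_cells=16, image_size=(200, 200),
                                 schedule=sched, cell_noise_sd=0.0, seed=7)
        assert np.allclose(series.truth_strains["eps_xx_true"], 0.15)

    def test_no_events_all_tracks_complete(self):
        sched = DeformationSchedule.uniform(2, 0.1)
        series = gen_cell_labels(n_cells=16, image_size=(200, 200),
                                 schedule=sched, division_rate=0.0,
                                 exit_rate=0.0, seed=8)
        assert all(f == "complete" for f in series.truth_fates.values())
        tracks = sl.track_cells(series.labels)
        assert all(t.fate == "complete" for t in tracks)

    def test_deterministic_given_seed(self):
        kw = dict(n_cells=12, image_size=(150, 150),
                  schedule=DeformationSchedule.uniform(1, 0.1),
                  cell_noise_sd=0.05, seed=99)
        assert np.array_equal(gen_cell_labels(**kw).labels,
                              gen_cell_labels(**kw).labels)

    def test_events_produce_noncomplete_truth_fates(self):
        sched = DeformationSchedule.uniform(4, 0.1)
        series = gen_cell_labels(n_cells=40, image_size=(300, 300),
                                 schedule=sched, division_rate=0.02,
                                 exit_rate=0.01, seed=4)
        fates = set(series.truth_fates.values())
        assert "divided" in fates and "left_frame" in fates

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            gen_cell_labels(n_cells=1)


class TestFilamentGenerator:
    def test_zero_tortuosity_gives_straightness_one(self):
        traces = gen_filaments(n=20, tortuosity_amp=0.0, seed=1)
        for t in traces:
            assert t.straightness == pytest.approx(1.0, abs=1e-9)

    def test_semicircle_template(self):
        traces = gen_filaments(n=10, shape="semicircle", seed=2, n_points=200)
        for t in traces:
            assert t.straightness == pytest.approx(2 / np.pi, abs=1e-3)

    def test_uniform_orientation_when_kappa_zero(self):
        traces = gen_filaments(n=1000, orientation_kappa=0.0, seed=3)
        angles = np.array([t.orientation for t in traces])
        counts, _ = np.histogram(angles, bins=np.linspace(-90, 90, 10))
        _, p = stats.chisquare(counts)
        assert p > 0.01

    def test_lengths_respect_range(self):
        traces = gen_filaments(n=50, length_range_px=(30, 40),
                               tortuosity_amp=0.0, seed=5)
        for t in traces:
            assert 30 <= t.length <= 40 + 1e-6

    def test_deterministic_given_seed(self):
        a = gen_filaments(n=10, seed=42)
        b = gen_filaments(n=10, seed=42)
        for x, y in zip(a, b):
            assert np.array_equal(x.points, y.points)


class TestDriftingAcquisition:
    def test_truth_records_cumulative_drift(self):
        acq = gen_drifting_acquisition(n_timepoints=4, z_slices=3,
                                       xy_drift_per_step=(3.0, -2.0), seed=6)
        assert acq.truth["cum_dx"].tolist() == [0.0, 3.0, 6.0, 9.0]
        assert acq.truth["cum_dy"].tolist() == [0.0, -2.0, -4.0, -6.0]

    def test_focus_drift_tracked_by_sharpest_z(self):
        acq = gen_drifting_acquisition(n_timepoints=5, z_slices=7,
                                       focus_drift=1.0,
                                       xy_drift_per_step=(0.0, 0.0), seed=7)
        found = [sl.sharpest_z(s) for s in acq.stacks]
        assert found == acq.truth["z_focus"].astype(int).tolist()

    def test_deterministic_given_seed(self):
        kw = dict(n_timepoints=3, z_slices=3, seed=11)
        assert np.array_equal(gen_drifting_acquisition(**kw).stacks,
                              gen_drifting_acquisition(**kw).stacks)


class TestEndToEnd:
    def test_beads_to_cumulative_strain_within_5_percent(self):
        """Full pipeline: render, match, differentiate, accumulate."""
        sched = DeformationSchedule.uniform(3, 0.10, nu=0.0)
        series = gen_bead_series(n_beads=600, image_size=(256, 256),
                                 schedule=sched, noise_sd=0.005, seed=13)
        step_means = []
        for k in range(sched.n_steps):
            field = sl.estimate_displacement(series.stack.frames[k],
                                             series.stack.frames[k + 1])
            strain = sl.strain_from_displacement(field)
            c = (slice(64, 192), slice(64, 192))
            step_means.append(float(np.nanmean(strain.eps_xx[c])))
        recovered = sl.accumulate(step_means)
        expected = sched.cumulative_eng()
        assert recovered == pytest.approx(expected, rel=0.05)
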