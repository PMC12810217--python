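"""Synthetic generators: determinism, ground-truth consistency, cohorts."""

import numpy as np
import pytest

from myomet import morphometry as mo
from myomet import synthetic as syn
from myomet.reference import ANTHROPOMETRICS, GROUPS


class TestMuscleMap:
    @pytest.mark.parametrize("vol", [15.0, 80.0, 300.0])
    def test_volume_within_2pct(self, vol):
        m = syn.generate_muscle_map("m", vol, 10.0, 3.0, noise_sd=0.0)
        assert mo.muscle_volume(m) == pytest.approx(vol, rel=0.02)

    def test_coarse_grid_volume(self):
        m = syn.generate_muscle_map(
            "m", 900.0, 10.0, 3.0, noise_sd=0.0, voxel_dims=(2.34, 2.34, 10.0)
        )
        assert mo.muscle_volume(m) == pytest.approx(900.0, rel=0.02)

    def test_noiseless_constant_field(self):
        m = syn.generate_muscle_map("m", 40.0, 5.0, 5.0, noise_sd=0.0)
        assert np.all(m.ff == 5.0)

    def test_noiseless_means_exact(self):
        m = syn.generate_muscle_map("m", 60.0, 27.9, 11.1, noise_sd=0.0)
        p = mo.shell_centre_partition(m)
        assert mo.mean_fat_fraction(m, p.shell_idx) == pytest.approx(27.9)
        assert mo.mean_fat_fraction(m, p.centre_idx) == pytest.approx(11.1)

    def test_same_seed_byte_identical(self, tmp_path):
        a = syn.generate_muscle_map("m", 30.0, 12.0, 4.0, noise_sd=1.0, seed=42)
        b = syn.generate_muscle_map("m", 30.0, 12.0, 4.0, noise_sd=1.0, seed=42)
        pa, pb = tmp_path / "a.tsv", tmp_path / "b.tsv"
        mo.write_voxel_table(a, pa)
        mo.write_voxel_table(b, pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_at_least_three_slices(self):
        m = syn.generate_muscle_map("m", 2.0, 5.0, 5.0, noise_sd=0.0)
        assert m.n_slices >= 3

    def test_subvoxel_volume_rejected(self):
        with pytest.raises(syn.SyntheticError, match="smaller than one voxel"):
            syn.generate_muscle_map("m", 0.001, 5.0, 5.0)

    def test_bad_ff_rejected(self):
        with pytest.raises(syn.SyntheticError):
            syn.generate_muscle_map("m", 10.0, 120.0, 5.0)


class TestJump:
    def test_quiet_standing_force(self):
        trace, _ = syn.generate_jump_trace(syn.JumpSpec(body_mass_kg=80.0))
        quiet = trace.force_n[: int(0.9 * trace.sample_rate_hz)]
        assert np.allclose(quiet, 784.8)

    def test_flight_clipped_to_zero(self):
        trace, truth = syn.generate_jump_trace(syn.JumpSpec(body_mass_kg=80.0))
        after = trace.times_s > truth.takeoff_time_s
        assert np.all(trace.force_n[after] == 0.0)

    def test_excessive_dip_rate_rejected(self):
        # 0.4 m dip in 0.3 s needs more than 1 g of downward acceleration
        with pytest.raises(syn.SyntheticError, match="negative"):
            syn.generate_jump_trace(
                syn.JumpSpec(body_mass_kg=80.0, dip_depth_m=0.4, dip_duration_s=0.3)
            )

    @pytest.mark.parametrize("mass,dip", [(60.0, 0.25), (80.0, 0.30), (100.0, 0.45)])
    def test_ground_truth_self_consistent(self, mass, dip):
        # sampled F*v peak agrees with the dense closed-form peak
        trace, truth = syn.generate_jump_trace(
            syn.JumpSpec(body_mass_kg=mass, dip_depth_m=dip)
        )
        sampled_peak = truth.power_w.max() / 1000.0
        assert sampled_peak == pytest.approx(truth.peak_power_kw, rel=0.005)

    def test_calibration_hits_target(self):
        spec = syn.calibrate_dip_for_power(75.0, 3.2)
        assert syn.analytic_peak_power(spec) == pytest.approx(3.2, rel=1e-4)

    def test_determinism_with_noise(self):
        spec = syn.JumpSpec(body_mass_kg=80.0, noise_sd_n=2.0, seed=7)
        a, _ = syn.generate_jump_trace(spec)
        b, _ = syn.generate_jump_trace(spec)
        assert np.array_equal(a.force_n, b.force_n)


class TestFid:
    def test_determinism(self):
        spec = syn.MrsSpec(noise_sd=1.0, seed=11)
        a, _ = syn.generate_fid(spec)
        b, _ = syn.generate_fid(spec)
        assert np.array_equal(a.samples, b.samples)

    def test_frequency_gap_in_signal(self):
        # EMCL-IMCL gap of 0.2 ppm at 123.25 MHz appears as 24.65 Hz
        # narrow lines so the overlapping-tail peak shift is << one bin
        spec = syn.MrsSpec(amplitudes=(0.0, 50.0, 50.0), dampings=(20.0, 6.0, 6.0),
                           n_points=4096)
        fid, _ = syn.generate_fid(spec)
        mag = np.abs(np.fft.fft(fid.samples))
        freq = np.fft.fftfreq(fid.n_points, 1 / fid.bandwidth_hz)
        # locate the two spectral peaks as dominant local maxima
        peaks = []
        for i in range(1, len(mag) - 1):
            if mag[i] > mag[i - 1] and mag[i] > mag[i + 1] and mag[i] > 0.2 * mag.max():
                peaks.append(freq[i])
        peaks = sorted(peaks)
        assert len(peaks) == 2
        assert peaks[1] - peaks[0] == pytest.approx(24.65, abs=fid.bandwidth_hz / fid.n_points)

    def test_invalid_specs_rejected(self):
        with pytest.raises(syn.SyntheticError):
            syn.MrsSpec(amplitudes=(-1.0, 1.0, 1.0))
        with pytest.raises(syn.SyntheticError):
            syn.MrsSpec(ppm=(4.7, 1.3, 1.5))


class TestCohort:
    def test_default_cohort_has_43_subjects(self, full_cohort):
        assert len(full_cohort.subjects) == 43
        counts = full_cohort.table().groupby("group").size().to_dict()
        assert counts == {g: ANTHROPOMETRICS[g]["n"] for g in GROUPS}

    def test_one_per_group(self):
        bundle = syn.generate_cohort(syn.default_cohort_spec(n_per_group=1, seed=2))
        assert len(bundle.subjects) == 4

    def test_zero_mass_sd_degenerate_draw(self):
        spec = syn.default_cohort_spec(n_per_group=2, seed=3)
        groups = tuple(
            syn.GroupDescriptor(g.label, g.n, g.age_y, g.height_cm, (80.0, 0.0))
            for g in spec.groups
        )
        bundle = syn.generate_cohort(
            syn.CohortSpec(groups=groups, muscles=spec.muscles,
                           voxel_dims=spec.voxel_dims, seed=3)
        )
        assert all(s.mass_kg == 80.0 for s in bundle.subjects)

    def test_duplicate_group_labels_rejected(self):
        spec = syn.default_cohort_spec(n_per_group=1)
        with pytest.raises(syn.SyntheticError, match="duplicate"):
            syn.CohortSpec(groups=spec.groups + (spec.groups[0],), muscles=spec.muscles)

    def test_subject_bundles_complete(self, full_cohort):
        s = full_cohort.subjects[0]
        assert len(s.maps) == 10  # the jumping muscles
        assert len(s.jump_traces) == 3
        assert s.fid.n_points == 1024
        # EMCL always distinctly above IMCL in the generating truth
        assert s.mrs_truth.amplitudes[1] > s.mrs_truth.amplitudes[2]

    def test_determinism(self):
        a = syn.generate_cohort(syn.default_cohort_spec(n_per_group=1, seed=9))
        b = syn.generate_cohort(syn.default_cohort_spec(n_per_group=1, seed=9))
        sa, sb = a.subjects[2], b.subjects[2]
        assert sa.mass_kg == sb.mass_kg
        assert np.array_equal(sa.maps["soleus"].ff, sb.maps["soleus"].ff)
        assert np.array_equal(sa.jump_traces[0].force_n, sb.jump_traces[0].force_n)
        assert np.array_equal(sa.fid.samples, sb.fid.samples)
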