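"""Morphometry: volume, FF means, shell/centre partition, composites, I/O."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from myomet import morphometry as mo
from myomet.synthetic import generate_muscle_map

from conftest import brute_force_partition


def cuboid(nx, ny, nz, ff=5.0, **kw):
    ijk = np.array([[i, j, k] for k in range(nz) for i in range(nx) for j in range(ny)])
    return mo.MuscleVoxelMap(ijk, np.full(len(ijk), float(ff)), **kw)


class TestVolume:
    def test_default_voxel_size(self):
        m = cuboid(10, 10, 10)
        assert mo.muscle_volume(m) == pytest.approx(1000 * 1.17 * 1.17 * 5.0 / 1000)
        assert mo.muscle_volume(m) == pytest.approx(6.8445, abs=5e-4)

    def test_empty_map_is_zero_with_warning(self):
        m = mo.MuscleVoxelMap(np.empty((0, 3), int), np.empty(0))
        with pytest.warns(UserWarning):
            assert mo.muscle_volume(m) == 0.0

    def test_matches_brute_force_count(self, rng):
        # random sparse voxel set: volume must equal an independent per-row sum
        ijk = rng.integers(0, 60, size=(50_000, 3))
        ijk = np.unique(ijk, axis=0)
        m = mo.MuscleVoxelMap(ijk, np.full(len(ijk), 1.0), voxel_dims=(2.0, 1.5, 3.0))
        brute = sum(2.0 * 1.5 * 3.0 for _ in range(len(ijk))) / 1000
        assert mo.muscle_volume(m) == pytest.approx(brute)

    def test_row_permutation_invariance(self, rng):
        ijk = np.unique(rng.integers(0, 20, size=(500, 3)), axis=0)
        perm = rng.permutation(len(ijk))
        a = mo.MuscleVoxelMap(ijk, np.full(len(ijk), 3.0))
        b = mo.MuscleVoxelMap(ijk[perm], np.full(len(ijk), 3.0))
        assert mo.muscle_volume(a) == mo.muscle_volume(b)


class TestMeanFF:
    def test_constant_field(self):
        assert mo.mean_fat_fraction(cuboid(5, 5, 3, ff=5.0)) == 5.0

    def test_two_voxel_average(self):
        m = mo.MuscleVoxelMap(np.array([[0, 0, 0], [1, 0, 0]]), np.array([4.0, 6.0]))
        assert mo.mean_fat_fraction(m) == 5.0

    def test_empty_region_errors(self):
        with pytest.raises(mo.MorphometryError):
            mo.mean_fat_fraction(cuboid(3, 3, 3), region=np.array([], dtype=int))

    def test_region_out_of_range(self):
        with pytest.raises(mo.MorphometryError):
            mo.mean_fat_fraction(cuboid(3, 3, 3), region=np.array([999]))


class TestPartition:
    def test_ring_thickness_is_2p34_mm(self):
        dx = mo.DEFAULT_VOXEL_DIMS[0]
        assert mo.DEFAULT_SHELL_THICKNESS * dx == pytest.approx(2.34)

    def test_single_slice_is_all_shell(self):
        m = cuboid(6, 6, 1)
        p = mo.shell_centre_partition(m)
        assert p.n_shell == 36 and p.n_centre == 0

    def test_three_slice_stack(self):
        # end slices (200) + two outer rings of the middle slice (64); centre 6x6
        m = cuboid(10, 10, 3)
        p = mo.shell_centre_partition(m)
        assert p.n_shell == 264
        assert p.n_centre == 36

    @pytest.mark.parametrize("shape", [(10, 10, 3), (7, 12, 5), (15, 6, 4)])
    def test_matches_brute_force_on_cuboids(self, shape):
        m = cuboid(*shape)
        p = mo.shell_centre_partition(m)
        expect = brute_force_partition(m.ijk)
        got = np.zeros(len(m), dtype=bool)
        got[p.shell_idx] = True
        assert np.array_equal(got, expect)

    def test_matches_brute_force_on_random_blob(self, rng):
        # union of random rectangles per slice: irregular in-plane outline
        rows = []
        for k in range(4):
            for _ in range(3):
                i0, j0 = rng.integers(0, 12, 2)
                di, dj = rng.integers(3, 9, 2)
                for i in range(i0, i0 + di):
                    for j in range(j0, j0 + dj):
                        rows.append((i, j, k))
        ijk = np.unique(np.array(rows), axis=0)
        m = mo.MuscleVoxelMap(ijk, np.zeros(len(ijk)))
        p = mo.shell_centre_partition(m)
        expect = brute_force_partition(ijk)
        got = np.zeros(len(m), dtype=bool)
        got[p.shell_idx] = True
        assert np.array_equal(got, expect)

    def test_generated_map_partition_is_exhaustive(self):
        m = generate_muscle_map("x", 30.0, 12.0, 4.0, noise_sd=0.5, seed=3)
        p = mo.shell_centre_partition(m)
        assert p.n_shell + p.n_centre == len(m)
        assert len(np.intersect1d(p.shell_idx, p.centre_idx)) == 0

    def test_cityblock_differs_only_on_diagonals(self):
        m = cuboid(10, 10, 3)
        cheb = mo.shell_centre_partition(m, connectivity="chebyshev")
        city = mo.shell_centre_partition(m, connectivity="cityblock")
        # city-block peeling keeps the diagonal corners of ring 2 in the centre
        assert city.n_centre >= cheb.n_centre


class TestLeanVolumeAndExclusion:
    @pytest.mark.parametrize(
        "vol,ff,expect", [(100.0, 10.0, 90.0), (250.0, 0.0, 250.0), (0.0, 50.0, 0.0)]
    )
    def test_lean_volume(self, vol, ff, expect):
        assert mo.lean_volume(vol, ff) == pytest.approx(expect)

    def test_lean_volume_round_trip_of_published_pair(self):
        # FF solved from a printed volume/lean-volume pair, then applied back
        ff = 100 * (1 - 4988 / 5285)
        assert mo.lean_volume(5285, ff) == pytest.approx(4988, abs=0.5)

    @pytest.mark.parametrize("ff,flag", [(30.0, True), (12.0, False), (25.0, True)])
    def test_exclusion_boundary(self, ff, flag):
        assert mo.high_fat_exclusion(ff) is flag


class TestComposite:
    def test_weighted_mean_ff(self):
        vv = mo.DEFAULT_VOXEL_DIMS[0] ** 2 * mo.DEFAULT_VOXEL_DIMS[2]
        n1, n2 = 100, 300
        a = cuboid(n1, 1, 1, ff=10.0)
        ijk2 = np.array([[i, 5, 0] for i in range(n2)])
        b = mo.MuscleVoxelMap(ijk2, np.full(n2, 2.0))
        comp = mo.composite_muscles([a, b])
        assert mo.muscle_volume(comp) == pytest.approx(
            mo.muscle_volume(a) + mo.muscle_volume(b)
        )
        assert mo.mean_fat_fraction(comp) == pytest.approx(4.0)

    def test_single_map_identity(self):
        a = cuboid(4, 4, 3, ff=7.0)
        comp = mo.composite_muscles([a])
        assert mo.muscle_volume(comp) == mo.muscle_volume(a)
        assert mo.mean_fat_fraction(comp) == mo.mean_fat_fraction(a)

    def test_overlap_rejected(self):
        a = cuboid(4, 4, 2)
        with pytest.raises(mo.MorphometryError, match="disjoint"):
            mo.composite_muscles([a, a])

    def test_composite_ff_equals_union_mean(self, rng):
        # two computation routes must agree: weighted member means vs union mean
        a = cuboid(5, 5, 3, ff=8.0)
        ijk = np.array([[i + 20, j, k] for k in range(2) for i in range(3) for j in range(7)])
        b = mo.MuscleVoxelMap(ijk, rng.uniform(0, 30, len(ijk)))
        comp = mo.composite_muscles([a, b])
        weighted = (len(a) * mo.mean_fat_fraction(a) + len(b) * mo.mean_fat_fraction(b)) / (
            len(a) + len(b)
        )
        assert mo.mean_fat_fraction(comp) == pytest.approx(weighted)


class TestValidation:
    def test_duplicate_coordinates_rejected(self):
        with pytest.raises(mo.MorphometryError, match="duplicate"):
            mo.MuscleVoxelMap(np.array([[0, 0, 0], [0, 0, 0]]), np.array([1.0, 2.0]))

    def test_ff_out_of_range_rejected(self):
        with pytest.raises(mo.MorphometryError):
            mo.MuscleVoxelMap(np.array([[0, 0, 0]]), np.array([101.0]))


class TestVoxelTableIO:
    def test_round_trip(self, tmp_path):
        m = generate_muscle_map(
            "soleus", 25.0, 8.0, 3.0, noise_sd=1.0, seed=9, subject_id="s1", group="old_control"
        )
        path = tmp_path / "soleus.tsv"
        mo.write_voxel_table(m, path)
        back = mo.read_voxel_table(path)
        assert np.array_equal(back.ijk, m.ijk)
        assert np.array_equal(back.ff, m.ff)  # generator emits 0.1%-quantised FF
        assert back.voxel_dims == m.voxel_dims
        assert back.muscle_name == "soleus" and back.subject_id == "s1"

    def test_grey_value_conversion(self, tmp_path):
        path = tmp_path / "grey.tsv"
        path.write_text("i\tj\tk\tff\n0\t0\t0\t123\n1\t0\t0\t1000\n")
        m = mo.read_voxel_table(path, grey_values=True)
        assert m.ff[0] == pytest.approx(12.3)
        assert m.ff[1] == pytest.approx(100.0)

    def test_grey_value_out_of_range(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("i\tj\tk\tff\n0\t0\t0\t1001\n")
        with pytest.raises(mo.VoxelTableParseError) as err:
            mo.read_voxel_table(path, grey_values=True)
        assert err.value.line == 2

    def test_malformed_row_reports_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("i\tj\tk\tff\n0\t0\t0\t5.0\nnope\tx\t0\t5.0\n")
        with pytest.raises(mo.VoxelTableParseError) as err:
            mo.read_voxel_table(path)
        assert err.value.line == 3

    def test_duplicate_rows_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("i\tj\tk\tff\n0\t0\t0\t5.0\n0\t0\t0\t6.0\n")
        with pytest.raises(mo.VoxelTableParseError):
            mo.read_voxel_table(path)


class TestNiftiImport:
    def test_two_label_volume(self, tmp_path):
        nib = pytest.importorskip("nibabel")
        ff = np.zeros((6, 6, 4), dtype=float)
        lab = np.zeros((6, 6, 4), dtype=np.int16)
        lab[1:4, 1:4, :] = 1
        lab[4:6, 4:6, :] = 2
        ff[lab == 1] = 12.5
        ff[lab == 2] = 4.0
        aff = np.diag([1.17, 1.17, 5.0, 1.0])
        nib.save(nib.Nifti1Image(ff, aff), tmp_path / "ff.nii")
        nib.save(nib.Nifti1Image(lab, aff), tmp_path / "lab.nii")
        maps = mo.maps_from_nifti(
            tmp_path / "ff.nii", tmp_path / "lab.nii", {1: "soleus", 2: "ta"}, "s1"
        )
        by_name = {m.muscle_name: m for m in maps}
        assert len(by_name["soleus"]) == 3 * 3 * 4
        assert mo.mean_fat_fraction(by_name["soleus"]) == pytest.approx(12.5)
        # header zooms are float32
        assert by_name["ta"].voxel_dims == pytest.approx((1.17, 1.17, 5.0), rel=1e-6)


@given(
    shell=st.floats(5, 40),
    centre=st.floats(0, 20),
    vol=st.floats(10, 60),
)
def test_partition_counts_and_volumes_add(shell, centre, vol):
    """|shell| + |centre| = |map| and volumes add exactly on generated maps."""
    m = generate_muscle_map("m", vol, shell, min(centre, shell), noise_sd=0.0, seed=0)
    p = mo.shell_centre_partition(m)
    assert p.n_shell + p.n_centre == len(m)
    vv = m.voxel_volume_mm3 / 1000
    assert p.n_shell * vv + p.n_centre * vv == pytest.approx(mo.muscle_volume(m))


@given(delta=st.floats(0.5, 20), centre=st.floats(0.5, 30))
def test_noiseless_shell_ff_exceeds_centre_ff(delta, centre):
    """Generated gradient maps always measure shell FF >= centre FF (no noise)."""
    m = generate_muscle_map("m", 20.0, centre + delta, centre, noise_sd=0.0, seed=0)
    p = mo.shell_centre_partition(m)
    if p.n_centre:
        assert mo.mean_fat_fraction(m, p.shell_idx) >= mo.mean_fat_fraction(m, p.centre_idx)
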