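import math

import numpy as np
import pytest

import beamfab as bf
from beamfab.qa import threshold_mask
from beamfab.synthetic import FixtureSpec, make_box_mesh

from conftest import circle_contour


def brute_force_hausdorff(a, b):
    """All-pairs symmetric largest nearest-point distance."""
    d = np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=-1))
    return max(d.min(axis=1).max(), d.min(axis=0).max())


def brute_force_hausdorff_python(a, b):
    """Pure-python double loop, independent of numpy vectorisation."""
    def directed(p_set, q_set):
        worst = 0.0
        for p in p_set:
            best = min(
                math.sqrt((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2)
                for q in q_set
            )
            worst = max(worst, best)
        return worst

    return max(directed(a, b), directed(b, a))


class TestSliceConformity:
    def test_identical_contours_zero(self):
        c = circle_contour(15.0, n=100)
        assert bf.slice_conformity(c, c) == 0.0

    def test_translation_three_four_five(self):
        c = circle_contour(15.0, n=720)
        shifted = bf.Contour(0.0, c.points + np.array([0.3, 0.4]))
        # every point moves exactly 0.5 mm; dense sampling keeps the
        # nearest-point distance at the translation length
        assert bf.slice_conformity(c, shifted) == pytest.approx(0.5, abs=1e-3)

    def test_exact_translation_on_matching_square_grids(self):
        sq = bf.Contour(0.0, [[0, 0], [100, 0], [100, 100], [0, 100]])
        a = bf.resample_contour(sq, 0.5)
        b = bf.Contour(0.0, a.points + np.array([0.3, 0.4]))
        assert bf.slice_conformity(a, b) == pytest.approx(0.5, abs=1e-12)

    def test_matches_brute_force_exactly(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            na, nb = rng.integers(3, 200, 2)
            a = bf.Contour(0.0, rng.uniform(-50, 50, (na, 2)))
            b = bf.Contour(0.0, rng.uniform(-50, 50, (nb, 2)))
            got = bf.slice_conformity(a, b)
            assert got == brute_force_hausdorff(a.points, b.points)

    def test_matches_pure_python_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(3):
            a = bf.Contour(0.0, rng.uniform(-20, 20, (40, 2)))
            b = bf.Contour(0.0, rng.uniform(-20, 20, (35, 2)))
            got = bf.slice_conformity(a, b)
            assert got == pytest.approx(
                brute_force_hausdorff_python(a.points, b.points), abs=1e-12
            )

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        a = bf.Contour(0.0, rng.uniform(-20, 20, (60, 2)))
        b = bf.Contour(0.0, rng.uniform(-20, 20, (80, 2)))
        assert bf.slice_conformity(a, b) == bf.slice_conformity(b, a)


class TestConformityReport:
    @staticmethod
    def _circle_stack(radius, zs):
        return bf.ContourStack(
            [circle_contour(radius, z=float(z), n=128) for z in zs]
        )

    def test_self_comparison_is_zero(self):
        s = self._circle_stack(20.0, [0, 1, 2, 3])
        rep = bf.conformity_report(s, s)
        assert rep.mean_mm == 0.0 and rep.sd_mm == 0.0

    def test_uniform_normal_offset_recovered(self):
        design = self._circle_stack(20.0, [0, 1, 2, 3])
        inflated = self._circle_stack(21.0, [0, 1, 2, 3])
        rep = bf.conformity_report(design, inflated)
        assert rep.mean_mm == pytest.approx(1.0, abs=0.05)

    def test_no_overlap_rejected(self):
        a = self._circle_stack(20.0, [0, 1])
        b = self._circle_stack(20.0, [10, 11])
        with pytest.raises(Exception, match="no z range"):
            bf.conformity_report(a, b)

    def test_registration_removes_translation(self):
        design = self._circle_stack(20.0, [0, 1, 2])
        moved = bf.ContourStack(
            [
                bf.Contour(c.z_mm, c.points + np.array([2.0, -1.0]))
                for c in design
            ]
        )
        raw = bf.conformity_report(design, moved)
        reg = bf.conformity_report(design, moved, register=True)
        assert raw.mean_mm > 1.5
        assert reg.mean_mm < 0.05
        assert reg.registered


class TestExtractSliceProfile:
    def test_disk_radius_recovered_subvoxel(self):
        # voxelized 20 mm-radius disk: extracted contour radius within
        # half a voxel at every angle
        spec = FixtureSpec(material_hu_sd=0.0, psf_sigma_mm=0.0, seed=0)
        disk = bf.stack_to_mesh(
            bf.ContourStack(
                [circle_contour(20.0, z=0.0, n=256),
                 circle_contour(20.0, z=5.0, n=256)]
            ),
            0.5,
        )
        vol = bf.voxelize_ct(disk, spec)
        c = bf.extract_slice_profile(vol, 2.5)
        r = np.linalg.norm(c.points, axis=1)
        assert np.all(np.abs(r - 20.0) < 0.25)

    def test_background_slice_has_no_contour(self, noisy_cube_scan):
        with pytest.raises(ValueError, match="no closed iso-contour|single intensity"):
            bf.extract_slice_profile(
                noisy_cube_scan, noisy_cube_scan.z_positions()[0], 600.0
            )

    def test_threshold_monotonicity(self, noisy_cube_scan):
        z = 15.0
        lo = bf.extract_slice_profile(noisy_cube_scan, z, -435.0)
        hi = bf.extract_slice_profile(noisy_cube_scan, z, 100.0)
        from shapely.geometry import Polygon

        assert Polygon(hi.points).area < Polygon(lo.points).area


class TestHuStats:
    def test_constant_cube_any_margin(self):
        hu = np.full((40, 40, 40), 130.0)
        v = bf.CTVolume(hu, (0.5, 0.5, 0.5), (0, 0, 0))
        mask = np.zeros_like(hu, dtype=bool)
        mask[5:-5, 5:-5, 5:-5] = True
        for margin in (0.0, 1.25):
            mean, sd = bf.hu_stats(v, mask, margin)
            assert mean == 130.0 and sd == 0.0

    def test_interface_erosion_recovers_interior(self, noisy_cube_scan):
        mask = threshold_mask(noisy_cube_scan)
        mean, sd = bf.hu_stats(noisy_cube_scan, mask, 1.25)
        assert mean == pytest.approx(130.1, abs=0.5)
        assert abs(sd - 10.1) / 10.1 < 0.15
        assert mask.sum() > 1e4

    def test_no_erosion_biased_toward_background(self, noisy_cube_scan):
        mask = threshold_mask(noisy_cube_scan)
        eroded_mean, _ = bf.hu_stats(noisy_cube_scan, mask, 1.25)
        raw_mean, _ = bf.hu_stats(noisy_cube_scan, mask, 0.0)
        assert raw_mean < eroded_mean  # pulled toward -1000 HU air
        assert abs(eroded_mean - 130.1) < abs(raw_mean - 130.1)

    def test_vanishing_mask_suggests_smaller_margin(self, noisy_cube_scan):
        mask = threshold_mask(noisy_cube_scan)
        # margin beyond the 30 mm cube's half-width leaves no voxels
        with pytest.raises(ValueError, match="smaller margin"):
            bf.hu_stats(noisy_cube_scan, mask, 16.0)


class TestDensityAndHeights:
    def test_density_from_cube(self):
        cube = make_box_mesh(10.0)  # 1000 mm^3 = 1 cm^3
        assert bf.estimate_density(1.19, cube) == pytest.approx(1.19)

    def test_density_compensator_scale(self):
        box = make_box_mesh((20.0, 20.0, 20.0))
        assert bf.estimate_density(7.76, box) == pytest.approx(0.97)

    def test_zero_mass_rejected(self):
        with pytest.raises(ValueError):
            bf.estimate_density(0.0, make_box_mesh(10.0))

    def test_height_check_perfect_match_passes(self):
        g = bf.CompensatorGrid(
            np.full((11, 11), 25.0), (1.0, 1.0), origin_mm=(0.0, 0.0)
        )
        checks, ok = bf.height_check(g, [(2.5, 3.5), (7.0, 7.0)], [25.0, 25.0])
        assert ok and all(c.deviation_mm == 0.0 for c in checks)

    def test_height_check_flags_out_of_tolerance_probe(self):
        g = bf.CompensatorGrid(np.full((11, 11), 25.0), (1.0, 1.0))
        checks, ok = bf.height_check(
            g, [(2.0, 2.0), (8.0, 8.0)], [25.0, 26.2]
        )
        assert not ok
        assert checks[1].deviation_mm == pytest.approx(1.2)

    def test_bilinear_exact_on_linear_ramp(self):
        ramp = np.tile(np.linspace(0.0, 10.0, 11), (11, 1))
        g = bf.CompensatorGrid(ramp, (1.0, 1.0))
        checks, ok = bf.height_check(g, [(3.3, 5.7)], [3.3])
        assert checks[0].design_mm == pytest.approx(3.3, abs=1e-12)
        assert ok


class TestHuToRed:
    TABLE = [(-1000.0, 0.0), (0.0, 1.0), (1000.0, 1.5)]

    def test_node_hit(self):
        assert bf.hu_to_red(self.TABLE, 0.0) == 1.0

    def test_midpoint_linearity(self):
        assert bf.hu_to_red(self.TABLE, -500.0) == pytest.approx(0.5)
        assert bf.hu_to_red(self.TABLE, 500.0) == pytest.approx(1.25)

    def test_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamping"):
            assert bf.hu_to_red(self.TABLE, 2000.0) == 1.5

    def test_unsorted_table_rejected(self):
        with pytest.raises(ValueError):
            bf.hu_to_red([(0.0, 1.0), (-1000.0, 0.0)], 0.0)
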