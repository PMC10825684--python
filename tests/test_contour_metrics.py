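"""Contour agreement metrics and DVH parameters, against brute-force oracles."""

import math

import numpy as np
import pytest

import ntcpsim as ns
from ntcpsim.contour_metrics import GeometryMismatchError


def _mask(grid, spacing=(1.0, 1.0, 1.0)):
    return ns.VoxelMask(grid=np.asarray(grid, bool), spacing=spacing)


def _dose(grid, spacing=(1.0, 1.0, 1.0)):
    return ns.DoseGrid(grid=np.asarray(grid, float), spacing=spacing)


# ---------------------------------------------------------------------------
# brute-force oracles: plain per-voxel / per-face loops

def _brute_dice(a, b):
    na = nb = ninter = 0
    for idx in np.ndindex(a.grid.shape):
        va, vb = bool(a.grid[idx]), bool(b.grid[idx])
        na += va
        nb += vb
        ninter += va and vb
    return 2.0 * ninter / (na + nb)


def _brute_faces(mask):
    """All boundary face centers, by explicit neighbour checks."""
    faces = []
    shape = mask.grid.shape
    for i, j, k in np.ndindex(shape):
        if not mask.grid[i, j, k]:
            continue
        center = [(i + 0.5) * mask.spacing[0], (j + 0.5) * mask.spacing[1],
                  (k + 0.5) * mask.spacing[2]]
        for di, dj, dk in [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                           (0, 0, 1), (0, 0, -1)]:
            ni, nj, nk = i + di, j + dj, k + dk
            inside = 0 <= ni < shape[0] and 0 <= nj < shape[1] and 0 <= nk < shape[2]
            if inside and mask.grid[ni, nj, nk]:
                continue
            ax = 0 if di else (1 if dj else 2)
            sign = di + dj + dk
            face = list(center)
            face[ax] = center[ax] + sign * mask.spacing[ax] / 2.0
            faces.append(tuple(face))
    return faces


def _brute_surface_dice(a, b, tol):
    fa, fb = _brute_faces(a), _brute_faces(b)
    def hits(src, dst):
        n = 0
        for p in src:
            dmin = min(
                math.dist(p, q) for q in dst
            )
            n += dmin <= tol + 1e-9
        return n
    return (hits(fa, fb) + hits(fb, fa)) / (len(fa) + len(fb))


def _brute_mean_dose(dose, mask):
    total = count = 0
    for idx in np.ndindex(mask.grid.shape):
        if mask.grid[idx]:
            total += dose.grid[idx]
            count += 1
    return total / count


def _brute_vxgy(dose, mask, x):
    above = count = 0
    for idx in np.ndindex(mask.grid.shape):
        if mask.grid[idx]:
            count += 1
            above += dose.grid[idx] >= x
    return 100.0 * above / count


class TestDice:
    def test_hand_counted_toy_grid(self):
        a = _mask(np.array([1, 1, 0]).reshape(3, 1, 1))
        b = _mask(np.array([0, 1, 1]).reshape(3, 1, 1))
        assert ns.dice(a, b) == 0.5

    def test_identical_and_disjoint(self):
        g = np.zeros((4, 4, 4), bool)
        g[1:3, 1:3, 1:3] = True
        a = _mask(g)
        assert ns.dice(a, a) == 1.0
        h = np.zeros((4, 4, 4), bool)
        h[0, 0, 0] = True
        assert ns.dice(a, _mask(h)) == 0.0

    def test_symmetry(self, rng):
        a = _mask(rng.random((5, 5, 5)) < 0.4)
        b = _mask(rng.random((5, 5, 5)) < 0.4)
        assert ns.dice(a, b) == ns.dice(b, a)

    def test_both_empty_rejected(self):
        e = _mask(np.zeros((3, 3, 3)))
        with pytest.raises(ValueError, match="empty"):
            ns.dice(e, e)

    def test_geometry_mismatch_rejected(self):
        a = _mask(np.ones((3, 3, 3)))
        with pytest.raises(GeometryMismatchError):
            ns.dice(a, _mask(np.ones((4, 3, 3))))
        with pytest.raises(GeometryMismatchError):
            ns.dice(a, _mask(np.ones((3, 3, 3)), spacing=(2, 1, 1)))


class TestSurfaceDice:
    def test_identical_masks_are_one_at_any_tolerance(self):
        g = np.zeros((6, 6, 6), bool)
        g[2:4, 2:4, 2:4] = True
        a = _mask(g)
        for tol in (0.0, 1.0, 5.0):
            assert ns.surface_dice(a, a, tol) == 1.0

    def test_parallel_slabs_separated_5mm(self):
        """Hand-checkable: all nearest surface distances are 4 or 5 mm."""
        ga = np.zeros((20, 5, 5), bool)
        gb = np.zeros((20, 5, 5), bool)
        ga[5, :, :] = True
        gb[10, :, :] = True
        a, b = _mask(ga), _mask(gb)
        assert ns.surface_dice(a, b, 3.0) < 1.0
        assert ns.surface_dice(a, b, 6.0) == 1.0

    def test_zero_tolerance_strict_on_different_masks(self):
        ga = np.zeros((6, 6, 6), bool)
        ga[2:4, 2:4, 2:4] = True
        gb = ga.copy()
        gb[4, 2, 2] = True  # one extra voxel
        assert ns.surface_dice(_mask(ga), _mask(gb), 0.0) < 1.0

    def test_monotone_in_tolerance(self, rng):
        a = _mask(rng.random((6, 6, 6)) < 0.4)
        b = _mask(rng.random((6, 6, 6)) < 0.4)
        if a.n_voxels == 0 or b.n_voxels == 0:
            pytest.skip("degenerate draw")
        values = [ns.surface_dice(a, b, t) for t in (0.0, 1.0, 2.0, 4.0, 8.0)]
        assert all(x <= y + 1e-12 for x, y in zip(values, values[1:]))

    def test_empty_mask_rejected(self):
        g = np.zeros((3, 3, 3), bool)
        g[1, 1, 1] = True
        with pytest.raises(ValueError, match="non-empty"):
            ns.surface_dice(_mask(g), _mask(np.zeros((3, 3, 3))), 1.0)


class TestDVHMetrics:
    def test_two_voxel_mean(self):
        g = np.zeros((2, 1, 1), bool)
        g[:, 0, 0] = True
        d = _dose(np.array([10.0, 20.0]).reshape(2, 1, 1))
        assert ns.mean_dose(d, _mask(g)) == 15.0

    def test_vxgy_hand_counted(self):
        g = np.ones((4, 1, 1), bool)
        d = _dose(np.array([2.0, 6.0, 11.0, 31.0]).reshape(4, 1, 1))
        m = _mask(g)
        assert ns.vxgy(d, m, 5) == 75.0
        assert ns.vxgy(d, m, 10) == 50.0
        assert ns.vxgy(d, m, 30) == 25.0
        assert ns.vxgy(d, m, 0) == 100.0
        assert ns.vxgy(d, m, 100) == 0.0

    def test_vxgy_threshold_inclusive(self):
        g = np.ones((2, 1, 1), bool)
        d = _dose(np.array([5.0, 4.999]).reshape(2, 1, 1))
        assert ns.vxgy(d, _mask(g), 5) == 50.0

    def test_vxgy_non_increasing_in_threshold(self, rng):
        g = rng.random((5, 5, 5)) < 0.6
        d = _dose(rng.uniform(0, 60, (5, 5, 5)))
        m = _mask(g)
        values = [ns.vxgy(d, m, x) for x in np.linspace(0, 60, 20)]
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_mean_dose_bounded_by_extremes(self, rng):
        g = rng.random((5, 5, 5)) < 0.5
        d = _dose(rng.uniform(0, 60, (5, 5, 5)))
        m = _mask(g)
        inside = d.grid[m.grid]
        assert inside.min() <= ns.mean_dose(d, m) <= inside.max()

    def test_empty_mask_rejected(self):
        d = _dose(np.ones((3, 3, 3)))
        with pytest.raises(ValueError, match="empty"):
            ns.mean_dose(d, _mask(np.zeros((3, 3, 3))))
        with pytest.raises(ValueError, match="empty"):
            ns.vxgy(d, _mask(np.zeros((3, 3, 3))), 5)


class TestBruteForceOracles:
    def test_all_metrics_match_explicit_loops(self):
        """50 random small masks, anisotropic spacing: exact for counts,
        1e-10 for means."""
        rng = np.random.default_rng(2024)
        for trial in range(50):
            shape = tuple(rng.integers(3, 7, 3))
            spacing = tuple(rng.uniform(0.5, 3.0, 3))
            ga = rng.random(shape) < 0.45
            gb = rng.random(shape) < 0.45
            if not ga.any() or not gb.any():
                continue
            a, b = _mask(ga, spacing), _mask(gb, spacing)
            d = _dose(rng.uniform(0, 50, shape), spacing)
            assert ns.dice(a, b) == _brute_dice(a, b)
            tol = float(rng.uniform(0, 5))
            assert ns.surface_dice(a, b, tol) == pytest.approx(
                _brute_surface_dice(a, b, tol), abs=1e-12
            )
            assert ns.mean_dose(d, a) == pytest.approx(
                _brute_mean_dose(d, a), abs=1e-10
            )
            x = float(rng.uniform(0, 50))
            assert ns.vxgy(d, a, x) == pytest.approx(_brute_vxgy(d, a, x), abs=1e-10)

    def test_sphere_pair_dice_matches_lens_formula(self):
        """Equal spheres radius r, centers d apart: the intersection is a
        lens of volume pi*(4r + d)*(2r - d)^2 / 12; Dice = V_lens/V_sphere."""
        r, d = 15.0, 8.0
        spacing = 0.75  # 40 voxels per diameter
        a, b, _ = ns.generate_phantom_pair(
            shape=(64, 64, 64),
            spacing=(spacing,) * 3,
            radius_mm=r,
            offset_mm=(d, 0.0, 0.0),
        )
        v_lens = math.pi * (4 * r + d) * (2 * r - d) ** 2 / 12.0
        v_sphere = 4.0 / 3.0 * math.pi * r**3
        assert ns.dice(a, b) == pytest.approx(v_lens / v_sphere, rel=0.02)


class TestCohortTableAndIO:
    def test_cohort_metric_table(self):
        rows = [{"dice": 0.9, "mhd": 4.0}, {"dice": 0.8, "mhd": 6.0}]
        table = ns.cohort_metric_table(rows)
        assert table.loc["dice", "mean"] == pytest.approx(0.85)
        assert table.loc["mhd", "sd"] == pytest.approx(np.std([4, 6], ddof=1))
        assert table.loc["dice", "n"] == 2

    def test_nrrd_round_trip(self, tmp_path):
        from ntcpsim.contour_metrics import read_dose, read_mask, write_dose, write_mask

        a, _, dose = ns.generate_phantom_pair(
            shape=(12, 10, 8), spacing=(1.5, 1.0, 2.0), radius_mm=4.0
        )
        write_mask(a, tmp_path / "a.nrrd")
        write_dose(dose, tmp_path / "d.nrrd")
        a2 = read_mask(tmp_path / "a.nrrd")
        d2 = read_dose(tmp_path / "d.nrrd")
        assert np.array_equal(a.grid, a2.grid)
        assert a2.spacing == pytest.approx(a.spacing)
        assert np.allclose(d2.grid, dose.grid, atol=1e-5)
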