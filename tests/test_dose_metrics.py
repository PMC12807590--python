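"""DVH, CI, HI, GM against counting oracles and analytic phantoms."""

import numpy as np
import pytest

from imrteval import (DoseGrid, StructureMask, compute_dvh, conformity_index,
                      dvh_metrics, gradient_measure, homogeneity_index)
from imrteval.exceptions import (AlignmentError, EmptyStructureError,
                                 UndefinedMetricError)


def _grid(values, spacing=0.3):
    values = np.asarray(values, dtype=float)
    sp = np.full(3, spacing)
    return DoseGrid(-(np.array(values.shape) - 1) * sp / 2, sp, values)


def _mask(values, spacing=0.3, name="m"):
    values = np.asarray(values, dtype=bool)
    sp = np.full(3, spacing)
    return StructureMask(name, -(np.array(values.shape) - 1) * sp / 2, sp, values)


def _sphere_setup(r_ptv=3.0, r_iso=5.0, spacing=0.2, dp=50.0, half=32):
    n = 2 * half + 1
    ax = spacing * (np.arange(n) - half)
    xx, yy, zz = np.meshgrid(ax, ax, ax, indexing="ij")
    r = np.sqrt(xx**2 + yy**2 + zz**2)
    # 50 Gy plateau inside the target, exponential fall-off hitting 50% at r_iso
    k = np.log(2.0) / (r_iso - r_ptv)
    dose = np.where(r <= r_ptv, dp, dp * np.exp(-k * (r - r_ptv)))
    sp = np.full(3, spacing)
    origin = -np.full(3, spacing * half)
    return (DoseGrid(origin, sp, dose),
            StructureMask("PTV", origin, sp, r <= r_ptv))


class TestDVH:
    def test_uniform_dose(self):
        dose = _grid(np.full((10, 10, 10), 50.0))
        mask = _mask(np.ones((10, 10, 10)))
        dvh = compute_dvh(dose, mask)
        assert dvh.diff_fraction.sum() == pytest.approx(1.0, abs=1e-9)
        assert dvh.mean_dose == pytest.approx(50.0)
        m = dvh_metrics(dvh)
        assert m["MLD"] == pytest.approx(50.0)
        for t in (5, 10, 13, 15, 20, 30):
            assert m[f"V_{t}"] == pytest.approx(100.0)
        assert m["D_2"] == pytest.approx(50.0, abs=0.05)
        assert m["D_98"] == pytest.approx(50.0, abs=0.05)

    def test_half_and_half(self):
        values = np.zeros((10, 10, 10))
        values[:5] = 10.0
        dvh = compute_dvh(_grid(values), _mask(np.ones((10, 10, 10))))
        assert dvh.volume_at_dose(5.0) == pytest.approx(0.5)

    def test_two_level_arithmetic(self):
        """40% of voxels at 4 Gy, 60% at 25 Gy."""
        values = np.full(1000, 25.0)
        values[:400] = 4.0
        dvh = compute_dvh(_grid(values.reshape(10, 10, 10)),
                          _mask(np.ones((10, 10, 10))))
        m = dvh_metrics(dvh, (5, 20))
        assert m["V_5"] == pytest.approx(60.0)
        assert m["V_20"] == pytest.approx(60.0)
        assert m["MLD"] == pytest.approx(0.4 * 4 + 0.6 * 25)

    def test_linear_ramp_against_counting(self):
        rng_vals = np.linspace(0.0, 20.0, 4000, endpoint=False).reshape(20, 20, 10)
        dose = _grid(rng_vals)
        mask = _mask(np.ones((20, 20, 10)))
        dvh = compute_dvh(dose, mask)
        for x in (2.0, 5.0, 8.0, 11.0, 14.0, 17.0):
            direct = np.mean(rng_vals >= x)
            assert dvh.volume_at_dose(x) == pytest.approx(direct, abs=5e-3)
            assert dvh.volume_at_dose(x) == pytest.approx(1 - x / 20, abs=5e-3)

    def test_lognormal_matches_voxel_space(self):
        rng = np.random.default_rng(0)
        values = rng.lognormal(1.5, 0.6, (12, 12, 12))
        mask_arr = rng.random((12, 12, 12)) < 0.7
        dvh = compute_dvh(_grid(values), _mask(mask_arr))
        voxels = values[mask_arr]
        m = dvh_metrics(dvh, (5, 10))
        assert m["MLD"] == pytest.approx(voxels.mean(), rel=1e-9)
        assert m["D_max"] == pytest.approx(voxels.max())
        assert m["V_5"] == pytest.approx(100 * np.mean(voxels >= 5), abs=0.5)
        assert m["V_10"] == pytest.approx(100 * np.mean(voxels >= 10), abs=0.5)

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyStructureError):
            compute_dvh(_grid(np.ones((5, 5, 5))), _mask(np.zeros((5, 5, 5))))

    def test_misaligned_raises(self):
        dose = _grid(np.ones((5, 5, 5)), spacing=0.3)
        mask = _mask(np.ones((5, 5, 5)), spacing=0.4)
        with pytest.raises(AlignmentError):
            compute_dvh(dose, mask)

    def test_cumulative_monotone_non_increasing(self):
        rng = np.random.default_rng(1)
        dvh = compute_dvh(_grid(rng.gamma(2, 5, (10, 10, 10))),
                          _mask(np.ones((10, 10, 10))))
        _, cum = dvh.cumulative()
        assert np.all(np.diff(cum) <= 1e-12)
        assert cum[0] == pytest.approx(1.0) and cum[-1] == 0.0


class TestIndices:
    def test_ci_exact_fill(self):
        values = np.zeros((10, 10, 10))
        values[2:8, 2:8, 2:8] = 50.0
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask[2:8, 2:8, 2:8] = True
        assert conformity_index(_grid(values), _mask(mask), 50.0) == pytest.approx(1.0)

    def test_ci_no_coverage(self):
        assert conformity_index(_grid(np.full((6, 6, 6), 30.0)),
                                _mask(np.ones((6, 6, 6))), 50.0) == 0.0

    def test_ci_sphere_in_sphere(self):
        dose, ptv = _sphere_setup(r_ptv=3.0, r_iso=5.0)
        # isodose for the prescription is exactly the PTV sphere
        ci = conformity_index(dose, ptv, 50.0)
        assert ci == pytest.approx(1.0, abs=0.02)

    def test_hi_uniform_zero(self):
        dvh = compute_dvh(_grid(np.full((8, 8, 8), 50.0)), _mask(np.ones((8, 8, 8))))
        hi = homogeneity_index(dvh.dose_at_volume(0.02), dvh.dose_at_volume(0.98), 50.0)
        assert hi == pytest.approx(0.0, abs=2e-3)

    def test_hi_arithmetic(self):
        assert homogeneity_index(52.5, 47.5, 50.0) == pytest.approx(0.1)

    def test_gm_concentric_spheres(self):
        dose, ptv = _sphere_setup()
        gm, r_ptv = gradient_measure(dose, ptv, 50.0)
        assert r_ptv == pytest.approx(3.0, abs=0.05)
        assert gm == pytest.approx(2.0, abs=0.15)

    def test_gm_coincident_surfaces_near_zero(self):
        # fall-off so sharp the 50% surface hugs the PTV boundary
        dose, ptv = _sphere_setup(r_ptv=3.0, r_iso=3.1)
        gm, _ = gradient_measure(dose, ptv, 50.0)
        assert gm == pytest.approx(0.0, abs=0.3)

    def test_gm_absent_isodose_raises(self):
        dose = _grid(np.full((6, 6, 6), 10.0))
        with pytest.raises(UndefinedMetricError):
            gradient_measure(dose, _mask(np.ones((6, 6, 6))), 50.0)

    def test_gm_ellipsoid_against_brute_force(self):
        from scipy import ndimage

        spacing = 0.25
        half = 30
        n = 2 * half + 1
        ax = spacing * (np.arange(n) - half)
        xx, yy, zz = np.meshgrid(ax, ax, ax, indexing="ij")
        rho = np.sqrt((xx / 1.0) ** 2 + (yy / 1.5) ** 2 + (zz / 2.0) ** 2)
        dp = 50.0
        dose_vals = np.where(rho <= 1.0, dp, dp * np.exp(-np.log(2) * (rho - 1.0) / 0.4))
        sp = np.full(3, spacing)
        origin = -np.full(3, spacing * half)
        dose = DoseGrid(origin, sp, dose_vals)
        ptv = StructureMask("PTV", origin, sp, rho <= 1.0)
        gm, r_ptv = gradient_measure(dose, ptv, dp)
        # independent path: centroid and surfaces recomputed directly
        region = dose_vals >= 0.5 * dp
        surf = region & ~ndimage.binary_erosion(region, ndimage.generate_binary_structure(3, 1), border_value=0)
        pts = np.argwhere(surf) * spacing + origin
        cent = (np.argwhere(rho <= 1.0) * spacing + origin).mean(axis=0)
        max_radial = max(float(np.sqrt(((p - cent) ** 2).sum())) for p in pts[:: max(1, len(pts) // 800)])
        vol = (rho <= 1.0).sum() * spacing**3
        expected = max_radial - (3 * vol / (4 * np.pi)) ** (1 / 3)
        assert gm == pytest.approx(expected, abs=0.08)

    def test_gm_decreases_with_steeper_falloff(self):
        shallow, ptv = _sphere_setup(r_iso=5.0)
        steep, _ = _sphere_setup(r_iso=4.0)
        assert (gradient_measure(steep, ptv, 50.0)[0]
                < gradient_measure(shallow, ptv, 50.0)[0])

    def test_ci_translation_invariance(self):
        rng = np.random.default_rng(2)
        values = rng.gamma(3, 8, (10, 10, 10))
        mask = rng.random((10, 10, 10)) < 0.4
        sp = np.full(3, 0.3)
        a = conformity_index(DoseGrid(np.zeros(3), sp, values),
                             StructureMask("m", np.zeros(3), sp, mask), 20.0)
        shift = np.array([3.0, -2.0, 7.0])
        b = conformity_index(DoseGrid(shift, sp, values),
                             StructureMask("m", shift, sp, mask), 20.0)
        assert a == pytest.approx(b)
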