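"""EAM / AAV / LSV / MCS against analytic values and enumeration oracles."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from imrteval import (Beam, Plan, aav, build_aperture, compute_complexity,
                      eam_aperture, lsv, mcs)
from imrteval.aperture import Aperture, ApertureRow
from imrteval.exceptions import UndefinedMetricError

from .conftest import make_cp, make_plan, random_snapped_cp


def _square_aperture(side: float) -> Aperture:
    row = ApertureRow(0.0, side, 0.0, side)
    return Aperture((row,), side * side, 4 * side, 1)


class TestEAM:
    def test_square_attains_isoperimetric_minimum(self):
        assert eam_aperture(_square_aperture(10.0)) == pytest.approx(4 / math.pi)

    def test_thin_rectangle(self, geom):
        bank_a = np.zeros(60)
        bank_b = np.zeros(60)
        bank_a[20], bank_b[20] = -1.0, 1.0  # 2 x 0.5 cm: P=5, A=1
        ap = build_aperture(make_cp(bank_a, bank_b), geom)
        assert eam_aperture(ap) == pytest.approx(25 / (4 * math.pi))

    def test_zero_area_raises(self):
        with pytest.raises(UndefinedMetricError):
            eam_aperture(Aperture((), 0.0, 0.0, 0))

    @given(st.floats(0.1, 10.0))
    def test_scale_invariance(self, scale):
        ap = _square_aperture(3.0)
        scaled = Aperture((), ap.area * scale**2, ap.perimeter * scale, 1)
        assert eam_aperture(scaled) == pytest.approx(eam_aperture(ap))

    def test_random_aperture_composes_with_oracle(self, geom):
        from .conftest import rasterize_aperture

        rng = np.random.default_rng(3)
        cp = random_snapped_cp(rng, geom)
        ap = build_aperture(cp, geom)
        area, perim = rasterize_aperture(cp, geom)
        assert eam_aperture(ap) == pytest.approx(
            perim**2 / (4 * math.pi * area), rel=1e-2)


class TestPlanEAM:
    def test_constant_shape_weighted_mean(self, geom):
        bank_a = np.zeros(60)
        bank_b = np.zeros(60)
        bank_a[25:30], bank_b[25:30] = -2.0, 2.0
        cps = [make_cp(bank_a, bank_b, mu_weight=w) for w in (0.2, 0.5, 0.3)]
        plan = make_plan(cps)
        single = eam_aperture(build_aperture(cps[0], geom))
        assert compute_complexity(plan).eam_plan == pytest.approx(single)

    def test_mu_weighted_arithmetic(self, geom):
        """Two apertures with EAM 1.5 and 3.0 weighted 3:1 pool to 1.875."""
        res = 0.75 * 1.5 + 0.25 * 3.0
        assert res == pytest.approx(1.875)
        # realize with actual apertures: squares have EAM 4/pi; verify the
        # pooling arithmetic itself on per-cp records
        bank_a = np.zeros(60)
        bank_b = np.zeros(60)
        bank_a[25:29], bank_b[25:29] = -1.0, 1.0  # 2 x 2 square
        sq = make_cp(bank_a, bank_b, mu_weight=0.75)
        bank_a2 = np.zeros(60)
        bank_b2 = np.zeros(60)
        bank_a2[25], bank_b2[25] = -1.0, 1.0  # 2 x 0.5 strip
        strip = make_cp(bank_a2, bank_b2, mu_weight=0.25)
        plan = make_plan([sq, strip])
        e1 = eam_aperture(build_aperture(sq, geom))
        e2 = eam_aperture(build_aperture(strip, geom))
        assert compute_complexity(plan).eam_plan == pytest.approx(
            0.75 * e1 + 0.25 * e2)

    def test_all_empty_raises(self):
        plan = make_plan([make_cp(0.0, 0.0)])
        with pytest.raises(UndefinedMetricError):
            compute_complexity(plan)


class TestAAV:
    def test_beam_max_everywhere_is_one(self, geom):
        cp = make_cp(-3.0, 3.0)
        beam = Beam(0.0, [cp], 100.0, "b")
        assert aav(cp, beam, geom) == pytest.approx(1.0)

    def test_all_closed_is_zero(self, geom):
        open_cp = make_cp(-3.0, 3.0, mu_weight=0.5, index=0)
        closed = make_cp(0.0, 0.0, mu_weight=0.5, index=1)
        beam = Beam(0.0, [open_cp, closed], 100.0, "b")
        assert aav(closed, beam, geom) == 0.0

    def test_three_cp_enumeration(self, geom):
        """Hand-enumerated ratio: gaps over per-pair maxima, in-jaw rows only."""
        jaw_y = (-5.0, -3.5)  # rows 20, 21, 22 (bands [-5,-4.5], [-4.5,-4], [-4,-3.5])
        rows = [20, 21, 22]
        gaps = {20: [2.0, 1.0, 0.5], 21: [1.0, 4.0, 2.0], 22: [0.0, 1.0, 3.0]}
        cps = []
        for k in range(3):
            bank_a = np.zeros(60)
            bank_b = np.zeros(60)
            for r in rows:
                bank_a[r], bank_b[r] = -gaps[r][k] / 2, gaps[r][k] / 2
            cps.append(make_cp(bank_a, bank_b, jaw_y=jaw_y, mu_weight=1 / 3, index=k))
        beam = Beam(0.0, cps, 90.0, "b")
        maxima = {r: max(gaps[r]) for r in rows}  # 2.0, 4.0, 3.0
        for k in range(3):
            expected = sum(gaps[r][k] for r in rows) / sum(maxima.values())
            assert aav(cps[k], beam, geom) == pytest.approx(expected)


class TestLSV:
    def test_straight_banks_give_one(self, geom):
        cp = make_cp(-4.0, 4.0)
        assert lsv(cp, geom) == pytest.approx(1.0)

    def test_single_in_jaw_pair_is_one(self, geom):
        cp = make_cp(-4.0, 4.0, jaw_y=(-10.0, -9.6))  # only row 10
        assert lsv(cp, geom) == pytest.approx(1.0)

    def test_alternating_bank_enumeration(self, geom):
        """Three in-jaw pairs alternating min/max; factor from direct formula."""
        jaw_y = (-5.0, -3.5)
        bank_a = np.zeros(60)
        bank_b = np.full(60, 6.0)
        bank_a[[20, 21, 22]] = [-2.0, 2.0, -2.0]
        cp = make_cp(bank_a, bank_b, jaw_y=jaw_y)
        bank_b = bank_b.copy()
        # bank A: pos_max = 4, |diffs| = [4, 4] -> sum(4-4)=0 -> factor 0
        assert lsv(cp, geom) == pytest.approx(0.0)
        bank_a[[20, 21, 22]] = [-2.0, 0.0, 2.0]
        cp = make_cp(bank_a, bank_b, jaw_y=jaw_y)
        # bank A: pos_max=4, diffs [2,2] -> (2+2)/(2*4) = 0.5; bank B flat -> 1
        assert lsv(cp, geom) == pytest.approx(0.5)


class TestMCS:
    def test_single_fully_open_cp_scores_one(self, geom):
        plan = make_plan([make_cp(-10.0, 10.0, jaw_x=(-10.0, 10.0))])
        assert mcs(plan) == pytest.approx(1.0)

    def test_static_rectangle_scores_one(self, geom):
        bank_a = np.zeros(60)
        bank_b = np.zeros(60)
        bank_a[25:32], bank_b[25:32] = -3.0, 3.0  # bands [-2.5, 1.0]
        cps = [make_cp(bank_a, bank_b, mu_weight=w, jaw_y=(-2.5, 1.0))
               for w in (0.4, 0.6)]
        assert mcs(make_plan(cps)) == pytest.approx(1.0)

    def test_three_cp_term_by_term_oracle(self, geom):
        rng = np.random.default_rng(11)
        cps = [random_snapped_cp(rng, geom) for _ in range(3)]
        weights = [0.5, 0.3, 0.2]
        cps = [make_cp(c.bank_a, c.bank_b, jaw_x=c.jaw_x, jaw_y=c.jaw_y,
                       mu_weight=w, index=i, geom=geom)
               for i, (c, w) in enumerate(zip(cps, weights))]
        plan = make_plan(cps)
        beam = plan.beams[0]
        a = [aav(cp, beam, geom) for cp in beam.control_points]
        s = [lsv(cp, geom) for cp in beam.control_points]
        expected = sum(
            w * 0.5 * (a[max(i - 1, 0)] + a[i]) * 0.5 * (s[max(i - 1, 0)] + s[i])
            for i, w in enumerate(weights))
        assert mcs(plan) == pytest.approx(expected)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_randomized_plans_bounded(self, geom, seed):
        rng = np.random.default_rng(seed)
        for _ in range(50):
            n_cp = rng.integers(1, 5)
            weights = rng.dirichlet(np.ones(n_cp))
            cps = [make_cp(*(lambda c: (c.bank_a, c.bank_b))(random_snapped_cp(rng, geom)),
                           mu_weight=float(weights[i]), index=i, geom=geom)
                   for i in range(n_cp)]
            plan = make_plan(cps)
            val = mcs(plan)
            assert 0.0 <= val <= 1.0
            for cp in plan.beams[0].control_points:
                assert 0.0 <= aav(cp, plan.beams[0], geom) <= 1.0
                assert 0.0 <= lsv(cp, geom) <= 1.0


def test_jaw_locking_never_increases_plan_eam(geom):
    """Tightening the Y-jaw to cut ragged rows keeps plan EAM from rising."""
    rng = np.random.default_rng(5)
    bank_a = np.zeros(60)
    bank_b = np.zeros(60)
    # smooth central block, ragged fringe rows above and below
    bank_a[24:32], bank_b[24:32] = -4.0, 4.0
    for r in list(range(18, 24)) + list(range(32, 38)):
        c = rng.uniform(-3, 3)
        bank_a[r], bank_b[r] = c - 0.4, c + 0.4
    wide = make_plan([make_cp(bank_a, bank_b, jaw_y=(-11.0, -1.0))])
    locked = make_plan([make_cp(bank_a, bank_b, jaw_y=(-8.0, -4.0))])
    assert (compute_complexity(locked).eam_plan
            <= compute_complexity(wide).eam_plan + 1e-12)


def test_per_segment_aggregates(geom):
    bank_a = np.zeros(60)
    bank_b = np.zeros(60)
    bank_a[25:30], bank_b[25:30] = -2.0, 2.0
    cp = make_cp(bank_a, bank_b)
    beams = [
        Beam(0.0, [make_cp(bank_a, bank_b, mu_weight=1.0)], 100.0, "c1", "PTV-C"),
        Beam(180.0, [make_cp(bank_a, bank_b, mu_weight=1.0)], 50.0, "t1", "PTV-T"),
    ]
    plan = Plan(beams, 50.0, 25, "SJL")
    res = compute_complexity(plan)
    assert set(res.per_segment) == {"PTV-C", "PTV-T"}
    single = eam_aperture(build_aperture(cp, geom))
    for seg in res.per_segment.values():
        assert seg["eam"] == pytest.approx(single)
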