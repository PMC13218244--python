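"""Posterior-pole measurements: zone geometry, Knudtson calibers,
tortuosity, vessel density and box-count fractal dimension."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oculovasc.fundus import (
    avr,
    boxcount_fd,
    calibers,
    knudtson_equivalent,
    measure_calibers_in_zone,
    path_tortuosity,
    tortuosity,
    vessel_density,
    zone_mask,
)
from oculovasc.synth import VesselTreeParams, gen_vessel_map
from oculovasc.types import VesselMap, ZoneSpec, ZONE_B, ZONE_C


def knudtson_oracle(widths, k):
    """Independent brute-force iteration of the pairing rule."""
    w = sorted(widths, reverse=True)[:6]
    while len(w) > 1:
        w = sorted(w, reverse=True)
        nxt = []
        while len(w) > 1:
            nxt.append(k * math.sqrt(w[0] ** 2 + w[-1] ** 2))
            w = w[1:-1]
        nxt.extend(w)  # odd leftover (the median) carries unchanged
        w = nxt
    return w[0]


class TestZoneGeometry:
    def test_zone_b_annulus_radii(self):
        # D = 100 px from a disc margin at R = 50: zone B spans [100, 150)
        m = zone_mask((200, 200), 100.0, ZONE_B, (400, 400))
        yy, xx = np.mgrid[0:400, 0:400]
        d = np.hypot(xx - 200, yy - 200)
        assert m[(d >= 100.5) & (d < 149.5)].all()
        assert not m[(d < 99.5) | (d >= 150.5)].any()

    def test_zone_c_annulus_radii(self):
        m = zone_mask((200, 200), 100.0, ZONE_C, (400, 400))
        yy, xx = np.mgrid[0:400, 0:400]
        d = np.hypot(xx - 200, yy - 200)
        assert m[(d >= 100.5) & (d < 249.5)].all()
        assert not m[(d < 99.5) | (d >= 250.5)].any()

    def test_degenerate_zone_rejected(self):
        with pytest.raises(ValueError):
            ZoneSpec(0.5, 0.5)
        with pytest.raises(ValueError):
            zone_mask((10, 10), -1.0, ZONE_B, (50, 50))


class TestKnudtson:
    @pytest.mark.parametrize(
        "widths,cls,expected",
        [
            ([10, 10], "artery", 0.88 * math.sqrt(200)),   # 12.445
            ([10, 10], "vein", 0.95 * math.sqrt(200)),     # 13.435
            ([7.0], "vein", 7.0),                          # single width passes through
        ],
    )
    def test_closed_form_pairings(self, widths, cls, expected):
        assert knudtson_equivalent(widths, cls) == pytest.approx(expected, abs=1e-12)

    def test_six_equal_widths_match_hand_oracle(self):
        est = knudtson_equivalent([10] * 6, "artery")
        assert est == pytest.approx(knudtson_oracle([10] * 6, 0.88), abs=1e-9)
        assert est == pytest.approx(17.48, abs=0.01)

    @settings(max_examples=200, derandomize=True)
    @given(
        st.lists(st.floats(1.0, 400.0), min_size=1, max_size=12),
        st.sampled_from(["artery", "vein"]),
        st.floats(0.1, 10.0),
        st.randoms(use_true_random=False),
    )
    def test_permutation_and_scale_equivariance(self, widths, cls, c, rnd):
        base = knudtson_equivalent(widths, cls)
        shuffled = list(widths)
        rnd.shuffle(shuffled)
        assert knudtson_equivalent(shuffled, cls) == pytest.approx(base, rel=1e-12)
        assert knudtson_equivalent([c * w for w in widths], cls) == pytest.approx(
            c * base, rel=1e-9)

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(1.0, 400.0), min_size=1, max_size=8),
           st.sampled_from(["artery", "vein"]))
    def test_matches_brute_force_oracle(self, widths, cls):
        k = {"artery": 0.88, "vein": 0.95}[cls]
        assert knudtson_equivalent(widths, cls) == pytest.approx(
            knudtson_oracle(widths, k), rel=1e-12)

    def test_empty_list_is_an_error(self):
        with pytest.raises(ValueError):
            knudtson_equivalent([], "artery")


class TestAvr:
    def test_ratio_and_edge_cases(self):
        assert avr(12.445, 13.435) == pytest.approx(0.9263, abs=5e-4)
        assert avr(5.0, 5.0) == 1.0
        assert avr(0.0, 4.0) == 0.0
        with pytest.raises(ZeroDivisionError):
            avr(1.0, 0.0)

    def test_avr_equals_crae_over_crve_on_pipeline_output(self):
        vm, _ = gen_vessel_map(VesselTreeParams(seed=11))
        res = calibers(vm)
        assert res.avr == res.crae / res.crve


class TestTortuosity:
    def test_straight_path_is_zero(self):
        path = np.column_stack([np.full(50, 3.0), np.linspace(0, 49, 50)])
        assert path_tortuosity(path)[0] == pytest.approx(0.0, abs=1e-12)

    def test_semicircle(self):
        th = np.linspace(0, np.pi, 2000)
        path = np.column_stack([np.sin(th), np.cos(th)])  # radius 1, chord 2
        t, _ = path_tortuosity(path)
        assert t == pytest.approx(np.pi / 2 - 1, abs=1e-4)

    def test_length_weighted_mean(self):
        # equal-length paths with tortuosity 0 and 0.2 average to 0.1
        straight = np.column_stack([np.zeros(100), np.linspace(0, 60, 100)])
        s = np.linspace(0, 60, 400)
        wavy = np.column_stack([np.sin(s / 2.1) * 2.57, s])
        t_w, arc_w = path_tortuosity(wavy)
        # rescale the straight path to the same arc length
        straight[:, 1] *= arc_w / 60.0
        combined = tortuosity([straight, wavy])
        assert combined == pytest.approx(t_w / 2, rel=1e-6)

    def test_closed_loop_excluded_with_warning(self):
        th = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        loop = np.column_stack([np.cos(th), np.sin(th)])
        loop = np.vstack([loop, loop[:1]])  # exact closure
        straight = np.column_stack([np.zeros(10), np.arange(10.0)])
        with pytest.warns(UserWarning):
            val = tortuosity([loop, straight])
        assert val == pytest.approx(0.0, abs=1e-12)


class TestVesselDensity:
    def test_trivial_and_brute_force(self):
        zone = np.zeros((50, 50), bool)
        zone[10:30, 10:60] = True  # clipped to 50: 20x40 = 800 px
        vessel = np.zeros((50, 50), bool)
        assert vessel_density(vessel, zone) == 0.0
        vessel[:] = True
        assert vessel_density(vessel, zone) == 1.0
        rng = np.random.default_rng(0)
        vessel = rng.random((50, 50)) < 0.3
        brute = sum(int(vessel[y, x] and zone[y, x]) for y in range(50) for x in range(50))
        assert vessel_density(vessel, zone) == brute / zone.sum()

    def test_empty_zone_is_an_error(self):
        with pytest.raises(ValueError):
            vessel_density(np.ones((5, 5), bool), np.zeros((5, 5), bool))


class TestBoxcountFd:
    def test_line(self, straight_line_512):
        assert abs(boxcount_fd(straight_line_512) - 1.0) <= 0.1

    def test_filled_rectangle(self, filled_rect_512):
        assert abs(boxcount_fd(filled_rect_512) - 2.0) <= 0.1

    def test_sierpinski_carpet(self, carpet4):
        assert abs(boxcount_fd(carpet4) - math.log(8) / math.log(3)) <= 0.07

    def test_translation_invariance(self, carpet4):
        base = boxcount_fd(carpet4)
        shifted = np.zeros((carpet4.shape[0] + 13, carpet4.shape[1] + 5), bool)
        shifted[13:, 5:] = carpet4
        assert abs(boxcount_fd(shifted) - base) <= 0.03

    def test_rotation_90_invariance(self, carpet4):
        assert abs(boxcount_fd(np.rot90(carpet4)) - boxcount_fd(carpet4)) <= 0.05

    def test_degenerate_range_is_an_error(self):
        with pytest.raises(ValueError):
            boxcount_fd(np.ones((12, 12), bool))


class TestCaliberRecovery:
    @pytest.mark.parametrize("cal_a,cal_v", [(60, 80), (120, 150), (250, 300)])
    def test_widths_recover_truth_within_one_pixel(self, cal_a, cal_v):
        # calibers spanning 6-30 px at 10 um/px
        p = VesselTreeParams(seed=3, caliber_mean_artery=cal_a,
                             caliber_mean_vein=cal_v, caliber_jitter=0.1)
        vm, truth = gen_vessel_map(p)
        zb = zone_mask(vm.od_center, vm.od_diameter, ZONE_B, vm.shape)
        measured = measure_calibers_in_zone(vm, zb)
        for cls in ("artery", "vein"):
            true = sorted(truth[truth.vessel_class == cls].caliber_px, reverse=True)
            est = measured[cls]
            assert len(est) == len(true)
            assert max(abs(e - t) for e, t in zip(est, true)) <= 1.0

    def test_straight_synthetic_vessel_width_12px(self):
        mask = np.zeros((100, 200), bool)
        mask[44:56, :] = True  # 12 px wide horizontal stroke
        vm = VesselMap(mask, np.zeros_like(mask), od_center=(0.0, 50.0),
                       od_diameter=40.0, laterality="right")
        zone = np.zeros_like(mask)
        zone[:, 60:140] = True
        est = measure_calibers_in_zone(vm, zone)["artery"]
        assert len(est) == 1 and abs(est[0] - 12.0) <= 1.0

    def test_two_parallel_vessels_sorted(self):
        mask = np.zeros((120, 200), bool)
        mask[20:28, :] = True    # 8 px
        mask[70:86, :] = True    # 16 px
        vm = VesselMap(np.zeros_like(mask), mask, od_center=(0.0, 60.0),
                       od_diameter=40.0, laterality="right")
        zone = np.zeros_like(mask)
        zone[:, 50:150] = True
        est = measure_calibers_in_zone(vm, zone)["vein"]
        assert len(est) == 2
        assert abs(est[0] - 16.0) <= 1.0 and abs(est[1] - 8.0) <= 1.0

    def test_empty_zone_gives_empty_list(self):
        vm = VesselMap(np.zeros((50, 50), bool), np.zeros((50, 50), bool),
                       od_center=(25.0, 25.0), od_diameter=10.0)
        est = measure_calibers_in_zone(vm, np.ones((50, 50), bool))
        assert est == {"artery": [], "vein": []}
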