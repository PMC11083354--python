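import numpy as np
import pytest

from nichecontact import (
    LabelScheme,
    LabelVolume,
    ValidationError,
    center_of_mass,
    connected_components,
    min_distance_to_zone,
    quantify_patient,
    select_main_component,
    tumor_core_mask,
    zone_fraction,
)

from oracles import bfs_components, brute_center_of_mass, brute_min_distance

SCHEME = LabelScheme()


def _vol(data, spacing=(1, 1, 1)):
    return LabelVolume(np.asarray(data, dtype=np.int16),
                       np.diag([*spacing, 1.0]))


class TestCoreMask:
    def test_all_edema_gives_empty_core(self):
        seg = _vol(np.full((4, 4, 4), SCHEME.edema))
        assert tumor_core_mask(seg, SCHEME).sum() == 0

    def test_core_counts_enhancing_and_necrosis(self):
        data = np.zeros((4, 4, 4), dtype=np.int16)
        data[0, 0, :3] = SCHEME.enhancing
        data[1, 1, :2] = SCHEME.necrosis
        data[2, 2, :2] = SCHEME.edema
        assert tumor_core_mask(_vol(data), SCHEME).sum() == 5


class TestConnectedComponents:
    def test_two_separated_cubes(self):
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask[1:4, 1:4, 1:4] = True
        mask[6:9, 1:4, 1:4] = True
        comps = connected_components(mask)
        assert [len(c) for c in comps] == [27, 27]

    def test_corner_touch_depends_on_connectivity(self):
        mask = np.zeros((6, 6, 6), dtype=bool)
        mask[0:2, 0:2, 0:2] = True
        mask[2:4, 2:4, 2:4] = True
        assert len(connected_components(mask, connectivity=26)) == 1
        assert len(connected_components(mask, connectivity=6)) == 2

    def test_empty_mask_gives_empty_list(self):
        assert connected_components(np.zeros((3, 3, 3), dtype=bool)) == []

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_matches_bfs_oracle_on_random_mask(self, connectivity, rng):
        mask = rng.random((20, 20, 20)) < 0.1
        comps = connected_components(mask, connectivity)
        oracle = bfs_components(mask, connectivity)
        assert len(comps) == len(oracle)
        assert sorted(len(c) for c in comps) == sorted(len(c) for c in oracle)


class TestMainComponent:
    @staticmethod
    def _fake(sizes):
        return [np.zeros((s, 3), dtype=int) + i for i, s in enumerate(sizes)]

    def test_largest_wins_and_satellites_flag_multifocal(self):
        main, multifocal = select_main_component(self._fake([100, 5, 3]), 1)
        assert len(main) == 100 and multifocal

    def test_single_component_is_unifocal(self):
        _, multifocal = select_main_component(self._fake([100]), 1)
        assert not multifocal

    def test_satellites_below_threshold_do_not_count(self):
        _, multifocal = select_main_component(self._fake([100, 5, 3]), 10)
        assert not multifocal

    def test_all_below_threshold_errors(self):
        with pytest.raises(ValidationError):
            select_main_component(self._fake([4]), 10)


class TestCenterOfMass:
    def test_single_voxel(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[3, 4, 0] = True
        np.testing.assert_allclose(center_of_mass(mask, _vol(mask)), [3, 4, 0])

    def test_symmetric_cube_center(self):
        mask = np.zeros((11, 11, 11), dtype=bool)
        mask[4:7, 4:7, 4:7] = True
        np.testing.assert_allclose(center_of_mass(mask, _vol(mask)), [5, 5, 5])

    def test_matches_brute_force_summation(self, rng):
        mask = rng.random((12, 13, 14)) < 0.2
        vol = _vol(mask, spacing=(1, 2, 0.5))
        got = center_of_mass(mask, vol)
        expect = brute_center_of_mass(mask, vol.affine)
        np.testing.assert_allclose(got, expect, atol=1e-12)

    def test_empty_mask_errors(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        with pytest.raises(ValidationError):
            center_of_mass(mask, _vol(mask))


class TestMinDistance:
    def test_three_four_five(self):
        zone = np.zeros((6, 6, 6), dtype=np.int16)
        zone[3, 4, 0] = 1
        assert min_distance_to_zone([0, 0, 0], _vol(zone)) == pytest.approx(5.0)

    def test_zero_at_zone_voxel_center(self):
        zone = np.zeros((4, 4, 4), dtype=np.int16)
        zone[2, 1, 3] = 1
        assert min_distance_to_zone([2, 1, 3], _vol(zone)) == 0.0

    def test_matches_exhaustive_scan(self, rng):
        zone = (rng.random((10, 11, 9)) < 0.08).astype(np.int16)
        zone[5, 5, 5] = 1
        vol = _vol(zone)
        point = rng.uniform(0, 9, 3)
        assert min_distance_to_zone(point, vol) == pytest.approx(
            brute_min_distance(point, zone, vol.affine), abs=1e-9)

    def test_empty_zone_errors(self):
        with pytest.raises(ValidationError):
            min_distance_to_zone([0, 0, 0], _vol(np.zeros((3, 3, 3))))


class TestZoneFraction:
    def test_quarter_overlap(self):
        tumor = np.zeros((4, 4, 4), dtype=bool)
        tumor[0, 0, :] = True
        tumor[1, 1, :] = True
        zone = np.zeros_like(tumor)
        zone[0, 0, :2] = True
        assert zone_fraction(tumor, zone) == pytest.approx(25.0)

    def test_disjoint_and_contained(self):
        tumor = np.zeros((4, 4, 4), dtype=bool)
        tumor[0] = True
        zone = np.zeros_like(tumor)
        zone[1] = True
        assert zone_fraction(tumor, zone) == 0.0
        assert zone_fraction(tumor, np.ones_like(tumor)) == 100.0

    def test_empty_tumor_errors(self):
        with pytest.raises(ValidationError):
            zone_fraction(np.zeros((3, 3, 3), bool), np.ones((3, 3, 3), bool))


class TestInvariances:
    def test_translation_equivariance(self, rng):
        tumor = np.zeros((20, 20, 20), dtype=np.int16)
        tumor[4:8, 4:8, 4:8] = SCHEME.enhancing
        zone = np.zeros_like(tumor)
        zone[10:12, 4:8, 4:8] = 1
        shift = (3, 2, 1)
        tumor2 = np.roll(tumor, shift, axis=(0, 1, 2))
        zone2 = np.roll(zone, shift, axis=(0, 1, 2))
        com1 = center_of_mass(tumor > 0, _vol(tumor))
        com2 = center_of_mass(tumor2 > 0, _vol(tumor2))
        d1 = min_distance_to_zone(com1, _vol(zone))
        d2 = min_distance_to_zone(com2, _vol(zone2))
        assert d1 == pytest.approx(d2, abs=1e-9)
        assert zone_fraction(tumor > 0, zone > 0) == zone_fraction(tumor2 > 0, zone2 > 0)

    def test_growing_zone_shrinks_distance_and_grows_fraction(self, rng):
        tumor = rng.random((16, 16, 16)) < 0.1
        tumor[8, 8, 8] = True
        zone_small = rng.random((16, 16, 16)) < 0.05
        zone_small[2, 2, 2] = True
        zone_big = zone_small | (rng.random((16, 16, 16)) < 0.05)
        com = center_of_mass(tumor, _vol(tumor))
        assert min_distance_to_zone(com, _vol(zone_big.astype(np.int16))) <= \
            min_distance_to_zone(com, _vol(zone_small.astype(np.int16)))
        assert zone_fraction(tumor, zone_big) >= zone_fraction(tumor, zone_small)

    def test_anisotropic_spacing_slice_offset(self):
        # a one-slice offset along the 4 mm axis must count as 4 mm
        zone = np.zeros((5, 5, 5), dtype=np.int16)
        zone[2, 2, 3] = 1
        vol = _vol(zone, spacing=(1, 1, 4))
        assert min_distance_to_zone([2, 2, 8], vol) == pytest.approx(4.0)


class TestQuantifyPatient:
    def _patient(self, satellite=False):
        data = np.zeros((24, 24, 24), dtype=np.int16)
        data[6:12, 6:12, 6:12] = SCHEME.enhancing
        data[8:10, 8:10, 8:10] = SCHEME.necrosis
        data[5:13, 5:13, 5:13][data[5:13, 5:13, 5:13] == 0] = SCHEME.edema
        if satellite:
            data[18:20, 18:20, 18:20] = SCHEME.enhancing
        zones = {}
        for name, sl in (("svz", (slice(0, 2), slice(None), slice(None))),
                         ("sgz", (slice(None), slice(0, 2), slice(None))),
                         ("cortex", (slice(22, 24), slice(None), slice(None)))):
            z = np.zeros((24, 24, 24), dtype=np.int16)
            z[sl] = 1
            zones[name] = _vol(z)
        return _vol(data), zones

    def test_no_overlap_means_no_contact(self):
        seg, zones = self._patient()
        rec = quantify_patient("p", seg, zones)
        assert not rec.contact_svz and rec.frac_svz_pct == 0.0
        assert rec.dist_svz_mm > 0

    def test_satellite_flags_multifocal(self):
        seg, zones = self._patient(satellite=True)
        rec = quantify_patient("p", seg, zones)
        assert rec.multifocal_preop
        assert rec.n_components == 2
        assert rec.selected_component_voxels == 216   # main 6x6x6 cube

    def test_contact_iff_positive_fraction(self):
        seg, zones = self._patient()
        zones["svz"].data[7, 7, 7] = 1    # inside the core
        rec = quantify_patient("p", seg, zones)
        assert rec.contact_svz and rec.frac_svz_pct > 0

    def test_fields_match_independent_recomputation(self, rng):
        from oracles import brute_fraction
        seg, zones = self._patient(satellite=True)
        rec = quantify_patient("p", seg, zones)
        core = np.isin(seg.data, SCHEME.core)
        main = np.zeros_like(core)
        main[6:12, 6:12, 6:12] = True       # largest component, known a priori
        com = brute_center_of_mass(main & core, seg.affine)
        np.testing.assert_allclose([rec.com_x_mm, rec.com_y_mm, rec.com_z_mm],
                                   com, atol=1e-9)
        assert rec.dist_svz_mm == pytest.approx(
            brute_min_distance(com, zones["svz"].data, seg.affine), abs=1e-9)
        assert rec.frac_cortex_pct == pytest.approx(
            brute_fraction(main, zones["cortex"].data > 0), abs=1e-12)
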