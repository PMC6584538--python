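"""3D morphometry: segmentation, partition, volume/area/densitometry."""

import math
from dataclasses import replace

import numpy as np
import pytest

from holosperm.core import RITomogram, ValidationError
from holosperm.morphometry3d import (
    RIBandSet,
    band_decomposition,
    partition_compartments,
    region_concentration,
    region_dry_mass,
    region_surface_area,
    region_volume,
    segment_cell,
    sphericity,
)
from holosperm.phantoms import build_phantom, make_analytic_shape
from holosperm.presets import MEDIUM_RI, ho_design


@pytest.fixture(scope="module")
def ho_segmentation(ho_phantom):
    tomo, _ = ho_phantom
    mask = segment_cell(tomo, (1.3400, 1.3850))
    return tomo, mask, partition_compartments(mask, tomo)


class TestSegmentCell:
    def test_uniform_medium_gives_empty_mask(self):
        tomo = RITomogram(np.full((20, 20, 20), MEDIUM_RI), (0.1,) * 3, MEDIUM_RI)
        assert not segment_cell(tomo, (1.34, 1.385)).any()

    def test_debris_removal_keeps_largest_component(self):
        vals = np.full((40, 40, 40), MEDIUM_RI)
        c = (np.arange(40) - 19.5) * 0.1
        Z, Y, X = np.meshgrid(c, c, c, indexing="ij")
        big = Z**2 + Y**2 + (X + 1.0) ** 2 <= 0.8**2
        small = Z**2 + Y**2 + (X - 1.4) ** 2 <= 0.4**2
        vals[big | small] = 1.36
        mask = segment_cell(RITomogram(vals, (0.1,) * 3, MEDIUM_RI), (1.34, 1.385))
        assert mask[big].all() and not mask[small].any()

    def test_whole_cell_band_recovers_design_volume(self, ho_phantom):
        tomo, labels = ho_phantom
        mask = segment_cell(tomo, (1.340, 1.385))
        v = region_volume(mask, tomo.voxel_size)
        assert v == pytest.approx(ho_design().analytic_volumes()["cell"], rel=0.02)


class TestPartitionCompartments:
    def test_boundaries_close_to_design(self, ho_segmentation):
        _, _, seg = ho_segmentation
        d = ho_design()
        s1, s2 = seg.boundaries
        assert abs(s1 - d.head_length) <= 0.5
        assert abs(s2 - (d.head_length + d.midpiece_length)) <= 0.5

    def test_segment_lengths_match_design(self, ho_segmentation):
        _, _, seg = ho_segmentation
        d = ho_design()
        lengths = seg.segment_lengths
        assert lengths["head"] == pytest.approx(d.head_length, rel=0.03)
        assert lengths["midpiece"] == pytest.approx(d.midpiece_length, rel=0.03)
        assert lengths["tail"] == pytest.approx(d.tail_length, rel=0.03)

    def test_compartment_volumes_conserved(self, ho_segmentation):
        tomo, mask, seg = ho_segmentation
        total = region_volume(mask, tomo.voxel_size)
        parts = sum(
            region_volume(seg.labels == lab, tomo.voxel_size) for lab in (1, 2, 3)
        )
        assert parts == pytest.approx(total, abs=1e-9)

    def test_head_only_phantom_is_all_head(self):
        d = replace(
            ho_design(),
            midpiece_length=1e-3, tail_length=1e-3,
            midpiece_radius=1e-3, tail_base_radius=1e-3, tail_tip_radius=1e-3,
        )
        tomo = build_phantom(d)
        mask = segment_cell(tomo, (1.34, 1.385))
        seg = partition_compartments(mask, tomo)
        n_head = (seg.labels == 1).sum()
        assert n_head / mask.sum() > 0.99
        assert seg.segment_lengths["tail"] < 1.0

    def test_compact_mask_cannot_be_oriented(self):
        t = make_analytic_shape("sphere", {"radius": 1.0}, ri=1.36)
        mask = segment_cell(t, (1.34, 1.385))
        with pytest.raises(ValidationError, match="orient"):
            partition_compartments(mask, t)


class TestVolumeAndArea:
    def test_empty_mask_zero_volume(self):
        assert region_volume(np.zeros((5, 5, 5), bool), (0.1,) * 3) == 0.0

    def test_sphere_volume_oracle(self):
        t = make_analytic_shape("sphere", {"radius": 2.0}, ri=1.36)
        m = t.values > MEDIUM_RI
        assert region_volume(m, t.voxel_size) == pytest.approx(
            4.0 / 3.0 * math.pi * 8.0, rel=0.02
        )

    def test_sphere_area_oracle(self):
        t = make_analytic_shape("sphere", {"radius": 2.0}, ri=1.36)
        m = t.values > MEDIUM_RI
        assert region_surface_area(m, t.voxel_size) == pytest.approx(
            4.0 * math.pi * 4.0, rel=0.03
        )

    def test_cube_area_oracle(self):
        t = make_analytic_shape("cube", {"edge": 1.0}, ri=1.36, voxel_size=(0.05,) * 3)
        m = t.values > MEDIUM_RI
        assert region_surface_area(m, t.voxel_size) == pytest.approx(6.0, rel=0.05)

    def test_hollow_sphere_reports_outer_surface(self):
        t = make_analytic_shape("sphere", {"radius": 2.0}, ri=1.36)
        solid = t.values > MEDIUM_RI
        c = [t.origin[i] + np.arange(t.shape[i]) * t.voxel_size[i] for i in range(3)]
        Z, Y, X = np.meshgrid(*c, indexing="ij")
        shell = solid & (Z**2 + Y**2 + X**2 >= 1.0)
        a_solid = region_surface_area(solid, t.voxel_size)
        a_shell = region_surface_area(shell, t.voxel_size)
        assert a_shell == pytest.approx(a_solid, rel=0.01)

    def test_mesh_convergence_monotone(self):
        errs = []
        for d in (0.2, 0.1, 0.05):
            t = make_analytic_shape("sphere", {"radius": 2.0}, ri=1.36, voxel_size=(d,) * 3)
            a = region_surface_area(t.values > MEDIUM_RI, t.voxel_size)
            errs.append(abs(a - 4 * math.pi * 4.0))
        assert errs[0] > errs[1] > errs[2]

    def test_scale_equivariance(self):
        t = make_analytic_shape("sphere", {"radius": 2.0}, ri=1.36)
        m = t.values > MEDIUM_RI
        v1, a1 = region_volume(m, (0.1,) * 3), region_surface_area(m, (0.1,) * 3)
        v2, a2 = region_volume(m, (0.2,) * 3), region_surface_area(m, (0.2,) * 3)
        assert v2 == pytest.approx(8 * v1, rel=1e-9)
        assert a2 == pytest.approx(4 * a1, rel=1e-9)

    def test_empty_mask_area_raises(self):
        with pytest.raises(ValidationError):
            region_surface_area(np.zeros((5, 5, 5), bool), (0.1,) * 3)


class TestSphericity:
    def test_sphere_is_one(self):
        r = 2.0
        assert sphericity(4 / 3 * math.pi * r**3, 4 * math.pi * r**2) == pytest.approx(1.0)

    def test_unit_cube_closed_form(self):
        assert sphericity(1.0, 6.0) == pytest.approx(0.8060, abs=5e-4)

    def test_meshed_sphere_within_tolerance(self):
        t = make_analytic_shape("sphere", {"radius": 2.0}, ri=1.36)
        m = t.values > MEDIUM_RI
        psi = sphericity(region_volume(m, t.voxel_size), region_surface_area(m, t.voxel_size))
        assert psi == pytest.approx(1.0, rel=0.02)

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            sphericity(0.0, 1.0)


class TestDensitometry:
    def test_medium_mask_zero_concentration(self):
        tomo = RITomogram(np.full((10, 10, 10), MEDIUM_RI), (0.1,) * 3, MEDIUM_RI)
        mask = np.ones((10, 10, 10), bool)
        assert region_concentration(tomo, mask) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_ri_concentration_oracle(self):
        # Δn = 0.013775 at increment 0.19 mL/g → 72.5 fg/µm³
        tomo = RITomogram(np.full((10, 10, 10), 1.350775), (0.1,) * 3, MEDIUM_RI)
        mask = np.ones((10, 10, 10), bool)
        c = region_concentration(tomo, mask, ri_increment=0.19)
        assert c == pytest.approx(72.5, rel=1e-6)

    def test_ri_band_midpoint_concentration_in_printed_range(self):
        # RI-III mid-band 1.3731 → ≈190 fg/µm³, inside the reported
        # midpiece RI-III concentration interval (≈188–249 fg/µm³)
        tomo = RITomogram(np.full((5, 5, 5), 1.3731), (0.1,) * 3, MEDIUM_RI)
        c = region_concentration(tomo, np.ones((5, 5, 5), bool), ri_increment=0.19)
        assert 185.0 <= c <= 250.0

    def test_dry_mass(self):
        assert region_dry_mass(0.0, 100.0) == 0.0
        assert region_dry_mass(72.5, 145.3) == pytest.approx(10.534, abs=5e-3)

    def test_empty_mask_concentration_raises(self):
        tomo = RITomogram(np.full((5, 5, 5), MEDIUM_RI), (0.1,) * 3, MEDIUM_RI)
        with pytest.raises(ValidationError):
            region_concentration(tomo, np.zeros((5, 5, 5), bool))


class TestBandDecomposition:
    def test_tail_has_no_dense_band(self, ho_segmentation):
        tomo, _, seg = ho_segmentation
        records = band_decomposition(tomo, seg)
        rec = {(r.region, r.band): r for r in records}
        assert not rec[("tail", "RI-III")].detectable
        assert rec[("midpiece", "RI-III")].detectable

    def test_zero_width_bands_undetectable(self, ho_segmentation):
        tomo, _, seg = ho_segmentation
        bands = RIBandSet(
            bands=(("empty-a", 1.9000, 1.9000), ("empty-b", 1.9100, 1.9100)),
            whole_cell=(1.34, 1.385),
        )
        records = band_decomposition(tomo, seg, bands)
        assert all(not r.detectable for r in records if r.band != "all")

    def test_band_volumes_bounded_by_region(self, ho_segmentation):
        tomo, _, seg = ho_segmentation
        records = band_decomposition(tomo, seg)
        for region in ("head", "midpiece", "tail"):
            total = next(r for r in records if r.region == region and r.band == "all")
            band_sum = sum(
                r.volume_um3 for r in records
                if r.region == region and r.band != "all" and r.detectable
            )
            assert band_sum <= total.volume_um3 + 1e-9

    def test_mass_additivity_over_bands(self, ho_segmentation):
        tomo, _, seg = ho_segmentation
        # bands tiling the detectable range exactly reproduce region mass
        bands = RIBandSet(
            bands=(("lo", 1.3400, 1.3599), ("hi", 1.3600, 1.3850)),
            whole_cell=(1.3400, 1.3850),
        )
        records = band_decomposition(tomo, seg, bands, min_voxels=1)
        for region in ("head", "midpiece", "tail"):
            total = next(r for r in records if r.region == region and r.band == "all")
            mass = sum(
                r.dry_mass_pg for r in records
                if r.region == region and r.band != "all" and r.detectable
            )
            assert mass == pytest.approx(total.dry_mass_pg, rel=1e-6)

    def test_overlapping_bands_rejected(self):
        with pytest.raises(ValidationError):
            RIBandSet(bands=(("a", 1.34, 1.36), ("b", 1.35, 1.37))).validate()
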