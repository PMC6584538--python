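"""Phantom generator: geometry oracles, populations, analytic fixtures."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from holosperm.core import SizingError, ValidationError
from holosperm.phantoms import (
    LABEL_HEAD,
    LABEL_MIDPIECE,
    LABEL_TAIL,
    BreedPopulationSpec,
    build_phantom,
    calibrate_head_axes,
    make_analytic_shape,
    sample_population,
    scale_to_cell_volume,
)
from holosperm.presets import HO_2D_STATS, MEDIUM_RI, default_population_spec, ho_design


class TestCalibrateHeadAxes:
    def test_unit_sphere(self):
        a, b, c = calibrate_head_axes(4.0 / 3.0 * math.pi, 1.0, 1.0)
        assert a == pytest.approx(1.0) and b == pytest.approx(1.0) and c == pytest.approx(1.0)

    def test_printed_head_volume_round_trip(self):
        a, b, c = calibrate_head_axes(94.18, 9.053 / 4.954, 2.0)
        assert 4.0 / 3.0 * math.pi * a * b * c == pytest.approx(94.18, rel=1e-12)
        assert a / b == pytest.approx(9.053 / 4.954)
        assert b / c == pytest.approx(2.0)

    @settings(deadline=None, max_examples=50)
    @given(
        v=st.floats(0.1, 500.0),
        r1=st.floats(1.0, 5.0),
        r2=st.floats(1.0, 5.0),
    )
    def test_volume_round_trip_property(self, v, r1, r2):
        a, b, c = calibrate_head_axes(v, r1, r2)
        assert 4.0 / 3.0 * math.pi * a * b * c == pytest.approx(v, rel=1e-9)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValidationError):
            calibrate_head_axes(-1.0, 1.0, 1.0)
        with pytest.raises(ValidationError):
            calibrate_head_axes(1.0, 0.5, 1.0)


class TestBuildPhantom:
    def test_zero_contrast_design_matches_background(self):
        d = replace(
            ho_design(),
            head_ri=MEDIUM_RI, midpiece_ri=MEDIUM_RI,
            midpiece_core_ri=MEDIUM_RI, tail_ri=MEDIUM_RI,
        )
        tomo = build_phantom(d, voxel_size=(0.2, 0.2, 0.2))
        assert np.all(tomo.values == MEDIUM_RI)

    def test_degenerate_sphere_head_volume(self):
        # 4 µm sphere head, vanishing flagellum: V = 4/3·π·2³ = 33.51 µm³
        d = replace(
            ho_design(),
            head_length=4.0, head_width=4.0, head_thickness=4.0,
            midpiece_length=1e-3, tail_length=1e-3,
            midpiece_radius=1e-3, tail_base_radius=1e-3, tail_tip_radius=1e-3,
        )
        tomo, labels = build_phantom(d, return_labels=True)
        v = np.count_nonzero(labels == LABEL_HEAD) * tomo.voxel_volume
        assert v == pytest.approx(4.0 / 3.0 * math.pi * 8.0, rel=0.02)

    def test_compartments_partition_cell(self, ho_phantom):
        tomo, labels = ho_phantom
        cell = tomo.values > tomo.medium_ri
        assert np.array_equal(cell, labels > 0)
        for a, b in [(LABEL_HEAD, LABEL_MIDPIECE), (LABEL_HEAD, LABEL_TAIL),
                     (LABEL_MIDPIECE, LABEL_TAIL)]:
            assert not np.any((labels == a) & (labels == b))

    def test_compartment_volumes_near_analytic(self, ho_phantom):
        tomo, labels = ho_phantom
        av = ho_design().analytic_volumes()
        for lab, name in [(LABEL_HEAD, "head"), (LABEL_MIDPIECE, "midpiece"), (LABEL_TAIL, "tail")]:
            v = np.count_nonzero(labels == lab) * tomo.voxel_volume
            assert v == pytest.approx(av[name], rel=0.02)

    def test_grid_too_small_raises(self):
        with pytest.raises(SizingError):
            build_phantom(ho_design(), shape=(10, 10, 10))

    def test_ri_below_medium_raises(self):
        with pytest.raises(ValidationError):
            build_phantom(replace(ho_design(), tail_ri=1.30))

    def test_scale_to_cell_volume_exact(self):
        d = scale_to_cell_volume(ho_design(), 145.3)
        assert d.analytic_volumes()["cell"] == pytest.approx(145.3, rel=1e-12)


class TestSamplePopulation:
    def test_zero_sd_gives_means(self):
        spec = BreedPopulationSpec(
            groups={"G": {"head_length": (9.0, 0.0), "tail_length": (46.0, 0.0)}},
            n_per_group=3, seed=0, base_design=ho_design(),
        )
        designs = sample_population(spec)["G"]
        assert all(d.head_length == 9.0 and d.tail_length == 46.0 for d in designs)

    def test_seed_determinism(self):
        spec = default_population_spec(n_per_group=5, seed=11)
        assert sample_population(spec) == sample_population(spec)

    def test_ho_head_width_mean_within_3_se(self):
        mean, sd = HO_2D_STATS["head_width"]
        pops = sample_population(default_population_spec(n_per_group=30, seed=2))
        sample = np.array([d.head_width for d in pops["HO"]])
        assert abs(sample.mean() - mean) <= 3.0 * sd / math.sqrt(30)

    def test_truncation_and_physical_bounds(self):
        pops = sample_population(default_population_spec(n_per_group=30, seed=3))
        for designs in pops.values():
            for d in designs:
                assert d.head_length > 0 and d.tail_length > 0
                assert d.head_width >= d.head_thickness
                assert min(d.head_ri, d.midpiece_ri, d.tail_ri) >= MEDIUM_RI

    def test_rejects_degenerate_n(self):
        spec = default_population_spec(n_per_group=1)
        with pytest.raises(ValidationError):
            sample_population(spec)


class TestAnalyticShapes:
    @pytest.mark.parametrize(
        "kind,params,voxel",
        [
            ("sphere", {"radius": 2.0}, 0.1),
            ("cube", {"edge": 1.0}, 0.05),
            ("cylinder", {"radius": 0.5, "length": 3.0}, 0.05),
            ("ellipsoid", {"semi_axes": (1.0, 2.0, 3.0)}, 0.1),
        ],
    )
    def test_voxel_volume_matches_metadata(self, kind, params, voxel):
        t = make_analytic_shape(kind, params, voxel_size=(voxel,) * 3)
        v = np.count_nonzero(t.values > t.medium_ri) * t.voxel_volume
        assert v == pytest.approx(t.metadata["analytic_volume"], rel=0.02)

    def test_sphere_area_metadata(self):
        t = make_analytic_shape("sphere", {"radius": 2.0})
        assert t.metadata["analytic_area"] == pytest.approx(4 * math.pi * 4.0, rel=1e-12)

    def test_unknown_kind_raises(self):
        with pytest.raises(ValidationError):
            make_analytic_shape("torus", {"radius": 1.0})
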