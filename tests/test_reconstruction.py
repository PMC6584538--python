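"""Reconstruction: demodulation, Ewald gridding, missing-cone iteration."""

import math

import numpy as np
import pytest

from conftest import make_slab, make_sphere
from holosperm.core import ValidationError
from holosperm.forward import (
    IlluminationPlan,
    scattered_fields,
    simulate_holograms,
    synthesize_hologram,
    ComplexField,
)
from holosperm.presets import MEDIUM_RI
from holosperm.reconstruction import (
    ReconstructionSettings,
    demodulate_hologram,
    demodulate_set,
    lauer_resolution,
    map_to_frequency_space,
    regularize_missing_cone,
    tomogram_from_spectrum,
)


class TestDemodulation:
    def test_plane_wave_recovers_unit_field(self):
        # narrow-band optics so the carrier clears the signal band on an
        # unoversampled camera; the object beam is the unit plane wave
        plan = IlluminationPlan(
            na_illumination=0.1, na_detection=0.5,
            camera_oversample=1, carrier_frequency=(10 / 3, 10 / 3),
        )
        f = ComplexField(
            amplitude=np.ones((64, 64)), phase=np.zeros((64, 64)),
            pixel_size=0.1, illum_dir=(0.0, 0.0, 1.0), wavelength=0.532, medium_ri=MEDIUM_RI,
        )
        holo = synthesize_hologram(f, plan)
        rec = demodulate_hologram(
            holo, plan, pixel_size=0.1, medium_ri=MEDIUM_RI,
            carrier=(np.round(10 / 3 * 6.4) / 6.4,) * 2, illum_dir=(0, 0, 1),
        )
        assert np.allclose(rec.amplitude, 1.0, atol=1e-6)
        assert np.allclose(rec.phase, 0.0, atol=1e-6)

    def test_forward_inverse_round_trip(self, plan):
        tomo = make_slab(5e-4)
        hset = simulate_holograms(tomo, plan)
        truth = scattered_fields(tomo, plan)
        rec = demodulate_set(hset, plan)
        for a, b in zip(rec, truth):
            err = np.linalg.norm(a.field - b.field) / np.linalg.norm(b.field)
            assert err <= 1e-3

    def test_carrier_na_conflict_raises(self, plan):
        holo = np.ones((64, 64))
        with pytest.raises(ValidationError, match="carrier/NA"):
            demodulate_hologram(
                holo, plan, pixel_size=0.05, medium_ri=MEDIUM_RI,
                carrier=(0.5, 0.5), illum_dir=(0, 0, 1),
            )


class TestFrequencyMapping:
    def test_normal_incidence_cap_fills_origin(self, plan):
        tomo = make_slab(0.001, n=32)
        fields = scattered_fields(tomo, plan, illum_dirs=np.array([[0.0, 0.0, 1.0]]))
        spec, support = map_to_frequency_space(fields, plan, (32,) * 3, (0.1,) * 3)
        assert support.filled_mask[0, 0, 0]
        assert support.n_filled > 0
        # a single cap: at most one z-entry per lateral frequency
        assert support.filled_mask.sum(axis=0).max() == 1

    def test_support_anisotropy_matches_missing_cone(self, plan):
        tomo = make_slab(0.001, n=64)
        fields = scattered_fields(tomo, plan)
        _, support = map_to_frequency_space(fields, plan, (64,) * 3, (0.1,) * 3)
        m = np.fft.fftshift(support.filled_mask)
        nz = np.nonzero(m.any(axis=(1, 2)))[0]
        nx = np.nonzero(m.any(axis=(0, 1)))[0]
        ax_extent = nz[-1] - nz[0] + 1
        lat_extent = nx[-1] - nx[0] + 1
        # lateral band ≈ 2(NA_i + NA_d)/λ cycles/µm
        assert lat_extent / 64 * 10 == pytest.approx(2 * 2.4 / 0.532, rel=0.1)
        assert 2.0 < lat_extent / ax_extent < 6.0

    def test_wrapped_phase_rejected(self, plan):
        f = ComplexField(
            amplitude=np.ones((32, 32)),
            phase=np.angle(np.exp(1j * np.linspace(0, 40 * np.pi, 32 * 32))).reshape(32, 32),
            pixel_size=0.1, illum_dir=(0.0, 0.0, 1.0), wavelength=0.532, medium_ri=MEDIUM_RI,
        )
        with pytest.raises(ValidationError, match="unwrap"):
            map_to_frequency_space([f], plan, (32,) * 3, (0.1,) * 3)


@pytest.fixture(scope="module")
def sphere_reconstruction(plan):
    tomo, inside = make_sphere(dn=0.01, radius=2.0, n=64)
    fields = scattered_fields(tomo, plan)
    spec, support = map_to_frequency_space(fields, plan, (64,) * 3, (0.1,) * 3)
    return tomo, inside, spec, support


class TestMissingCone:
    def test_zero_iterations_is_naive_inverse(self, plan, sphere_reconstruction):
        tomo, _, spec, support = sphere_reconstruction
        naive = tomogram_from_spectrum(spec, tomo.medium_ri, 0.532, tomo.voxel_size)
        zero = regularize_missing_cone(
            spec, support, ReconstructionSettings(regularization_iterations=0),
            tomo.medium_ri, 0.532, tomo.voxel_size,
        )
        assert np.allclose(naive.values, zero.values)

    def test_nonnegativity_iteration_reduces_rmse(self, plan, sphere_reconstruction):
        tomo, inside, spec, support = sphere_reconstruction
        naive = tomogram_from_spectrum(spec, tomo.medium_ri, 0.532, tomo.voxel_size)
        rec = regularize_missing_cone(
            spec, support, ReconstructionSettings(), tomo.medium_ri, 0.532, tomo.voxel_size,
        )
        rmse = lambda t: float(np.sqrt(np.mean((t.values[inside] - tomo.values[inside]) ** 2)))
        assert rmse(rec) <= 0.002
        assert rmse(rec) < rmse(naive)

    def test_support_voxels_preserved(self, plan, sphere_reconstruction):
        tomo, _, spec, support = sphere_reconstruction
        rec = regularize_missing_cone(
            spec, support, ReconstructionSettings(), tomo.medium_ri, 0.532, tomo.voxel_size,
        )
        k0 = 2 * math.pi / 0.532
        v = rec.values**2 * k0**2 - tomo.medium_ri**2 * k0**2
        s = np.fft.fftn(v)
        m = support.filled_mask
        rel = np.linalg.norm(s[m] - spec[m]) / np.linalg.norm(spec[m])
        # the output RI map is real-valued, so the measured voxels are
        # preserved up to the Hermitian projection of the (slightly
        # non-Hermitian) gridded data — a few 1e-3 relative
        assert rel < 5e-3

    def test_reconstructed_volume_closure(self, plan, sphere_reconstruction):
        tomo, inside, spec, support = sphere_reconstruction
        rec = regularize_missing_cone(
            spec, support, ReconstructionSettings(), tomo.medium_ri, 0.532, tomo.voxel_size,
        )
        thresh = tomo.medium_ri + 0.005  # midway between medium and sphere RI
        vol = np.count_nonzero(rec.values >= thresh) * rec.voxel_volume
        true_vol = np.count_nonzero(inside) * tomo.voxel_volume
        assert vol == pytest.approx(true_vol, rel=0.10)

    def test_point_scatterer_elongates_axially_without_regularization(self, plan):
        tomo, _ = make_sphere(dn=0.005, radius=0.15, n=64)
        fields = scattered_fields(tomo, plan)
        spec, _ = map_to_frequency_space(fields, plan, (64,) * 3, (0.1,) * 3)
        naive = tomogram_from_spectrum(spec, tomo.medium_ri, 0.532, tomo.voxel_size)
        v = naive.values - tomo.medium_ri
        iz, iy, ix = np.unravel_index(np.argmax(v), v.shape)

        def fwhm(p):
            half = p.max() / 2
            idx = np.nonzero(p >= half)[0]
            return idx[-1] - idx[0] + 1

        ratio = fwhm(v[:, iy, ix]) / fwhm(v[iz, iy, :])
        assert ratio > 1.5


class TestLauerResolution:
    def test_zero_illumination_na_limit(self):
        plan = IlluminationPlan(na_illumination=1e-9, na_detection=1.0)
        lat, ax = lauer_resolution(plan, MEDIUM_RI)
        assert lat == pytest.approx(0.532 / (2 * 1.0) * 1e3, rel=1e-6)

    def test_wavelength_scaling(self):
        l1 = lauer_resolution(IlluminationPlan(wavelength=0.532), MEDIUM_RI)
        l2 = lauer_resolution(IlluminationPlan(wavelength=1.064), MEDIUM_RI)
        assert l2[0] == pytest.approx(2 * l1[0])
        assert l2[1] == pytest.approx(2 * l1[1])

    def test_na_at_or_above_medium_rejected(self):
        with pytest.raises(ValidationError):
            lauer_resolution(IlluminationPlan(na_detection=1.337), MEDIUM_RI)
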