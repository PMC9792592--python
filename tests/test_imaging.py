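"""Fourier-optics image formation: spectra, ideal/chip differentiation,
synthetic targets, edge peaks, resolution and phase contrast."""

import numpy as np
import pytest

from planarchip import (
    GridError,
    ImagingConfig,
    ObjectField,
    PhysicsError,
    SyntheticSPResponse,
    angular_spectrum,
    apply_otf,
    count_edge_peaks,
    ideal_otf,
    make_bar_target,
    make_phase_cells,
    make_step_target,
    make_vortex_plate,
    phase_contrast_intensity,
    profile_through_center,
    resolution_check,
    smallest_resolved_width,
)

LAM = 643.0
PITCH = 0.1


def small_field(values):
    return ObjectField(values, PITCH, LAM)


class TestAngularSpectrum:
    def test_plane_wave_single_coefficient(self):
        n = 64
        x = (np.arange(n) - n // 2) * PITCH
        X, _ = np.meshgrid(x, x)
        k1 = 2 * np.pi * 4 / (n * PITCH)  # on-grid frequency
        obj = small_field(np.exp(1j * k1 * X))
        kx, ky, A = angular_spectrum(obj)
        mag = np.abs(A)
        j, i = np.unravel_index(np.argmax(mag), mag.shape)
        assert kx[i] == pytest.approx(k1)
        assert ky[j] == pytest.approx(0.0)
        mag[j, i] = 0
        assert mag.max() < 1e-10 * np.abs(A).max()

    def test_parseval(self):
        rng = np.random.default_rng(7)
        obj = small_field(rng.normal(size=(32, 32)) + 1j * rng.normal(size=(32, 32)))
        kx, ky, A = angular_spectrum(obj)
        dk = kx[1] - kx[0]
        lhs = np.sum(np.abs(obj.field) ** 2) * PITCH ** 2
        rhs = np.sum(np.abs(A) ** 2) * dk * (ky[1] - ky[0])
        assert abs(lhs - rhs) / lhs < 1e-9

    def test_gaussian_fourier_pair(self):
        n = 256
        w = 1.5  # um
        x = (np.arange(n) - n // 2) * PITCH
        X, Y = np.meshgrid(x, x)
        obj = small_field(np.exp(-(X ** 2 + Y ** 2) / w ** 2))
        kx, ky, A = angular_spectrum(obj)
        prof = np.abs(A[n // 2])
        prof = prof / prof.max()
        expect = np.exp(-kx ** 2 * (w / 2) ** 2)  # spectral waist 2/w
        assert np.max(np.abs(prof - expect)) < 1e-6


class TestApplyOTF:
    def test_unity_otf_is_identity(self):
        rng = np.random.default_rng(3)
        obj = small_field(rng.normal(size=(64, 64)) + 1j * rng.normal(size=(64, 64)))
        out = apply_otf(obj, ImagingConfig(lambda ux, uy: np.ones_like(ux, complex), na=None))
        assert np.max(np.abs(out.field - obj.field)) < 1e-12

    def test_derivative_theorem_on_plane_wave(self):
        n = 128
        x = (np.arange(n) - n // 2) * PITCH
        X, _ = np.meshgrid(x, x)
        k1 = 2 * np.pi * 6 / (n * PITCH)
        obj = small_field(np.exp(1j * k1 * X))
        out = apply_otf(obj, ImagingConfig(ideal_otf(1, "x"), na=None))
        k0 = obj.k0_per_um
        assert np.allclose(np.abs(out.field), k1 / k0, atol=1e-10)

    def test_linearity(self):
        rng = np.random.default_rng(11)
        a = rng.normal(size=(32, 32)) + 1j * rng.normal(size=(32, 32))
        b = rng.normal(size=(32, 32)) + 1j * rng.normal(size=(32, 32))
        cfg = ImagingConfig(ideal_otf(2, "x"), na=None)
        out_sum = apply_otf(small_field(a + 2j * b), cfg).field
        out_parts = apply_otf(small_field(a), cfg).field + 2j * apply_otf(small_field(b), cfg).field
        assert np.max(np.abs(out_sum - out_parts)) < 1e-10

    @pytest.mark.parametrize("order", [1, 2, 3, 4])
    def test_ideal_otf_matches_finite_differences(self, order):
        """(i kx / k0)^n acts as the n-th x-derivative of smooth fields."""
        n = 256
        x = (np.arange(n) - n // 2) * PITCH
        X, Y = np.meshgrid(x, x)
        L = n * PITCH
        field = np.exp(np.sin(2 * np.pi * X / L) + 0.5 * np.cos(4 * np.pi * Y / L))
        obj = small_field(field)
        out = apply_otf(obj, ImagingConfig(ideal_otf(order, "x"), na=None))
        k0 = obj.k0_per_um
        num = field
        for _ in range(order):  # high-order central differences as oracle
            num = np.gradient(num, PITCH, axis=1, edge_order=2)
        interior = (slice(8, -8), slice(8, -8))
        err = np.linalg.norm(out.field[interior] * k0 ** order - num[interior])
        assert err / np.linalg.norm(num[interior]) < 0.01

    def test_rotation_covariance_of_radial_otf(self):
        """Rotating the object under the isotropic radial OTF rotates the
        differentiated image with it (2D differentiation)."""
        obj = make_bar_target(2.0, shape=(128, 128), pitch_um=PITCH, wavelength_nm=LAM,
                              angle_deg=0.0)
        cfg = ImagingConfig(ideal_otf(2, "radial"), na=0.45)
        base = apply_otf(obj, cfg).intensity
        rotated_obj = ObjectField(np.rot90(obj.field), PITCH, LAM)
        rotated = apply_otf(rotated_obj, cfg).intensity
        assert np.max(np.abs(np.rot90(base) - rotated)) < 1e-10 * base.max()

    def test_nyquist_violation_rejected(self):
        obj = ObjectField(np.ones((32, 32)), 1.0, LAM)  # 1 um pitch
        with pytest.raises(GridError):
            apply_otf(obj, ImagingConfig(ideal_otf(1, "x"), na=0.45))

    def test_background_floor_in_crossed_configuration(self, chip, lambda2):
        """With the offset on the ky axis the OTF vanishes at the carrier, so
        the far-from-edge background is tiny relative to the edge response."""
        obj = make_step_target(shape=(256, 256), pitch_um=PITCH, wavelength_nm=lambda2,
                               sigma_um=0.3, angle_deg=0.0)
        out = apply_otf(obj, ImagingConfig(chip, na=0.45, offset=(0.0, -0.18)))
        s, prof = profile_through_center(out.intensity, PITCH, 0.0)
        far = prof[np.abs(s) > 5]
        assert np.median(far) >= 0
        assert np.median(far) < 0.01 * prof.max()


class TestTargets:
    def test_hard_step_is_binary(self):
        obj = make_step_target(shape=(64, 64), sigma_um=0.0)
        assert set(np.unique(obj.field.real)) == {0.0, 1.0}

    def test_bar_plateau_width(self):
        w = 2.0
        obj = make_bar_target(w, shape=(256, 256), pitch_um=PITCH)
        row = obj.field[128].real
        plateau = int(np.sum(row > 0.5))
        per_bar = w / PITCH
        assert abs(plateau - 3 * per_bar) <= 3  # three bars, +-1 px per bar

    def test_smoothed_step_derivative_is_gaussian(self):
        sigma = 0.4
        obj = make_step_target(shape=(256, 256), pitch_um=PITCH, sigma_um=sigma)
        row = obj.field[128].real
        x = obj.x
        deriv = np.gradient(row, PITCH)
        expect = np.exp(-x ** 2 / (2 * sigma ** 2)) / (sigma * np.sqrt(2 * np.pi))
        # np.gradient carries O(pitch^2) central-difference error (~1%)
        assert np.max(np.abs(deriv - expect)) < 2e-2 * expect.max()

    def test_too_narrow_bars_rejected(self):
        with pytest.raises(GridError):
            make_bar_target(0.15, pitch_um=PITCH)

    def test_vortex_charge_zero_is_flat(self):
        obj = make_vortex_plate(shape=(64, 64), charge=0)
        assert np.allclose(obj.field, 1.0)

    @pytest.mark.parametrize("charge", [1, 2, -1])
    def test_vortex_winding_number(self, charge):
        """Loop integral of the phase gradient around the center = 2 pi m."""
        obj = make_vortex_plate(shape=(128, 128), charge=charge)
        phase = np.angle(obj.field)
        n = 96
        ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
        r_px = 30
        rows = (64 + r_px * np.sin(ang)).astype(int)
        cols = (64 + r_px * np.cos(ang)).astype(int)
        loop = phase[rows, cols]
        winding = np.sum(np.angle(np.exp(1j * np.diff(np.append(loop, loop[0]))))) / (2 * np.pi)
        assert winding == pytest.approx(charge, abs=1e-6)

    def test_phase_cells_deterministic_and_unit_amplitude(self):
        a = make_phase_cells(shape=(64, 64), seed=5)
        b = make_phase_cells(shape=(64, 64), seed=5)
        assert np.array_equal(a.field, b.field)
        assert np.allclose(np.abs(a.field), 1.0, atol=1e-12)

    def test_empty_phantom_gives_null_differentiated_image(self):
        obj = make_phase_cells(shape=(64, 64), n_cells=0)
        out = apply_otf(obj, ImagingConfig(SyntheticSPResponse({2: 1.0}), na=0.45))
        assert np.max(out.intensity) < 1e-20

    def test_excessive_phase_amplitude_rejected(self):
        with pytest.raises(PhysicsError):
            make_phase_cells(phase_amplitude=3.5)


def hermite_gaussian_peak_oracle(order, sigma=0.3):
    """|d^n/dx^n smoothed step|^2 evaluated from the closed-form Gaussian
    derivative (Hermite polynomial times Gaussian): exactly n local maxima."""
    x = np.linspace(-3, 3, 4001)
    g = np.exp(-x ** 2 / (2 * sigma ** 2))
    d = g.copy()
    for _ in range(order - 1):
        d = np.gradient(d, x[1] - x[0])
    profile = d ** 2
    interior = profile[1:-1]
    peaks = np.sum((interior > profile[:-2]) & (interior > profile[2:])
                   & (interior > 1e-6 * profile.max()))
    return int(peaks)


class TestEdgePeaks:
    @pytest.mark.parametrize("order", [1, 2, 3, 4])
    def test_ideal_differentiator_peak_count(self, order):
        assert hermite_gaussian_peak_oracle(order) == order  # oracle self-check
        obj = make_step_target(shape=(512, 512), pitch_um=PITCH, wavelength_nm=LAM,
                               sigma_um=0.3)
        out = apply_otf(obj, ImagingConfig(ideal_otf(order, "x"), na=0.45))
        s, prof = profile_through_center(out.intensity, PITCH, 0.0)
        assert count_edge_peaks(s, prof) == order

    def test_flat_profile_counts_zero(self):
        s = np.linspace(-5, 5, 200)
        assert count_edge_peaks(s, np.ones_like(s)) == 0

    def test_empty_window_rejected(self):
        with pytest.raises(GridError):
            count_edge_peaks(np.linspace(10, 20, 50), np.ones(50), edge_um=0.0,
                             window_um=1.0)


class TestResolution:
    def test_wide_bars_resolved_narrow_not(self, chip, lambda2):
        smallest, detail = smallest_resolved_width(
            chip, [4.0, 2.0, 0.4], wavelength_nm=lambda2, na=0.45,
            shape=(512, 512), angle_deg=45.0)
        assert detail[4.0] and detail[2.0]
        # 0.4 um is below the diffraction limit lam/(2 NA) ~ 0.71 um
        assert not detail[0.4]
        assert smallest == 2.0

    def test_resolution_check_on_synthetic_profile(self):
        s = np.linspace(-3, 3, 601)
        edges = [(-1.0, 1.0)]
        two_ridges = np.exp(-((s + 1) ** 2) / 0.1) + np.exp(-((s - 1) ** 2) / 0.1)
        assert resolution_check(s, two_ridges, edges)
        merged = np.exp(-(s ** 2) / 4.0)
        assert not resolution_check(s, merged, edges)


class TestPhaseContrast:
    def test_linear_ramp_gives_uniform_gradient_squared(self):
        n = 128
        x = (np.arange(n) - n // 2) * PITCH
        X, _ = np.meshgrid(x, x)
        alpha = 2 * np.pi * 5 / (n * PITCH)  # grid-periodic ramp
        obj = ObjectField(np.exp(1j * alpha * X), PITCH, LAM, "phase")
        intensity = phase_contrast_intensity(obj)
        assert np.max(np.abs(intensity - alpha ** 2)) / alpha ** 2 < 1e-6

    def test_constant_phase_gives_zero(self):
        obj = ObjectField(np.full((64, 64), np.exp(0.7j)), PITCH, LAM, "phase")
        assert np.max(phase_contrast_intensity(obj)) < 1e-20

    def test_amplitude_object_rejected(self):
        obj = make_step_target(shape=(64, 64), sigma_um=0.0)
        with pytest.raises(PhysicsError):
            phase_contrast_intensity(obj)

    def test_ideal_plate_seam_is_continuous(self):
        """An exact 2-pi spiral has a continuous field across the seam: the
        x-differentiated image shows no line along it."""
        obj = make_vortex_plate(shape=(256, 256), pitch_um=PITCH, wavelength_nm=LAM,
                                seam_angle_deg=90.0)
        out = apply_otf(obj, ImagingConfig(ideal_otf(1, "x"), na=0.45))
        seam = out.intensity[160:240, 128]
        mirror = out.intensity[160:240, 129]
        assert abs(seam.mean() - mirror.mean()) < 0.5 * max(seam.mean(), mirror.mean())

    def test_physical_plate_seam_lights_up(self):
        """A plate designed for another wavelength keeps a residual phase
        step on the seam; the first-order image renders it as a bright line
        (input intensity is uniform)."""
        obj = make_vortex_plate(shape=(256, 256), pitch_um=PITCH, wavelength_nm=LAM,
                                seam_angle_deg=90.0, design_wavelength_nm=532.0)
        assert np.allclose(np.abs(obj.field), 1.0)  # invisible in bright field
        out = apply_otf(obj, ImagingConfig(ideal_otf(1, "x"), na=0.45))
        inten = out.intensity
        seam = inten[160:240, 127:130].mean()   # along +y through the center
        control = inten[160:240, 60:63].mean()
        assert seam > 5 * control
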