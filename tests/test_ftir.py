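"""IR band metrics: sub-resolution position, FWHM oracles, shift tables."""

import numpy as np
import pytest
from scipy.optimize import brentq

from dibperm.ftir import (
    FtirError,
    Spectrum,
    band_fwhm,
    band_position,
    normalize,
    shift_table,
)
from dibperm.synth import IrScenario, gen_spectrum, ir_preset

GRID = np.arange(400.0, 4000.0 + 2.0, 4.0)


def gaussian_band(center, height=1.0, fwhm=21.67, grid=GRID):
    return height * np.exp(-4 * np.log(2) * (grid - center) ** 2 / fwhm**2)


def spectrum(absorbance, grid=GRID):
    return Spectrum(wavenumber=grid, absorbance=absorbance)


CH2 = (2900.0, 2940.0)


class TestNormalize:
    def test_idempotent(self):
        sp = spectrum(gaussian_band(2922.0, height=3.1))
        once = normalize(sp, CH2)
        twice = normalize(once, CH2)
        np.testing.assert_allclose(twice.absorbance, once.absorbance)
        assert np.max(once.absorbance[(GRID >= 2900) & (GRID <= 2940)]) == 1.0

    def test_scale_invariance(self):
        a = gaussian_band(2922.0) + 0.6 * gaussian_band(2850.0)
        n1 = normalize(spectrum(a), CH2)
        n2 = normalize(spectrum(3.7 * a), CH2)
        np.testing.assert_allclose(n1.absorbance, n2.absorbance)

    def test_band_height_ratio_preserved(self):
        sc = IrScenario(bands=((2922.0, 1.0, 21.67, 1.0), (2850.0, 0.7, 18.0, 1.0)))
        sp, _ = gen_spectrum(sc)
        norm = normalize(sp, CH2)
        def height(s, window):
            lo, hi = window
            m = (s.wavenumber >= lo) & (s.wavenumber <= hi)
            return np.max(s.absorbance[m])
        ratio_raw = height(sp, (2840, 2870)) / height(sp, CH2)
        ratio_norm = height(norm, (2840, 2870)) / height(norm, CH2)
        assert ratio_norm == pytest.approx(ratio_raw, rel=1e-12)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(FtirError):
            normalize(spectrum(-np.abs(gaussian_band(2922.0))), CH2)


class TestBandPosition:
    def test_on_grid_center_exact(self):
        assert band_position(spectrum(gaussian_band(2920.0)), CH2) == pytest.approx(2920.0)

    def test_off_grid_center_sub_resolution(self):
        pos = band_position(spectrum(gaussian_band(2921.3)), CH2)
        assert pos == pytest.approx(2921.3, abs=0.1)

    def test_random_centers_within_tenth_wavenumber(self, rng):
        for _ in range(200):
            center = 2920.0 + rng.uniform(-2.0, 2.0)
            fwhm = rng.uniform(15.0, 30.0)
            pos = band_position(spectrum(gaussian_band(center, fwhm=fwhm)), CH2)
            assert abs(pos - center) <= 0.1

    def test_noisy_positions_mostly_within_half_wavenumber(self, rng):
        hits = 0
        n = 200
        for _ in range(n):
            center = 2920.0 + rng.uniform(-2.0, 2.0)
            a = gaussian_band(center) + rng.normal(0.0, 0.01, size=GRID.shape)
            try:
                pos = band_position(spectrum(a), CH2)
            except FtirError:
                continue
            hits += abs(pos - center) <= 0.5
        assert hits >= 0.95 * n

    def test_baseline_offset_invariance(self):
        a = gaussian_band(2921.3)
        p0 = band_position(spectrum(a), CH2)
        p1 = band_position(spectrum(a + 0.1), CH2)
        assert p1 == pytest.approx(p0, abs=1e-9)

    def test_amplitude_scale_invariance(self):
        a = gaussian_band(2921.3)
        assert band_position(spectrum(5.5 * a), CH2) == pytest.approx(
            band_position(spectrum(a), CH2), abs=1e-12
        )

    def test_centroid_method_close_to_apex_for_symmetric_band(self):
        pos = band_position(spectrum(gaussian_band(2921.3)), CH2, method="centroid")
        assert pos == pytest.approx(2921.3, abs=0.3)

    def test_edge_peak_rejected(self):
        with pytest.raises(FtirError):
            band_position(spectrum(gaussian_band(2942.0)), CH2)


class TestBandFwhm:
    def test_gaussian_analytic(self):
        sigma = 10.0
        a = np.exp(-0.5 * ((GRID - 2250.0) / sigma) ** 2)
        assert band_fwhm(spectrum(a), (2150, 2350)) == pytest.approx(23.548, abs=0.05)

    def test_lorentzian_analytic(self):
        gamma = 5.0
        a = 1.0 / (1.0 + ((GRID - 2250.0) / gamma) ** 2)
        assert band_fwhm(spectrum(a), (2150, 2350)) == pytest.approx(10.0, abs=0.05)

    def test_control_bandwidth_recovered(self):
        sp, truth = gen_spectrum(ir_preset("dopc_control_ch2as"))
        assert band_fwhm(sp, CH2) == pytest.approx(truth["bands"][0][2], abs=0.1)

    def test_pseudo_voigt_matches_numeric_root_oracle(self, rng):
        for _ in range(20):
            center = 2250.0 + rng.uniform(-2.0, 2.0)
            fwhm = rng.uniform(12.0, 30.0)
            eta = rng.uniform(0.0, 1.0)
            sc = IrScenario(bands=((center, 1.0, fwhm, eta),))
            sp, _ = gen_spectrum(sc)
            # oracle: exact half-max roots of the analytic band profile
            def f(x):
                g = np.exp(-4 * np.log(2) * (x - center) ** 2 / fwhm**2)
                lor = 1.0 / (1.0 + 4 * (x - center) ** 2 / fwhm**2)
                return eta * g + (1 - eta) * lor - 0.5
            left = brentq(f, center - 3 * fwhm, center)
            right = brentq(f, center, center + 3 * fwhm)
            measured = band_fwhm(sp, (center - 60, center + 60))
            assert measured == pytest.approx(right - left, abs=0.05)

    def test_truncated_band_rejected(self):
        with pytest.raises(FtirError):
            band_fwhm(spectrum(gaussian_band(2920.0, fwhm=80.0)), (2900, 2940))


class TestShiftTable:
    def _series(self, shifts, noise=0.0, seed=0):
        spectra = {}
        for i, (label, shift) in enumerate(shifts.items()):
            sc = IrScenario(bands=((1230.0 + shift, 1.0, 20.0, 1.0),),
                            noise_sd=noise, seed=seed + i)
            spectra[label], _ = gen_spectrum(sc)
        return spectra

    def test_identical_to_control_is_none(self):
        spectra = self._series({"1:0": 0.0, "dup": 0.0})
        table = shift_table(spectra, "1:0", (1200, 1260))
        row = table[table.label == "dup"].iloc[0]
        assert row.shift_cm1 == pytest.approx(0.0, abs=1e-9)
        assert row.classification == "none"

    def test_generated_pattern_recovered(self):
        shifts = {"1:0": 0.0, "100:1": -2.0, "50:1": -4.0, "30:1": -6.0,
                  "20:1": -3.0, "10:1": 1.0}
        table = shift_table(self._series(shifts), "1:0", (1200, 1260))
        got = dict(zip(table.label, table.classification))
        assert got == {"1:0": "none", "100:1": "red", "50:1": "red", "30:1": "red",
                       "20:1": "red", "10:1": "blue"}
        for label, shift in shifts.items():
            row = table[table.label == label].iloc[0]
            assert row.shift_cm1 == pytest.approx(shift, abs=0.1)

    def test_scale_invariance(self, rng):
        spectra = self._series({"1:0": 0.0, "30:1": -6.0})
        scaled = {
            k: Spectrum(wavenumber=v.wavenumber, absorbance=v.absorbance * rng.uniform(0.5, 9.0))
            for k, v in spectra.items()
        }
        t1 = shift_table(spectra, "1:0", (1200, 1260))
        t2 = shift_table(scaled, "1:0", (1200, 1260))
        np.testing.assert_allclose(t1.shift_cm1.to_numpy(), t2.shift_cm1.to_numpy(), atol=1e-9)

    def test_missing_control_rejected(self):
        with pytest.raises(FtirError):
            shift_table(self._series({"100:1": -2.0}), "1:0", (1200, 1260))
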