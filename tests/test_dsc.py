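"""Thermogram analysis: baseline, apex, enthalpy, two-component recovery."""

import numpy as np
import pytest

from dibperm.dsc import (
    DscError,
    Thermogram,
    baseline_correct,
    deconvolve,
    find_tm,
    integrate_enthalpy,
    to_molar_heat_capacity,
)
from dibperm.synth import DscScenario, dsc_preset, gen_thermogram

GRID = np.arange(-40.0, 0.0 + 0.025, 0.05)


def gaussian(T, center, area, sigma):
    return area / (sigma * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((T - center) / sigma) ** 2)


def make_tg(signal, T=GRID, **kw):
    return Thermogram(temperature=T, signal=signal, **kw)


class TestBaseline:
    def test_flat_baseline_is_identity(self):
        y = gaussian(GRID, -17.0, 9.0, 1.0)
        out = baseline_correct(make_tg(y))
        np.testing.assert_allclose(out.signal, y, atol=1e-12)

    def test_pure_ramp_removed(self):
        out = baseline_correct(make_tg(0.03 * GRID + 1.7))
        np.testing.assert_allclose(out.signal, 0.0, atol=1e-10)

    def test_peak_area_preserved_on_ramp(self):
        y = gaussian(GRID, -17.0, 9.01, 1.0) + 0.02 * GRID + 0.5
        out = baseline_correct(make_tg(y))
        assert integrate_enthalpy(out) == pytest.approx(9.01, rel=5e-3)

    def test_overlapping_windows_rejected(self):
        with pytest.raises(DscError):
            baseline_correct(make_tg(GRID * 0.0), pre_window=(-40, -30), post_window=(-32, 0))


class TestFindTm:
    def test_recovers_control_center(self, control_thermogram):
        tg, truth = control_thermogram
        tm = find_tm(baseline_correct(tg))
        assert tm == pytest.approx(truth["components"][0][0], abs=0.05)

    def test_grid_point_center_exact(self):
        center = GRID[460]  # exactly on the grid
        tm = find_tm(make_tg(gaussian(GRID, center, 5.0, 1.0)))
        assert tm == pytest.approx(center, abs=1e-12)

    def test_two_component_apex_matches_dense_oracle(self):
        comps = [(-19.21, 4.16, 1.0), (-22.08, 2.24, 1.0)]
        y = sum(gaussian(GRID, *c) for c in comps)
        dense = np.arange(-40.0, 0.0, 0.0005)
        oracle = dense[np.argmax(sum(gaussian(dense, *c) for c in comps))]
        assert find_tm(make_tg(y)) == pytest.approx(oracle, abs=0.01)

    def test_no_peak_errors(self):
        with pytest.raises(DscError):
            find_tm(make_tg(np.full_like(GRID, -1.0)))


class TestEnthalpy:
    def test_zero_signal(self):
        assert integrate_enthalpy(make_tg(np.zeros_like(GRID))) == 0.0

    def test_rectangular_pulse(self):
        h, lo, hi = 2.0, -20.0, -15.0
        y = np.where((GRID >= lo) & (GRID <= hi), h, 0.0)
        assert integrate_enthalpy(make_tg(y)) == pytest.approx(h * (hi - lo), rel=0.01)

    def test_control_preset_recovered(self, control_thermogram):
        tg, truth = control_thermogram
        dh = integrate_enthalpy(baseline_correct(tg))
        assert dh == pytest.approx(truth["total_dh"], rel=0.01)

    def test_raw_heat_flow_requires_metadata(self):
        tg = make_tg(np.ones_like(GRID), signal_units="mW", n_lipid=None)
        with pytest.raises(DscError):
            integrate_enthalpy(tg)
        with pytest.raises(DscError):
            to_molar_heat_capacity(tg)

    def test_heat_flow_conversion(self):
        # 1 mW at 6 °C/min over 1e-5 mol -> 1000 J/(mol °C) = 0.23901 kcal/(mol °C)
        tg = make_tg(np.ones_like(GRID), signal_units="mW", scan_rate=6.0, n_lipid=1e-5)
        out = to_molar_heat_capacity(tg)
        assert out.signal_units == "kcal/mol/C"
        np.testing.assert_allclose(out.signal, 1000.0 / 4184.0)


class TestDeconvolve:
    def test_single_gaussian_k1(self, control_thermogram):
        tg, truth = control_thermogram
        res = deconvolve(tg, k=1)
        (comp,) = res.components
        assert comp.rel_area == pytest.approx(100.0, abs=1e-6)
        assert comp.tm == pytest.approx(truth["components"][0][0], abs=0.01)
        assert res.dh == pytest.approx(truth["total_dh"], rel=0.01)

    def test_two_to_one_area_ratio(self):
        sigma = 1.0
        y = gaussian(GRID, -14.0, 6.0, sigma) + gaussian(GRID, -19.0, 3.0, sigma)
        res = deconvolve(make_tg(y), k=2, window=(-30, -5))
        assert res.components[0].rel_area == pytest.approx(66.667, abs=0.5)
        assert res.components[1].rel_area == pytest.approx(33.333, abs=0.5)

    def test_components_sorted_high_tm_first(self):
        tg, _ = gen_thermogram(dsc_preset("dopc_10to1"))
        res = deconvolve(tg, k=2)
        assert res.components[0].tm > res.components[1].tm

    def test_area_additivity(self):
        tg, truth = gen_thermogram(dsc_preset("dopc_10to1"))
        res = deconvolve(tg, k=2)
        total = integrate_enthalpy(tg, window=(-40, 0))
        assert sum(c.area for c in res.components) == pytest.approx(total, rel=1e-3)

    def test_auto_model_order_prefers_two_when_split(self):
        tg, _ = gen_thermogram(dsc_preset("dopc_4to1"))
        assert deconvolve(tg, k="auto").k == 2

    def test_auto_model_order_prefers_one_when_single(self):
        tg, _ = gen_thermogram(dsc_preset("dopc_1to0", noise_sd=0.02, seed=3))
        assert deconvolve(tg, k="auto").k == 1

    def test_random_two_component_recovery(self, rng):
        """Centers within 0.1 °C and relative areas within 2 points for 50
        random resolvable two-component thermograms with noise.

        Separation is kept at >= 2.5x the wider component (and >= 1.5 °C):
        closer pairs overlap into a single envelope whose split is not
        identifiable at these noise levels, for any fitting method."""
        for _ in range(50):
            c_hi = rng.uniform(-12.0, -9.0)
            widths = rng.uniform(0.8, 2.0, size=2)
            sep = max(rng.uniform(1.5, 6.0), 2.5 * float(np.max(widths)))
            areas = rng.uniform(1.0, 8.0, size=2)
            comps = ((c_hi, areas[0], widths[0]), (c_hi - sep, areas[1], widths[1]))
            apex = max(a / (w * np.sqrt(2 * np.pi)) for _, a, w in comps)
            sc = DscScenario(
                components=comps,
                noise_sd=rng.uniform(0.0, 0.02) * apex,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            tg, truth = gen_thermogram(sc)
            res = deconvolve(tg, k=2, window=(-25, -2))
            want = sorted(zip([c[0] for c in comps], truth["rel_areas"]), key=lambda x: -x[0])
            for comp, (center, rel) in zip(res.components, want):
                assert comp.tm == pytest.approx(center, abs=0.1)
                assert comp.rel_area == pytest.approx(rel, abs=2.0)

    def test_rel_areas_normalized(self):
        tg, _ = gen_thermogram(dsc_preset("dopcchol_30to1"))
        res = deconvolve(tg, k=2)
        assert sum(c.rel_area for c in res.components) == pytest.approx(100.0, abs=0.1)


class TestScanDirection:
    def test_cooling_scan_normalized_and_tm_matches(self):
        heat, _ = gen_thermogram(dsc_preset("dopc_50to1"))
        cool, _ = gen_thermogram(dsc_preset("dopc_50to1", direction="cooling"))
        assert cool.direction == "cooling"
        assert np.all(np.diff(cool.temperature) > 0)
        assert find_tm(cool) == pytest.approx(find_tm(heat), abs=1e-9)

    def test_non_monotone_grid_rejected(self):
        with pytest.raises(DscError):
            Thermogram(temperature=np.array([0.0, 1.0, 0.5]), signal=np.zeros(3))
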