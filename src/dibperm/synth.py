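"""Synthetic droplet-pair series, DSC thermograms and IR spectra.

Every analysis stage in this package is validated by parameter recovery:
a generator with known ground truth emits data mimicking the instruments
(a ~100 μm DIB droplet pair filmed for ~5 min at 1 Hz; a −40→0 °C DSC scan
at 5 °C/min; a 400–4000 cm⁻¹ ATR-FTIR spectrum at 4 cm⁻¹ resolution), and
the estimators must return the generating parameters.

Preset scenarios encode the published study conditions — permeabilities of
DOPC and DOPC/cholesterol bilayers across curcumin mole ratios, the
Tm/ΔH/component-split table of the calorimetry series, and the CH2/PO2⁻
band parameters — so recovery can be exercised at exactly those values.

Noise models: multiplicative Gaussian on radii (imaging error scales with
droplet size); additive Gaussian on thermogram and spectrum signals.  All
randomness flows through an explicit per-scenario seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .dsc import Thermogram
from .ftir import Spectrum
from .geometry import (
    DropletObservationSeries,
    contact_area,
    radius_from_volume,
    truncated_sphere_volume,
)
from .transport import OsmoticSystem, OSM_PER_L_TO_PER_UM3, simulate_flux

__all__ = [
    "DibScenario",
    "DscScenario",
    "IrScenario",
    "gen_dib_series",
    "gen_thermogram",
    "gen_spectrum",
    "DIB_PRESETS",
    "DSC_PRESETS",
    "IR_PRESETS",
    "dib_preset",
    "dsc_preset",
    "ir_preset",
    "SynthError",
]


class SynthError(ValueError):
    pass


# --------------------------------------------------------------------------
# droplet-pair scenarios

@dataclass(frozen=True)
class DibScenario:
    """One droplet-pair recording: ~100 μm droplets, one pure water and one
    ~0.186 Osm/L (nominally 0.1 M NaCl, osmotic coefficient 0.93), filmed
    for 300 s at 1 Hz."""

    pf_true: float            # μm/s
    r1_0: float = 50.0        # μm
    r2_0: float = 50.0        # μm
    rc_0: float = 25.0        # μm
    osm1: float = 0.0         # Osm/L (droplet 1: pure water)
    osm2: float = 0.186       # Osm/L (droplet 2: 0.1 M NaCl, phi=0.93)
    duration: float = 300.0   # s
    frame_rate: float = 1.0   # Hz
    radius_noise_sd: float = 0.005  # fractional
    seed: int = 0
    geometry: str = "truncated"

    def __post_init__(self) -> None:
        if self.pf_true < 0 or self.osm1 < 0 or self.osm2 < 0:
            raise SynthError("pf_true and osmolarities must be nonnegative")
        if min(self.r1_0, self.r2_0, self.duration, self.frame_rate) <= 0:
            raise SynthError("radii, duration and frame rate must be positive")
        if self.rc_0 < 0 or self.rc_0 > min(self.r1_0, self.r2_0):
            raise SynthError("contact radius must satisfy 0 <= rc <= min(R1, R2)")
        if self.radius_noise_sd < 0:
            raise SynthError("noise must be nonnegative")


def gen_dib_series(sc: DibScenario):
    """Simulate a droplet-pair observation series with known Pf.

    Forward-simulates the osmotic volume exchange, inverts the
    truncated-sphere geometry back to radii at constant contact radius,
    and applies multiplicative Gaussian radius noise.  Returns
    ``(DropletObservationSeries, truth)`` where ``truth`` records the full
    scenario for downstream recovery tests.
    """
    n_frames = int(round(sc.duration * sc.frame_rate)) + 1
    t = np.arange(n_frames) / sc.frame_rate

    if sc.geometry == "truncated":
        v1_0 = truncated_sphere_volume(sc.r1_0, sc.rc_0)
        v2_0 = truncated_sphere_volume(sc.r2_0, sc.rc_0)
    else:
        v1_0 = 4.0 / 3.0 * np.pi * sc.r1_0**3
        v2_0 = 4.0 / 3.0 * np.pi * sc.r2_0**3
    area = contact_area(sc.rc_0)
    n1 = sc.osm1 * OSM_PER_L_TO_PER_UM3 * v1_0
    n2 = sc.osm2 * OSM_PER_L_TO_PER_UM3 * v2_0

    system = OsmoticSystem(v1=v1_0, v2=v2_0, n1=n1, n2=n2, area=area, pf=sc.pf_true)
    v1, v2 = simulate_flux(system, t)

    r1 = radius_from_volume(v1, np.full_like(v1, sc.rc_0), geometry=sc.geometry)
    r2 = radius_from_volume(v2, np.full_like(v2, sc.rc_0), geometry=sc.geometry)

    if sc.radius_noise_sd > 0:
        rng = np.random.default_rng(sc.seed)
        r1 = r1 * (1.0 + rng.normal(0.0, sc.radius_noise_sd, size=r1.shape))
        r2 = r2 * (1.0 + rng.normal(0.0, sc.radius_noise_sd, size=r2.shape))
    if np.any(r1 <= 0) or np.any(r2 <= 0):
        raise SynthError("radius noise drove a radius nonpositive")
    # observation noise may push a radius below the (noiseless) contact radius
    rc = np.minimum(np.full_like(r1, sc.rc_0), np.minimum(r1, r2))

    obs = DropletObservationSeries(t=t, r1=r1, r2=r2, rc=rc)
    truth = {"kind": "dib", **asdict(sc)}
    return obs, truth


# --------------------------------------------------------------------------
# DSC scenarios

@dataclass(frozen=True)
class DscScenario:
    """A synthetic thermogram: Gaussian components (center °C, area
    kcal/mol, width = Gaussian sigma °C) on a −40→0 °C grid sampled every
    0.05 °C, plus an optional linear baseline and additive noise."""

    components: tuple         # of (center, area, sigma)
    t_min: float = -40.0
    t_max: float = 0.0
    grid_step: float = 0.05   # °C
    noise_sd: float = 0.0     # kcal/mol/°C
    baseline: tuple = (0.0, 0.0)  # (slope, intercept)
    seed: int = 0
    scan_rate: float = 5.0    # °C/min
    direction: str = "heating"

    def __post_init__(self) -> None:
        if not self.components:
            raise SynthError("at least one component required")
        for c, a, s in self.components:
            if a <= 0 or s <= 0:
                raise SynthError("component areas and widths must be positive")
            if not (self.t_min <= c <= self.t_max):
                raise SynthError(f"component center {c} outside the scan range")
        if self.grid_step <= 0 or self.noise_sd < 0:
            raise SynthError("grid step must be positive, noise nonnegative")


def gen_thermogram(sc: DscScenario):
    """Sum of Gaussian excess-heat-capacity components + baseline + noise."""
    T = np.arange(sc.t_min, sc.t_max + sc.grid_step / 2, sc.grid_step)
    y = np.zeros_like(T)
    for center, area, sigma in sc.components:
        y += area / (sigma * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((T - center) / sigma) ** 2)
    slope, intercept = sc.baseline
    y += slope * T + intercept
    if sc.noise_sd > 0:
        rng = np.random.default_rng(sc.seed)
        y = y + rng.normal(0.0, sc.noise_sd, size=y.shape)
    if sc.direction == "cooling":
        T, y = T[::-1], y[::-1]
    tg = Thermogram(temperature=T, signal=y, scan_rate=sc.scan_rate, direction=sc.direction)
    truth = {
        "kind": "dsc",
        **asdict(sc),
        "total_dh": float(sum(a for _, a, _ in sc.components)),
        "rel_areas": [100.0 * a / sum(x[1] for x in sc.components) for _, a, _ in sc.components],
    }
    return tg, truth


# --------------------------------------------------------------------------
# IR scenarios

def _pseudo_voigt(x, center, height, fwhm, gauss_fraction):
    """Height-normalized pseudo-Voigt: eta*Gaussian + (1-eta)*Lorentzian,
    sharing one FWHM."""
    g = np.exp(-4.0 * np.log(2.0) * (x - center) ** 2 / fwhm**2)
    lor = 1.0 / (1.0 + 4.0 * (x - center) ** 2 / fwhm**2)
    return height * (gauss_fraction * g + (1.0 - gauss_fraction) * lor)


@dataclass(frozen=True)
class IrScenario:
    """A synthetic ATR-FTIR spectrum: pseudo-Voigt bands (center cm⁻¹,
    height a.u., FWHM cm⁻¹, Gaussian fraction) on the 400–4000 cm⁻¹ grid at
    4 cm⁻¹ spacing, plus additive noise."""

    bands: tuple              # of (center, height, fwhm, gauss_fraction)
    nu_min: float = 400.0
    nu_max: float = 4000.0
    step: float = 4.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.bands:
            raise SynthError("at least one band required")
        for c, h, w, eta in self.bands:
            if h <= 0 or w <= 0:
                raise SynthError("band heights and FWHMs must be positive")
            if not (self.nu_min <= c <= self.nu_max):
                raise SynthError(f"band center {c} outside the spectral range")
            if not (0.0 <= eta <= 1.0):
                raise SynthError("gauss_fraction must lie in [0, 1]")
        if self.step <= 0 or self.noise_sd < 0:
            raise SynthError("step must be positive, noise nonnegative")


def gen_spectrum(sc: IrScenario):
    """Sum of pseudo-Voigt bands + additive Gaussian noise on a fixed grid."""
    nu = np.arange(sc.nu_min, sc.nu_max + sc.step / 2, sc.step)
    a = np.zeros_like(nu)
    for center, height, fwhm, eta in sc.bands:
        a += _pseudo_voigt(nu, center, height, fwhm, eta)
    if sc.noise_sd > 0:
        rng = np.random.default_rng(sc.seed)
        a = a + rng.normal(0.0, sc.noise_sd, size=a.shape)
    sp = Spectrum(wavenumber=nu, absorbance=a, resolution=sc.step)
    truth = {"kind": "ftir", **asdict(sc)}
    return sp, truth


# --------------------------------------------------------------------------
# preset registry: published study conditions as ground truths
#
# DIB presets: reported osmotic permeabilities (μm/s) of DOPC bilayers at
# lipid:curcumin mole ratios, and of the DOPC/cholesterol (4/1) control.
# DSC presets: reported Tm (°C) and ΔH (kcal/mol); split transitions carry
# two components with the printed second-peak center and relative area
# (width not printed; 1.0 °C sigma adopted).
# IR presets: CH2 antisymmetric-stretch bandwidths and the PO2⁻ band-shift
# series built from the reported shift magnitudes around a 1230 cm⁻¹
# control (absolute table values not republished).

DIB_PRESETS: dict = {
    "dopc_control": 74.0,
    "dopc_100to1": 72.0,
    "dopc_50to1": 68.0,
    "dopc_30to1": 74.0,
    "dopc_10to1": 78.0,
    "dopc_4to1": 82.0,
    "dopcchol_control": 70.0,
}


def _two_comp(main_tm, second_tm, total_dh, second_rel, sigma=1.0):
    # printed rel. area belongs to the second (lower-T, additive-rich) peak
    return (
        (main_tm, total_dh * (1.0 - second_rel / 100.0), sigma),
        (second_tm, total_dh * (second_rel / 100.0), sigma),
    )


DSC_PRESETS: dict = {
    "dopc_1to0": ((-16.98, 9.01, 1.0),),
    "dopc_100to1": ((-17.39, 8.76, 1.0),),
    "dopc_50to1": ((-17.48, 7.52, 1.0),),
    "dopc_30to1": ((-17.84, 7.46, 1.0),),
    "dopc_10to1": _two_comp(-19.21, -22.08, 6.40, 35.0),
    "dopc_4to1": _two_comp(-20.30, -22.28, 6.24, 82.0),
    "dopcchol_1to0": ((-19.37, 2.81, 1.0),),
    "dopcchol_100to1": ((-19.80, 2.36, 1.0),),
    "dopcchol_50to1": ((-20.39, 2.16, 1.0),),
    "dopcchol_30to1": _two_comp(-23.41, -26.00, 1.49, 56.0),
    "dopcchol_10to1": _two_comp(-23.45, -26.11, 1.48, 60.0),
    "dopcchol_4to1": _two_comp(-24.08, -26.76, 0.94, 72.0),
}

# CH2 antisymmetric stretch: control vs high-curcumin bandwidths (DOPC),
# and the near-constant DOPC/Chol pair.
IR_PRESETS: dict = {
    "dopc_control_ch2as": ((2922.0, 1.0, 21.67, 1.0),),
    "dopc_10to1_ch2as": ((2923.0, 1.0, 23.35, 1.0),),
    "dopcchol_control_ch2as": ((2922.0, 1.0, 24.27, 1.0),),
    "dopcchol_10to1_ch2as": ((2922.0, 1.0, 24.09, 1.0),),
}

#: PO2⁻ antisymmetric-stretch shift series (cm⁻¹ vs control at 1230):
#: red shifts growing to −6 at 30:1, then reversal toward blue.
PO2_SHIFT_SERIES: dict = {
    "1:0": 0.0,
    "100:1": -2.0,
    "50:1": -4.0,
    "30:1": -6.0,
    "20:1": -3.0,
    "10:1": 1.0,
}
PO2_CONTROL_CENTER = 1230.0
PO2_FWHM = 20.0


def dib_preset(name: str, seed: int = 0, **overrides) -> DibScenario:
    """Scenario for a named permeability condition (ground-truth Pf preset)."""
    if name not in DIB_PRESETS:
        raise SynthError(f"unknown DIB preset {name!r}; options: {sorted(DIB_PRESETS)}")
    return DibScenario(pf_true=DIB_PRESETS[name], seed=seed, **overrides)


def dsc_preset(name: str, seed: int = 0, **overrides) -> DscScenario:
    """Scenario for a named calorimetry condition (Tm/ΔH table preset)."""
    if name not in DSC_PRESETS:
        raise SynthError(f"unknown DSC preset {name!r}; options: {sorted(DSC_PRESETS)}")
    return DscScenario(components=DSC_PRESETS[name], seed=seed, **overrides)


def ir_preset(name: str, seed: int = 0, **overrides) -> IrScenario:
    """Scenario for a named IR band condition."""
    if name not in IR_PRESETS:
        raise SynthError(f"unknown IR preset {name!r}; options: {sorted(IR_PRESETS)}")
    return IrScenario(bands=IR_PRESETS[name], seed=seed, **overrides)


def po2_series_scenarios(seed: int = 0, noise_sd: float = 0.0) -> dict:
    """Labelled PO2⁻ band scenarios implementing the shift series."""
    return {
        label: IrScenario(
            bands=((PO2_CONTROL_CENTER + shift, 1.0, PO2_FWHM, 1.0),),
            noise_sd=noise_sd,
            seed=seed + i,
        )
        for i, (label, shift) in enumerate(PO2_SHIFT_SERIES.items())
    }
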