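"""DSC thermogram analysis: baseline correction, Tm, ΔH, deconvolution.

A lipid multilamellar-vesicle suspension scanned through its main phase
transition yields an excess heat-capacity peak.  The analysis chain is

1. ``baseline_correct`` — subtract a straight line anchored in flat
   pre-/post-transition windows;
2. ``find_tm`` — apex temperature with 3-point parabolic refinement;
3. ``integrate_enthalpy`` — trapezoidal area (kcal/mol) over the analysis
   window;
4. ``deconvolve`` — nonlinear least-squares fit of one or two Gaussian
   components, the standard descriptive model for a split transition into
   additive-rich (lower Tm) and additive-poor (higher Tm) domains.

Signals are molar excess heat capacity (kcal mol⁻¹ °C⁻¹); raw heat flow in
mW can be converted given the scan rate and moles of lipid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from lmfit.models import GaussianModel, PseudoVoigtModel

__all__ = [
    "Thermogram",
    "TransitionComponent",
    "TransitionResult",
    "baseline_correct",
    "to_molar_heat_capacity",
    "find_tm",
    "integrate_enthalpy",
    "deconvolve",
    "DscError",
]

DEFAULT_WINDOW = (-30.0, -5.0)  # °C, analysis window for DOPC-like transitions


class DscError(ValueError):
    pass


@dataclass
class Thermogram:
    """Temperature-resolved excess heat signal.

    ``signal_units`` is ``"kcal/mol/C"`` (molar excess heat capacity, the
    analysis-ready form) or ``"mW"`` (raw heat flow, requiring ``scan_rate``
    in °C/min and ``n_lipid`` in mol for conversion).  A descending
    temperature grid (cooling scan) is accepted and stored ascending with
    ``direction="cooling"``.
    """

    temperature: np.ndarray
    signal: np.ndarray
    signal_units: str = "kcal/mol/C"
    scan_rate: float | None = 5.0
    n_lipid: float | None = None
    direction: str = "heating"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.temperature.shape != self.signal.shape or self.temperature.ndim != 1:
            raise DscError("temperature and signal must be equal-length 1-D arrays")
        if len(self.temperature) < 3:
            raise DscError("thermogram needs at least 3 samples")
        dT = np.diff(self.temperature)
        if np.all(dT < 0):  # cooling scan: normalize ascending, keep provenance
            self.temperature = self.temperature[::-1].copy()
            self.signal = self.signal[::-1].copy()
            self.direction = "cooling"
        elif not np.all(dT > 0):
            raise DscError("temperature grid must be strictly monotone")
        if self.scan_rate is not None and self.scan_rate <= 0:
            raise DscError("scan rate must be positive")


def to_molar_heat_capacity(tg: Thermogram) -> Thermogram:
    """Convert a raw heat-flow thermogram (mW) to kcal mol⁻¹ °C⁻¹.

    Cp(T) = P / (β n) with P in watts, β in °C/s and n in mol, then J→kcal.
    """
    if tg.signal_units == "kcal/mol/C":
        return tg
    if tg.signal_units != "mW":
        raise DscError(f"unknown signal units {tg.signal_units!r}")
    if tg.scan_rate is None or tg.n_lipid is None or tg.n_lipid <= 0:
        raise DscError("raw heat-flow conversion requires scan_rate and n_lipid")
    beta_c_per_s = tg.scan_rate / 60.0
    cp_j = (tg.signal / 1000.0) / (beta_c_per_s * tg.n_lipid)
    return replace(tg, signal=cp_j / 4184.0, signal_units="kcal/mol/C")


def _window_mask(T: np.ndarray, window) -> np.ndarray:
    lo, hi = sorted(window)
    return (T >= lo) & (T <= hi)


def baseline_correct(tg: Thermogram, pre_window=(-40.0, -32.0), post_window=(-4.0, 0.0)) -> Thermogram:
    """Subtract the straight line fitted through two flat windows.

    The windows must lie on the grid, not overlap, and sit outside the
    transition region (the caller's responsibility).
    """
    lo1, hi1 = sorted(pre_window)
    lo2, hi2 = sorted(post_window)
    if max(lo1, lo2) < min(hi1, hi2):
        raise DscError("baseline windows overlap")
    m = _window_mask(tg.temperature, pre_window) | _window_mask(tg.temperature, post_window)
    if np.count_nonzero(_window_mask(tg.temperature, pre_window)) < 2:
        raise DscError("pre-transition window contains fewer than 2 grid points")
    if np.count_nonzero(_window_mask(tg.temperature, post_window)) < 2:
        raise DscError("post-transition window contains fewer than 2 grid points")
    slope, intercept = np.polyfit(tg.temperature[m], tg.signal[m], 1)
    corrected = tg.signal - (slope * tg.temperature + intercept)
    return replace(tg, signal=corrected, meta={**tg.meta, "baseline": (float(slope), float(intercept))})


def _parabolic_refine(x: np.ndarray, y: np.ndarray, i: int) -> float:
    """Vertex of the parabola through samples i-1, i, i+1 (x at max if flat)."""
    if i == 0 or i == len(x) - 1:
        return float(x[i])
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom == 0.0:
        return float(x[i])
    delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
    h = 0.5 * (x[i + 1] - x[i - 1])
    return float(x[i] + delta * h)


def find_tm(tg: Thermogram, window=None) -> float:
    """Apex temperature of the (baseline-corrected) endotherm.

    Global maximum on the grid, refined by 3-point parabolic interpolation;
    ties resolve to the lower temperature (first maximum on the ascending
    grid).
    """
    T, y = tg.temperature, tg.signal
    if window is not None:
        m = _window_mask(T, window)
        T, y = T[m], y[m]
    if T.size < 3:
        raise DscError("window contains fewer than 3 samples")
    if np.all(y <= 0):
        raise DscError("no positive excursion: cannot locate a transition peak")
    i = int(np.argmax(y))
    return _parabolic_refine(T, y, i)


def integrate_enthalpy(tg: Thermogram, window=DEFAULT_WINDOW) -> float:
    """Trapezoidal transition enthalpy (kcal/mol) over ``window``."""
    if tg.signal_units != "kcal/mol/C":
        raise DscError(
            "integrate_enthalpy needs molar heat capacity; convert raw heat flow "
            "with to_molar_heat_capacity (requires scan_rate and n_lipid)"
        )
    m = _window_mask(tg.temperature, window)
    if np.count_nonzero(m) < 2:
        raise DscError("integration window contains fewer than 2 samples")
    return float(np.trapezoid(tg.signal[m], tg.temperature[m]))


@dataclass(frozen=True)
class TransitionComponent:
    tm: float        # component centre, °C
    area: float      # kcal/mol
    rel_area: float  # % of total
    width: float     # Gaussian sigma (or FWHM/2.3548-equivalent), °C
    degenerate: bool = False


@dataclass
class TransitionResult:
    """Deconvolution summary: apex Tm, total ΔH, per-component shares.

    Components are sorted by descending Tm so the additive-poor (higher-Tm)
    component comes first; relative areas sum to 100 %.
    """

    tm: float
    dh: float
    components: list
    fit_quality: float
    aic: float | None = None
    k: int = 1

    def __post_init__(self) -> None:
        if self.components:
            total = sum(c.rel_area for c in self.components)
            if abs(total - 100.0) > 0.1:
                raise DscError(f"relative areas sum to {total:.3f}, expected 100")


def _estimate_fwhm(T: np.ndarray, y: np.ndarray, i_apex: int) -> float:
    half = y[i_apex] / 2.0
    left = T[i_apex]
    for j in range(i_apex, 0, -1):
        if y[j - 1] <= half:
            left = np.interp(half, [y[j - 1], y[j]], [T[j - 1], T[j]])
            break
    right = T[i_apex]
    for j in range(i_apex, len(y) - 1):
        if y[j + 1] <= half:
            right = np.interp(half, [y[j + 1], y[j]], [T[j + 1], T[j]])
            break
    fwhm = right - left
    step = float(np.median(np.diff(T)))
    return max(fwhm, 2.0 * step)


def _fit_once(T, y, centers, sigmas, amplitudes, lineshape):
    model = None
    params = None
    Model = GaussianModel if lineshape == "gaussian" else PseudoVoigtModel
    for i, (c, s, a) in enumerate(zip(centers, sigmas, amplitudes)):
        comp = Model(prefix=f"c{i}_")
        p = comp.make_params()
        p[f"c{i}_center"].set(value=c, min=T[0], max=T[-1])
        p[f"c{i}_sigma"].set(value=s, min=1e-3, max=(T[-1] - T[0]))
        p[f"c{i}_amplitude"].set(value=a, min=0.0)
        if model is None:
            model, params = comp, p
        else:
            model = model + comp
            params.update(p)
    return model.fit(y, params, x=T)


def deconvolve(
    tg: Thermogram,
    k: int | str = 2,
    init=None,
    window=DEFAULT_WINDOW,
    lineshape: str = "gaussian",
) -> TransitionResult:
    """Fit ``k`` peak components to a baseline-corrected thermogram.

    ``k`` is 1, 2 or ``"auto"``: AIC choice between 1 and 2, with the
    two-component model additionally required to produce two resolvably
    distinct, non-degenerate components (centers ≥ 0.5 °C apart) — a noisy
    single transition otherwise "splits" into two coincident Gaussians that
    improve the AIC without describing a real second domain.  When ``init``
    (list of (center, sigma, amplitude) triples) is omitted, starts are
    derived from the apex: for k=2 the conventional (apex, apex−2 °C)
    start, its mirror (apex, apex+2 °C) and a start at the largest residual
    of the one-component fit are tried and the lower-residual fit kept,
    which keeps the fit well-posed whichever side of the apex the minor
    component sits on.
    """
    if k == "auto":
        r1 = deconvolve(tg, 1, init=None, window=window, lineshape=lineshape)
        r2 = deconvolve(tg, 2, init=None, window=window, lineshape=lineshape)
        resolved = (
            abs(r2.components[0].tm - r2.components[1].tm) >= 0.5
            and not any(c.degenerate for c in r2.components)
        )
        return r2 if (resolved and r2.aic < r1.aic) else r1
    if k not in (1, 2):
        raise DscError(f"component count must be 1, 2 or 'auto', got {k!r}")

    m = _window_mask(tg.temperature, window)
    T, y = tg.temperature[m], tg.signal[m]
    if T.size < 3 * k + 1:
        raise DscError("too few samples in the analysis window for the requested fit")
    if np.all(y <= 0):
        raise DscError("no positive excursion in the analysis window")

    i_apex = int(np.argmax(y))
    apex_T = T[i_apex]
    sigma0 = _estimate_fwhm(T, y, i_apex) / 2.3548
    total_area = float(np.trapezoid(np.clip(y, 0, None), T))

    if init is not None:
        starts = [list(init)]
    elif k == 1:
        starts = [[(apex_T, sigma0, total_area)]]
    else:
        starts = [
            [(apex_T, sigma0, total_area / 2), (apex_T - 2.0, sigma0, total_area / 2)],
            [(apex_T, sigma0, total_area / 2), (apex_T + 2.0, sigma0, total_area / 2)],
        ]
        # third start: second center at the largest single-Gaussian residual
        single = _fit_once(T, y, [apex_T], [sigma0], [total_area], lineshape)
        t_resid = float(T[int(np.argmax(np.abs(y - single.best_fit)))])
        if abs(t_resid - apex_T) > 0.25 * sigma0:
            starts.append(
                [(apex_T, sigma0, total_area / 2), (t_resid, sigma0, total_area / 2)]
            )

    best = None
    for start in starts:
        centers, sigmas, amps = zip(*start)
        res = _fit_once(T, y, centers, sigmas, amps, lineshape)
        if best is None or res.chisqr < best.chisqr:
            best = res
    if not best.success:
        raise RuntimeError(f"deconvolution failed to converge: {best.message}")

    areas = [float(best.params[f"c{i}_amplitude"].value) for i in range(k)]
    centers = [float(best.params[f"c{i}_center"].value) for i in range(k)]
    sigmas = [float(best.params[f"c{i}_sigma"].value) for i in range(k)]
    total = sum(areas)
    comps = [
        TransitionComponent(
            tm=c,
            area=a,
            rel_area=100.0 * a / total,
            width=s,
            degenerate=bool(s < 1e-2 or a < 1e-3 * total),
        )
        for c, a, s in zip(centers, areas, sigmas)
    ]
    comps.sort(key=lambda c: -c.tm)

    dense_T = np.linspace(T[0], T[-1], 20 * len(T))
    dense_y = best.eval(x=dense_T)
    tm = _parabolic_refine(dense_T, dense_y, int(np.argmax(dense_y)))

    return TransitionResult(
        tm=tm,
        dh=total,
        components=comps,
        fit_quality=float(np.sqrt(best.chisqr / len(T))),
        aic=float(best.aic),
        k=k,
    )
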