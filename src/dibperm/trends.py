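"""Concentration bookkeeping and biphasic dose-response detection.

Additive loading is expressed either as a lipid:additive mole ratio
(e.g. "50:1") or as additive mole percent; a response measured across the
concentration series (Pf, Tm, a band shift, ...) is classified as flat,
monotonic, or biphasic (interior extremum).  The classifier is descriptive
— a noise tolerance separates real structure from scatter — not an
inferential test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConcentrationSeries",
    "Classification",
    "ratio_to_molpercent",
    "parse_ratio_label",
    "percent_change",
    "classify_response",
    "TrendError",
]


class TrendError(ValueError):
    pass


def ratio_to_molpercent(lipid_parts: float, additive_parts: float) -> float:
    """Mole percent of the additive in a lipid:additive mixture.

    100 * additive / (lipid + additive); e.g. 50:1 -> 1.96 mol %,
    4:1 -> 20 mol %, 1:0 (control) -> 0 mol %.
    """
    if lipid_parts < 0 or additive_parts < 0:
        raise TrendError("mole-ratio parts must be nonnegative")
    if lipid_parts == 0 and additive_parts == 0:
        raise TrendError("mole ratio 0:0 is undefined")
    return 100.0 * additive_parts / (lipid_parts + additive_parts)


def parse_ratio_label(label: str) -> float:
    """Mol % from a 'lipid:additive' label such as '50:1' or '1:0'."""
    try:
        lipid, additive = (float(x) for x in label.split(":"))
    except Exception as exc:
        raise TrendError(f"cannot parse mole-ratio label {label!r}") from exc
    return ratio_to_molpercent(lipid, additive)


def percent_change(control: float, sample: float) -> float:
    """Signed percent change of ``sample`` relative to ``control``."""
    if control == 0:
        raise TrendError("percent change undefined for zero control")
    return 100.0 * (sample - control) / control


@dataclass
class ConcentrationSeries:
    """Responses indexed by additive mole percent.

    ``labels`` carry the original mole-ratio strings; ``y_sd`` optional
    per-point dispersions.  Points are sorted by mol % on construction.
    """

    labels: list
    molpct: np.ndarray
    y: np.ndarray
    y_sd: np.ndarray | None = None
    sorted_on_input: bool = field(default=True, init=False)

    def __post_init__(self) -> None:
        self.molpct = np.asarray(self.molpct, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.y_sd is not None:
            self.y_sd = np.asarray(self.y_sd, dtype=float)
        n = len(self.molpct)
        if len(self.labels) != n or len(self.y) != n:
            raise TrendError("labels, molpct and y must have equal lengths")
        if self.y_sd is not None and len(self.y_sd) != n:
            raise TrendError("y_sd length mismatch")
        if np.any(self.molpct < 0) or np.any(self.molpct >= 100):
            raise TrendError("mole percent must lie in [0, 100)")
        order = np.argsort(self.molpct, kind="stable")
        if not np.all(order == np.arange(n)):
            self.sorted_on_input = False
            self.labels = [self.labels[i] for i in order]
            self.molpct = self.molpct[order]
            self.y = self.y[order]
            if self.y_sd is not None:
                self.y_sd = self.y_sd[order]
        if np.any(np.diff(self.molpct) <= 0):
            raise TrendError("mole percents must be distinct")

    @classmethod
    def from_ratio_labels(cls, labels, y, y_sd=None) -> "ConcentrationSeries":
        molpct = [parse_ratio_label(lab) for lab in labels]
        return cls(labels=list(labels), molpct=molpct, y=y, y_sd=y_sd)


@dataclass(frozen=True)
class Classification:
    kind: str                   # flat | monotonic_* | biphasic_* | complex
    extremum_label: str | None  # label of interior extremum for biphasic
    tol: float                  # tolerance actually used


def _default_tol(series: ConcentrationSeries) -> float:
    if series.y_sd is not None and np.any(series.y_sd > 0):
        return float(np.sqrt(np.mean(series.y_sd**2)))
    return 0.01 * abs(series.y[0])


def classify_response(series: ConcentrationSeries, tol: float | None = None) -> Classification:
    """Classify the shape of a concentration-response series.

    With tolerance ``tol`` (default pooled y_sd, else 1 % of the control
    response): *flat* if the whole range fits within tol; *monotonic* if all
    above-tolerance successive steps share one sign; *biphasic_min* if the
    global minimum is interior with an above-tolerance fall before it and
    rise after it (``biphasic_max`` mirrored); otherwise *complex*.
    """
    if len(series.y) < 3:
        raise TrendError("need at least 3 concentration points")
    if tol is None:
        tol = _default_tol(series)
    if tol < 0:
        raise TrendError("tolerance must be nonnegative")
    y = series.y
    if np.max(y) - np.min(y) <= tol:
        return Classification("flat", None, tol)
    diffs = np.diff(y)
    signs = np.sign(diffs)
    signs[np.abs(diffs) <= tol] = 0
    nz = signs[signs != 0]
    if nz.size and np.all(nz < 0):
        return Classification("monotonic_decreasing", None, tol)
    if nz.size and np.all(nz > 0):
        return Classification("monotonic_increasing", None, tol)

    i_min = int(np.argmin(y))
    if 0 < i_min < len(y) - 1:
        falls = np.max(y[: i_min + 1]) - y[i_min] > tol
        rises = np.max(y[i_min:]) - y[i_min] > tol
        if falls and rises:
            return Classification("biphasic_min", series.labels[i_min], tol)
    i_max = int(np.argmax(y))
    if 0 < i_max < len(y) - 1:
        rises = y[i_max] - np.min(y[: i_max + 1]) > tol
        falls = y[i_max] - np.min(y[i_max:]) > tol
        if rises and falls:
            return Classification("biphasic_max", series.labels[i_max], tol)
    return Classification("complex", None, tol)
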