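"""CSV readers/writers for the three data dialects.

Fixed headers, decimal-point-only numbers, UTF-8:

* droplet series      ``t_s,R1_um,R2_um,rc_um``
* thermogram          ``T_C,signal``  (+ optional JSON metadata sidecar)
* spectrum            ``wavenumber_cm1,absorbance``

Parse errors carry 1-based line numbers.  Thermogram sidecars
(``<name>.meta.json``) hold scan rate, moles of lipid, units and scan
direction; a missing sidecar defers any unit error to the point of use
(enthalpy integration), not to the read.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dsc import Thermogram
from .ftir import Spectrum
from .geometry import DropletObservationSeries

__all__ = [
    "read_series",
    "write_series",
    "read_thermogram",
    "write_thermogram",
    "read_spectrum",
    "write_spectrum",
    "sidecar_path",
    "ParseError",
]

SERIES_HEADER = ["t_s", "R1_um", "R2_um", "rc_um"]
THERMOGRAM_HEADER = ["T_C", "signal"]
SPECTRUM_HEADER = ["wavenumber_cm1", "absorbance"]


class ParseError(ValueError):
    """CSV parse failure; ``line`` is the 1-based offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"{message} (line {line})" if line is not None else message)


def _read_table(path, expected_header):
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip()
    if [c.strip() for c in header.split(",")] != expected_header:
        raise ParseError(
            f"{path.name}: expected header {','.join(expected_header)!r}, got {header!r}",
            line=1,
        )
    try:
        df = pd.read_csv(path, encoding="utf-8", float_precision="round_trip")
    except Exception as exc:
        raise ParseError(f"{path.name}: {exc}") from exc
    for col in expected_header:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        nonnum = df[col].isna() | bad
        if nonnum.any():
            raise ParseError(
                f"{path.name}: non-numeric value in column {col!r}",
                line=int(nonnum.idxmax()) + 2,
            )
    return df.astype(float)


def read_series(path) -> DropletObservationSeries:
    """Read a droplet-pair observation series CSV."""
    df = _read_table(path, SERIES_HEADER)
    if len(df) < 2:
        raise ParseError(f"{Path(path).name}: need at least 2 data rows", line=2)
    t = df["t_s"].to_numpy()
    bad = np.flatnonzero(np.diff(t) <= 0)
    if bad.size:
        raise ParseError(f"{Path(path).name}: time not strictly increasing", line=int(bad[0]) + 3)
    return DropletObservationSeries(
        t=t, r1=df["R1_um"].to_numpy(), r2=df["R2_um"].to_numpy(), rc=df["rc_um"].to_numpy()
    )


def write_series(obs: DropletObservationSeries, path) -> None:
    df = pd.DataFrame({"t_s": obs.t, "R1_um": obs.r1, "R2_um": obs.r2, "rc_um": obs.rc})
    df.to_csv(path, index=False, float_format="%.17g", encoding="utf-8")


def sidecar_path(path) -> Path:
    return Path(path).with_suffix(Path(path).suffix + ".meta.json")


def read_thermogram(path) -> Thermogram:
    """Read a thermogram CSV, merging the JSON metadata sidecar if present.

    Without a sidecar the signal is assumed to already be molar excess heat
    capacity (kcal/mol/°C); raw heat-flow files must declare ``signal_units``
    and supply ``scan_rate`` / ``n_lipid`` in the sidecar.
    """
    df = _read_table(path, THERMOGRAM_HEADER)
    meta = {}
    sp = sidecar_path(path)
    if sp.exists():
        meta = json.loads(sp.read_text(encoding="utf-8"))
    T = df["T_C"].to_numpy()
    if np.any(np.diff(T) == 0) or (np.any(np.diff(T) > 0) and np.any(np.diff(T) < 0)):
        raise ParseError(f"{Path(path).name}: temperature grid not monotone")
    return Thermogram(
        temperature=T,
        signal=df["signal"].to_numpy(),
        signal_units=meta.get("signal_units", "kcal/mol/C"),
        scan_rate=meta.get("scan_rate", 5.0),
        n_lipid=meta.get("n_lipid"),
        direction=meta.get("direction", "heating"),
        meta=meta,
    )


def write_thermogram(tg: Thermogram, path, write_sidecar: bool = True) -> None:
    pd.DataFrame({"T_C": tg.temperature, "signal": tg.signal}).to_csv(
        path, index=False, float_format="%.17g", encoding="utf-8"
    )
    if write_sidecar:
        meta = {
            "signal_units": tg.signal_units,
            "scan_rate": tg.scan_rate,
            "n_lipid": tg.n_lipid,
            "direction": tg.direction,
        }
        sidecar_path(path).write_text(json.dumps(meta, indent=1), encoding="utf-8")


def read_spectrum(path) -> Spectrum:
    """Read a spectrum CSV; descending grids are reordered ascending."""
    df = _read_table(path, SPECTRUM_HEADER)
    return Spectrum(
        wavenumber=df["wavenumber_cm1"].to_numpy(), absorbance=df["absorbance"].to_numpy()
    )


def write_spectrum(sp: Spectrum, path) -> None:
    pd.DataFrame({"wavenumber_cm1": sp.wavenumber, "absorbance": sp.absorbance}).to_csv(
        path, index=False, float_format="%.17g", encoding="utf-8"
    )
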