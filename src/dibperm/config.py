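"""Validated run configuration for the CLI.

A YAML/JSON config file may carry per-subcommand defaults; flags given on
the command line win.  Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class FitPfConfig(_Strict):
    osm1: float | None = None
    osm2: float | None = None
    area_mode: str | None = None
    geometry: str | None = None


class DscFitConfig(_Strict):
    k: str | None = None
    window: str | None = None


class FtirBandsConfig(_Strict):
    window: str | None = None
    control: str | None = None
    tau: float | None = None
    method: str | None = None


class ClassifyConfig(_Strict):
    tol: str | None = None


class RunConfig(_Strict):
    fit_pf: FitPfConfig = FitPfConfig()
    dsc_fit: DscFitConfig = DscFitConfig()
    ftir_bands: FtirBandsConfig = FtirBandsConfig()
    classify: ClassifyConfig = ClassifyConfig()


def load_config(path: str | Path | None) -> RunConfig:
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    return RunConfig.model_validate(raw)
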