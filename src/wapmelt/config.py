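"""Structured pipeline configuration.

A single YAML file drives the CLI.  Unknown keys are rejected with a clear
error so that typos cannot silently change an analysis.  All thresholds
carry the pipeline defaults: SIC ice edge 15 % with 5-day persistence, MLD
quality cutoff QI = 0.5, period split at 1 January 2019 (the regional
climate-shift boundary separating 2002–2018 from 2019 onward), DJF summer
season, and the Palmer-LTER-grid ROI.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .errors import ConfigError


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class EndMemberConfig(_Strict):
    s_sim: float
    s_met: float
    s_ow: float
    d18o_sim: float
    d18o_met: float
    d18o_ow: float


class SynthConfig(_Strict):
    """Parameters of the synthetic-data generators (see wapmelt.synth)."""

    n_mixture_samples: int = 200
    mixture_noise_sd: float = 0.0
    sic_anchor_year: int = 2002
    sic_advance_jd: int = 120
    sic_retreat_jd: int = 330
    sic_plateau: float = 80.0
    sic_noise_sd: float = 3.0
    sic_cadence: str = "daily"
    mld_m: float = 40.0
    mld_step_kgm3: float = 0.5
    rho_target: float = 0.70
    coupled_start: str = "2002-09-01"
    coupled_end: str = "2021-08-31"  # spans the 2019 period split


class PipelineConfig(_Strict):
    seed: int = 0
    roi_vertices: list[tuple[float, float]] = [
        (-66.86, -63.97), (-78.48, -68.09), (-76.14, -69.24)]
    endmembers: EndMemberConfig | None = None
    period_split: str = "2019-01-01"
    season: str = "DJF"
    sic_threshold_pct: float = 15.0
    sic_persistence_days: int = 5
    qi_threshold: float = 0.5
    chla_transform: str = "log10-y"
    paths: dict[str, str] = {}
    synth: SynthConfig = SynthConfig()

    def config_hash(self) -> str:
        """Stable hash of the full configuration, for provenance."""
        blob = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    try:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    except yaml.YAMLError as e:
        raise ConfigError(f"{path}: not valid YAML: {e}") from e
    try:
        return PipelineConfig(**raw)
    except ValidationError as e:
        raise ConfigError(f"{path}: invalid configuration:\n{e}") from e


#: Example configuration shipped with the package.  The end-member values
#: are ILLUSTRATIVE, in the range of the WAP δ18O literature; a real
#: analysis must supply its own calibration.
EXAMPLE_CONFIG_YAML = """\
# wapmelt example configuration (illustrative values)
seed: 0
roi_vertices:
  - [-66.86, -63.97]
  - [-78.48, -68.09]
  - [-76.14, -69.24]
endmembers:          # illustrative WAP literature-range values, NOT a
  s_sim: 6.0         # calibration; supply your own for real data
  s_met: 0.0
  s_ow: 34.73
  d18o_sim: 1.9
  d18o_met: -16.0
  d18o_ow: -0.14
period_split: "2019-01-01"
sic_threshold_pct: 15.0
sic_persistence_days: 5
qi_threshold: 0.5
chla_transform: log10-y
"""
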