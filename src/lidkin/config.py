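"""Schema-validated run configuration for the end-to-end pipeline."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field, model_validator


class SimulateConfig(BaseModel):
    """Synthetic-experiment section (ground truth + delay schedule)."""

    tau1: float = 200e-9
    tau2: float = 825e-6
    n0: float = 2000.0
    probe_yield_radical: float = 0.25
    probe_yield_distonic: float = 0.10
    pump_frag_ag: float = 500.0
    alpha: float = Field(0.4, ge=0)
    channel_split: float = Field(0.65, ge=0, le=1)
    has_histidine: bool = True
    parent_mz: float = 755.0
    n_delays: int = Field(200, ge=1)
    t_min: float = 50e-9
    t_max: float = 20e-3
    n_negative: int = Field(5, ge=0)
    n_repeats: int = Field(120, ge=1)


class ChannelConfig(BaseModel):
    """Channel-table section: parent plus loss/pump windows."""

    parent_mz: float
    has_histidine: bool = True
    loss_masses: tuple[float, ...] = (129.0, 185.0)
    pump_centers: Optional[tuple[float, ...]] = None
    half_width: float = Field(0.5, gt=0)


class FitConfig(BaseModel):
    """Decay-fit section (fit window, bootstrap size)."""

    t_min: float = Field(30e-6, gt=0)
    n_boot: int = Field(10_000, ge=1)
    weighted: bool = True
    bootstrap: str = "parametric"


class RunConfig(BaseModel):
    """Full pipeline configuration.

    Either ``simulate`` (generate a synthetic dataset) or ``dataset`` (a
    JSON-lines file) must be given; a loaded dataset additionally needs a
    ``channels`` table.  Every run writes its resolved configuration
    beside the outputs so results can be regenerated bit-identically.
    """

    seed: int = 0
    system: str = "synthetic"
    simulate: Optional[SimulateConfig] = None
    dataset: Optional[Path] = None
    channels: Optional[ChannelConfig] = None
    calibration_floor: bool = True
    fit: FitConfig = FitConfig()
    outdir: Path = Path("lidkin_out")

    @model_validator(mode="after")
    def _check_inputs(self) -> "RunConfig":
        if self.simulate is None and self.dataset is None:
            raise ValueError("config must provide either 'simulate' or 'dataset'")
        if self.dataset is not None and self.channels is None:
            raise ValueError("field 'channels': required when loading a dataset")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.model_dump(mode="json"), sort_keys=False)
        )
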