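"""Run configuration: a validated YAML schema for end-to-end benchmark runs.

Unknown keys are rejected before any compute; all randomness in a run
flows from the single ``seed`` via named substreams (data, folds,
calibration splits, policies, mutation trials).
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = ["SyntheticSpec", "CsvSpec", "DatasetSpec", "RunConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SyntheticSpec(_Strict):
    s: float = 0.0
    n_per_class: int = Field(default=1000, ge=1)
    seed: Optional[int] = None  # defaults to the run's data substream


class CsvSpec(_Strict):
    path: str
    schema_path: str = Field(alias="schema")
    model_config = ConfigDict(extra="forbid", populate_by_name=True)


class DatasetSpec(_Strict):
    name: str
    synthetic: Optional[SyntheticSpec] = None
    csv: Optional[CsvSpec] = None

    @model_validator(mode="after")
    def _exactly_one_source(self):
        if (self.synthetic is None) == (self.csv is None):
            raise ValueError("dataset spec needs exactly one of 'synthetic' or 'csv'")
        return self


class RunConfig(_Strict):
    datasets: list[DatasetSpec]
    models: list[str] = ["logistic"]
    methods: list[str] = ["identity", "cpp", "epp", "roc", "psta", "fact", "gstar", "mab"]
    k: int = Field(default=5, ge=2)
    seed: int = 0
    ugr: Optional[list[float]] = None
    fairness_metric: str = "eop"
    performance_metric: str = "bacc"
    healthcare_factor: float = Field(default=0.9, gt=0.0, le=0.99)
    outdir: str = "results"


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    return RunConfig.model_validate(raw)
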