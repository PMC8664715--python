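"""Pipeline configuration: one validated object holding every tunable, with
the screen's standard thresholds as defaults.  The resolved configuration is
written beside each run's outputs so any result can be reproduced."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

from pydantic import BaseModel, ConfigDict, Field

from .errors import ParameterError


class PipelineConfig(BaseModel):
    """All tunables of the connectivity pipeline.

    Defaults: fold change > 1.8 and FDR < 5% for signature compilation,
    top/bottom 50 profile genes for set scoring, top 25 pro / top 15 anti
    compounds, a 5 µM dose-band boundary, and |z| >= 2 for target genes.
    Unknown keys are rejected.
    """

    model_config = ConfigDict(extra="forbid")

    fc_threshold: float = Field(default=1.8, gt=1.0)
    fdr_threshold: float = Field(default=0.05, gt=0.0, lt=1.0)
    n_top: int = Field(default=50, ge=1)
    method: Literal["signed_jaccard", "wks"] = "signed_jaccard"
    n_perm: int = Field(default=999, ge=99)
    k_pro: int = Field(default=25, ge=1)
    k_anti: int = Field(default=15, ge=1)
    dose_boundary_um: float = Field(default=5.0, gt=0.0)
    z_cutoff: float = Field(default=2.0, gt=0.0)
    restrict_targets: bool = True
    pool_order: Literal["pool_then_rank", "rank_then_pool"] = "pool_then_rank"
    enrich_n_null: int = Field(default=200, ge=10)
    seed: int = Field(default=0, ge=0)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        try:
            return cls.model_validate(json.loads(Path(path).read_text()))
        except Exception as exc:
            raise ParameterError(f"bad config {path}: {exc}") from exc

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=1) + "\n")
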