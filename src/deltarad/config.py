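"""Pipeline configuration: schema-checked defaults and per-stage seeding.

The cohort section is generated from :class:`deltarad.synth.CohortConfig`
so the simulation defaults live in exactly one place.  Unknown keys are
rejected; an empty config file yields all defaults.  Per-stage random
seeds are derived from the master seed and the stage name, so any stage
can be re-run in isolation with the stream it had inside a full run.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import typing
import zlib
from pathlib import Path

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, ValidationError, create_model

from .synth import CohortConfig

__all__ = ["PipelineConfig", "validate_config", "stage_seed", "config_hash"]


def _cohort_section():
    hints = typing.get_type_hints(CohortConfig)
    fields = {
        f.name: (hints[f.name], f.default)
        for f in dataclasses.fields(CohortConfig)
    }
    return create_model("CohortSection", __config__=ConfigDict(extra="forbid"), **fields)


CohortSection = _cohort_section()


class PipelineConfig(BaseModel):
    """Every tunable constant of the analysis, with the study defaults."""

    model_config = ConfigDict(extra="forbid")

    cohort: CohortSection = Field(default_factory=CohortSection)
    #: fixed-bin-number discretization for texture features
    n_bins: int = Field(default=32, ge=2)
    #: test-retest reliability threshold (features kept when ICC > threshold)
    icc_threshold: float = Field(default=0.80, le=1.0, ge=-1.0)
    #: |f0| guard for the per-day delta, as a fraction of the cohort median |f0|
    delta_epsilon_factor: float = Field(default=1e-8, gt=0)
    #: delta columns with more missingness than this are dropped
    max_missing_fraction: float = Field(default=0.20, ge=0.0, le=1.0)
    # survival forest
    rsf_n_trees: int = Field(default=500, ge=10)
    rsf_min_samples_leaf: int = Field(default=6, ge=1)
    # Boruta (forest size inside the selection loop is separate: the loop
    # refits every iteration, the final signature forest only once)
    boruta_n_trees: int = Field(default=100, ge=10)
    boruta_max_iter: int = Field(default=50, ge=5)
    boruta_alpha: float = Field(default=0.05, gt=0, lt=1)
    #: signature size
    k_features: int = Field(default=10, ge=1)
    maxstat_quantile_range: tuple[float, float] = (0.10, 0.90)
    tdroc_horizons_months: tuple[float, ...] = (6.0, 9.0, 12.0)
    n_bootstrap_ci: int = Field(default=1000, ge=10)
    n_bootstrap_compare: int = Field(default=2000, ge=10)
    n_permutations_maxstat: int = Field(default=200, ge=10)
    tdroc_n_boot: int = Field(default=200, ge=10)
    #: also write per-patient NIfTI volumes during run_all (slower; the
    #: stage-wise CLI always writes them)
    write_images: bool = False

    def cohort_config(self) -> CohortConfig:
        return CohortConfig(**self.cohort.model_dump())


def validate_config(path: str | Path | None) -> PipelineConfig:
    """Load and schema-check a JSON config; ``None``/empty file = defaults.

    Raises
    ------
    ValueError
        With a JSON-pointer-style location for every schema violation.
    """
    if path is None:
        return PipelineConfig()
    text = Path(path).read_text().strip()
    data = json.loads(text) if text else {}
    try:
        return PipelineConfig.model_validate(data)
    except ValidationError as exc:
        msgs = [
            "/" + "/".join(str(p) for p in err["loc"]) + ": " + err["msg"]
            for err in exc.errors()
        ]
        raise ValueError("invalid config: " + "; ".join(msgs)) from None


def config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: SeedSequence(master, crc32(stage))."""
    ss = np.random.SeedSequence([int(master_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31 - 1))
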