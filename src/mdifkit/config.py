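"""Run configuration: the scan/assay constants that affect every result.

All physical constants live here with their units so a pipeline run can log
full provenance. Unknown keys are rejected rather than silently ignored.
"""

from __future__ import annotations

from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator


class RunConfig(BaseModel):
    """Constants and switches for a quantification run.

    Times are minutes internally; file interfaces use seconds (PET
    convention) with explicit unit suffixes.
    """

    model_config = ConfigDict(extra="forbid")

    R: float = Field(0.9, gt=0, description="blood-to-plasma ratio (1.0 for a.u. simulations)")
    brain_density: float = Field(1.05, gt=0, description="g/mL, for mL<->g conversions")
    lumped_constant: float = Field(0.52, gt=0)
    plasma_glucose: Optional[float] = Field(None, gt=0, description="umol/mL")
    t_star: float = Field(20.0, gt=0, description="Patlak start time, minutes")
    seed: int = Field(0, ge=0)
    sime_starts: int = Field(8, ge=0, description="Latin-hypercube starts (plus box midpoint)")
    n_regions: int = Field(6, ge=2, description="region TACs entering SIME")
    frame_eval: Literal["mid", "average"] = Field(
        "mid", description="evaluate model curves at frame mid-times or frame averages"
    )
    compute_cmrglu: bool = False

    @model_validator(mode="after")
    def _cmrglu_needs_glucose(self):
        if self.compute_cmrglu and self.plasma_glucose is None:
            raise ValueError("compute_cmrglu requires plasma_glucose")
        return self

    def provenance(self) -> dict:
        """Everything that can affect numbers, for the report header."""
        return self.model_dump()
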