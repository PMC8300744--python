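"""File formats: trace CSVs, metadata sidecars, run configuration.

A trace file is a two-column CSV (``time_s``, ``absorbance_au``) with a
JSON sidecar (``<name>.meta.json``) holding the assay metadata in the
units practitioners use at the bench: µM concentrations, M^-1 cm^-1 molar
absorptivity, cm path length.  Concentrations are converted to molar at
this boundary and nowhere else.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .estimation import DEFAULT_EPSILON, AbsorbanceTrace, AssayContext

__all__ = [
    "TraceMetadata",
    "RunConfig",
    "write_trace",
    "read_trace",
    "sidecar_path",
]

TIME_COL = "time_s"
ABS_COL = "absorbance_au"


class TraceMetadata(BaseModel):
    """Sidecar schema; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    dpph0_uM: float = Field(gt=0)
    aoh_known_uM: float = Field(gt=0)
    epsilon: float = Field(default=DEFAULT_EPSILON, gt=0)
    path_length_cm: float = Field(default=1.0, gt=0)
    label: str = ""

    def to_context(self) -> AssayContext:
        return AssayContext(
            dpph0_nominal=self.dpph0_uM * 1e-6,
            aoh_known=self.aoh_known_uM * 1e-6,
            label=self.label,
        )


class RunConfig(BaseModel):
    """Configuration for the command-line entry points."""

    model_config = ConfigDict(extra="forbid")

    model: str = "auto"  # simple | side | auto
    fix_dpph0: bool = True
    n_starts: int = Field(default=5, ge=1)
    seed: int = 0
    sigma_au: float = Field(default=0.003, ge=0)
    dpph0_uM: float = Field(default=100.0, gt=0)
    concentrations_uM: list = Field(
        default_factory=lambda: [10.0, 20.0, 50.0, 100.0, 200.0, 400.0, 800.0]
    )
    duration_s: float = Field(default=300.0, gt=0)
    step_s: float = Field(default=1.0, gt=0)
    k1: float = Field(default=5.67e3, gt=0)
    k2: float = Field(default=0.0, ge=0)
    n_true: float = Field(default=2.0, gt=0)
    epsilon: float = Field(default=DEFAULT_EPSILON, gt=0)
    path_length_cm: float = Field(default=1.0, gt=0)


def sidecar_path(csv_path) -> Path:
    p = Path(csv_path)
    return p.with_suffix("").with_suffix(p.suffix).parent / (p.stem + ".meta.json")


def write_trace(
    csv_path,
    trace: AbsorbanceTrace,
    ctx: AssayContext,
    ground_truth: Optional[dict] = None,
) -> None:
    """Write the trace CSV, its metadata sidecar and an optional ground truth."""
    p = Path(csv_path)
    pd.DataFrame({TIME_COL: trace.times, ABS_COL: trace.absorbance}).to_csv(
        p, index=False, float_format="%.10g"
    )
    meta = TraceMetadata(
        dpph0_uM=ctx.dpph0_nominal * 1e6,
        aoh_known_uM=ctx.aoh_known * 1e6,
        epsilon=trace.epsilon,
        path_length_cm=trace.path_length,
        label=ctx.label,
    )
    sidecar_path(p).write_text(meta.model_dump_json(indent=2))
    if ground_truth is not None:
        truth_p = p.parent / (p.stem + ".truth.json")
        truth_p.write_text(json.dumps(ground_truth, indent=2))


def read_trace(csv_path) -> Tuple[AbsorbanceTrace, AssayContext]:
    """Read a trace CSV plus its sidecar back into domain objects."""
    p = Path(csv_path)
    df = pd.read_csv(p)
    for col in (TIME_COL, ABS_COL):
        if col not in df.columns:
            raise ValueError(f"{p}: missing column {col!r}")
    if df.empty:
        raise ValueError(f"{p}: empty trace file")
    times = df[TIME_COL].to_numpy(dtype=float)
    absorb = df[ABS_COL].to_numpy(dtype=float)
    if not (np.isfinite(times).all() and np.isfinite(absorb).all()):
        raise ValueError(f"{p}: non-numeric values in trace")
    sp = sidecar_path(p)
    if not sp.exists():
        raise FileNotFoundError(f"metadata sidecar not found: {sp}")
    meta = TraceMetadata.model_validate_json(sp.read_text())
    trace = AbsorbanceTrace(
        times=times,
        absorbance=absorb,
        epsilon=meta.epsilon,
        path_length=meta.path_length_cm,
    )
    return trace, meta.to_context()
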