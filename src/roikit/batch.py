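"""Deterministic batch execution of a pipeline + measurement set.

Files are processed independently (the only parallelism is per-file, so
determinism is trivially preserved): output rows are concatenated in
sorted-input order and are identical for any worker count.  Unreadable or
failing files become rows of the error report, never a crashed batch.
"""

from __future__ import annotations

import json
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .core import Spacing
from .io import read_image
from .measurement_sets import MeasurementSet, ResultTable, evaluate_measurement_set
from .profiles import Pipeline, run_pipeline

__all__ = ["BatchPlan", "BatchResult", "batch_execute"]


class BatchPlan(BaseModel):
    """Everything needed to reproduce a batch run."""

    inputs: list[str]
    pipeline: Pipeline
    measurement_set: MeasurementSet
    worker_count: int = 1
    spacing_nm: tuple[float, float, float] | None = None  # fallback when TIFFs lack metadata
    measure_mask_from_step: int | None = None  # use this step's mask as the measuring mask

    @field_validator("inputs")
    @classmethod
    def _nonempty(cls, v: list[str]) -> list[str]:
        if not v:
            raise ValueError("empty input list")
        return v

    @field_validator("worker_count")
    @classmethod
    def _workers(cls, v: int) -> int:
        if v < 1:
            raise ValueError(f"worker_count must be >= 1, got {v}")
        return v


@dataclass
class BatchResult:
    table: ResultTable
    errors: list[dict] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def _process_one(args: tuple) -> tuple[str, pd.DataFrame | None, dict | None, str | None]:
    """Worker: one file -> (path, rows, provenance, error)."""
    path, plan = args
    try:
        spacing = Spacing(*plan.spacing_nm) if plan.spacing_nm else None
        image = read_image(path, spacing=spacing)
        result = run_pipeline(image, plan.pipeline)
        mask = None
        if plan.measure_mask_from_step is not None:
            # re-derive the mask recorded by the requested step
            from .profiles import run_extraction
            from .core import labels_to_mask

            current = None
            for i, step in enumerate(plan.pipeline.steps):
                if step.mask_op.mode == "use_as_mask":
                    outcome = run_extraction(image, step.profile, mask=current)
                    current = labels_to_mask(
                        outcome.labels, step.mask_op.selected, step.mask_op.dilate_radius_nm
                    )
                if i == plan.measure_mask_from_step:
                    mask = current
                    break
        table = evaluate_measurement_set(
            image,
            result.labels,
            plan.measurement_set,
            mask=mask,
            source=Path(path).name,
        )
        provenance = {
            "file": str(path),
            "steps": result.step_provenance,
            "measurements": table.provenance,
        }
        return str(path), table.table, provenance, None
    except Exception as exc:  # per-file isolation: any failure becomes a report row
        return str(path), None, None, f"{type(exc).__name__}: {exc}"


def batch_execute(plan: BatchPlan) -> BatchResult:
    """Run the plan over all inputs; rows in sorted-input order."""
    paths = sorted(plan.inputs)
    jobs = [(p, plan) for p in paths]
    if plan.worker_count > 1:
        with ProcessPoolExecutor(max_workers=plan.worker_count) as pool:
            outcomes = list(pool.map(_process_one, jobs))
    else:
        outcomes = [_process_one(j) for j in jobs]
    frames: list[pd.DataFrame] = []
    provenances: list[dict] = []
    errors: list[dict] = []
    for path, frame, provenance, error in outcomes:
        if error is not None:
            errors.append({"file": path, "error": error})
        else:
            frames.append(frame)
            provenances.append(provenance)
    if frames:
        table = pd.concat(frames, ignore_index=True)
    else:
        table = pd.DataFrame(columns=["source", "component"])
    provenance = {
        "software": f"roikit {__version__}",
        "plan": plan.model_dump(exclude={"inputs"}),
        "inputs": paths,
        "per_file": provenances,
        "errors": errors,
    }
    return BatchResult(ResultTable(table, provenance), errors)


def write_batch_outputs(result: BatchResult, out_dir: str | Path, stem: str = "results") -> Path:
    """Write results CSV + provenance JSON + error report into a directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"{stem}.csv"
    result.table.to_csv(csv_path)
    if result.errors:
        (out_dir / f"{stem}.errors.json").write_text(json.dumps(result.errors, indent=2))
    return csv_path
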