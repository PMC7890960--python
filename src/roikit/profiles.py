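"""Serializable extraction profiles and incremental pipelines.

A profile names one extraction algorithm with its parameters; a pipeline
chains profiles, optionally turning each step's output into the next
step's mask (the incremental workflow: segment the nucleus, cut it out,
then extract structures inside it).  Everything round-trips through JSON
exactly, so a segmentation can be published and re-run elsewhere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path
from typing import Callable, Literal

import numpy as np
from pydantic import BaseModel, Field, ValidationError, field_validator

from .core import BinaryMask, Image, LabelMap, labels_to_mask
from .extraction import (
    ExtractionOutcome,
    connected_components,
    double_threshold_extract,
    gaussian_prefilter,
    size_filter,
    threshold_extract,
)
from .thresholding import (
    ThresholdResult,
    classify_multilevel,
    multi_otsu,
    build_histogram,
    range_threshold,
)

__all__ = [
    "ExtractionProfile",
    "MaskOp",
    "PipelineStep",
    "Pipeline",
    "PipelineResult",
    "EXTRACTION_ALGORITHMS",
    "run_extraction",
    "run_pipeline",
    "save_profile",
    "load_profile",
    "save_pipeline",
    "load_pipeline",
]


def _threshold_algorithm(image: Image, mask: BinaryMask | None, **params) -> ExtractionOutcome:
    return threshold_extract(image, mask=mask, **params)


def _range_algorithm(image: Image, mask: BinaryMask | None, **params) -> ExtractionOutcome:
    channel = params.get("channel", 0)
    low, high = float(params["low"]), float(params["high"])
    data = gaussian_prefilter(
        image.channel(channel), params.get("noise_sigma_nm", 0.0), image.spacing
    )
    binary = range_threshold(data, low, high, spacing=image.spacing)
    if mask is not None:
        mask.check_shape(image.spatial_shape)
        binary = BinaryMask(binary.member & mask.member, image.spacing)
    labels = size_filter(
        connected_components(binary, params.get("connectivity", 26)),
        params.get("min_size_voxels", 0),
    )
    return ExtractionOutcome(
        labels,
        {
            "algorithm": "range_threshold",
            "realized_threshold_low": low,
            "realized_threshold_high": high,
            "component_count": labels.component_count,
        },
    )


def _multi_otsu_algorithm(image: Image, mask: BinaryMask | None, **params) -> ExtractionOutcome:
    channel = params.get("channel", 0)
    n_classes = int(params.get("n_classes", 3))
    data = gaussian_prefilter(
        image.channel(channel), params.get("noise_sigma_nm", 0.0), image.spacing
    )
    hist = build_histogram(data, n_bins=params.get("n_bins"), mask=mask)
    result = multi_otsu(hist, n_classes)
    classes = classify_multilevel(data, result, spacing=image.spacing)
    if mask is not None:
        masked = classes.labels.copy()
        masked[~mask.member] = 0
        present = np.unique(masked)
        present = present[present > 0]
        lut = np.zeros(classes.component_count + 1, dtype=np.int32)
        lut[present] = np.arange(1, len(present) + 1)
        classes = LabelMap(lut[masked], image.spacing)
    return ExtractionOutcome(
        classes,
        {
            "algorithm": "multi_otsu",
            "realized_thresholds": list(result.thresholds),
            "component_count": classes.component_count,
        },
    )


def _double_threshold(flood_method: str) -> Callable:
    def run(image: Image, mask: BinaryMask | None, **params) -> ExtractionOutcome:
        variant = params.pop("variant", "distance") if flood_method == "watershed" else None
        method = f"watershed_{variant}" if variant else flood_method
        return double_threshold_extract(image, mask=mask, flood_method=method, **params)

    return run


#: Algorithms addressable from profile JSON.
EXTRACTION_ALGORITHMS: dict[str, Callable] = {
    "threshold": _threshold_algorithm,
    "range_threshold": _range_algorithm,
    "multi_otsu": _multi_otsu_algorithm,
    "double_threshold_watershed": _double_threshold("watershed"),
    "mso": _double_threshold("mso"),
}


class ExtractionProfile(BaseModel):
    """One named extraction algorithm plus its full parameter map."""

    name: str
    algorithm: str
    parameters: dict = Field(default_factory=dict)
    format_version: str = "1"

    @field_validator("algorithm")
    @classmethod
    def _known(cls, v: str) -> str:
        if v not in EXTRACTION_ALGORITHMS:
            raise ValueError(f"unknown algorithm {v!r}; known: {sorted(EXTRACTION_ALGORITHMS)}")
        return v

    @field_validator("format_version")
    @classmethod
    def _version(cls, v: str) -> str:
        if v.split(".")[0] != "1":
            raise ValueError(f"version unsupported: {v}")
        return v


class MaskOp(BaseModel):
    """What to do with a step's output: nothing, or become the next mask."""

    mode: Literal["none", "use_as_mask"] = "none"
    selected: list[int] | None = None  # None = all components
    dilate_radius_nm: float = 0.0


class PipelineStep(BaseModel):
    profile: ExtractionProfile
    mask_op: MaskOp = Field(default_factory=MaskOp)
    requires_mask: bool = False


class Pipeline(BaseModel):
    """An ordered chain of extraction steps."""

    name: str = "pipeline"
    steps: list[PipelineStep]
    format_version: str = "1"

    @field_validator("steps")
    @classmethod
    def _nonempty(cls, v: list[PipelineStep]) -> list[PipelineStep]:
        if not v:
            raise ValueError("pipeline needs at least one step")
        produced = False
        for i, step in enumerate(v):
            if step.requires_mask and not produced:
                raise ValueError(
                    f"step {i}: requires a mask but no earlier step sets mask_op use_as_mask"
                )
            produced = step.mask_op.mode == "use_as_mask"
        return v

    @field_validator("format_version")
    @classmethod
    def _version(cls, v: str) -> str:
        if v.split(".")[0] != "1":
            raise ValueError(f"version unsupported: {v}")
        return v


@dataclass
class PipelineResult:
    labels: LabelMap
    step_provenance: list[dict] = dataclass_field(default_factory=list)
    final_mask: BinaryMask | None = None


def run_extraction(
    image: Image, profile: ExtractionProfile, mask: BinaryMask | None = None
) -> ExtractionOutcome:
    """Execute one profile on an image (optionally inside a mask)."""
    algorithm = EXTRACTION_ALGORITHMS[profile.algorithm]
    return algorithm(image, mask, **dict(profile.parameters))


def run_pipeline(image: Image, pipeline: Pipeline) -> PipelineResult:
    """Execute steps in order; ``use_as_mask`` feeds a step's components
    (optionally dilated) to the next step as its extraction region."""
    current_mask: BinaryMask | None = None
    provenance: list[dict] = []
    outcome: ExtractionOutcome | None = None
    for i, step in enumerate(pipeline.steps):
        if step.requires_mask and current_mask is None:
            raise ValueError(f"step {i}: mask required but not produced by an earlier step")
        try:
            outcome = run_extraction(image, step.profile, mask=current_mask)
        except ValueError as exc:
            raise ValueError(f"step {i} ({step.profile.name}): {exc}") from exc
        record = {"step": i, "profile": step.profile.model_dump(), **outcome.provenance}
        if step.mask_op.mode == "use_as_mask":
            current_mask = labels_to_mask(
                outcome.labels,
                selected=step.mask_op.selected,
                dilate_radius_nm=step.mask_op.dilate_radius_nm,
            )
            record["mask_voxels"] = current_mask.n_true
        provenance.append(record)
    assert outcome is not None
    return PipelineResult(outcome.labels, provenance, current_mask)


# ---------------------------------------------------------------------------
# JSON (de)serialization.
# ---------------------------------------------------------------------------


def _save(model: BaseModel, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(model.model_dump(), indent=2, sort_keys=True) + "\n")
    return path


def _load(model_cls: type[BaseModel], path: str | Path) -> BaseModel:
    try:
        document = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed document: {path}: {exc}") from exc
    if not isinstance(document, dict):
        raise ValueError(f"malformed document: {path}: expected a JSON object")
    try:
        return model_cls.model_validate(document)
    except ValidationError as exc:
        # surface the registry/version message directly
        for err in exc.errors():
            msg = err.get("msg", "")
            for key in ("unknown algorithm", "version unsupported", "unknown measurement"):
                if key in msg:
                    raise ValueError(msg.removeprefix("Value error, ")) from exc
        raise ValueError(f"malformed document: {exc}") from exc


def save_profile(profile: ExtractionProfile, path: str | Path) -> Path:
    return _save(profile, path)


def load_profile(path: str | Path) -> ExtractionProfile:
    return _load(ExtractionProfile, path)


def save_pipeline(pipeline: Pipeline, path: str | Path) -> Path:
    return _save(pipeline, path)


def load_pipeline(path: str | Path) -> Pipeline:
    return _load(Pipeline, path)
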