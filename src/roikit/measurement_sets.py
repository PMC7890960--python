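"""Declarative measurement sets and tabular results.

A measurement set is a serializable list of named measurements (the JSON
the batch engine consumes); evaluating one against an image + label map
(+ optional containing mask) yields a :class:`ResultTable` with one row
per component plus a ``total`` row for aggregates, every column in
physical units, and a provenance block sufficient to re-run the analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from . import measure
from .core import BinaryMask, Image, LabelMap

__all__ = [
    "MeasurementSpec",
    "MeasurementSet",
    "ResultTable",
    "evaluate_measurement_set",
    "MEASUREMENT_REGISTRY",
]

#: measurement id -> (per-component?, needs mask?, needs channel?, unit)
MEASUREMENT_REGISTRY: dict[str, tuple[bool, bool, bool, str]] = {
    "volume": (True, False, False, "um3"),
    "surface": (True, False, False, "um2"),
    "diameter": (True, False, False, "um"),
    "moment": (True, False, True, "intensity.nm2"),
    "principal_axis_1": (True, False, True, "um"),
    "principal_axis_2": (True, False, True, "um"),
    "principal_axis_3": (True, False, True, "um"),
    "border_rim_volume": (True, True, False, "um3"),
    "border_rim_brightness": (True, True, True, "intensity"),
    "distance_split": (False, True, True, "um3"),
    "mask_distance_mass": (True, True, True, "um"),
    "mask_distance_geometric": (True, True, False, "um"),
    "mask_distance_border": (True, True, False, "um"),
    "count": (False, False, False, "1"),
    "brightness_sum": (True, False, True, "intensity"),
    "brightness_mean": (True, False, True, "intensity"),
    "brightness_max": (True, False, True, "intensity"),
    "volume_ratio_to_mask": (False, True, False, "1"),
}


class MeasurementSpec(BaseModel):
    """One measurement request: id, evaluation area, channel, parameters."""

    id: str
    area: Literal["roi_component", "roi_total", "mask"] = "roi_component"
    channel: int | str = 0
    parameters: dict = Field(default_factory=dict)

    @field_validator("id")
    @classmethod
    def _known_id(cls, v: str) -> str:
        if v not in MEASUREMENT_REGISTRY:
            raise ValueError(f"unknown measurement {v!r}; known: {sorted(MEASUREMENT_REGISTRY)}")
        return v


class MeasurementSet(BaseModel):
    """A named, serializable list of measurements."""

    name: str = "measurements"
    measurements: list[MeasurementSpec] = Field(default_factory=list)
    format_version: str = "1"

    @field_validator("format_version")
    @classmethod
    def _version(cls, v: str) -> str:
        if v.split(".")[0] != "1":
            raise ValueError(f"version unsupported: {v}")
        return v


@dataclass
class ResultTable:
    """Measurement rows plus the provenance needed to reproduce them."""

    table: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.table.to_csv(path, index=False)
        sidecar = path.with_suffix(path.suffix + ".provenance.json")
        sidecar.write_text(json.dumps(self.provenance, indent=2, sort_keys=True, default=str))
        return path


def _column_name(spec: MeasurementSpec, suffix: str = "") -> str:
    unit = MEASUREMENT_REGISTRY[spec.id][3]
    return f"{spec.id}{suffix} [{unit}]"


def _component_value(
    spec: MeasurementSpec,
    image: Image,
    comp: np.ndarray,
    mask: BinaryMask | None,
) -> float:
    spacing = image.spacing
    mid = spec.id
    member = BinaryMask(comp, spacing)
    channel = image.channel(spec.channel) if MEASUREMENT_REGISTRY[mid][2] else None
    if mid == "volume":
        return measure.volume(member, spacing)
    if mid == "surface":
        return measure.surface(member, spacing)
    if mid == "diameter":
        return measure.diameter(member, spacing)
    if mid == "moment":
        geom = measure.ComponentGeometry.from_mask(member, spacing, channel)
        return measure.moment(geom)
    if mid.startswith("principal_axis_"):
        geom = measure.ComponentGeometry.from_mask(member, spacing, channel)
        lengths, _ = measure.principal_axes(geom)
        return float(lengths[int(mid[-1]) - 1])
    if mid == "border_rim_volume":
        rim = measure.border_rim(member, mask, float(spec.parameters["rim_width_nm"]))
        return rim["volume_um3"]
    if mid == "border_rim_brightness":
        rim = measure.border_rim(member, mask, float(spec.parameters["rim_width_nm"]), channel)
        return rim["brightness_sum"]
    if mid == "mask_distance_mass":
        geom = measure.ComponentGeometry.from_mask(member, spacing, channel)
        return measure.mask_roi_distance(geom, mask, "mass_center")
    if mid == "mask_distance_geometric":
        geom = measure.ComponentGeometry.from_mask(member, spacing)
        return measure.mask_roi_distance(geom, mask, "geometric_center")
    if mid == "mask_distance_border":
        geom = measure.ComponentGeometry.from_mask(member, spacing)
        return measure.mask_roi_distance(geom, mask, "border")
    if mid == "brightness_sum":
        return measure.brightness_stats(member, channel)["sum"]
    if mid == "brightness_mean":
        return measure.brightness_stats(member, channel)["mean"]
    if mid == "brightness_max":
        return measure.brightness_stats(member, channel)["max"]
    raise ValueError(f"unknown measurement {mid!r}")


def evaluate_measurement_set(
    image: Image,
    roi: LabelMap,
    measurement_set: MeasurementSet | list[MeasurementSpec],
    mask: BinaryMask | None = None,
    source: str = "image",
) -> ResultTable:
    """Evaluate every spec for every component (plus a ``total`` row).

    Per-component specs fill one column over component rows; aggregate
    specs (count, totals, mask-relative ratios, distance-split bands) fill
    the ``total`` row.  Specs that need a containing mask raise
    ``mask required`` when none is given.
    """
    specs = (
        measurement_set.measurements
        if isinstance(measurement_set, MeasurementSet)
        else list(measurement_set)
    )
    for spec in specs:
        if MEASUREMENT_REGISTRY[spec.id][1] and mask is None:
            raise ValueError(f"mask required: measurement {spec.id!r} is mask-relative")
    k = roi.component_count
    rows: list[dict] = []
    for comp_id in list(range(1, k + 1)) + ["total"]:
        rows.append({"source": source, "component": comp_id})
    df = pd.DataFrame(rows)
    spacing = image.spacing
    fg = roi.labels > 0
    for spec in specs:
        per_component = MEASUREMENT_REGISTRY[spec.id][0]
        if per_component and spec.area == "roi_component":
            col = _column_name(spec)
            values = [
                _component_value(spec, image, roi.labels == comp_id, mask)
                for comp_id in range(1, k + 1)
            ]
            df[col] = values + [np.nan]
        elif spec.id == "count":
            df[_column_name(spec)] = [np.nan] * k + [float(k)]
        elif spec.id == "volume_ratio_to_mask":
            ratio = (
                measure.volume(fg, spacing) / measure.volume(mask, spacing) if fg.any() else 0.0
            )
            df[_column_name(spec)] = [np.nan] * k + [ratio]
        elif spec.id == "distance_split":
            n_bands = int(spec.parameters.get("n_bands", 3))
            mode = spec.parameters.get("mode", "equal_radius")
            bands = measure.mask_distance_split(mask, n_bands, mode)
            channel = image.channel(spec.channel)
            for b in range(1, bands.component_count + 1):
                in_band = fg & (bands.labels == b)
                df[_column_name(spec, f"_band{b}_volume")] = [np.nan] * k + [
                    float(in_band.sum()) * spacing.voxel_volume * measure.NM3_TO_UM3
                ]
                df[_column_name(spec, f"_band{b}_brightness")] = [np.nan] * k + [
                    float(channel[in_band].sum())
                ]
        else:
            # per-component measurement requested over the whole ROI or mask
            target = fg if spec.area == "roi_total" else mask.member
            col = _column_name(spec, f"_{spec.area}")
            value = _component_value(spec, image, target, mask) if target.any() else np.nan
            df[col] = [np.nan] * k + [value]
    provenance = {
        "measurement_set": (
            measurement_set.model_dump()
            if isinstance(measurement_set, MeasurementSet)
            else [s.model_dump() for s in specs]
        ),
        "component_count": k,
        "spacing_nm": {"z": spacing.z, "y": spacing.y, "x": spacing.x},
    }
    return ResultTable(df, provenance)
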