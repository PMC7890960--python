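"""TIFF reading and writing for multichannel z-stacks and label maps.

Accepted layouts: (z, y, x) single channel, (c, z, y, x) and (z, c, y, x).
Voxel spacing is read from ImageJ-style metadata / resolution tags when
present, otherwise it must be supplied by the caller; only pixel-size
fields are consumed, full OME-XML compliance is not attempted.  Spacing in
TIFF metadata is conventionally in micrometres; the in-memory model uses
nanometres.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile

from .core import Image, LabelMap, Spacing

__all__ = ["read_image", "write_image", "read_labels", "write_labels"]

_UNIT_TO_NM = {"nm": 1.0, "um": 1000.0, "micron": 1000.0, "µm": 1000.0, "μm": 1000.0}


def _spacing_from_tiff(tif: tifffile.TiffFile) -> Spacing | None:
    try:
        ij = tif.imagej_metadata or {}
        unit = _UNIT_TO_NM.get(str(ij.get("unit", "um")))
        z_step = ij.get("spacing")
        page = tif.pages[0]
        xres = page.tags.get("XResolution")
        yres = page.tags.get("YResolution")
        if unit is None or z_step is None or xres is None or yres is None:
            return None
        xr = xres.value[0] / xres.value[1]
        yr = yres.value[0] / yres.value[1]
        if xr <= 0 or yr <= 0:
            return None
        return Spacing(float(z_step) * unit, unit / yr, unit / xr)
    except (KeyError, ZeroDivisionError, TypeError):
        return None


def _arrange_axes(arr: np.ndarray, layout: str) -> tuple[np.ndarray, str]:
    if arr.ndim == 2:
        arr = arr[np.newaxis]
    if arr.ndim == 3:
        return arr[np.newaxis], "zyx"
    if arr.ndim != 4:
        raise ValueError(f"shape mismatch: cannot interpret TIFF with shape {arr.shape}")
    if layout == "auto":
        # channel counts are small; prefer the interpretation with fewer channels
        layout = "czyx" if arr.shape[0] <= arr.shape[1] else "zcyx"
    if layout == "czyx":
        return arr, layout
    if layout == "zcyx":
        return np.moveaxis(arr, 1, 0), layout
    raise ValueError(f"unknown layout {layout!r}; use 'auto', 'czyx' or 'zcyx'")


def read_image(
    path: str | Path,
    spacing: Spacing | tuple[float, float, float] | None = None,
    layout: str = "auto",
    channel_names: tuple[str, ...] = (),
) -> Image:
    """Read a multichannel z-stack; spacing from metadata unless given."""
    with tifffile.TiffFile(str(path)) as tif:
        arr = tif.asarray()
        axes = tif.series[0].axes if tif.series else ""
        meta_spacing = _spacing_from_tiff(tif)
    if layout == "auto" and arr.ndim == 4 and axes:
        ax = axes.upper().replace("S", "C").replace("Q", "C")
        if ax == "ZCYX":
            layout = "zcyx"
        elif ax == "CZYX":
            layout = "czyx"
    arr, _ = _arrange_axes(arr, layout)
    if spacing is None:
        spacing = meta_spacing
    if spacing is None:
        raise ValueError(f"spacing required: no pixel-size metadata in {path}")
    if not isinstance(spacing, Spacing):
        spacing = Spacing(*spacing)
    return Image(arr, spacing, channel_names)


def _imagej_kwargs(spacing: Spacing) -> dict:
    return {
        "imagej": True,
        "resolution": (1000.0 / spacing.x, 1000.0 / spacing.y),
        "metadata": {"spacing": spacing.z / 1000.0, "unit": "um", "axes": "ZCYX"},
    }


def write_image(path: str | Path, image: Image) -> Path:
    """Write the stack with spacing metadata (ImageJ convention requires
    ZCYX plane order and micrometre units)."""
    path = Path(path)
    data = np.moveaxis(image.intensities, 0, 1)  # (c,z,y,x) -> (z,c,y,x)
    if np.issubdtype(data.dtype, np.floating):
        data = data.astype(np.float32)
    kwargs = _imagej_kwargs(image.spacing)
    tifffile.imwrite(str(path), data, **kwargs)
    return path


def write_labels(path: str | Path, label_map: LabelMap) -> Path:
    """Write a label map as single-channel unsigned-integer TIFF."""
    path = Path(path)
    dtype = np.uint16 if label_map.component_count < 2**16 else np.uint32
    kwargs = _imagej_kwargs(label_map.spacing)
    kwargs["metadata"]["axes"] = "ZYX"
    tifffile.imwrite(str(path), label_map.labels.astype(dtype), **kwargs)
    return path


def read_labels(
    path: str | Path, spacing: Spacing | tuple[float, float, float] | None = None
) -> LabelMap:
    """Read a single-channel integer TIFF as a label map."""
    image = read_image(path, spacing=spacing)
    if image.n_channels != 1:
        raise ValueError(f"shape mismatch: label TIFF has {image.n_channels} channels")
    arr = image.intensities[0]
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("label TIFF contains non-integer values")
        arr = np.round(arr).astype(np.int32)
    return LabelMap(arr.astype(np.int32), image.spacing)
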