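"""Voxel-grid data model with physical spacing.

All spatial grids are indexed ``(z, y, x)``; multichannel images are
``(channel, z, y, x)``.  Coordinates are 0-based and a voxel's physical
position is its *center*, at ``index * step`` nanometres (the center of
voxel 0 is the origin).  All spacing and geometry inside the library is in
nanometres; unit conversion happens only at the I/O and reporting
boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "Spacing",
    "Image",
    "BinaryMask",
    "LabelMap",
    "DEFAULT_SPACING",
    "validate_image",
    "apply_mask",
    "crop_to_mask",
    "labels_to_mask",
    "physical_ball",
]


@dataclass(frozen=True)
class Spacing:
    """Physical voxel size in nanometres along (z, y, x).

    Confocal stacks are typically anisotropic, with the z step two to
    three times the xy step.
    """

    z: float
    y: float
    x: float

    def __post_init__(self) -> None:
        steps = (self.z, self.y, self.x)
        if not all(np.isfinite(s) and s > 0 for s in steps):
            raise ValueError(f"invalid spacing: steps must be positive finite, got {steps}")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in nm^3."""
        return self.z * self.y * self.x

    def as_array(self) -> np.ndarray:
        return np.array([self.z, self.y, self.x], dtype=float)


#: Reference confocal spacing: 70 nm in xy, 210 nm in z.
DEFAULT_SPACING = Spacing(210.0, 70.0, 70.0)


@dataclass
class Image:
    """A multichannel 3D intensity image with physical spacing.

    ``intensities`` has axis order (channel, z, y, x).  A 3D array is
    promoted to a single channel.
    """

    intensities: np.ndarray
    spacing: Spacing
    channel_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities)
        if arr.ndim == 3:
            arr = arr[np.newaxis]
        if arr.ndim != 4:
            raise ValueError(f"shape mismatch: expected (c, z, y, x) or (z, y, x), got {arr.shape}")
        self.intensities = arr
        if not self.channel_names:
            self.channel_names = tuple(f"channel_{i}" for i in range(arr.shape[0]))
        else:
            self.channel_names = tuple(self.channel_names)

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.intensities.shape[1:]

    def channel_index(self, channel: int | str) -> int:
        if isinstance(channel, str):
            try:
                return self.channel_names.index(channel)
            except ValueError:
                raise KeyError(f"unknown channel {channel!r}; have {self.channel_names}") from None
        if not 0 <= channel < self.n_channels:
            raise KeyError(f"unknown channel index {channel}; have {self.n_channels} channels")
        return channel

    def channel(self, channel: int | str) -> np.ndarray:
        """Return one (z, y, x) channel as an array view."""
        return self.intensities[self.channel_index(channel)]


@dataclass
class BinaryMask:
    """A (z, y, x) boolean region, e.g. the segmented nucleus."""

    member: np.ndarray
    spacing: Spacing

    def __post_init__(self) -> None:
        arr = np.asarray(self.member)
        if arr.ndim != 3:
            raise ValueError(f"shape mismatch: mask must be (z, y, x), got {arr.shape}")
        self.member = arr.astype(bool, copy=False)

    @property
    def n_true(self) -> int:
        return int(self.member.sum())

    def check_shape(self, spatial_shape: tuple[int, int, int]) -> None:
        if self.member.shape != tuple(spatial_shape):
            raise ValueError(
                f"shape mismatch: mask {self.member.shape} vs image {tuple(spatial_shape)}"
            )


@dataclass
class LabelMap:
    """Consecutive integer labeling of connected structures; 0 = background."""

    labels: np.ndarray
    spacing: Spacing
    component_count: int = field(default=-1)

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 3:
            raise ValueError(f"shape mismatch: labels must be (z, y, x), got {arr.shape}")
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValueError(f"labels must be integer, got dtype {arr.dtype}")
        if arr.size and arr.min() < 0:
            raise ValueError("labels must be non-negative")
        self.labels = arr
        k = int(arr.max()) if arr.size else 0
        if self.component_count < 0:
            self.component_count = k
        present = np.unique(arr)
        present = present[present > 0]
        if len(present) != self.component_count or (
            len(present) and present[-1] != self.component_count
        ):
            raise ValueError(
                f"labels not consecutive 1..{self.component_count}: present {present.tolist()}"
            )

    def component_mask(self, label: int) -> BinaryMask:
        if not 1 <= label <= self.component_count:
            raise ValueError(f"unknown label {label}; have 1..{self.component_count}")
        return BinaryMask(self.labels == label, self.spacing)

    def foreground_mask(self) -> BinaryMask:
        return BinaryMask(self.labels > 0, self.spacing)

    def sizes(self) -> np.ndarray:
        """Voxel counts of components 1..k."""
        return np.bincount(self.labels.ravel(), minlength=self.component_count + 1)[1:]


def validate_image(image: Image) -> Image:
    """Check Image invariants; return the image unchanged if they hold."""
    # Spacing validity is enforced by Spacing itself, but the image may have
    # been constructed with a raw tuple.
    if not isinstance(image.spacing, Spacing):
        image = replace(image, spacing=Spacing(*image.spacing))
    arr = image.intensities
    if len(image.channel_names) != arr.shape[0]:
        raise ValueError(
            f"shape mismatch: {len(image.channel_names)} channel names for {arr.shape[0]} channels"
        )
    if len(set(image.channel_names)) != len(image.channel_names):
        raise ValueError(f"shape mismatch: duplicate channel names {image.channel_names}")
    if any(s < 1 for s in arr.shape[1:]):
        raise ValueError(f"shape mismatch: empty spatial dimension in {arr.shape}")
    if np.issubdtype(arr.dtype, np.floating) and not np.isfinite(arr).all():
        raise ValueError("non-finite intensities: image contains NaN or Inf")
    if np.issubdtype(arr.dtype, np.floating) and arr.size and arr.min() < 0:
        raise ValueError("non-finite intensities: negative intensities not allowed")
    return image


def apply_mask(image: Image, mask: BinaryMask, fill: float = 0) -> Image:
    """Cut the image out along a mask: voxels outside become ``fill``.

    This is the incremental-workflow primitive: a structure segmented at one
    level (e.g. the nucleus) is turned into a mask and the raw image is cut
    out along it before the next extraction level runs.
    """
    mask.check_shape(image.spatial_shape)
    out = image.intensities.copy()
    out[:, ~mask.member] = fill
    return Image(out, image.spacing, image.channel_names)


def crop_to_mask(
    image: Image, mask: BinaryMask, margin_voxels: int = 0
) -> tuple[Image, BinaryMask, tuple[int, int, int]]:
    """Crop image and mask to the mask bounding box (+margin, clamped).

    Returns the cropped image, the cropped mask and the (z, y, x) offset of
    the crop origin in the source grid.
    """
    mask.check_shape(image.spatial_shape)
    if not mask.member.any():
        raise ValueError("empty mask: nothing to crop to")
    coords = np.nonzero(mask.member)
    lo = [max(int(c.min()) - margin_voxels, 0) for c in coords]
    hi = [
        min(int(c.max()) + margin_voxels + 1, n)
        for c, n in zip(coords, image.spatial_shape)
    ]
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    sub = Image(image.intensities[(slice(None),) + sl].copy(), image.spacing, image.channel_names)
    sub_mask = BinaryMask(mask.member[sl].copy(), mask.spacing)
    return sub, sub_mask, (lo[0], lo[1], lo[2])


def physical_ball(radius_nm: float, spacing: Spacing) -> np.ndarray:
    """Anisotropic ball footprint: offsets with center distance <= radius.

    The footprint always contains the center voxel, so radius 0 is a no-op
    structuring element.
    """
    if radius_nm < 0:
        raise ValueError(f"invalid radius: {radius_nm}")
    steps = spacing.as_array()
    half = np.floor(radius_nm / steps).astype(int)
    zz, yy, xx = np.meshgrid(
        np.arange(-half[0], half[0] + 1) * steps[0],
        np.arange(-half[1], half[1] + 1) * steps[1],
        np.arange(-half[2], half[2] + 1) * steps[2],
        indexing="ij",
    )
    return zz**2 + yy**2 + xx**2 <= radius_nm**2


def labels_to_mask(
    label_map: LabelMap,
    selected: set[int] | list[int] | None = None,
    dilate_radius_nm: float = 0.0,
) -> BinaryMask:
    """Convert selected components to a mask, optionally dilated.

    ``selected=None`` selects every component; an empty selection yields an
    all-false mask.  Dilation uses a spacing-aware ball of the given
    physical radius (center-to-center distance), so a radius of one xy step
    grows by one voxel laterally but not axially for anisotropic stacks.
    """
    if dilate_radius_nm < 0:
        raise ValueError(f"invalid radius: {dilate_radius_nm}")
    if selected is None:
        member = label_map.labels > 0
    else:
        sel = sorted(set(int(s) for s in selected))
        bad = [s for s in sel if s <= 0 or s > label_map.component_count]
        if bad:
            raise ValueError(
                f"unknown label: {bad} outside 1..{label_map.component_count}"
            )
        member = np.isin(label_map.labels, sel) if sel else np.zeros_like(label_map.labels, bool)
    if dilate_radius_nm > 0 and member.any():
        member = ndi.binary_dilation(
            member, structure=physical_ball(dilate_radius_nm, label_map.spacing)
        )
    return BinaryMask(member, label_map.spacing)
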