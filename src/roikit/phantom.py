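"""Synthetic 3D phantoms with exact ground truth.

Every generator is a pure function of its parameters and seed, so a
phantom can be regenerated bit-identically anywhere.  Shapes are digital:
a voxel belongs to a shape iff its *center* satisfies the membership
predicate (no partial-volume anti-aliasing), and the only noise model is
additive Gaussian — tests need controlled signal-to-noise, not realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import BinaryMask, Image, LabelMap, Spacing

__all__ = [
    "PhantomTruth",
    "ScenePhantom",
    "ball_phantom",
    "ellipsoid_phantom",
    "bridged_blobs_phantom",
    "gradient_blobs_phantom",
    "nucleus_scene_phantom",
]

#: Isotropic default spacing for phantoms; fine enough that digitization
#: error stays well inside the analytic tolerances used in tests.
PHANTOM_SPACING = Spacing(70.0, 70.0, 70.0)


@dataclass
class PhantomTruth:
    """A generated image with its exact ground truth."""

    image: Image
    truth_labels: LabelMap
    truth_mask: BinaryMask
    parameters: dict = field(default_factory=dict)


@dataclass
class ScenePhantom:
    """A multi-nucleus scene: DNA-like channel + nuclear-body channel."""

    image: Image
    nuclei: LabelMap
    chromocenters: LabelMap
    bodies: LabelMap
    per_nucleus: list[dict]
    parameters: dict = field(default_factory=dict)


def _grid_positions(shape: tuple[int, int, int], spacing: Spacing) -> tuple[np.ndarray, ...]:
    steps = spacing.as_array()
    axes = [np.arange(n) * s for n, s in zip(shape, steps)]
    return np.meshgrid(*axes, indexing="ij")


def _add_noise(data: np.ndarray, noise_sd: float, seed: int) -> np.ndarray:
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    if noise_sd == 0:
        return data
    rng = np.random.default_rng(seed)
    noisy = data + rng.normal(0.0, noise_sd, size=data.shape)
    return np.clip(noisy, 0.0, None)


def ball_phantom(
    radius_nm: float,
    spacing: Spacing = PHANTOM_SPACING,
    intensity_in: float = 100.0,
    intensity_out: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    margin_voxels: int = 3,
) -> PhantomTruth:
    """A digital ball: centers within ``radius_nm`` of the grid center."""
    steps = spacing.as_array()
    if radius_nm <= steps.max():
        raise ValueError(f"radius too small: {radius_nm} nm vs max step {steps.max()} nm")
    half = np.ceil(radius_nm / steps).astype(int) + margin_voxels
    shape = tuple(2 * half + 1)
    center = half * steps
    zz, yy, xx = _grid_positions(shape, spacing)
    inside = (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2 <= radius_nm**2
    data = np.where(inside, float(intensity_in), float(intensity_out))
    data = _add_noise(data, noise_sd, seed)
    params = {
        "kind": "ball",
        "radius_nm": radius_nm,
        "intensity_in": intensity_in,
        "intensity_out": intensity_out,
        "noise_sd": noise_sd,
        "seed": seed,
        "center_nm": center.tolist(),
    }
    return PhantomTruth(
        Image(data, spacing, ("signal",)),
        LabelMap(inside.astype(np.int32), spacing),
        BinaryMask(inside, spacing),
        params,
    )


def ellipsoid_phantom(
    semi_axes_nm: tuple[float, float, float],
    rotation: np.ndarray | None = None,
    spacing: Spacing = PHANTOM_SPACING,
    intensity_in: float = 100.0,
    intensity_out: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    margin_voxels: int = 3,
) -> PhantomTruth:
    """A digital ellipsoid with optional rigid rotation.

    Semi-axes are given along (z, y, x) before rotation; membership is the
    quadratic form ||diag(1/a) R^T (p - c)|| <= 1.
    """
    semi = np.asarray(semi_axes_nm, dtype=float)
    steps = spacing.as_array()
    if (semi <= steps.max()).any():
        raise ValueError(f"radius too small: semi-axes {semi} nm vs max step {steps.max()} nm")
    R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
    if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
        raise ValueError("rotation must be a 3x3 orthonormal matrix")
    extent = np.abs(R) @ semi  # bounding half-extents of the rotated ellipsoid
    half = np.ceil(extent / steps).astype(int) + margin_voxels
    shape = tuple(2 * half + 1)
    center = half * steps
    zz, yy, xx = _grid_positions(shape, spacing)
    rel = np.stack([zz - center[0], yy - center[1], xx - center[2]], axis=-1)
    local = rel @ R  # p' = R^T (p - c), row-vector convention
    inside = ((local / semi) ** 2).sum(axis=-1) <= 1.0
    data = _add_noise(np.where(inside, float(intensity_in), float(intensity_out)), noise_sd, seed)
    params = {
        "kind": "ellipsoid",
        "semi_axes_nm": semi.tolist(),
        "rotation": R.tolist(),
        "intensity_in": intensity_in,
        "intensity_out": intensity_out,
        "noise_sd": noise_sd,
        "seed": seed,
        "center_nm": center.tolist(),
    }
    return PhantomTruth(
        Image(data, spacing, ("signal",)),
        LabelMap(inside.astype(np.int32), spacing),
        BinaryMask(inside, spacing),
        params,
    )


def bridged_blobs_phantom(
    radius_voxels: float = 10.0,
    gap_voxels: float = 8.0,
    bridge_radius_voxels: float = 3.0,
    bridge_intensity_fraction: float = 0.3,
    blob_intensity: float = 100.0,
    spacing: Spacing = PHANTOM_SPACING,
    noise_sd: float = 0.0,
    seed: int = 0,
    margin_voxels: int = 3,
) -> PhantomTruth:
    """Two bright balls joined by a dim cylindrical bridge along x.

    The classic conjoined-territories situation: each ball is a separate
    ground-truth object; bridge voxels belong to the nearer ball, with the
    exact equidistant mid-slab excluded from the truth.
    """
    if not 0.0 <= bridge_intensity_fraction < 1.0:
        raise ValueError(
            f"bridge fraction must be in [0, 1), got {bridge_intensity_fraction}"
        )
    steps = spacing.as_array()
    radius_nm = radius_voxels * steps[2]
    gap_nm = gap_voxels * steps[2]
    if gap_nm <= 0:
        raise ValueError("blobs overlap: gap must be positive")
    bridge_radius_nm = bridge_radius_voxels * min(steps[0], steps[1])
    half_sep = radius_nm + gap_nm / 2.0  # center-to-midpoint distance
    half_zy = np.ceil(radius_nm / steps[:2]).astype(int) + margin_voxels
    half_x = int(np.ceil((half_sep + radius_nm) / steps[2])) + margin_voxels
    shape = (2 * half_zy[0] + 1, 2 * half_zy[1] + 1, 2 * half_x + 1)
    mid = np.array([half_zy[0], half_zy[1], half_x]) * steps
    c1 = mid - np.array([0.0, 0.0, half_sep])
    c2 = mid + np.array([0.0, 0.0, half_sep])
    zz, yy, xx = _grid_positions(shape, spacing)

    def ball(c: np.ndarray) -> np.ndarray:
        return (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2 <= radius_nm**2

    b1, b2 = ball(c1), ball(c2)
    if (b1 & b2).any():
        raise ValueError("blobs overlap")
    axial = (xx >= c1[2]) & (xx <= c2[2])
    radial = (zz - mid[0]) ** 2 + (yy - mid[1]) ** 2 <= bridge_radius_nm**2
    bridge = axial & radial & ~b1 & ~b2
    data = np.zeros(shape)
    data[bridge] = bridge_intensity_fraction * blob_intensity
    data[b1 | b2] = blob_intensity
    data = _add_noise(data, noise_sd, seed)
    truth = np.zeros(shape, dtype=np.int32)
    truth[b1] = 1
    truth[b2] = 2
    d1 = np.abs(xx - c1[2])
    d2 = np.abs(xx - c2[2])
    truth[bridge & (d1 < d2)] = 1
    truth[bridge & (d2 < d1)] = 2  # equidistant mid-slab stays 0
    params = {
        "kind": "bridged_blobs",
        "radius_nm": radius_nm,
        "gap_nm": gap_nm,
        "bridge_radius_nm": bridge_radius_nm,
        "bridge_intensity_fraction": bridge_intensity_fraction,
        "blob_intensity": blob_intensity,
        "noise_sd": noise_sd,
        "seed": seed,
        "centers_nm": [c1.tolist(), c2.tolist()],
    }
    return PhantomTruth(
        Image(data, spacing, ("signal",)),
        LabelMap(truth, spacing),
        BinaryMask(truth > 0, spacing),
        params,
    )


def gradient_blobs_phantom(
    radius_voxels: float = 6.0,
    capsule_length_voxels: float = 36.0,
    gap_voxels: float = 8.0,
    bridge_radius_voxels: float = 2.0,
    bridge_intensity_fraction: float = 0.3,
    peak_intensity: float = 200.0,
    dip_intensity: float = 140.0,
    spacing: Spacing = PHANTOM_SPACING,
    noise_sd: float = 0.0,
    seed: int = 0,
    margin_voxels: int = 3,
) -> PhantomTruth:
    """An elongated object with three internal brightness maxima, bridged
    to a second ball — the phantom on which intensity watershed fails.

    Object 1 is a capsule along x whose brightness oscillates between
    ``dip_intensity`` and ``peak_intensity`` with three maxima; object 2 is
    a uniform ball at ``peak_intensity``; a dim bridge joins them.  Both
    objects stay above any core threshold between the bridge and the dip,
    so two-stage core detection finds exactly two cores, while watershed
    seeded at the local maxima splits the capsule.  Maxima voxel positions
    are exposed in ``parameters['maxima_voxels']``.
    """
    steps = spacing.as_array()
    r_nm = radius_voxels * min(steps)
    cap_len = capsule_length_voxels * steps[2]
    gap_nm = gap_voxels * steps[2]
    bridge_r = bridge_radius_voxels * min(steps[0], steps[1])
    half_zy = np.ceil(r_nm / steps[:2]).astype(int) + margin_voxels
    total_x = cap_len + 2 * r_nm + gap_nm + 2 * r_nm
    half_x = int(np.ceil(total_x / 2 / steps[2])) + margin_voxels
    shape = (2 * half_zy[0] + 1, 2 * half_zy[1] + 1, 2 * half_x + 1)
    mid = np.array([half_zy[0], half_zy[1], half_x]) * steps
    zz, yy, xx = _grid_positions(shape, spacing)
    # capsule: segment from xa to xb at radius r_nm
    xa = mid[2] - total_x / 2 + r_nm
    xb = xa + cap_len
    seg_x = np.clip(xx, xa, xb)
    capsule = (zz - mid[0]) ** 2 + (yy - mid[1]) ** 2 + (xx - seg_x) ** 2 <= r_nm**2
    ball_c = np.array([mid[0], mid[1], xb + r_nm + gap_nm + r_nm])
    ball = (zz - ball_c[0]) ** 2 + (yy - ball_c[1]) ** 2 + (xx - ball_c[2]) ** 2 <= r_nm**2
    if (capsule & ball).any():
        raise ValueError("blobs overlap")
    bridge = (
        (xx >= xb + r_nm)
        & (xx <= ball_c[2])
        & ((zz - mid[0]) ** 2 + (yy - mid[1]) ** 2 <= bridge_r**2)
        & ~capsule
        & ~ball
    )
    # three maxima along the capsule axis at 1/6, 3/6, 5/6 of its length
    phase = np.clip((xx - xa) / cap_len, 0.0, 1.0)
    profile = dip_intensity + (peak_intensity - dip_intensity) * 0.5 * (
        1.0 - np.cos(3.0 * 2.0 * np.pi * phase)
    )
    data = np.zeros(shape)
    data[capsule] = profile[capsule]
    data[ball] = peak_intensity
    data[bridge] = bridge_intensity_fraction * peak_intensity
    data = _add_noise(data, noise_sd, seed)
    truth = np.zeros(shape, dtype=np.int32)
    truth[capsule] = 1
    truth[ball] = 2
    d1 = np.abs(xx - (xb + r_nm))  # distance to capsule tip along x
    d2 = np.abs(xx - (ball_c[2] - r_nm))
    truth[bridge & (d1 < d2)] = 1
    truth[bridge & (d2 < d1)] = 2
    maxima_x_nm = [xa + f * cap_len for f in (1 / 6, 3 / 6, 5 / 6)]
    maxima_voxels = [
        (int(round(mid[0] / steps[0])), int(round(mid[1] / steps[1])), int(round(x / steps[2])))
        for x in maxima_x_nm
    ]
    ball_voxel = tuple(int(round(c / s)) for c, s in zip(ball_c, steps))
    params = {
        "kind": "gradient_blobs",
        "radius_nm": r_nm,
        "peak_intensity": peak_intensity,
        "dip_intensity": dip_intensity,
        "bridge_intensity_fraction": bridge_intensity_fraction,
        "noise_sd": noise_sd,
        "seed": seed,
        "maxima_voxels": maxima_voxels,
        "ball_maximum_voxel": ball_voxel,
    }
    return PhantomTruth(
        Image(data, spacing, ("signal",)),
        LabelMap(truth, spacing),
        BinaryMask(truth > 0, spacing),
        params,
    )


def nucleus_scene_phantom(
    n_nuclei: int = 2,
    n_chromocenters: int = 5,
    n_bodies: int = 3,
    nucleus_radius_nm: float = 2000.0,
    chromocenter_radius_nm: float = 300.0,
    body_radius_nm: float = 250.0,
    nucleus_intensity: float = 80.0,
    chromocenter_intensity: float = 200.0,
    body_intensity: float = 150.0,
    spacing: Spacing = Spacing(210.0, 70.0, 70.0),
    noise_sd: float = 0.0,
    seed: int = 0,
    max_retries: int = 200,
) -> ScenePhantom:
    """A scene of non-overlapping nuclei with bright interior structures.

    The DNA-like channel holds the nucleus bodies plus brighter
    chromocenter spots; a second channel holds small bright nuclear
    bodies.  Ground truth records every structure and per-nucleus counts.
    """
    if n_nuclei < 0 or n_chromocenters < 0 or n_bodies < 0:
        raise ValueError("counts must be >= 0")
    rng = np.random.default_rng(seed)
    steps = spacing.as_array()
    # lay nuclei along x with jitter in a box wide enough for all of them
    pitch = 2.4 * nucleus_radius_nm
    box = np.array(
        [
            2.6 * nucleus_radius_nm,
            2.6 * nucleus_radius_nm,
            max(pitch * max(n_nuclei, 1), 2.6 * nucleus_radius_nm),
        ]
    )
    shape = tuple(int(np.ceil(b / s)) + 1 for b, s in zip(box, steps))
    zz, yy, xx = _grid_positions(shape, spacing)
    dna = np.zeros(shape)
    bodies_ch = np.zeros(shape)
    nuclei_lab = np.zeros(shape, dtype=np.int32)
    cc_lab = np.zeros(shape, dtype=np.int32)
    body_lab = np.zeros(shape, dtype=np.int32)
    per_nucleus: list[dict] = []
    centers: list[np.ndarray] = []
    cc_next = 1
    body_next = 1
    for i in range(n_nuclei):
        placed = None
        for _ in range(max_retries):
            c = np.array(
                [
                    box[0] / 2 + rng.uniform(-0.1, 0.1) * nucleus_radius_nm,
                    box[1] / 2 + rng.uniform(-0.1, 0.1) * nucleus_radius_nm,
                    pitch * (i + 0.5) + rng.uniform(-0.1, 0.1) * nucleus_radius_nm,
                ]
            )
            if all(np.linalg.norm(c - p) > 2.05 * nucleus_radius_nm for p in centers):
                placed = c
                break
        if placed is None:
            raise ValueError("cannot place nuclei without overlap")
        centers.append(placed)
        nuc = (zz - placed[0]) ** 2 + (yy - placed[1]) ** 2 + (
            xx - placed[2]
        ) ** 2 <= nucleus_radius_nm**2
        nuclei_lab[nuc] = i + 1
        dna[nuc] = nucleus_intensity
        info = {"nucleus_label": i + 1, "chromocenter_count": 0, "body_count": 0}

        def place_spots(n: int, radius: float) -> list[np.ndarray]:
            """Non-overlapping spot centers fully inside the nucleus."""
            reach = nucleus_radius_nm - radius - max(steps)
            spots: list[np.ndarray] = []
            for _ in range(n):
                for _ in range(max_retries):
                    offset = rng.uniform(-1.0, 1.0, size=3) * reach
                    if np.linalg.norm(offset) > reach:
                        continue
                    c_spot = placed + offset
                    # 3-step clearance so digitized balls never touch
                    if all(
                        np.linalg.norm(c_spot - s) > 2.0 * radius + 3.0 * max(steps)
                        for s in spots
                    ):
                        spots.append(c_spot)
                        break
                else:
                    raise ValueError("cannot place nuclei without overlap: substructure retry limit")
            return spots

        for c_spot in place_spots(n_chromocenters, chromocenter_radius_nm):
            spot = (zz - c_spot[0]) ** 2 + (yy - c_spot[1]) ** 2 + (
                xx - c_spot[2]
            ) ** 2 <= chromocenter_radius_nm**2
            dna[spot] = chromocenter_intensity
            cc_lab[spot] = cc_next
            cc_next += 1
            info["chromocenter_count"] += 1
        for c_spot in place_spots(n_bodies, body_radius_nm):
            spot = (zz - c_spot[0]) ** 2 + (yy - c_spot[1]) ** 2 + (
                xx - c_spot[2]
            ) ** 2 <= body_radius_nm**2
            bodies_ch[spot] = body_intensity
            body_lab[spot] = body_next
            body_next += 1
            info["body_count"] += 1
        per_nucleus.append(info)
    dna = _add_noise(dna, noise_sd, seed * 2 + 1 if noise_sd else 0)
    bodies_ch = _add_noise(bodies_ch, noise_sd, seed * 2 + 2 if noise_sd else 0)
    image = Image(np.stack([dna, bodies_ch]), spacing, ("dna", "bodies"))
    params = {
        "kind": "nucleus_scene",
        "n_nuclei": n_nuclei,
        "n_chromocenters": n_chromocenters,
        "n_bodies": n_bodies,
        "nucleus_radius_nm": nucleus_radius_nm,
        "chromocenter_radius_nm": chromocenter_radius_nm,
        "body_radius_nm": body_radius_nm,
        "noise_sd": noise_sd,
        "seed": seed,
        "centers_nm": [c.tolist() for c in centers],
    }
    return ScenePhantom(
        image,
        LabelMap(nuclei_lab, spacing),
        LabelMap(cc_lab, spacing),
        LabelMap(body_lab, spacing),
        per_nucleus,
        params,
    )
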