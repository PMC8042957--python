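"""Implant-axis estimation and longitudinal slice extraction.

The measurement protocol works on 2D longitudinal planes that contain the
implant's long axis, identified by their rotation angle about that axis
(0°, 45°, 90°, 135° by default; each plane also shows the opposite side at
angle + 180°).  The axis is recovered automatically as the principal axis of
the supra-threshold (metal) voxels — replacing the manual marker-based
alignment a human operator performs in scanner software.

Slices are sampled from the *grayscale* volume by trilinear interpolation
and thresholded afterwards; interpolating label images instead would create
stair-step contact artifacts.  Out-of-volume samples take the background
value 0.  The sample grid is anchored so that, when the axis is aligned with
a coordinate axis and passes through voxel centres, samples land exactly on
voxel centres and extraction is lossless.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import SliceImage, Volume


@dataclass
class ImplantAxis:
    """Implant long axis: a point on the axis plus a unit direction (z, y, x order)."""

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        if self.point.shape != (3,) or self.direction.shape != (3,):
            raise ValueError("axis point and direction must be 3-vectors")
        if abs(np.linalg.norm(self.direction) - 1.0) > 1e-9:
            raise ValueError("axis direction must be a unit vector")


def estimate_axis(v: Volume, implant_threshold: float = 200.0) -> ImplantAxis:
    """Estimate the implant axis from the metal voxels.

    The axis point is the centroid of voxels with intensity >=
    ``implant_threshold``; the direction is the principal axis of their
    coordinate scatter (eigenvector of the largest covariance eigenvalue),
    sign-normalised so its axial (z) component is positive.
    """
    coords = np.argwhere(v.voxels >= implant_threshold)
    if coords.shape[0] == 0:
        raise ValueError(f"no implant found: no voxels >= {implant_threshold}")
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    cov = centered.T @ centered / coords.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    direction = evecs[:, np.argmax(evals)]
    # sign-normalise: axial (z) component positive; fall back to the first
    # non-negligible component when the implant lies in a coordinate plane
    if abs(direction[0]) > 1e-9:
        if direction[0] < 0:
            direction = -direction
    else:
        for c in direction:
            if abs(c) > 1e-9:
                if c < 0:
                    direction = -direction
                break
    return ImplantAxis(point=centroid, direction=direction / np.linalg.norm(direction))


@dataclass
class SliceAngleSet:
    """Ordered set of extraction angles about the implant axis (degrees)."""

    angles_deg: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)

    def __post_init__(self) -> None:
        angles = tuple(float(a) for a in self.angles_deg)
        if any(not (0.0 <= a < 360.0) for a in angles):
            raise ValueError("angles must lie in [0, 360)")
        if len({a % 180.0 for a in angles}) != len(angles):
            raise ValueError("angles duplicate modulo 180 (each plane already shows both sides)")
        self.angles_deg = angles


def _radial_basis(direction: np.ndarray, angle_deg: float) -> np.ndarray:
    """In-plane radial unit vector at ``angle_deg`` from the +x reference."""
    d = direction
    ex = np.array([0.0, 0.0, 1.0])  # +x in (z, y, x) order
    e1 = ex - (ex @ d) * d
    if np.linalg.norm(e1) < 1e-6:  # axis parallel to x: reference from +y
        ey = np.array([0.0, 1.0, 0.0])
        e1 = ey - (ey @ d) * d
    e1 /= np.linalg.norm(e1)
    # cross product in geometric (x, y, z) order: arrays are (z, y, x), which
    # is a left-handed permutation, so cross() on them would flip the sense
    e2 = np.cross(d[::-1], e1[::-1])[::-1]
    theta = np.radians(angle_deg)
    return np.cos(theta) * e1 + np.sin(theta) * e2


def implant_axial_range(v: Volume, axis: ImplantAxis, implant_threshold: float = 200.0) -> tuple[float, float]:
    """Axial-coordinate range (along the axis direction) spanned by the implant."""
    coords = np.argwhere(v.voxels >= implant_threshold)
    if coords.shape[0] == 0:
        raise ValueError("no implant voxels above threshold")
    t = (coords - axis.point) @ axis.direction
    return float(t.min()), float(t.max())


def extract_longitudinal_slice(
    v: Volume,
    axis: ImplantAxis,
    angle_deg: float,
    implant_threshold: float = 200.0,
    axial_range: tuple[float, float] | None = None,
    axial_margin: float = 0.1,
) -> SliceImage:
    """Extract the longitudinal plane through ``axis`` at ``angle_deg``.

    The plane's rows run along the axis direction (row 0 = implant top, the
    end with the smaller axial coordinate), its columns along the radial
    direction at ``angle_deg`` measured from the +x reference perpendicular.
    Pixels are sampled at voxel-size spacing by trilinear interpolation;
    samples outside the volume read 0.  The axial extent covers the implant
    bounding box plus ``axial_margin`` on each end; the radial extent covers
    the whole volume.

    ``axial_range`` may be supplied (from :func:`implant_axial_range`) to
    avoid re-scanning the volume when extracting several angles.
    """
    if not (0.0 <= angle_deg < 360.0):
        raise ValueError(f"angle_deg must lie in [0, 360), got {angle_deg}")
    d = axis.direction
    radial = _radial_basis(d, angle_deg)

    if axial_range is None:
        axial_range = implant_axial_range(v, axis, implant_threshold)
    t_lo, t_hi = axial_range
    pad = axial_margin * (t_hi - t_lo)
    # anchor the axial grid on integer axial coordinates of the volume
    a0 = axis.point @ d
    shift_t = np.round(a0) - a0
    t_vals = np.arange(np.floor(t_lo - pad), np.ceil(t_hi + pad) + 1) + shift_t

    corners = np.array(
        [[z, y, x] for z in (0, v.shape[0] - 1) for y in (0, v.shape[1] - 1) for x in (0, v.shape[2] - 1)],
        dtype=float,
    )
    rel = corners - axis.point
    perp = rel - np.outer(rel @ d, d)
    smax = int(np.ceil(np.linalg.norm(perp, axis=1).max())) + 1
    b0 = axis.point @ radial
    shift_s = np.round(b0) - b0
    s_vals = np.arange(-smax, smax + 1) + shift_s

    pos = (
        axis.point[:, None, None]
        + t_vals[None, :, None] * d[:, None, None]
        + s_vals[None, None, :] * radial[:, None, None]
    )
    pixels = ndimage.map_coordinates(
        v.voxels.astype(np.float32), pos, order=1, mode="constant", cval=0.0
    )
    origin = axis.point + t_vals[0] * d + s_vals[0] * radial
    return SliceImage(
        pixels=pixels,
        pixel_size_um=v.voxel_size_um,
        angle_deg=angle_deg,
        origin=origin,
        basis=np.stack([d, radial]),
    )
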