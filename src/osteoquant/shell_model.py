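"""Cylindrical implant-shell geometry.

The stabilizing shell bridging the segmental defect is modeled as a rigid
cylinder (axis point at the rostral endcap center, unit axis direction, outer
radius R, length L). It is the geometric reference for all morphometric
markers: new bone deposits on its outer surface, contact length is measured
along it, and the half-circumference pi*R normalizes the surface/contact
markers. The model is fitted by least squares to landmark points picked on
the shell's outer rim in CT.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "ShellModel",
    "RegionPartition",
    "fit_cylinder",
    "radial_project",
    "partition_slices",
    "shell_to_json",
    "shell_from_json",
]

_UNIT_TOL = 1e-9


@dataclasses.dataclass
class ShellModel:
    """Rigid cylinder: rostral endcap center, unit axis, outer radius, length."""

    axis_point_mm: tuple[float, float, float]
    axis_dir: tuple[float, float, float]
    radius_mm: float
    length_mm: float
    fit_rms_mm: float = 0.0

    def __post_init__(self) -> None:
        d = np.asarray(self.axis_dir, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("axis_dir must be a nonzero vector")
        self.axis_dir = tuple(d / n)
        self.axis_point_mm = tuple(float(v) for v in self.axis_point_mm)
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")
        if self.length_mm <= 0:
            raise ValueError("length_mm must be positive")

    # -- coordinate helpers -------------------------------------------------

    def axial_coordinate(self, points_mm: np.ndarray) -> np.ndarray:
        """Signed distance along the axis from the rostral endcap, in mm."""
        p = np.atleast_2d(points_mm) - np.asarray(self.axis_point_mm)
        return p @ np.asarray(self.axis_dir)

    def radial_distance(self, points_mm: np.ndarray) -> np.ndarray:
        """Distance from the cylinder axis, in mm."""
        pts = np.atleast_2d(points_mm).astype(float)
        p = pts - np.asarray(self.axis_point_mm)
        d = np.asarray(self.axis_dir)
        axial = p @ d
        radial_vec = p - np.outer(axial, d)
        return np.linalg.norm(radial_vec, axis=-1)

    def axial_fraction(self, z_mm: float | np.ndarray) -> np.ndarray:
        """Fraction of shell length at a given slice-axis (axis 2) position.

        Requires the shell axis to be reasonably aligned with the slice axis
        (the axial-scan geometry this package assumes).
        """
        dz = self.axis_dir[2]
        if abs(dz) < 0.5:
            raise ValueError("shell axis is nearly parallel to the slice planes")
        s = (np.asarray(z_mm, dtype=float) - self.axis_point_mm[2]) / dz
        return s / self.length_mm

    def cross_section_center(self, z_mm: float) -> tuple[float, float]:
        """(depth, width) mm coordinates of the axis at slice position z_mm."""
        dz = self.axis_dir[2]
        if abs(dz) < 0.5:
            raise ValueError("shell axis is nearly parallel to the slice planes")
        t = (z_mm - self.axis_point_mm[2]) / dz
        c = np.asarray(self.axis_point_mm) + t * np.asarray(self.axis_dir)
        return float(c[0]), float(c[1])


@dataclasses.dataclass(frozen=True)
class RegionPartition:
    """Lengthwise VOI thirds, as fractions of shell length from the rostral end.

    Slices outside [0.05, 0.95) are excluded. Intervals are half-open toward
    the distal end so every retained slice gets exactly one label.
    """

    proximal: tuple[float, float] = (0.05, 0.35)
    middle: tuple[float, float] = (0.35, 0.65)
    distal: tuple[float, float] = (0.65, 0.95)

    def __post_init__(self) -> None:
        ivals = [self.proximal, self.middle, self.distal]
        for lo, hi in ivals:
            if not (0.0 <= lo < hi <= 1.0):
                raise ValueError(f"invalid interval ({lo}, {hi})")
        if self.proximal[1] != self.middle[0] or self.middle[1] != self.distal[0]:
            raise ValueError("region intervals must be contiguous")

    def label(self, fraction: float) -> str | None:
        """'P'/'M'/'D' for a z-fraction, or None if outside the analyzed range."""
        if self.proximal[0] <= fraction < self.proximal[1]:
            return "P"
        if self.middle[0] <= fraction < self.middle[1]:
            return "M"
        if self.distal[0] <= fraction < self.distal[1]:
            return "D"
        return None


# ---------------------------------------------------------------------------
# cylinder fitting


def _orthonormal_basis(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0])
    if abs(d @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(d, helper)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    return u, v


def fit_cylinder(
    landmarks: Sequence[Sequence[float]], length_mm: float | None = None
) -> ShellModel:
    """Least-squares cylinder through >= 6 landmark points (mm).

    The axis is initialized from the principal direction of the point cloud
    and refined together with the radius by minimizing sum((distance to axis
    - R)^2). Length is taken from the landmark extent along the fitted axis
    unless supplied. Collinear or coplanar landmark sets are rejected.
    """
    pts = np.asarray(landmarks, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("landmarks must be an (n, 3) array of mm coordinates")
    n = pts.shape[0]
    if n < 6:
        raise ValueError(f"cylinder fit needs at least 6 landmarks, got {n}")

    centroid = pts.mean(axis=0)
    centered = pts - centroid
    svals = np.linalg.svd(centered, compute_uv=False)
    if svals[0] == 0 or svals[1] / svals[0] < 1e-8:
        raise ValueError("degenerate landmarks: points are collinear")
    if svals[2] / svals[0] < 1e-8:
        raise ValueError("degenerate landmarks: points are coplanar (cylinder underdetermined)")

    _, _, Vt = np.linalg.svd(centered)
    d0 = Vt[0]
    u, v = _orthonormal_basis(d0)

    def unpack(params: np.ndarray):
        a, b, alpha, beta, R = params
        d = d0 + alpha * u + beta * v
        d = d / np.linalg.norm(d)
        c = centroid + a * u + b * v
        return c, d, R

    def residuals(params: np.ndarray) -> np.ndarray:
        c, d, R = unpack(params)
        p = pts - c
        axial = p @ d
        rad = np.linalg.norm(p - np.outer(axial, d), axis=1)
        return rad - R

    p0 = pts - centroid
    axial0 = p0 @ d0
    r0 = np.linalg.norm(p0 - np.outer(axial0, d0), axis=1).mean()
    sol = least_squares(residuals, x0=[0.0, 0.0, 0.0, 0.0, max(r0, 1e-6)], method="lm")
    c, d, R = unpack(sol.x)
    if R <= 0:
        raise ValueError("cylinder fit collapsed to non-positive radius")

    # deterministic orientation: axis points toward increasing slice index
    if d[2] < 0 or (d[2] == 0 and (d[1] < 0 or (d[1] == 0 and d[0] < 0))):
        d = -d
    axial = (pts - c) @ d
    p_rostral = c + axial.min() * d
    L = float(length_mm) if length_mm is not None else float(axial.max() - axial.min())
    rms = float(np.sqrt(np.mean(residuals(sol.x) ** 2)))
    return ShellModel(tuple(p_rostral), tuple(d), float(R), L, fit_rms_mm=rms)


def radial_project(point_mm: Sequence[float], shell: ShellModel) -> np.ndarray:
    """Project a point onto the shell surface along the ray from the axis.

    The projection keeps the point's axial coordinate and polar angle and
    moves it to radius R. Undefined for points on the axis.
    """
    p = np.asarray(point_mm, dtype=float)
    d = np.asarray(shell.axis_dir)
    rel = p - np.asarray(shell.axis_point_mm)
    axial = rel @ d
    radial_vec = rel - axial * d
    rho = np.linalg.norm(radial_vec)
    if rho < 1e-12:
        raise ValueError("radial projection undefined for a point on the shell axis")
    foot = np.asarray(shell.axis_point_mm) + axial * d
    return foot + shell.radius_mm * radial_vec / rho


def partition_slices(
    shell: ShellModel,
    slice_zs_mm: Sequence[float],
    partition: RegionPartition | None = None,
) -> list[str | None]:
    """Label each slice position 'P'/'M'/'D' or None (excluded)."""
    partition = partition or RegionPartition()
    fracs = shell.axial_fraction(np.asarray(slice_zs_mm, dtype=float))
    return [partition.label(float(f)) for f in np.atleast_1d(fracs)]


# ---------------------------------------------------------------------------
# serialization


def shell_to_json(shell: ShellModel, path: str | Path) -> None:
    obj = {
        "axis_point_mm": list(shell.axis_point_mm),
        "axis_dir": list(shell.axis_dir),
        "radius_mm": shell.radius_mm,
        "length_mm": shell.length_mm,
        "fit_rms_mm": shell.fit_rms_mm,
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2)


def shell_from_json(path: str | Path) -> ShellModel:
    with open(path) as fh:
        obj = json.load(fh)
    return ShellModel(
        tuple(obj["axis_point_mm"]),
        tuple(obj["axis_dir"]),
        float(obj["radius_mm"]),
        float(obj["length_mm"]),
        fit_rms_mm=float(obj.get("fit_rms_mm", 0.0)),
    )
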