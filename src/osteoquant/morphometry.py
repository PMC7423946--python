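"""Per-slice new-bone morphometry: NBB area, NBS length, NBC length.

Given a binary bone-surface mask (from US detection or CT segmentation) and
the fitted shell cylinder, each axial slice is reduced to a depth profile
(one surface depth per image column, resolving partial occlusion by keeping
the shallowest pixel), smoothed with a cubic smoothing spline, and closed
against the shell circle by radial projection of the curve endpoints. The
enclosed region defines the three markers:

* NBB (new-bone bulk) area — area between the fitted curve and the shell
  arc it projects onto; surrogate for deposited bone mass.
* NBC (new-bone contact) length — the part of the region perimeter lying on
  the shell surface; the imaging analog of bone-to-implant contact.
* NBS (new-bone surface) length — the complementary perimeter (the free
  surface), plus exposed shell arcs between disjoint deposits.

Normalizations: NBB by the B-mode field-of-view area (percent), NBS and NBC
by the shell endcap half-circumference pi*R (NBS a plain ratio, NBC in
percent).
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Sequence

import numpy as np
from scipy.interpolate import make_smoothing_spline
from scipy.spatial import cKDTree
from skimage.morphology import skeletonize

from .imaging_io import BinaryMask, FrameGeometry, assert_same_grid
from .shell_model import RegionPartition, ShellModel

__all__ = [
    "DepthProfile",
    "SplineConfig",
    "SliceMorphometry",
    "DistanceReport",
    "NBBRegion",
    "extract_depth_profile",
    "fit_profile_spline",
    "compute_nbb",
    "split_perimeter",
    "quantify_scan",
    "common_range_restrict",
    "mean_absolute_distance",
]

log = logging.getLogger(__name__)

_ARC_STEP_RAD = 0.005


@dataclasses.dataclass
class DepthProfile:
    """One surface depth per image column (NaN where no surface detected)."""

    lateral_mm: np.ndarray
    depth_mm: np.ndarray
    slice_index: int = 0
    slice_z_mm: float = 0.0

    def __post_init__(self) -> None:
        self.lateral_mm = np.asarray(self.lateral_mm, dtype=float)
        self.depth_mm = np.asarray(self.depth_mm, dtype=float)
        if self.lateral_mm.shape != self.depth_mm.shape:
            raise ValueError("lateral and depth arrays must have equal shape")

    @property
    def n_detected(self) -> int:
        return int(np.isfinite(self.depth_mm).sum())


@dataclasses.dataclass
class SplineConfig:
    """Penalized least-squares smoothing-spline convention.

    ``smoothing_p`` is the mixing parameter p in

        p * sum(residual^2) + (1 - p) * integral(curvature^2),

    so p = 1 interpolates and p -> 0 approaches a straight line. The default
    0.5 weighs fidelity and roughness equally under this convention.
    ``max_gap_columns`` limits bridging across missing columns: wider gaps
    split the profile into separately fitted runs.
    """

    smoothing_p: float = 0.5
    max_gap_columns: int = 3
    min_run_points: int = 4

    def __post_init__(self) -> None:
        if not (0.0 <= self.smoothing_p <= 1.0):
            raise ValueError("smoothing_p must be in [0, 1]")
        if self.max_gap_columns < 0 or self.min_run_points < 2:
            raise ValueError("invalid spline run settings")


@dataclasses.dataclass
class SliceMorphometry:
    """Raw and normalized markers for one axial slice."""

    slice_z_mm: float
    nbb_area_mm2: float
    nbs_length_mm: float
    nbc_length_mm: float
    nbb_norm_pct: float
    nbs_norm: float
    nbc_norm_pct: float
    region: str = "X"
    scan_id: str = ""


@dataclasses.dataclass
class DistanceReport:
    """Symmetric mean absolute distance between two detected surfaces."""

    mean_abs_distance_mm: float
    sd_mm: float
    n_points: int


@dataclasses.dataclass
class FittedProfile:
    """Spline-smoothed depth profile, evaluated on the column grid."""

    lateral_mm: np.ndarray
    depth_mm: np.ndarray  # NaN outside fitted runs
    runs: list[tuple[int, int]]  # inclusive column-index ranges
    slice_z_mm: float = 0.0


@dataclasses.dataclass
class NBBRegion:
    """Filled interspace between the fitted curve and the shell circle.

    ``runs`` holds per contiguous curve the polar samples (theta, rho) around
    the slice's shell cross-section center, with rho clipped to >= R (points
    inside the shell cannot contribute negative bulk).
    """

    runs: list[tuple[np.ndarray, np.ndarray]]
    radius_mm: float
    center_mm: tuple[float, float]
    area_mm2: float
    slice_z_mm: float = 0.0


# ---------------------------------------------------------------------------
# depth profile extraction


_NB8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _prune_skeleton(skel: np.ndarray, max_len: int) -> np.ndarray:
    """Remove spur branches of up to ``max_len`` pixels ending at a junction.

    Open arcs (endpoint to endpoint) are never pruned — they are the surface
    curve itself, not spurs.
    """
    if max_len <= 0:
        return skel
    skel = skel.copy()
    kernel = np.ones((3, 3), dtype=int)
    kernel[1, 1] = 0

    def degree_map(s):
        from scipy import ndimage as ndi

        return ndi.convolve(s.astype(int), kernel, mode="constant")

    deg = degree_map(skel)
    endpoints = np.argwhere(skel & (deg == 1))
    for ep in map(tuple, endpoints):
        if not skel[ep]:
            continue
        path = [ep]
        prev = None
        cur = ep
        while True:
            nbrs = [
                (cur[0] + dr, cur[1] + dc)
                for dr, dc in _NB8
                if 0 <= cur[0] + dr < skel.shape[0]
                and 0 <= cur[1] + dc < skel.shape[1]
                and skel[cur[0] + dr, cur[1] + dc]
                and (cur[0] + dr, cur[1] + dc) != prev
            ]
            nbrs = [p for p in nbrs if p not in path]
            if deg[cur] >= 3 and cur != ep:
                # reached a junction: prune the walked spur (keep the junction)
                if len(path) - 1 <= max_len:
                    for p in path[:-1]:
                        skel[p] = False
                break
            if not nbrs or len(path) > max_len + 1:
                break
            prev = cur
            cur = nbrs[0]
            path.append(cur)
        deg = degree_map(skel)
    return skel


def extract_depth_profile(
    slice_mask: np.ndarray,
    spacing_mm: tuple[float, float],
    prune_len_px: int = 5,
    slice_index: int = 0,
    slice_z_mm: float = 0.0,
    thin: bool = True,
) -> DepthProfile:
    """Reduce a 2-D mask to one surface depth per column.

    With ``thin=True`` (surface-band masks, e.g. US detections) the
    foreground is skeletonized to 1-pixel-wide curves and spur branches
    shorter than ``prune_len_px`` are pruned before taking the minimum-depth
    pixel per column — the skeleton centerline localizes the surface at the
    middle of the detected band. With ``thin=False`` (solid bulk masks, e.g.
    CT segmentations) the outer envelope — the shallowest foreground pixel
    per column — is the surface directly. Either way at most one depth per
    column survives, resolving partial-occlusion ambiguity.
    """
    m = np.asarray(slice_mask, dtype=bool)
    if m.ndim != 2:
        raise ValueError("slice mask must be 2-D")
    nd, nw = m.shape
    lateral = np.arange(nw) * spacing_mm[1]
    depth = np.full(nw, np.nan)
    if m.any():
        if thin:
            skel = skeletonize(m)
            m = _prune_skeleton(skel, prune_len_px)
        rows, cols = np.nonzero(m)
        for c in np.unique(cols):
            depth[c] = rows[cols == c].min() * spacing_mm[0]
    return DepthProfile(lateral, depth, slice_index, slice_z_mm)


# ---------------------------------------------------------------------------
# spline fitting


def _valid_runs(valid: np.ndarray, max_gap: int) -> list[tuple[int, int]]:
    """Group detected columns, bridging gaps of at most ``max_gap`` columns."""
    idx = np.nonzero(valid)[0]
    if idx.size == 0:
        return []
    runs = []
    start = prev = idx[0]
    for i in idx[1:]:
        if i - prev > max_gap + 1:
            runs.append((int(start), int(prev)))
            start = i
        prev = i
    runs.append((int(start), int(prev)))
    return runs


def fit_profile_spline(profile: DepthProfile, cfg: SplineConfig) -> FittedProfile:
    """Cubic smoothing spline per contiguous run of the depth profile.

    Minimizes p * sum(residual^2) + (1-p) * integral(f'')^2 via the
    equivalent penalty lam = (1-p)/p. Runs shorter than ``min_run_points``
    are passed through unsmoothed (logged). The fit is evaluated on the
    column grid across each run, including bridged small gaps.
    """
    valid = np.isfinite(profile.depth_mm)
    out = np.full_like(profile.depth_mm, np.nan)
    runs = _valid_runs(valid, cfg.max_gap_columns)
    p = cfg.smoothing_p
    # the penalized-spline solver needs >= 5 support points
    min_pts = max(cfg.min_run_points, 5)
    for lo, hi in runs:
        sel = np.arange(lo, hi + 1)
        pts = sel[valid[sel]]
        x, y = profile.lateral_mm[pts], profile.depth_mm[pts]
        if pts.size < min_pts:
            log.info(
                "fit_profile_spline: run of %d points passed through unsmoothed",
                pts.size,
            )
            out[pts] = y
            continue
        if p == 0.0:
            coeffs = np.polyfit(x, y, 1)
            out[sel] = np.polyval(coeffs, profile.lateral_mm[sel])
        else:
            lam = (1.0 - p) / p
            spl = make_smoothing_spline(x, y, lam=lam)
            out[sel] = spl(profile.lateral_mm[sel])
    return FittedProfile(profile.lateral_mm.copy(), out, runs, profile.slice_z_mm)


# ---------------------------------------------------------------------------
# region construction and perimeter split


def _polar_of_curve(
    x_mm: np.ndarray, y_mm: np.ndarray, center: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Polar (theta, rho) of curve points about the shell cross-section center.

    theta = 0 toward the transducer (negative depth offset), positive toward
    increasing lateral coordinate.
    """
    od = y_mm - center[0]
    ow = x_mm - center[1]
    theta = np.arctan2(ow, -od)
    rho = np.hypot(od, ow)
    return theta, rho


def _cartesian(theta: np.ndarray, rho: np.ndarray, center: tuple[float, float]):
    return np.stack(
        [center[0] - rho * np.cos(theta), center[1] + rho * np.sin(theta)], axis=1
    )


def _shoelace(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def compute_nbb(
    fitted: FittedProfile,
    shell: ShellModel,
    slice_z_mm: float,
    frame: FrameGeometry,
) -> NBBRegion:
    """Close the fitted curve against the shell circle and measure its area.

    Each curve run is converted to polar samples about the slice's shell
    center, points inside the circle are clipped onto it, and the region is
    the polygon [curve -> radial drop -> shell arc back -> radial rise]. The
    area is the shoelace area of that polygon; a curve crossing the circle
    contributes only its outside lobes (the clipped stretch coincides with
    the arc and cancels).
    """
    del frame  # frame enters only at normalization time; kept for symmetry
    center = shell.cross_section_center(slice_z_mm)
    R = shell.radius_mm
    runs_polar: list[tuple[np.ndarray, np.ndarray]] = []
    total = 0.0
    for lo, hi in fitted.runs:
        sel = np.arange(lo, hi + 1)
        good = np.isfinite(fitted.depth_mm[sel])
        if good.sum() < 2:
            continue
        x = fitted.lateral_mm[sel][good]
        y = fitted.depth_mm[sel][good]
        theta, rho = _polar_of_curve(x, y, center)
        rho = np.maximum(rho, R)
        runs_polar.append((theta, rho))
        curve = _cartesian(theta, rho, center)
        n_arc = max(2, int(abs(theta[-1] - theta[0]) / _ARC_STEP_RAD) + 1)
        arc_theta = np.linspace(theta[-1], theta[0], n_arc)
        arc = _cartesian(arc_theta, np.full(n_arc, R), center)
        total += _shoelace(np.vstack([curve, arc]))
    if runs_polar and total <= 0.0:
        log.info("compute_nbb: curve entirely on/inside the shell circle (zero area)")
    return NBBRegion(runs_polar, R, center, total, slice_z_mm)


def split_perimeter(
    region: NBBRegion, shell: ShellModel, contact_tol_mm: float
) -> tuple[float, float]:
    """Split the region perimeter into free-surface (NBS) and contact (NBC).

    Perimeter within ``contact_tol_mm`` of the shell circle belongs to the
    contact part; per deposit interval NBC is the projected shell arc R*dtheta
    and NBS the curve polyline plus the two radial closure segments. Exposed
    shell arcs between disjoint deposits are added to NBS (they separate bone
    that was detected on both sides).
    """
    if contact_tol_mm < 0:
        raise ValueError("contact_tol_mm must be >= 0")
    R = region.radius_mm
    nbs = 0.0
    nbc = 0.0
    intervals: list[tuple[float, float]] = []
    for theta, rho in region.runs:
        deposit = rho > R + contact_tol_mm
        if not deposit.any():
            continue
        # maximal runs of deposit columns
        d = np.diff(deposit.astype(int))
        starts = list(np.nonzero(d == 1)[0] + 1)
        ends = list(np.nonzero(d == -1)[0])
        if deposit[0]:
            starts.insert(0, 0)
        if deposit[-1]:
            ends.append(len(deposit) - 1)
        for i0, i1 in zip(starts, ends):
            th = theta[i0 : i1 + 1]
            rh = rho[i0 : i1 + 1]
            pts = _cartesian(th, rh, region.center_mm)
            if len(pts) > 1:
                nbs += float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
            nbs += float(rh[0] - R) + float(rh[-1] - R)
            lo, hi = float(min(th[0], th[-1])), float(max(th[0], th[-1]))
            nbc += R * (hi - lo)
            intervals.append((lo, hi))
    intervals.sort()
    for (_, prev_hi), (next_lo, _) in zip(intervals, intervals[1:]):
        gap = next_lo - prev_hi
        if gap > 0:
            nbs += R * gap
    return nbs, nbc


# ---------------------------------------------------------------------------
# scan-level quantification


def quantify_scan(
    mask: BinaryMask,
    shell: ShellModel,
    frame: FrameGeometry,
    spline_cfg: SplineConfig | None = None,
    contact_tol_mm: float | None = None,
    prune_len_px: int = 5,
    partition: RegionPartition | None = None,
    scan_id: str = "",
    thin: bool = True,
) -> list[SliceMorphometry]:
    """Run the per-slice chain over a detected scan.

    profile -> spline -> region -> perimeter split -> normalization. Slices
    with no detected bone and slices outside the 5-95% axial range of the
    shell are excluded; each retained slice carries its P/M/D region label.
    The default contact tolerance is one in-plane voxel diagonal.
    """
    spline_cfg = spline_cfg or SplineConfig()
    partition = partition or RegionPartition()
    if contact_tol_mm is None:
        contact_tol_mm = math.hypot(mask.voxel_mm[0], mask.voxel_mm[1])
    R = shell.radius_mm
    half_circ = math.pi * R
    out: list[SliceMorphometry] = []
    for k in range(mask.values.shape[2]):
        z = mask.origin_mm[2] + k * mask.voxel_mm[2]
        label = partition.label(float(shell.axial_fraction(z)))
        if label is None:
            continue
        profile = extract_depth_profile(
            mask.values[:, :, k],
            (mask.voxel_mm[0], mask.voxel_mm[1]),
            prune_len_px=prune_len_px,
            slice_index=k,
            slice_z_mm=z,
            thin=thin,
        )
        if profile.n_detected == 0:
            continue
        fitted = fit_profile_spline(profile, spline_cfg)
        region = compute_nbb(fitted, shell, z, frame)
        nbs, nbc = split_perimeter(region, shell, contact_tol_mm)
        out.append(
            SliceMorphometry(
                slice_z_mm=z,
                nbb_area_mm2=region.area_mm2,
                nbs_length_mm=nbs,
                nbc_length_mm=nbc,
                nbb_norm_pct=100.0 * region.area_mm2 / frame.fov_area_mm2,
                nbs_norm=nbs / half_circ,
                nbc_norm_pct=100.0 * nbc / half_circ,
                region=label,
                scan_id=scan_id,
            )
        )
    if not out:
        log.warning("quantify_scan: no slice yielded detected bone")
    return out


def common_range_restrict(
    mask_a: BinaryMask, mask_b: BinaryMask
) -> tuple[BinaryMask, BinaryMask]:
    """Restrict both masks to their common bone-bearing lateral/slice extents.

    Bone outside the intersection of the two scans' detected ranges cannot be
    compared and is dropped from both.
    """
    assert_same_grid(mask_a, mask_b)

    def extent(vals: np.ndarray, axis_keep: int) -> tuple[int, int] | None:
        other = tuple(i for i in range(3) if i != axis_keep)
        any_ = vals.any(axis=other)
        idx = np.nonzero(any_)[0]
        if idx.size == 0:
            return None
        return int(idx[0]), int(idx[-1])

    out = []
    ranges = {}
    for axis in (1, 2):
        ra = extent(mask_a.values, axis)
        rb = extent(mask_b.values, axis)
        if ra is None or rb is None:
            ranges[axis] = None
        else:
            lo, hi = max(ra[0], rb[0]), min(ra[1], rb[1])
            ranges[axis] = (lo, hi) if lo <= hi else None
    for m in (mask_a, mask_b):
        vals = m.values.copy()
        if any(r is None for r in ranges.values()):
            log.warning("common_range_restrict: disjoint bone ranges, masks emptied")
            vals[:] = False
        else:
            (wl, wh), (zl, zh) = ranges[1], ranges[2]
            vals[:, :wl, :] = False
            vals[:, wh + 1 :, :] = False
            vals[:, :, :zl] = False
            vals[:, :, zh + 1 :] = False
        out.append(BinaryMask(vals, m.voxel_mm, m.origin_mm))
    return out[0], out[1]


def _profile_points(profiles: Sequence[DepthProfile]) -> np.ndarray:
    pts = []
    for p in profiles:
        good = np.isfinite(p.depth_mm)
        if good.any():
            pts.append(
                np.stack(
                    [
                        p.lateral_mm[good],
                        p.depth_mm[good],
                        np.full(int(good.sum()), p.slice_z_mm),
                    ],
                    axis=1,
                )
            )
    if not pts:
        return np.empty((0, 3))
    return np.vstack(pts)


def mean_absolute_distance(
    surf_a: Sequence[DepthProfile], surf_b: Sequence[DepthProfile]
) -> DistanceReport:
    """Symmetric mean absolute distance between two surface reconstructions.

    Surfaces are the detected profile point clouds (lateral, depth, slice) in
    mm over the common restricted range; the metric averages the two directed
    mean nearest-neighbor distances.
    """
    A = _profile_points(surf_a)
    B = _profile_points(surf_b)
    if A.shape[0] == 0 or B.shape[0] == 0:
        raise ValueError("mean_absolute_distance requires two non-empty surfaces")
    d_ab = cKDTree(B).query(A)[0]
    d_ba = cKDTree(A).query(B)[0]
    mad = 0.5 * (d_ab.mean() + d_ba.mean())
    pooled = np.concatenate([d_ab, d_ba])
    return DistanceReport(
        mean_abs_distance_mm=float(mad),
        sd_mm=float(pooled.std(ddof=1)) if pooled.size > 1 else 0.0,
        n_points=int(pooled.size),
    )


def profiles_from_mask(
    mask: BinaryMask, prune_len_px: int = 5, thin: bool = True
) -> list[DepthProfile]:
    """Raw (unsmoothed) depth profiles for every slice of a detected mask."""
    out = []
    for k in range(mask.values.shape[2]):
        z = mask.origin_mm[2] + k * mask.voxel_mm[2]
        out.append(
            extract_depth_profile(
                mask.values[:, :, k],
                (mask.voxel_mm[0], mask.voxel_mm[1]),
                prune_len_px=prune_len_px,
                slice_index=k,
                slice_z_mm=z,
                thin=thin,
            )
        )
    return out
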