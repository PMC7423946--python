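"""Synthetic co-registered US/CT phantoms of a shell-stabilized defect.

The generator emulates the imaging situation the pipeline is built for: a
radio-lucent cylindrical shell bridges a segmental long-bone defect, native
bone fragments occupy the shell ends, and new bone of known radial thickness
is deposited in angular/longitudinal sectors on the shell's outer surface.
From one ground-truth scene it renders

* a CT-like volume: high-intensity bone over soft-tissue background, the
  shell wall near-background (radio-lucent), additive Gaussian noise;
* a US-like B-mode volume: per image column only the outermost bone-or-shell
  interface appears, as a bright ridge with acoustic shadow beneath,
  multiplicative speckle above, and a bright skin band at the top.

The phantom renders geometric ridges plus noise rather than simulating wave
propagation: the detection pipeline consumes interface geometry and contrast,
so physical acoustics would add cost without test power. Analytic per-slice
marker values (:func:`true_slice_morphometry`) provide the oracle that the
image pipeline is checked against.

Angle convention: theta = 0 points from the shell axis toward the transducer
(decreasing depth), positive theta toward increasing lateral coordinate; the
half exposed to the probe is |theta| < pi/2.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .imaging_io import FrameGeometry, Volume
from .shell_model import RegionPartition, ShellModel

__all__ = [
    "PhantomConfig",
    "PhantomScene",
    "build_scene",
    "render_ct",
    "render_us",
    "true_slice_morphometry",
    "scene_to_json",
    "CT_SOFT",
    "CT_SHELL",
    "CT_BONE",
]

# CT rendering intensities (arbitrary units). The shell is radio-lucent:
# close to, but distinct from, soft tissue.
CT_SOFT = 100.0
CT_SHELL = 130.0
CT_BONE = 1000.0

# US rendering levels (normalized echo intensity).
US_BACKGROUND = 0.25
US_RIDGE_AMPL = 1.0
US_SHADOW_FACTOR = 0.05
US_SKIN = 0.85


@dataclasses.dataclass
class PhantomConfig:
    """Ground-truth geometry and rendering parameters.

    ``deposit_spans`` entries are (theta_start, theta_end, z_start_mm,
    z_end_mm, thickness_mm): a new-bone sector of constant radial thickness on
    the shell's outer surface. Angles are in radians within the lateral half
    exposed to the probe (|theta| <= pi/2); z is axial distance from the
    rostral shell end.
    """

    shell_radius_mm: float = 10.0
    shell_length_mm: float = 20.0
    voxel_mm: float = 0.2
    grid_shape: tuple[int, int, int] = (256, 256, 120)
    deposit_spans: tuple[tuple[float, float, float, float, float], ...] = ()
    speckle_snr: float = 5.0
    ct_noise_sd: float = 20.0
    skin_depth_mm: float = 1.0
    seed: int = 0
    defect_span_mm: tuple[float, float] | None = None
    shell_wall_mm: float = 1.5
    ridge_sigma_mm: float = 0.25
    center_mm: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.shell_radius_mm <= 0 or self.shell_length_mm <= 0:
            raise ValueError("shell radius and length must be positive")
        if self.voxel_mm <= 0:
            raise ValueError("voxel_mm must be positive")
        if len(self.grid_shape) != 3 or any(int(n) <= 0 for n in self.grid_shape):
            raise ValueError("grid_shape must be three positive integers")
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        if self.speckle_snr <= 0:
            raise ValueError("speckle_snr must be positive")
        if self.ct_noise_sd < 0 or self.skin_depth_mm < 0:
            raise ValueError("ct_noise_sd and skin_depth_mm must be >= 0")
        if self.shell_length_mm / self.voxel_mm > self.grid_shape[2] + 1e-9:
            raise ValueError("shell does not fit the slice extent of the grid")
        spans = []
        for span in self.deposit_spans:
            t0, t1, z0, z1, th = (float(v) for v in span)
            if th < 0:
                raise ValueError("deposit thickness must be >= 0")
            if not (t0 < t1):
                raise ValueError("theta span must have theta_start < theta_end")
            if t0 < -math.pi / 2 - 1e-9 or t1 > math.pi / 2 + 1e-9:
                raise ValueError("theta span must lie in the lateral half [-pi/2, pi/2]")
            if not (0.0 <= z0 < z1 <= self.shell_length_mm + 1e-9):
                raise ValueError("z span must lie within the shell length")
            spans.append((t0, t1, z0, z1, th))
        self.deposit_spans = tuple(spans)

    @property
    def shell_start_z_mm(self) -> float:
        """Axial (slice-axis) position of the rostral shell end; centered."""
        extent = self.grid_shape[2] * self.voxel_mm
        return (extent - self.shell_length_mm) / 2.0

    @property
    def center_in_plane_mm(self) -> tuple[float, float]:
        if self.center_mm is not None:
            return (float(self.center_mm[0]), float(self.center_mm[1]))
        nd, nw, _ = self.grid_shape
        return (0.55 * nd * self.voxel_mm, 0.5 * nw * self.voxel_mm)

    @property
    def defect_span(self) -> tuple[float, float]:
        if self.defect_span_mm is not None:
            lo, hi = (float(v) for v in self.defect_span_mm)
            if not (0.0 <= lo < hi <= self.shell_length_mm):
                raise ValueError("defect_span_mm must lie within the shell length")
            return (lo, hi)
        L = self.shell_length_mm
        return (0.25 * L, 0.75 * L)


@dataclasses.dataclass
class PhantomScene:
    """Ground truth: shell geometry plus a radial new-bone thickness field.

    ``thickness_field(theta, z)`` gives radial deposit thickness in mm at
    polar angle theta (rad) and axial position z (mm from the rostral shell
    end); it is zero outside the configured deposit sectors.
    """

    shell: ShellModel
    thickness_field: Callable[[np.ndarray, np.ndarray], np.ndarray]
    fragment_zs: tuple[tuple[float, float], ...]
    deposit_spans: tuple[tuple[float, float, float, float, float], ...]
    config: PhantomConfig
    transform_us_to_ct: np.ndarray = dataclasses.field(
        default_factory=lambda: np.eye(4)
    )

    def active_spans(self, z_mm: float) -> list[tuple[float, float, float]]:
        """Deposit sectors (theta0, theta1, thickness) crossing axial z."""
        out = [
            (t0, t1, th)
            for (t0, t1, z0, z1, th) in self.deposit_spans
            if z0 <= z_mm < z1 and th > 0
        ]
        return sorted(out)

    def sample_shell_landmarks(
        self, n: int = 24, seed: int = 0, noise_sd_mm: float = 0.0
    ) -> np.ndarray:
        """Random points on the shell's outer surface (rim landmarks for fitting)."""
        rng = np.random.default_rng(seed)
        theta = rng.uniform(-math.pi, math.pi, size=n)
        s = rng.uniform(0.0, self.shell.length_mm, size=n)
        cd, cw = self.config.center_in_plane_mm
        z0 = self.config.shell_start_z_mm
        R = self.shell.radius_mm
        pts = np.stack(
            [
                cd - R * np.cos(theta),
                cw + R * np.sin(theta),
                z0 + s,
            ],
            axis=1,
        )
        if noise_sd_mm > 0:
            pts = pts + rng.normal(0.0, noise_sd_mm, size=pts.shape)
        return pts


def build_scene(config: PhantomConfig) -> PhantomScene:
    """Deterministic ground-truth scene from a config (no randomness)."""
    spans = config.deposit_spans
    # reject overlapping sectors that disagree on thickness
    for i in range(len(spans)):
        for j in range(i + 1, len(spans)):
            a, b = spans[i], spans[j]
            th_overlap = min(a[1], b[1]) - max(a[0], b[0])
            z_overlap = min(a[3], b[3]) - max(a[2], b[2])
            if th_overlap > 1e-12 and z_overlap > 1e-12 and a[4] != b[4]:
                raise ValueError(
                    "overlapping deposit spans with conflicting thickness: "
                    f"{a} vs {b}"
                )

    def thickness_field(theta: np.ndarray, z: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        z = np.asarray(z, dtype=float)
        theta, z = np.broadcast_arrays(theta, z)
        out = np.zeros_like(theta, dtype=float)
        for t0, t1, z0, z1, th in spans:
            sel = (theta >= t0) & (theta < t1) & (z >= z0) & (z < z1)
            out = np.where(sel, np.maximum(out, th), out)
        return out

    cd, cw = config.center_in_plane_mm
    shell = ShellModel(
        axis_point_mm=(cd, cw, config.shell_start_z_mm),
        axis_dir=(0.0, 0.0, 1.0),
        radius_mm=config.shell_radius_mm,
        length_mm=config.shell_length_mm,
    )
    lo, hi = config.defect_span
    fragments = []
    if lo > 1e-9:
        fragments.append((0.0, lo))
    if hi < config.shell_length_mm - 1e-9:
        fragments.append((hi, config.shell_length_mm))
    return PhantomScene(
        shell=shell,
        thickness_field=thickness_field,
        fragment_zs=tuple(fragments),
        deposit_spans=spans,
        config=config,
    )


# ---------------------------------------------------------------------------
# rendering


def _polar_grids(config: PhantomConfig, oversample: int = 1):
    """(rho, theta) of in-plane voxel centers; optionally finer along depth."""
    nd, nw, _ = config.grid_shape
    vox = config.voxel_mm
    cd, cw = config.center_in_plane_mm
    d = np.arange(nd * oversample) * (vox / oversample)
    w = np.arange(nw) * vox
    od = d[:, None] - cd
    ow = w[None, :] - cw
    rho = np.hypot(od, ow)
    theta = np.arctan2(ow, -od)
    return rho, theta


def _in_fragment(scene: PhantomScene, s: float) -> bool:
    return any(lo <= s < hi for lo, hi in scene.fragment_zs)


def render_ct(
    scene: PhantomScene, config: PhantomConfig, seed: int | None = None
) -> Volume:
    """CT-like volume: bone bright, shell wall radio-lucent, Gaussian noise."""
    nd, nw, ns = config.grid_shape
    vox = config.voxel_mm
    rho, theta = _polar_grids(config)
    R = config.shell_radius_mm
    wall = config.shell_wall_mm
    vol = np.full((nd, nw, ns), CT_SOFT, dtype=np.float64)
    z0 = config.shell_start_z_mm
    for k in range(ns):
        s = k * vox - z0
        if not (0.0 <= s < config.shell_length_mm):
            continue
        sl = np.full((nd, nw), CT_SOFT)
        shell_wall = (rho <= R) & (rho > R - wall)
        sl[shell_wall] = CT_SHELL
        if _in_fragment(scene, s):
            sl[rho <= R - wall] = CT_BONE
        t = scene.thickness_field(theta, s)
        deposit = (rho > R) & (rho <= R + t)
        sl[deposit] = CT_BONE
        vol[:, :, k] = sl
    if config.ct_noise_sd > 0:
        rng = np.random.default_rng(config.seed if seed is None else seed)
        vol = vol + rng.normal(0.0, config.ct_noise_sd, size=vol.shape)
    return Volume(vol, (vox, vox, vox))


def surface_depth_mm(
    scene: PhantomScene, config: PhantomConfig, oversample: int = 4
) -> np.ndarray:
    """Analytic-resolution outermost interface depth per (column, slice).

    For each image column the depth (mm) at which a ray from the transducer
    first meets shell or bone material; NaN where the ray misses. Resolved at
    ``voxel/oversample`` depth steps.
    """
    nd, nw, ns = config.grid_shape
    vox = config.voxel_mm
    rho, theta = _polar_grids(config, oversample=oversample)
    R = config.shell_radius_mm
    z0 = config.shell_start_z_mm
    step = vox / oversample
    depth = np.full((nw, ns), np.nan)
    for k in range(ns):
        s = k * vox - z0
        if not (0.0 <= s < config.shell_length_mm):
            continue
        t = scene.thickness_field(theta, s)
        material = rho <= R + t
        hit = material.any(axis=0)
        first = material.argmax(axis=0)
        col_depth = first * step
        depth[:, k] = np.where(hit, col_depth, np.nan)
    return depth


def render_us(
    scene: PhantomScene, config: PhantomConfig, seed: int | None = None
) -> Volume:
    """B-mode-like volume: bright outermost-interface ridge, shadow, speckle.

    Only the first bone-or-shell interface along each probe ray is rendered
    (acoustic shadowing hides everything beneath); speckle is multiplicative
    with mean 1 and SNR ``config.speckle_snr``.
    """
    nd, nw, ns = config.grid_shape
    vox = config.voxel_mm
    ridge = surface_depth_mm(scene, config)
    d_mm = np.arange(nd) * vox
    vol = np.empty((nd, nw, ns), dtype=np.float64)
    sig = config.ridge_sigma_mm
    for k in range(ns):
        rd = ridge[:, k][None, :]  # (1, nw)
        d = d_mm[:, None]  # (nd, 1)
        base = np.full((nd, nw), US_BACKGROUND)
        with np.errstate(invalid="ignore"):
            below = d > rd
            base = np.where(below, US_BACKGROUND * US_SHADOW_FACTOR, base)
            bump = np.where(
                np.isfinite(rd),
                US_RIDGE_AMPL * np.exp(-((d - rd) ** 2) / (2.0 * sig**2)),
                0.0,
            )
        sl = base + bump
        if config.skin_depth_mm > 0:
            sl[d_mm < config.skin_depth_mm, :] = US_SKIN
        vol[:, :, k] = sl
    snr = config.speckle_snr
    if np.isfinite(snr):
        rng = np.random.default_rng(config.seed if seed is None else seed)
        # gamma with mean 1, sd 1/snr: k = snr^2, scale = 1/snr^2
        speckle = rng.gamma(shape=snr**2, scale=1.0 / snr**2, size=vol.shape)
        vol = vol * speckle
    return Volume(vol, (vox, vox, vox))


# ---------------------------------------------------------------------------
# analytic ground-truth morphometry


def true_slice_morphometry(
    scene: PhantomScene,
    z_mm: float,
    frame: FrameGeometry,
    partition: RegionPartition | None = None,
):
    """Closed-form per-slice markers for the configured sector deposits.

    For a sector of thickness t over angular span phi on a shell of radius R:
    NBB area = (phi/2)((R+t)^2 - R^2), NBC length = phi R, NBS length =
    phi (R+t) + 2t; exposed shell arcs between disjoint sectors add to NBS.
    ``z_mm`` is the volume slice-axis position (mm).
    """
    from .morphometry import SliceMorphometry  # local import avoids a cycle

    config = scene.config
    s = z_mm - config.shell_start_z_mm
    if not (0.0 <= s <= config.shell_length_mm):
        raise ValueError(f"slice z={z_mm} mm lies outside the shell")
    R = scene.shell.radius_mm
    spans = scene.active_spans(s)
    nbb = nbs = nbc = 0.0
    for t0, t1, th in spans:
        phi = t1 - t0
        nbb += 0.5 * phi * ((R + th) ** 2 - R**2)
        nbc += phi * R
        nbs += phi * (R + th) + 2.0 * th
    for (_, prev_end, _), (next_start, _, _) in zip(spans, spans[1:]):
        gap = next_start - prev_end
        if gap > 0:
            nbs += gap * R
    partition = partition or RegionPartition()
    label = partition.label(s / scene.shell.length_mm)
    return SliceMorphometry(
        slice_z_mm=float(z_mm),
        nbb_area_mm2=nbb,
        nbs_length_mm=nbs,
        nbc_length_mm=nbc,
        nbb_norm_pct=100.0 * nbb / frame.fov_area_mm2,
        nbs_norm=nbs / (math.pi * R),
        nbc_norm_pct=100.0 * nbc / (math.pi * R),
        region=label or "X",
        scan_id="truth",
    )


def scene_to_json(scene: PhantomScene, path: str | Path) -> None:
    """Ground-truth sidecar: shell parameters and deposit sectors."""
    cfg = scene.config
    obj = {
        "shell": {
            "axis_point_mm": list(scene.shell.axis_point_mm),
            "axis_dir": list(scene.shell.axis_dir),
            "radius_mm": scene.shell.radius_mm,
            "length_mm": scene.shell.length_mm,
        },
        "deposit_spans": [list(s) for s in scene.deposit_spans],
        "fragment_zs": [list(f) for f in scene.fragment_zs],
        "voxel_mm": cfg.voxel_mm,
        "grid_shape": list(cfg.grid_shape),
        "seed": cfg.seed,
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2)
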