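"""Bone-surface detection in 3-D ultrasound via log-Gabor phase symmetry.

Bone interfaces appear in B-mode as thin bright ridges — locally even-
symmetric intensity profiles along the beam direction. Phase symmetry
measures that evenness from a quadrature (even/odd) filter pair and is
therefore high on ridges and low on step edges, independently of local
contrast. The filter bank holds a single scale and a single orientation
(depth-aligned): long-bone surfaces present as gently curved, near-level
sheets, so one depth-oriented band-pass suffices.

Pipeline: :func:`preprocess_us` (depth-gain compensation + median filter) ->
:func:`phase_symmetry_3d` (response in [0, 1]) -> :func:`binarize_and_clean`
(threshold, border/skin/shell exclusions, area opening).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import ndimage
from .imaging_io import BinaryMask, Volume
from .shell_model import ShellModel

__all__ = [
    "PSConfig",
    "preprocess_us",
    "log_gabor_radial",
    "log_gabor_bank_3d",
    "phase_symmetry_3d",
    "binarize_and_clean",
]

log = logging.getLogger(__name__)


@dataclasses.dataclass
class PSConfig:
    """Phase-symmetry detector settings.

    center_wavelength_mm
        Band-pass center wavelength; defaults to 4 voxels' physical size at
        use time. Must be >= 2 voxels (sampling limit).
    bandwidth_ratio
        Log-Gabor sigma/f0 ratio on the log-frequency axis (0.55 ~ 2 octaves).
    orientation
        Unit 3-vector of the single filter orientation (depth axis default).
    angular_sigma_rad
        Gaussian angular spread around the orientation; wide by default so
        curved shell/bone surfaces up to ~45 degrees off-axis still respond.
    binarize_percentile
        Response percentile used as the binarization threshold.
    skin_band_mm
        Depth band below the transducer cleared of detections (skin layer).
    shell_exclusion_mm
        Tolerance for removing detections that delineate the bare shell
        surface (within this distance of the fitted cylinder).
    min_component_voxels
        Area-opening size: smaller 26-connected components are removed.
    noise_k, epsilon
        Noise compensation: responses below ``noise_k * mean local energy``
        are zeroed (the mean tracks the volume's overall energy scale even
        when most voxels are signal-free); ``epsilon`` (relative to mean
        energy) guards the normalization against division by zero.
    """

    center_wavelength_mm: float | None = None
    bandwidth_ratio: float = 0.55
    orientation: tuple[float, float, float] = (1.0, 0.0, 0.0)
    angular_sigma_rad: float = np.pi / 4
    binarize_percentile: float = 98.0
    skin_band_mm: float = 0.0
    shell_exclusion_mm: float = 0.6
    min_component_voxels: int = 30
    noise_k: float = 2.0
    epsilon: float = 1e-3

    def __post_init__(self) -> None:
        if not (0.0 < self.binarize_percentile < 100.0):
            raise ValueError("binarize_percentile must be in (0, 100)")
        for name in ("skin_band_mm", "shell_exclusion_mm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.center_wavelength_mm is not None and self.center_wavelength_mm <= 0:
            raise ValueError("center_wavelength_mm must be positive")
        if not (0.0 < self.bandwidth_ratio < 1.0):
            raise ValueError("bandwidth_ratio must be in (0, 1)")
        o = np.asarray(self.orientation, dtype=float)
        n = np.linalg.norm(o)
        if n == 0:
            raise ValueError("orientation must be a nonzero vector")
        self.orientation = tuple(o / n)
        if self.min_component_voxels < 0:
            raise ValueError("min_component_voxels must be >= 0")

    def wavelength_mm(self, voxel_mm: tuple[float, float, float]) -> float:
        if self.center_wavelength_mm is not None:
            return self.center_wavelength_mm
        return 4.0 * max(voxel_mm)


def preprocess_us(
    vol: Volume,
    median_size=(3, 3, 1),
    max_gain: float = 10.0,
    gain_smooth_mm: float = 1.5,
) -> Volume:
    """Normalize, depth-gain compensate and median-filter a B-mode volume.

    Depth-gain compensation equalizes the per-depth mean intensity, countering
    attenuation with depth. The gain curve is smoothed over ``gain_smooth_mm``
    along depth (roughly two band-pass wavelengths) so that compensation
    itself cannot imprint level structures the ridge detector would respond
    to, while still tracking smooth attenuation profiles, and
    clipped to ``[1/max_gain, max_gain]``. The 3x3x1 in-plane median
    suppresses impulse speckle without moving ridge centers. A constant
    volume is returned unchanged (nothing to enhance).
    """
    v = np.asarray(vol.values, dtype=np.float64)
    ptp = v.max() - v.min()
    if ptp == 0:
        log.warning("preprocess_us: constant volume, returned unchanged")
        return Volume(v.copy(), vol.voxel_mm, vol.origin_mm)
    v = (v - v.min()) / ptp
    depth_mean = v.mean(axis=(1, 2))
    if gain_smooth_mm > 0:
        sigma = gain_smooth_mm / vol.voxel_mm[0]
        depth_mean = ndimage.gaussian_filter1d(depth_mean, sigma, mode="nearest")
    target = depth_mean.mean()
    with np.errstate(divide="ignore", invalid="ignore"):
        gain = np.where(depth_mean > 0, target / depth_mean, 1.0)
    gain = np.clip(gain, 1.0 / max_gain, max_gain)
    v = v * gain[:, None, None]
    v = ndimage.median_filter(v, size=median_size)
    return Volume(v, vol.voxel_mm, vol.origin_mm)


def log_gabor_radial(f: np.ndarray, f0: float, sigma_ratio: float) -> np.ndarray:
    """Radial log-Gabor transfer G(f) = exp(-(log(f/f0))^2 / (2 log(s)^2)).

    Unit peak at f = f0, zero DC response, symmetric in log-frequency.
    """
    f = np.asarray(f, dtype=float)
    out = np.zeros_like(f)
    pos = f > 0
    out[pos] = np.exp(
        -(np.log(f[pos] / f0) ** 2) / (2.0 * np.log(sigma_ratio) ** 2)
    )
    return out


def log_gabor_bank_3d(
    shape: tuple[int, int, int],
    spacing_mm: tuple[float, float, float],
    cfg: PSConfig,
) -> np.ndarray:
    """Frequency-domain quadrature filter (single scale, single orientation).

    Returns the complex transfer function H on the FFT grid: applying
    ``ifftn(fftn(img) * H)`` yields the analytic response whose real part is
    the even (symmetric) and imaginary part the odd (antisymmetric) filter
    output. H keeps only the frequency half-space along ``cfg.orientation``
    (doubled), weighted by the radial log-Gabor and a Gaussian angular spread.
    """
    wavelength = cfg.wavelength_mm(tuple(spacing_mm))
    if wavelength < 2.0 * max(spacing_mm):
        raise ValueError(
            f"center wavelength {wavelength} mm is below the sampling limit "
            f"2 x {max(spacing_mm)} mm"
        )
    f0 = 1.0 / wavelength
    axes = [np.fft.fftfreq(n, d=sp) for n, sp in zip(shape, spacing_mm)]
    fd, fw, fs = np.meshgrid(*axes, indexing="ij", sparse=True)
    fmag = np.sqrt(fd**2 + fw**2 + fs**2)
    radial = log_gabor_radial(fmag, f0, cfg.bandwidth_ratio)
    o = np.asarray(cfg.orientation)
    proj = fd * o[0] + fw * o[1] + fs * o[2]
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.where(fmag > 0, proj / np.where(fmag > 0, fmag, 1.0), 0.0)
    angle = np.arccos(np.clip(np.abs(cosang), -1.0, 1.0))
    angular = np.exp(-(angle**2) / (2.0 * cfg.angular_sigma_rad**2))
    H = 2.0 * radial * angular * (proj > 0)
    return H.astype(np.complex128)


def phase_symmetry_3d(vol: Volume, cfg: PSConfig) -> Volume:
    """Per-voxel phase-symmetry response in [0, 1].

    sym = max(even - |odd| - T, 0) / (E + eps) with local energy
    E = sqrt(even^2 + odd^2) and noise floor T = noise_k * mean(E).
    Polarity-sensitive: only bright ridges (positive even response) count —
    bone interfaces are hyperechoic, and full-wave rectification would also
    fire on the dark side lobes of the band-pass response, producing striped
    false surfaces above the true one. The measure is contrast-normalized:
    rescaling the input by a positive factor leaves it unchanged down to the
    epsilon floor. The volume is reflect-padded by two wavelengths before the
    FFT so circular wrap-around cannot leak structure across borders.
    """
    wavelength = cfg.wavelength_mm(vol.voxel_mm)
    pads = tuple(
        min(n, int(np.ceil(2.0 * wavelength / sp)))
        for n, sp in zip(vol.values.shape, vol.voxel_mm)
    )
    padded = np.pad(vol.values, [(p, p) for p in pads], mode="reflect")
    H = log_gabor_bank_3d(padded.shape, vol.voxel_mm, cfg)
    resp = np.fft.ifftn(np.fft.fftn(padded) * H)
    crop = tuple(slice(p, p + n) for p, n in zip(pads, vol.values.shape))
    even = resp.real[crop]
    odd = resp.imag[crop]
    energy = np.hypot(even, odd)
    T = cfg.noise_k * energy.mean()
    num = np.maximum(even - np.abs(odd) - T, 0.0)
    denom = energy + cfg.epsilon * energy.mean() + 1e-300
    sym = np.clip(num / denom, 0.0, 1.0)
    return Volume(sym, vol.voxel_mm, vol.origin_mm)


def binarize_and_clean(
    response: Volume,
    cfg: PSConfig,
    shell: ShellModel | None = None,
    exclusion_mask: BinaryMask | None = None,
) -> BinaryMask:
    """Threshold the response and apply the exclusion rules.

    In order: percentile threshold; removal of components touching the
    lateral/longitudinal image borders; clearing of the skin band; removal of
    voxels delineating the bare shell surface (within ``shell_exclusion_mm``
    of the fitted cylinder, inside its axial extent); optional user exclusion
    mask (e.g. vessel lumina); 26-connected area opening. Cleanup only ever
    removes voxels from the thresholded mask.
    """
    r = np.asarray(response.values, dtype=float)
    if not np.any(r > 0):
        log.warning("binarize_and_clean: all-zero response, returning empty mask")
        return BinaryMask(np.zeros(r.shape, dtype=bool), response.voxel_mm, response.origin_mm)
    thr = float(np.percentile(r, cfg.binarize_percentile))
    mask = r > max(thr, 0.0)
    n_thresholded = int(mask.sum())

    # components touching lateral (axis 1) or longitudinal (axis 2) borders
    labels, _ = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    border_labels = np.unique(
        np.concatenate(
            [
                labels[:, 0, :].ravel(),
                labels[:, -1, :].ravel(),
                labels[:, :, 0].ravel(),
                labels[:, :, -1].ravel(),
            ]
        )
    )
    border_labels = border_labels[border_labels != 0]
    if border_labels.size:
        mask &= ~np.isin(labels, border_labels)

    if cfg.skin_band_mm > 0:
        depth_mm = response.axis_coords_mm(0)
        mask[depth_mm < cfg.skin_band_mm, :, :] = False

    if shell is not None and cfg.shell_exclusion_mm > 0:
        mask &= ~_near_shell(response, shell, cfg.shell_exclusion_mm)

    if exclusion_mask is not None:
        mask &= ~np.asarray(exclusion_mask.values, dtype=bool)

    if cfg.min_component_voxels > 1:
        mask = area_open(mask, cfg.min_component_voxels)
    log.info(
        "binarize_and_clean: threshold=%.4g, %d voxels thresholded, %d kept",
        thr,
        n_thresholded,
        int(mask.sum()),
    )
    return BinaryMask(mask, response.voxel_mm, response.origin_mm)


def area_open(mask: np.ndarray, min_voxels: int) -> np.ndarray:
    """Remove 26-connected components smaller than ``min_voxels``."""
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    if n == 0:
        return mask
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_voxels
    keep[0] = False
    return keep[labels]


def _near_shell(vol: Volume, shell: ShellModel, tol_mm: float) -> np.ndarray:
    """Voxels within tol of the shell outer surface, inside its axial extent."""
    nd, nw, ns = vol.values.shape
    d = vol.axis_coords_mm(0)
    w = vol.axis_coords_mm(1)
    z = vol.axis_coords_mm(2)
    p0 = np.asarray(shell.axis_point_mm)
    dirv = np.asarray(shell.axis_dir)
    D, W, Z = np.meshgrid(d, w, z, indexing="ij", sparse=True)
    rd = D - p0[0]
    rw = W - p0[1]
    rz = Z - p0[2]
    axial = rd * dirv[0] + rw * dirv[1] + rz * dirv[2]
    rad2 = (
        (rd - axial * dirv[0]) ** 2
        + (rw - axial * dirv[1]) ** 2
        + (rz - axial * dirv[2]) ** 2
    )
    rho = np.sqrt(rad2)
    near = np.abs(rho - shell.radius_mm) <= tol_mm
    inside_axial = (axial >= -tol_mm) & (axial <= shell.length_mm + tol_mm)
    return near & inside_axial
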