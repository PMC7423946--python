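"""New-bone segmentation in CT by Gaussian smoothing and Otsu thresholding.

The intensity threshold separating mineralized tissue from soft tissue is
estimated per scan from the defect zone — the axial range where native bone
is absent — so the native cortex cannot bias it. Intensities are sampled
from a radial band just outside the shell's outer surface (where deposits
form, surrounded by soft tissue), the Otsu criterion picks the threshold
maximizing between-class variance, and small remnants are cleared with an
area opening.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import ndimage

from .imaging_io import BinaryMask, Volume
from .shell_model import ShellModel

__all__ = ["CTSegConfig", "otsu_threshold", "segment_ct"]

log = logging.getLogger(__name__)


@dataclasses.dataclass
class CTSegConfig:
    """CT segmentation settings.

    defect_zone_mm
        (z_lo, z_hi) along the slice axis, volume coordinates: the axial
        range with no native bone, used for threshold sampling.
    sample_band_mm
        Radial band outside the shell surface, (inner, outer) offsets from
        radius R, from which threshold-sample intensities are drawn. The
        shell wall (rho <= R) is excluded.
    """

    gaussian_sigma_mm: float = 0.3
    defect_zone_mm: tuple[float, float] = (0.0, 0.0)
    min_component_voxels: int = 30
    n_bins: int = 256
    sample_band_mm: tuple[float, float] = (0.0, 8.0)

    def __post_init__(self) -> None:
        if self.gaussian_sigma_mm < 0:
            raise ValueError("gaussian_sigma_mm must be >= 0")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        lo, hi = self.defect_zone_mm
        if hi < lo:
            raise ValueError("defect_zone_mm must be (lo, hi) with lo <= hi")
        b0, b1 = self.sample_band_mm
        if not (0.0 <= b0 < b1):
            raise ValueError("sample_band_mm must satisfy 0 <= inner < outer")


def otsu_threshold(intensities: np.ndarray, n_bins: int = 256) -> float:
    """Histogram threshold maximizing between-class variance.

    The sample is binned over its range; every interior bin edge is a split
    candidate for maximizing w0*w1*(mu0 - mu1)^2. When several edges tie (a
    plateau, as happens with exactly two distinct values), the midpoint of
    the plateau is returned so the threshold falls between the classes
    rather than hugging the lower one. A constant sample has no separable
    classes and is rejected.
    """
    x = np.asarray(intensities, dtype=float).ravel()
    if x.size < 2 or np.unique(x).size < 2:
        raise ValueError("Otsu threshold undefined for a constant sample")
    counts, edges = np.histogram(x, bins=n_bins)
    counts = counts.astype(float)
    total = counts.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    w0 = np.cumsum(counts)[:-1]
    w1 = total - w0
    csum = np.cumsum(counts * centers)[:-1]
    tsum = (counts * centers).sum()
    valid = (w0 > 0) & (w1 > 0)
    mu0 = np.where(valid, csum / np.where(w0 > 0, w0, 1), 0.0)
    mu1 = np.where(valid, (tsum - csum) / np.where(w1 > 0, w1, 1), 0.0)
    sigma_b = np.where(valid, w0 * w1 * (mu0 - mu1) ** 2, -np.inf)
    best = sigma_b.max()
    ties = np.nonzero(sigma_b >= best * (1.0 - 1e-12))[0]
    k = int(round(0.5 * (ties[0] + ties[-1])))  # plateau midpoint
    return float(edges[k + 1])


def segment_ct(
    vol: Volume,
    cfg: CTSegConfig,
    shell: ShellModel,
    return_threshold: bool = False,
):
    """Segment new bone: smooth -> defect-zone Otsu threshold -> area opening.

    The Gaussian sigma is given in mm and converted per axis by the voxel
    spacing. The returned mask covers the whole volume; thresholding is
    global but the threshold itself comes only from the defect-zone sample.
    """
    sigma_vox = [cfg.gaussian_sigma_mm / s for s in vol.voxel_mm]
    smoothed = (
        ndimage.gaussian_filter(np.asarray(vol.values, dtype=float), sigma_vox)
        if cfg.gaussian_sigma_mm > 0
        else np.asarray(vol.values, dtype=float)
    )

    z = vol.axis_coords_mm(2)
    lo, hi = cfg.defect_zone_mm
    zsel = (z >= lo) & (z < hi)
    if not np.any(zsel):
        raise ValueError("defect zone selects no slices")
    rho = _radial_distance_grid(vol, shell)
    b0, b1 = cfg.sample_band_mm
    R = shell.radius_mm
    band = (rho > R + b0) & (rho <= R + b1)
    sample = smoothed[:, :, zsel][band[:, :, zsel]]
    if sample.size == 0:
        raise ValueError("defect-zone sample band selects no voxels")
    thr = otsu_threshold(sample, cfg.n_bins)
    log.info("segment_ct: Otsu threshold = %.4g from %d voxels", thr, sample.size)

    from .us_detect import area_open

    mask = smoothed >= thr
    if cfg.min_component_voxels > 1:
        mask = area_open(mask, cfg.min_component_voxels)
    out = BinaryMask(mask, vol.voxel_mm, vol.origin_mm)
    return (out, thr) if return_threshold else out


def _radial_distance_grid(vol: Volume, shell: ShellModel) -> np.ndarray:
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
    return np.sqrt(
        (rd - axial * dirv[0]) ** 2
        + (rw - axial * dirv[1]) ** 2
        + (rz - axial * dirv[2]) ** 2
    )
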