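"""Shared fixtures: small phantom scenes and synthetic curve masks."""

import math

import numpy as np
import pytest

from osteoquant import phantom as ph
from osteoquant.imaging_io import BinaryMask, FrameGeometry
from osteoquant.shell_model import ShellModel


SECTOR = dict(theta0=-math.pi / 4, theta1=math.pi / 4, thickness=2.0)


@pytest.fixture(scope="session")
def sector_config():
    """Quarter-circle deposit of 2 mm on a 10 mm shell, noise-free rendering."""
    return ph.PhantomConfig(
        shell_radius_mm=10.0,
        shell_length_mm=10.0,
        voxel_mm=0.2,
        grid_shape=(160, 144, 60),
        deposit_spans=((SECTOR["theta0"], SECTOR["theta1"], 0.5, 9.5, SECTOR["thickness"]),),
        speckle_snr=float("inf"),
        ct_noise_sd=0.0,
        skin_depth_mm=1.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def sector_scene(sector_config):
    return ph.build_scene(sector_config)


@pytest.fixture(scope="session")
def speckled_config(sector_config):
    """Same geometry with speckle SNR 4 and CT noise."""
    import dataclasses

    return dataclasses.replace(
        sector_config, speckle_snr=4.0, ct_noise_sd=30.0, seed=7
    )


def curve_mask_from_surface(
    radius_fn,
    shell: ShellModel,
    grid_shape=(160, 144, 1),
    voxel_mm=0.2,
    theta_range=(-math.pi / 2, math.pi / 2),
    slice_z_mm=None,
):
    """Rasterize a polar surface rho(theta) into a 1-slice curve mask.

    Dense theta sampling guarantees an 8-connected 1-2 px curve — a synthetic
    stand-in for a detected bone-surface band on a known geometry.
    """
    nd, nw, ns = grid_shape
    if slice_z_mm is None:
        slice_z_mm = shell.axis_point_mm[2] + 0.5 * shell.length_mm
    cd, cw = shell.cross_section_center(slice_z_mm)
    k = int(round((slice_z_mm) / voxel_mm))
    theta = np.linspace(theta_range[0], theta_range[1], 4000)
    rho0 = np.asarray(radius_fn(theta), dtype=float)
    keep = np.isfinite(rho0)
    theta, rho0 = theta[keep], rho0[keep]
    vals = np.zeros(grid_shape, dtype=bool)
    # a ~3-voxel-thick radial band, like a real detection, so the skeleton
    # centerline reproduces the surface without end erosion
    for dr in (-voxel_mm, 0.0, voxel_mm):
        rho = rho0 + dr
        rows = np.round((cd - rho * np.cos(theta)) / voxel_mm).astype(int)
        cols = np.round((cw + rho * np.sin(theta)) / voxel_mm).astype(int)
        ok = (rows >= 0) & (rows < nd) & (cols >= 0) & (cols < nw)
        vals[rows[ok], cols[ok], min(max(k, 0), ns - 1)] = True
    return BinaryMask(vals, (voxel_mm, voxel_mm, voxel_mm))


@pytest.fixture
def single_slice_shell():
    """Shell whose mid-length sits at the only slice of a 1-slice grid."""
    return ShellModel(
        axis_point_mm=(17.6, 14.4, -10.0),
        axis_dir=(0.0, 0.0, 1.0),
        radius_mm=10.0,
        length_mm=20.0,
    )


@pytest.fixture
def frame_32mm():
    return FrameGeometry(fov_width_mm=28.8, fov_depth_mm=32.0)
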