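"""End-to-end phantom study: simulate -> detect -> segment -> quantify -> stats.

One call renders two repeated US scans and a CT benchmark from a single
ground-truth scene, runs both detection paths, restricts to the common bone
range, computes per-slice morphometry for all three scans, averages the US
repeats, and summarizes repeatability (surface distance, Bland-Altman of the
normalized markers) and US-vs-CT agreement per region. The CLI ``run-all``
command and the reproduction script both use this code path.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Any

import numpy as np

from . import ct_segment, morphometry, phantom, stats, us_detect
from .imaging_io import FrameGeometry
from .shell_model import RegionPartition

log = logging.getLogger(__name__)


def default_ps_config(config: phantom.PhantomConfig) -> us_detect.PSConfig:
    """Detector settings matched to the phantom's rendering geometry."""
    # skin clearance covers the band-pass ringing below the skin layer
    wavelength = 4.0 * config.voxel_mm
    return us_detect.PSConfig(
        skin_band_mm=config.skin_depth_mm + 2.0 * wavelength,
        shell_exclusion_mm=3.0 * config.voxel_mm,
        min_component_voxels=30,
    )


def default_ct_config(config: phantom.PhantomConfig) -> ct_segment.CTSegConfig:
    lo, hi = config.defect_span
    z0 = config.shell_start_z_mm
    return ct_segment.CTSegConfig(
        defect_zone_mm=(z0 + lo, z0 + hi),
        sample_band_mm=(0.0, 8.0),
    )


def run_phantom_study(
    config: phantom.PhantomConfig,
    seed: int,
    ps_cfg: us_detect.PSConfig | None = None,
    ct_cfg: ct_segment.CTSegConfig | None = None,
    spline_cfg: morphometry.SplineConfig | None = None,
) -> dict[str, Any]:
    """Full chain on one synthetic scene; returns all intermediate products.

    ``seed`` drives every stochastic stage (speckle of both US renderings,
    CT noise) through fixed offsets, so identical (config, seed) pairs give
    identical results.
    """
    scene = phantom.build_scene(config)
    ps_cfg = ps_cfg or default_ps_config(config)
    ct_cfg = ct_cfg or default_ct_config(config)
    spline_cfg = spline_cfg or morphometry.SplineConfig()
    partition = RegionPartition()

    us1 = phantom.render_us(scene, config, seed=seed)
    us2 = phantom.render_us(scene, config, seed=seed + 1)
    ct = phantom.render_ct(scene, config, seed=seed + 2)
    frame = FrameGeometry.from_volume(us1)

    masks_us = []
    for us in (us1, us2):
        pre = us_detect.preprocess_us(us)
        resp = us_detect.phase_symmetry_3d(pre, ps_cfg)
        masks_us.append(us_detect.binarize_and_clean(resp, ps_cfg, shell=scene.shell))
    mask_ct, ct_threshold = ct_segment.segment_ct(
        ct, ct_cfg, scene.shell, return_threshold=True
    )

    mask_us1, mask_us2 = morphometry.common_range_restrict(masks_us[0], masks_us[1])

    prof_us1 = morphometry.profiles_from_mask(mask_us1)
    prof_us2 = morphometry.profiles_from_mask(mask_us2)
    mad_us = morphometry.mean_absolute_distance(prof_us1, prof_us2)

    slices_us1 = morphometry.quantify_scan(
        mask_us1, scene.shell, frame, spline_cfg, partition=partition, scan_id="us1"
    )
    slices_us2 = morphometry.quantify_scan(
        mask_us2, scene.shell, frame, spline_cfg, partition=partition, scan_id="us2"
    )
    # CT masks are solid bulk: quantify from the outer envelope, not a skeleton
    slices_ct = morphometry.quantify_scan(
        mask_ct, scene.shell, frame, spline_cfg, partition=partition, scan_id="ct",
        thin=False,
    )
    slices_us_avg = stats.average_repeats(slices_us1, slices_us2)

    # US-vs-US Bland-Altman over slices common to the two repeats
    z1 = {round(s.slice_z_mm, 6): s for s in slices_us1}
    z2 = {round(s.slice_z_mm, 6): s for s in slices_us2}
    common = sorted(set(z1) & set(z2))
    ba_us = {}
    for m in stats.NORMALIZED_MARKERS:
        diffs = [getattr(z1[k], m) - getattr(z2[k], m) for k in common]
        ba_us[m] = stats.bland_altman(diffs) if len(diffs) >= 2 else None

    # US-vs-CT per region, differences oriented CT - US
    za = {round(s.slice_z_mm, 6): s for s in slices_us_avg}
    zc = {round(s.slice_z_mm, 6): s for s in slices_ct}
    common_ct = sorted(set(za) & set(zc))
    mad_us_ct = None
    if common_ct:
        prof_ct = morphometry.profiles_from_mask(mask_ct, thin=False)
        zs = set(common_ct)
        mad_us_ct = morphometry.mean_absolute_distance(
            [p for p in prof_us1 if round(p.slice_z_mm, 6) in zs],
            [p for p in prof_ct if round(p.slice_z_mm, 6) in zs],
        )
    ba_ct: dict[str, dict[str, Any]] = {}
    ttest_ct: dict[str, dict[str, Any]] = {}
    for region in ("P", "M", "D"):
        keys = [k for k in common_ct if za[k].region == region]
        ba_ct[region] = {}
        ttest_ct[region] = {}
        for m in stats.NORMALIZED_MARKERS:
            us_vals = [getattr(za[k], m) for k in keys]
            ct_vals = [getattr(zc[k], m) for k in keys]
            if len(keys) >= 2:
                diffs = np.asarray(ct_vals) - np.asarray(us_vals)
                ba_ct[region][m] = stats.bland_altman(diffs)
                ttest_ct[region][m] = stats.paired_t_test(us_vals, ct_vals)
            else:
                ba_ct[region][m] = None
                ttest_ct[region][m] = None

    return {
        "scene": scene,
        "frame": frame,
        "volumes": {"us1": us1, "us2": us2, "ct": ct},
        "masks": {"us1": mask_us1, "us2": mask_us2, "ct": mask_ct},
        "ct_threshold": ct_threshold,
        "slices": {
            "us1": slices_us1,
            "us2": slices_us2,
            "ct": slices_ct,
            "us_avg": slices_us_avg,
        },
        "mad_us_us": mad_us,
        "mad_us_ct": mad_us_ct,
        "bland_altman_us_us": ba_us,
        "bland_altman_ct_us": ba_ct,
        "ttest_ct_us": ttest_ct,
    }


def summarize(result: dict[str, Any]) -> dict[str, Any]:
    """JSON-serializable summary of a phantom study result."""

    def ba_dict(r):
        return None if r is None else dataclasses.asdict(r)

    out: dict[str, Any] = {
        "ct_threshold": result["ct_threshold"],
        "n_slices": {k: len(v) for k, v in result["slices"].items()},
        "mad_us_us_mm": dataclasses.asdict(result["mad_us_us"]),
        "mad_us_ct_mm": (
            None
            if result["mad_us_ct"] is None
            else dataclasses.asdict(result["mad_us_ct"])
        ),
        "bland_altman_us_us": {
            m: ba_dict(r) for m, r in result["bland_altman_us_us"].items()
        },
        "bland_altman_ct_us": {
            reg: {m: ba_dict(r) for m, r in d.items()}
            for reg, d in result["bland_altman_ct_us"].items()
        },
        "ttest_ct_us": {
            reg: {m: (None if t is None else {"t": t[0], "p": t[1]}) for m, t in d.items()}
            for reg, d in result["ttest_ct_us"].items()
        },
    }
    return out
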