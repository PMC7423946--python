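"""Agreement statistics for morphometric markers.

Bland-Altman limits of agreement (fixed 1.96 normal multiplier, sample SD
with n-1 denominator), two-tailed Student's t-test on paired slice-wise
differences, per-region aggregation of normalized markers, and averaging of
repeated scans.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .morphometry import SliceMorphometry
from .shell_model import RegionPartition

__all__ = [
    "BlandAltmanResult",
    "StatsConfig",
    "bland_altman",
    "paired_t_test",
    "aggregate_regions",
    "average_repeats",
    "plot_bland_altman",
    "NORMALIZED_MARKERS",
]

log = logging.getLogger(__name__)

LOA_MULTIPLIER = 1.96

NORMALIZED_MARKERS = ("nbb_norm_pct", "nbs_norm", "nbc_norm_pct")


@dataclasses.dataclass(frozen=True)
class BlandAltmanResult:
    """Mean difference, its sample SD and the 95% limits of agreement."""

    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int


@dataclasses.dataclass(frozen=True)
class StatsConfig:
    alpha: float = 0.05
    paired: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")


def bland_altman(diffs: Sequence[float]) -> BlandAltmanResult:
    """Limits of agreement mean +/- 1.96 * SD of the paired differences."""
    d = np.asarray(diffs, dtype=float)
    if d.size < 2:
        raise ValueError("Bland-Altman analysis needs at least 2 differences")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        mean_diff=mean,
        sd_diff=sd,
        loa_low=mean - LOA_MULTIPLIER * sd,
        loa_high=mean + LOA_MULTIPLIER * sd,
        n=int(d.size),
    )


def paired_t_test(
    us_values: Sequence[float],
    ct_values: Sequence[float],
    cfg: StatsConfig | None = None,
) -> tuple[float, float]:
    """Two-tailed Student's t-test on d = ct - us; returns (t, p).

    Paired by default (slices are matched across modalities); set
    ``StatsConfig(paired=False)`` for the independent-samples variant. With
    zero variance of the differences, t is 0 (p = 1) for a zero mean and
    +/-inf (p = 0, with a warning) otherwise.
    """
    cfg = cfg or StatsConfig()
    us = np.asarray(us_values, dtype=float)
    ct = np.asarray(ct_values, dtype=float)
    if not cfg.paired:
        t, p = sps.ttest_ind(ct, us)
        return float(t), float(p)
    if us.shape != ct.shape:
        raise ValueError("paired test requires equal-length samples")
    n = us.size
    if n < 2:
        raise ValueError("t-test needs at least 2 pairs")
    d = ct - us
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return 0.0, 1.0
        log.warning("paired_t_test: zero variance with nonzero mean; p -> 0")
        return float(np.sign(d.mean()) * np.inf), 0.0
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = float(2.0 * sps.t.sf(abs(t), n - 1))
    return t, p


def aggregate_regions(
    slices: Sequence[SliceMorphometry],
    partition: RegionPartition | None = None,
) -> dict[str, dict[str, list[float]]]:
    """Group per-slice normalized markers by region label P/M/D.

    Slices labeled outside the partition (region 'X') are dropped.
    """
    del partition  # labels are attached at quantification time
    out: dict[str, dict[str, list[float]]] = {
        r: {m: [] for m in NORMALIZED_MARKERS} for r in ("P", "M", "D")
    }
    for s in slices:
        if s.region not in out:
            continue
        for m in NORMALIZED_MARKERS:
            out[s.region][m].append(getattr(s, m))
    return out


def average_repeats(
    scan1: Sequence[SliceMorphometry], scan2: Sequence[SliceMorphometry]
) -> list[SliceMorphometry]:
    """Element-wise mean of markers from two repeated scans, slice-aligned.

    Slices are matched on axial position; records present in only one scan
    are dropped with a warning.
    """
    key = lambda s: round(s.slice_z_mm, 6)
    m1 = {key(s): s for s in scan1}
    m2 = {key(s): s for s in scan2}
    common = sorted(set(m1) & set(m2))
    if len(common) < max(len(m1), len(m2)):
        log.warning(
            "average_repeats: slice sets differ (%d vs %d, %d common); "
            "restricted to the intersection",
            len(m1),
            len(m2),
            len(common),
        )
    out = []
    for k in common:
        a, b = m1[k], m2[k]
        out.append(
            SliceMorphometry(
                slice_z_mm=a.slice_z_mm,
                nbb_area_mm2=0.5 * (a.nbb_area_mm2 + b.nbb_area_mm2),
                nbs_length_mm=0.5 * (a.nbs_length_mm + b.nbs_length_mm),
                nbc_length_mm=0.5 * (a.nbc_length_mm + b.nbc_length_mm),
                nbb_norm_pct=0.5 * (a.nbb_norm_pct + b.nbb_norm_pct),
                nbs_norm=0.5 * (a.nbs_norm + b.nbs_norm),
                nbc_norm_pct=0.5 * (a.nbc_norm_pct + b.nbc_norm_pct),
                region=a.region,
                scan_id=f"avg({a.scan_id},{b.scan_id})",
            )
        )
    return out


def plot_bland_altman(
    values_a: Sequence[float],
    values_b: Sequence[float],
    path: str,
    label_a: str = "method A",
    label_b: str = "method B",
) -> BlandAltmanResult:
    """Bland-Altman scatter (difference vs mean) with limits of agreement."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    diffs = b - a
    res = bland_altman(diffs)
    means = 0.5 * (a + b)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(means, diffs, s=12, alpha=0.7)
    for y, style in ((res.mean_diff, "-"), (res.loa_low, "--"), (res.loa_high, "--")):
        ax.axhline(y, color="k", linestyle=style, linewidth=0.8)
    ax.set_xlabel(f"mean of {label_a} and {label_b}")
    ax.set_ylabel(f"{label_b} - {label_a}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return res
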