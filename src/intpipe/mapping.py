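"""Mass-univariate group comparison of INT maps.

Voxelwise two-sample t-maps, connected-component cluster extraction at an
uncorrected threshold with BH-FDR reported at cluster peaks, and ROI mean
extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from intpipe.timescale import IntMap

__all__ = [
    "StatMap",
    "ClusterRecord",
    "RoiMask",
    "voxelwise_ttest",
    "extract_clusters",
    "roi_mean",
]

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass
class StatMap:
    """Voxelwise t and two-sided p grids under a mask.

    ``df`` is a scalar for the pooled-variance test and a per-voxel grid for
    Welch.  Sign convention is group A minus group B.
    """

    t: np.ndarray
    p: np.ndarray
    df: float | np.ndarray
    mask: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))


@dataclass(frozen=True)
class ClusterRecord:
    """One supra-threshold connected component."""

    label: int
    size: int
    peak_mm: tuple[float, float, float]
    peak_ijk: tuple[int, int, int]
    peak_t: float
    fdr_q_at_peak: float


@dataclass
class RoiMask:
    """Named binary ROI within the brain mask."""

    name: str
    voxels: np.ndarray

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if not self.voxels.any():
            raise ValueError(f"ROI {self.name!r} is empty")


def _stack(maps: Sequence[IntMap]) -> np.ndarray:
    ref = maps[0]
    out = np.empty((len(maps), int(ref.mask.sum())))
    for i, m in enumerate(maps):
        if m.grid.shape != ref.grid.shape or not np.array_equal(m.mask, ref.mask):
            raise ValueError("all maps must share one grid and mask")
        out[i] = m.values
    return out


def voxelwise_ttest(
    maps_a: Sequence[IntMap],
    maps_b: Sequence[IntMap],
    variant: str = "pooled",
) -> StatMap:
    """Per-voxel two-sample t test between two lists of INT maps.

    ``variant`` is ``"pooled"`` (equal-variance, the mass-univariate
    convention) or ``"welch"``.  Positive t means group A larger.
    """
    if len(maps_a) < 2 or len(maps_b) < 2:
        raise ValueError("need at least 2 maps per group")
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown variant {variant!r}")
    ref = maps_a[0]
    a = _stack(list(maps_a) + list(maps_b))
    data_a, data_b = a[: len(maps_a)], a[len(maps_a) :]

    res = stats.ttest_ind(data_a, data_b, axis=0, equal_var=(variant == "pooled"))
    mask = ref.mask
    t_grid = np.full(mask.shape, np.nan)
    p_grid = np.full(mask.shape, np.nan)
    t_grid[mask] = res.statistic
    p_grid[mask] = res.pvalue
    if variant == "pooled":
        df: float | np.ndarray = float(len(maps_a) + len(maps_b) - 2)
    else:
        df = np.full(mask.shape, np.nan)
        df[mask] = res.df
    return StatMap(t=t_grid, p=p_grid, df=df, mask=mask, affine=ref.affine.copy())


def extract_clusters(
    stat: StatMap,
    p_thresh: float = 0.001,
    direction: str = "a_gt_b",
    connectivity: int = 18,
    min_cluster_size: int = 5,
) -> tuple[list[ClusterRecord], list[RoiMask], np.ndarray]:
    """Supra-threshold clusters of a t-map.

    Thresholds at ``p < p_thresh`` in the requested direction (``a_gt_b``
    keeps positive t), labels connected components under 6/18/26
    connectivity, drops components smaller than ``min_cluster_size`` and
    sorts by size descending (ties by peak |t| descending).  The peak is the
    in-cluster voxel with maximal |t|, reported in millimetres through the
    affine alongside the BH-FDR q-value computed over all in-mask voxel
    p-values.

    Returns ``(records, roi_masks, label_grid)`` where ``label_grid`` holds
    integer labels 1..k in sorted order (0 = background).
    """
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError(f"connectivity must be one of 6/18/26, got {connectivity}")
    if direction not in ("a_gt_b", "b_gt_a"):
        raise ValueError(f"unknown direction {direction!r}")
    mask = stat.mask
    sign_ok = stat.t > 0 if direction == "a_gt_b" else stat.t < 0
    with np.errstate(invalid="ignore"):
        supra = mask & sign_ok & (stat.p < p_thresh)

    # BH-FDR over every in-mask p-value, mapped back onto the grid
    q_grid = np.full(mask.shape, np.nan)
    q_grid[mask] = multipletests(stat.p[mask], method="fdr_bh")[1]

    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    labels, n_components = ndimage.label(supra, structure=structure)

    clusters = []
    for lab in range(1, n_components + 1):
        voxels = labels == lab
        size = int(voxels.sum())
        if size < min_cluster_size:
            continue
        idx = np.argwhere(voxels)
        t_vals = stat.t[voxels]
        peak_local = int(np.argmax(np.abs(t_vals)))
        peak_ijk = tuple(int(v) for v in idx[peak_local])
        peak_t = float(stat.t[peak_ijk])
        peak_mm = tuple(
            float(v) for v in (stat.affine @ np.array([*peak_ijk, 1.0]))[:3]
        )
        clusters.append((size, abs(peak_t), voxels, peak_ijk, peak_mm, peak_t))

    clusters.sort(key=lambda c: (-c[0], -c[1]))
    records: list[ClusterRecord] = []
    rois: list[RoiMask] = []
    label_grid = np.zeros(mask.shape, dtype=np.int32)
    for new_label, (size, _, voxels, peak_ijk, peak_mm, peak_t) in enumerate(
        clusters, start=1
    ):
        label_grid[voxels] = new_label
        records.append(
            ClusterRecord(
                label=new_label,
                size=size,
                peak_mm=peak_mm,
                peak_ijk=peak_ijk,
                peak_t=peak_t,
                fdr_q_at_peak=float(q_grid[peak_ijk]),
            )
        )
        rois.append(RoiMask(name=f"cluster{new_label:02d}", voxels=voxels))
    return records, rois, label_grid


def roi_mean(int_map: IntMap, roi: RoiMask) -> float:
    """Arithmetic mean INT (seconds) over the ROI's in-mask voxels."""
    if roi.voxels.shape != int_map.mask.shape:
        raise ValueError(
            f"ROI shape {roi.voxels.shape} != map shape {int_map.mask.shape}"
        )
    sel = roi.voxels & int_map.mask
    if not sel.any():
        raise ValueError(f"ROI {roi.name!r} does not intersect the map mask")
    return float(int_map.grid[sel].mean())
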