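"""The seven per-patient tumour-budding features.

Features (fixed order, used as cohort CSV column headers):

1. ``Number of TB in ten 0.785mm2 fields of view``  -- total bud count over
   the ten non-overlapping circular fields of view holding the most buds.
2. ``Number of TB in a single 0.785mm2 field of view`` -- the single hottest
   field.
3. ``Number of TB in ten 0.238mm2 fields of view`` -- as 1 with smaller
   fields.
4-7. Count and density (buds/mm^2) of buds in the tumour core and in the
   invasive front.

Fields of view are circular (0.785 mm^2 -> radius 500 um; 0.238 mm^2 ->
radius ~275.2 um), searched over a regular grid of candidate centres across
the whole image and selected greedily, hottest first, rejecting fields that
overlap an already selected one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .regions import ClusterSet, RegionPartition

#: Canonical feature order and spelling (cohort CSV headers).
FEATURE_NAMES = (
    "Number of TB in core",
    "Number of TB in invasive front",
    "Density of TB in core",
    "Density of TB in invasive front",
    "Number of TB in a single 0.785mm2 field of view",
    "Number of TB in ten 0.785mm2 fields of view",
    "Number of TB in ten 0.238mm2 fields of view",
)

FOV_AREA_LARGE_MM2 = 0.785
FOV_AREA_SMALL_MM2 = 0.238


@dataclass
class FovSpec:
    """Circular field-of-view specification for hotspot counting."""

    area_mm2: float
    k: int = 1
    stride_um: float | None = None  # default: radius / 2

    def __post_init__(self) -> None:
        if self.area_mm2 <= 0:
            raise ValueError("area_mm2 must be positive")
        if self.k < 1:
            raise ValueError("k must be >= 1")

    @property
    def radius_um(self) -> float:
        return math.sqrt(self.area_mm2 * 1e6 / math.pi)

    @property
    def grid_stride_um(self) -> float:
        return self.stride_um if self.stride_um is not None else self.radius_um / 2.0


@dataclass
class BudFeatureVector:
    n_tb_core: int
    n_tb_front: int
    density_tb_core: float
    density_tb_front: float
    n_tb_single_fov_0785: int
    n_tb_ten_fov_0785: int
    n_tb_ten_fov_0238: int
    empty_core: bool = False
    empty_front: bool = False

    def as_series(self) -> pd.Series:
        return pd.Series(
            {
                FEATURE_NAMES[0]: self.n_tb_core,
                FEATURE_NAMES[1]: self.n_tb_front,
                FEATURE_NAMES[2]: self.density_tb_core,
                FEATURE_NAMES[3]: self.density_tb_front,
                FEATURE_NAMES[4]: self.n_tb_single_fov_0785,
                FEATURE_NAMES[5]: self.n_tb_ten_fov_0785,
                FEATURE_NAMES[6]: self.n_tb_ten_fov_0238,
            }
        )


def hotspot_fovs(
    bud_xy_um: np.ndarray,
    extent_um: tuple[float, float],
    spec: FovSpec,
) -> tuple[int, list[tuple[float, float, int]]]:
    """Total bud count over the ``k`` hottest non-overlapping fields of view.

    Candidate field centres lie on a regular grid of step ``stride_um``
    covering the image extent; each candidate's count is the number of bud
    centroids within the field radius.  Fields are selected greedily by
    descending count (ties resolved in raster order of the grid); a candidate
    whose centre lies closer than one field diameter to an already selected
    centre is skipped.  Returns the summed count and the list of
    ``(cx_um, cy_um, count)`` selections.
    """
    w, h = extent_um
    if w <= 0 or h <= 0:
        raise ValueError("image extent must be positive")
    buds = np.asarray(bud_xy_um, float).reshape(-1, 2)
    if len(buds) == 0:
        return 0, []
    r = spec.radius_um
    stride = spec.grid_stride_um
    xs = np.arange(0.0, w + stride / 2, stride)
    ys = np.arange(0.0, h + stride / 2, stride)
    gx, gy = np.meshgrid(xs, ys)  # raster order: y-major
    centres = np.column_stack([gx.ravel(), gy.ravel()])
    tree = cKDTree(buds)
    counts = tree.query_ball_point(centres, r, return_length=True)
    order = np.argsort(-counts, kind="stable")  # stable keeps raster order on ties
    chosen: list[tuple[float, float, int]] = []
    for idx in order:
        c = int(counts[idx])
        if c == 0 or len(chosen) >= spec.k:
            break
        cx, cy = centres[idx]
        if all((cx - sx) ** 2 + (cy - sy) ** 2 >= (2 * r) ** 2 for sx, sy, _ in chosen):
            chosen.append((float(cx), float(cy), c))
    return sum(c for _, _, c in chosen), chosen


def region_features(
    bud_xy_px: np.ndarray,
    partition: RegionPartition,
) -> tuple[int, int, float, float, bool, bool]:
    """Bud counts and densities (buds/mm^2) in core and invasive front.

    A bud belongs to a region when its centroid pixel lies inside the
    region's mask.  Empty regions yield density 0 with an empty-region flag.
    """
    buds = np.asarray(bud_xy_px, float).reshape(-1, 2)
    h, w = partition.core.shape
    n_core = n_front = 0
    for x, y in buds:
        c, r = int(round(x)), int(round(y))
        if not (0 <= r < h and 0 <= c < w):
            continue
        if partition.core[r, c]:
            n_core += 1
        if partition.invasive_front[r, c]:
            n_front += 1
    area_core = partition.area_mm2("core")
    area_front = partition.area_mm2("front")
    empty_core = area_core == 0
    empty_front = area_front == 0
    d_core = 0.0 if empty_core else n_core / area_core
    d_front = 0.0 if empty_front else n_front / area_front
    return n_core, n_front, d_core, d_front, empty_core, empty_front


def compute_feature_vector(
    clusters: ClusterSet,
    partition: RegionPartition,
    fov_stride_um: float | None = None,
) -> BudFeatureVector:
    """Assemble the seven budding features from the image-analysis outputs."""
    if "is_bud" not in clusters.table:
        raise ValueError("missing upstream output: bud classification (classify_buds)")
    buds = clusters.bud_table()
    ps = clusters.pixel_size_um
    xy_px = buds[["centroid_x_px", "centroid_y_px"]].to_numpy(float)
    xy_um = xy_px * ps
    h, w = clusters.labels.shape
    extent = (w * ps, h * ps)
    n_core, n_front, d_core, d_front, empty_core, empty_front = region_features(xy_px, partition)
    single_785, _ = hotspot_fovs(xy_um, extent, FovSpec(FOV_AREA_LARGE_MM2, k=1, stride_um=fov_stride_um))
    ten_785, _ = hotspot_fovs(xy_um, extent, FovSpec(FOV_AREA_LARGE_MM2, k=10, stride_um=fov_stride_um))
    ten_238, _ = hotspot_fovs(xy_um, extent, FovSpec(FOV_AREA_SMALL_MM2, k=10, stride_um=fov_stride_um))
    return BudFeatureVector(
        n_tb_core=n_core,
        n_tb_front=n_front,
        density_tb_core=d_core,
        density_tb_front=d_front,
        n_tb_single_fov_0785=single_785,
        n_tb_ten_fov_0785=ten_785,
        n_tb_ten_fov_0238=ten_238,
        empty_core=empty_core,
        empty_front=empty_front,
    )
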