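"""Tumour-cell clusters, bud classification, and core/front morphology.

Tumour cell clusters are the connected components of the tumour mask.  A
cluster is a tumour bud when it contains between 1 and 4 detected nuclei
(clusters with 0 detected nuclei are treated as artefacts, not buds).  The
tumour core is the main tumour mass obtained by morphological closing of the
mask followed by removal of closed regions too small to be the core; the
invasive front is the 1000 um band straddling the core boundary (500 um
inside + 500 um outside), obtained by Euclidean dilation and erosion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt
from skimage.measure import label as cc_label, regionprops_table

from .nuclei import NucleusSet
from .segmentation import TumourMask

FRONT_WIDTH_UM = 500.0  # half-width of the invasive front band, per side


@dataclass
class ClusterSet:
    """Labelled tumour-cell clusters with per-cluster measurements.

    ``table`` has one row per cluster: label, area_um2, centroid_x_px,
    centroid_y_px, and once computed, nucleus_count and is_bud.
    """

    labels: np.ndarray
    pixel_size_um: float
    table: pd.DataFrame

    @property
    def n_clusters(self) -> int:
        return len(self.table)

    def bud_table(self) -> pd.DataFrame:
        if "is_bud" not in self.table:
            raise ValueError("buds not classified yet; run classify_buds")
        return self.table[self.table["is_bud"]]


@dataclass
class RegionPartition:
    """Binary core and invasive-front masks with physical resolution."""

    core: np.ndarray
    invasive_front: np.ndarray
    pixel_size_um: float
    border_width_um: float = 2 * FRONT_WIDTH_UM
    truncated: bool = False  # front band clipped by the image border

    def area_mm2(self, which: str) -> float:
        mask = self.core if which == "core" else self.invasive_front
        return float(mask.sum()) * self.pixel_size_um**2 / 1e6


def extract_clusters(mask: TumourMask | np.ndarray, connectivity: int = 2,
                     pixel_size_um: float | None = None) -> ClusterSet:
    """Connected components of the tumour mask (default 8-connectivity).

    Labels follow scan order, so the component whose first pixel is
    top-left-most gets label 1.
    """
    if isinstance(mask, TumourMask):
        arr, ps = mask.mask, mask.pixel_size_um
    else:
        arr = np.asarray(mask)
        if arr.dtype != bool and not np.isin(np.unique(arr), (0, 1)).all():
            raise ValueError("mask must be binary")
        arr = arr.astype(bool)
        if pixel_size_um is None:
            raise ValueError("pixel_size_um required for a bare array")
        ps = pixel_size_um
    if connectivity not in (1, 2):
        raise ValueError("connectivity must be 1 (4-conn) or 2 (8-conn)")
    labels = cc_label(arr, connectivity=connectivity)
    if labels.max() == 0:
        table = pd.DataFrame(columns=["label", "area_um2", "centroid_x_px", "centroid_y_px"])
    else:
        props = regionprops_table(labels, properties=("label", "area", "centroid"))
        table = pd.DataFrame(
            {
                "label": props["label"],
                "area_um2": props["area"] * ps * ps,
                "centroid_x_px": props["centroid-1"],
                "centroid_y_px": props["centroid-0"],
            }
        )
    return ClusterSet(labels, ps, table)


def count_nuclei_per_cluster(clusters: ClusterSet, nuclei: NucleusSet) -> ClusterSet:
    """Assign each nucleus to the cluster containing its centre pixel.

    Nuclei whose (rounded) centre falls on background are left unassigned.
    """
    labels = clusters.labels
    h, w = labels.shape
    counts = np.zeros(labels.max() + 1, dtype=int)
    for x, y in nuclei.centres:
        c, r = int(round(x)), int(round(y))
        if 0 <= r < h and 0 <= c < w:
            lab = labels[r, c]
            if lab > 0:
                counts[lab] += 1
    table = clusters.table.copy()
    table["nucleus_count"] = counts[table["label"].to_numpy(int)] if len(table) else pd.Series(dtype=int)
    return ClusterSet(labels, clusters.pixel_size_um, table)


def classify_buds(clusters: ClusterSet) -> ClusterSet:
    """Flag clusters containing between 1 and 4 nuclei as tumour buds.

    Idempotent; clusters with 0 detected nuclei are never buds.
    """
    if "nucleus_count" not in clusters.table:
        raise ValueError("nucleus counts missing; run count_nuclei_per_cluster first")
    table = clusters.table.copy()
    nc = table["nucleus_count"]
    table["is_bud"] = (nc >= 1) & (nc <= 4)
    return ClusterSet(clusters.labels, clusters.pixel_size_um, table)


# ---------------------------------------------------------------------------
# Euclidean morphology in physical units
# ---------------------------------------------------------------------------

def dilate_um(mask: np.ndarray, radius_um: float, pixel_size_um: float) -> np.ndarray:
    """Euclidean dilation by a physical radius (exact distance transform)."""
    mask = np.asarray(mask, bool)
    if radius_um <= 0 or not mask.any():
        return mask.copy()
    dist = distance_transform_edt(~mask, sampling=pixel_size_um)
    return dist <= radius_um


def erode_um(mask: np.ndarray, radius_um: float, pixel_size_um: float) -> np.ndarray:
    """Euclidean erosion by a physical radius."""
    mask = np.asarray(mask, bool)
    if radius_um <= 0 or not mask.any():
        return mask.copy()
    dist = distance_transform_edt(mask, sampling=pixel_size_um)
    return dist > radius_um


def closing_um(mask: np.ndarray, radius_um: float, pixel_size_um: float) -> np.ndarray:
    return erode_um(dilate_um(mask, radius_um, pixel_size_um), radius_um, pixel_size_um)


def detect_core(
    mask: TumourMask | np.ndarray,
    closing_radius_um: float = 100.0,
    min_core_area_um2: float = 5e5,
    pixel_size_um: float | None = None,
) -> np.ndarray:
    """Main tumour mass: morphological closing, then drop small closed regions.

    Closing bridges interstices narrower than the closing diameter between
    nearby clusters; components of the closed mask with area below
    ``min_core_area_um2`` (isolated buds, debris) are removed.
    """
    if isinstance(mask, TumourMask):
        arr, ps = mask.mask, mask.pixel_size_um
    else:
        arr = np.asarray(mask, bool)
        ps = pixel_size_um
        if ps is None:
            raise ValueError("pixel_size_um required for a bare array")
    closed = closing_um(arr, closing_radius_um, ps)
    # The EDT closing is extensive away from image borders but discretisation
    # can shave single boundary pixels; re-add the original mask pixels of
    # retained components to keep closing extensive on them.
    labels = cc_label(closed, connectivity=2)
    if labels.max() == 0:
        return np.zeros(arr.shape, bool)
    areas = np.bincount(labels.ravel())[1:] * ps * ps
    keep = np.flatnonzero(areas >= min_core_area_um2) + 1
    core = np.isin(labels, keep)
    core |= arr & dilate_um(core, 2 * ps, ps)
    return core


def detect_invasive_front(
    core: np.ndarray,
    pixel_size_um: float,
    width_um: float = FRONT_WIDTH_UM,
) -> tuple[np.ndarray, bool]:
    """Invasive front band: dilate(core, w) XOR erode(core, w).

    Returns the band and a flag that is True when the outer band would
    extend past the image border (the band is then truncated).
    """
    core = np.asarray(core, bool)
    if not core.any():
        return np.zeros(core.shape, bool), False
    dil = dilate_um(core, width_um, pixel_size_um)
    ero = erode_um(core, width_um, pixel_size_um)
    front = dil ^ ero
    w_px = int(np.ceil(width_um / pixel_size_um))
    border = np.zeros(core.shape, bool)
    border[:w_px, :] = border[-w_px:, :] = True
    border[:, :w_px] = border[:, -w_px:] = True
    truncated = bool((core & border).any())
    if truncated:
        warnings.warn("core lies within the front width of the image border; "
                      "invasive front band is truncated", stacklevel=2)
    return front, truncated


def build_partition(
    mask: TumourMask,
    closing_radius_um: float = 100.0,
    min_core_area_um2: float = 5e5,
    front_width_um: float = FRONT_WIDTH_UM,
    core_excludes_inner_front: bool = False,
) -> RegionPartition:
    """Convenience: core + invasive front from a tumour mask.

    By default the core is the full closed main mass, so it overlaps the
    inner half of the front band; ``core_excludes_inner_front`` supports
    the alternative reading where the core stops at the band's inner edge.
    """
    core = detect_core(mask, closing_radius_um, min_core_area_um2)
    front, truncated = detect_invasive_front(core, mask.pixel_size_um, front_width_um)
    if core_excludes_inner_front:
        core = core & ~front
    return RegionPartition(core, front, mask.pixel_size_um,
                           border_width_um=2 * front_width_um, truncated=truncated)
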