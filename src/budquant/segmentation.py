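"""Tumour (PanCK+ epithelium) mask segmentation.

The production pipeline the package models uses an ensemble of two trained
semantic-segmentation networks whose predictions are merged by pixel-wise
union.  Training such models needs manual annotations, so the segmenter here
is a *pluggable interface*: any object producing a :class:`TumourMask` from a
PanCK :class:`~budquant.image.ChannelImage` can be dropped in.  The shipped
:class:`ReferenceSegmenter` is a classical intensity pipeline
(background subtraction -> Gaussian smoothing -> global threshold -> small
hole removal -> small object removal) that is exact on the two-level
synthetic slides of :mod:`budquant.simulate`; the ensemble-by-union rule and
the Dice overlap metric are implemented exactly as used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import gaussian, threshold_otsu
from skimage.morphology import disk, binary_opening
from sklearn.base import BaseEstimator

from .image import PANCK, ChannelImage


@dataclass
class TumourMask:
    """Binary tumour mask aligned with its source channel."""

    mask: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        if self.mask.dtype != bool:
            vals = np.unique(self.mask)
            if not np.isin(vals, (0, 1)).all():
                raise ValueError("mask must be binary")
            self.mask = self.mask.astype(bool)
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def area_um2(self) -> float:
        return float(self.mask.sum()) * self.pixel_size_um**2


class ReferenceSegmenter(BaseEstimator):
    """Classical reference tumour segmenter.

    Parameters
    ----------
    smooth_sigma_um : Gaussian smoothing scale before thresholding (um).
    threshold : ``"otsu"`` for a parameter-free global threshold, or a fixed
        float applied to the background-subtracted, smoothed image.
    background : ``"min"`` subtracts the image minimum (makes the fixed
        threshold mode invariant to additive intensity shifts), or ``None``.
    min_area_um2 : objects smaller than this are removed (debris).
    max_hole_area_um2 : holes smaller than this are filled.  Kept small by
        default so that genuine gaps between a tumour mass and a bud sitting
        in one of its concavities are preserved.
    opening_radius_um : optional morphological opening radius applied as a
        final contour-regularisation step; 0 disables it.
    """

    def __init__(
        self,
        smooth_sigma_um: float = 1.0,
        threshold: str | float = "otsu",
        background: str | None = "min",
        min_area_um2: float = 50.0,
        max_hole_area_um2: float = 100.0,
        opening_radius_um: float = 0.0,
    ) -> None:
        self.smooth_sigma_um = smooth_sigma_um
        self.threshold = threshold
        self.background = background
        self.min_area_um2 = min_area_um2
        self.max_hole_area_um2 = max_hole_area_um2
        self.opening_radius_um = opening_radius_um

    def fit(self, X=None, y=None) -> "ReferenceSegmenter":
        # Stateless: nothing is learnt from data.
        return self

    def segment(self, panck: ChannelImage) -> TumourMask:
        if panck.channel_name != PANCK:
            raise ValueError("segmenter expects the PanCK channel")
        img = panck.pixels
        if np.any(img < 0):
            raise ValueError("negative pixel values")
        ps = panck.pixel_size_um
        if np.ptp(img) == 0:
            # Constant image: no contrast, nothing to segment.
            return TumourMask(np.zeros(img.shape, bool), ps)
        if self.background == "min":
            img = img - img.min()
        elif self.background is not None:
            raise ValueError(f"unknown background mode {self.background!r}")
        sigma_px = self.smooth_sigma_um / ps
        if sigma_px > 0:
            img = gaussian(img, sigma=sigma_px, preserve_range=True)
        if self.threshold == "otsu":
            thr = threshold_otsu(img)
        else:
            thr = float(self.threshold)
        mask = img > thr
        px_area = ps * ps
        if self.max_hole_area_um2 > 0:
            mask = _fill_small_holes(mask, self.max_hole_area_um2 / px_area)
        if self.min_area_um2 > 0:
            mask = _drop_small_objects(mask, self.min_area_um2 / px_area)
        if self.opening_radius_um > 0:
            mask = binary_opening(mask, disk(max(1, round(self.opening_radius_um / ps))))
        return TumourMask(mask, ps)

    def transform(self, X: ChannelImage) -> TumourMask:
        return self.segment(X)


def segment_reference(panck: ChannelImage, **params) -> TumourMask:
    """Functional wrapper around :class:`ReferenceSegmenter`."""
    return ReferenceSegmenter(**params).segment(panck)


def _fill_small_holes(mask: np.ndarray, max_area_px: float) -> np.ndarray:
    """Fill enclosed background regions strictly smaller than ``max_area_px``."""
    lab, n = ndi.label(~mask)
    if n == 0:
        return mask
    areas = np.bincount(lab.ravel())
    border_labels = np.unique(np.concatenate([
        lab[0, :], lab[-1, :], lab[:, 0], lab[:, -1]
    ]))
    fill = np.zeros(n + 1, bool)
    fill[1:] = areas[1:] < max_area_px
    fill[border_labels] = False
    return mask | fill[lab]


def _drop_small_objects(mask: np.ndarray, min_area_px: float) -> np.ndarray:
    """Remove 8-connected foreground components smaller than ``min_area_px``."""
    lab, n = ndi.label(mask, structure=np.ones((3, 3), int))
    if n == 0:
        return mask
    areas = np.bincount(lab.ravel())
    keep = np.zeros(n + 1, bool)
    keep[1:] = areas[1:] >= min_area_px
    return keep[lab]


def _check_pair(a: TumourMask, b: TumourMask) -> None:
    if a.mask.shape != b.mask.shape:
        raise ValueError(f"mask shapes differ: {a.mask.shape} vs {b.mask.shape}")
    if not np.isclose(a.pixel_size_um, b.pixel_size_um):
        raise ValueError("mask resolutions differ")


def ensemble_union(mask_a: TumourMask, mask_b: TumourMask) -> TumourMask:
    """Merge two segmenters' masks by pixel-wise logical OR.

    This is the ensembling rule used to combine the two tumour-mask models:
    a pixel is tumour if either model calls it tumour.
    """
    _check_pair(mask_a, mask_b)
    return TumourMask(mask_a.mask | mask_b.mask, mask_a.pixel_size_um)


def dice_score(mask_a, mask_b) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    a = mask_a.mask if isinstance(mask_a, TumourMask) else np.asarray(mask_a, bool)
    b = mask_b.mask if isinstance(mask_b, TumourMask) else np.asarray(mask_b, bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        return 1.0
    inter = int(np.logical_and(a, b).sum())
    return 2.0 * inter / total
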