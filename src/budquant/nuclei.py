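"""Nucleus centre detection from the Hoechst channel.

The detection contract has two stages.  First, two per-pixel *prediction
maps* are produced: a proximity map whose local maxima sit on nucleus
centres, and a size map giving the expected nucleus radius (um) at each
pixel.  In the modelled production system both maps come from regression
random forests trained on annotated nuclei; here a classical reference
generator stands in: the proximity map is a scale-normalised
Laplacian-of-Gaussian (blob) response at the configured nucleus scale and
the size map is constant.  Second, a deterministic local-maxima algorithm
turns the maps into centres, suppressing any maximum lying within
``separation_factor x predicted radius`` of a stronger one (greedy,
strongest first, ties broken in raster order).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_laplace
from skimage.feature import peak_local_max
from sklearn.base import BaseEstimator

from .image import HOECHST, ChannelImage


@dataclass
class PredictionMaps:
    """Pixel-wise proximity-to-centre and nucleus-size (um) maps."""

    proximity: np.ndarray
    size_um: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.proximity = np.asarray(self.proximity, float)
        self.size_um = np.asarray(self.size_um, float)
        if self.proximity.shape != self.size_um.shape:
            raise ValueError("map shapes differ")


@dataclass
class NucleusSet:
    """Detected nucleus centres (x, y) in pixel coordinates with radii in um."""

    centres: np.ndarray  # (N, 2) float, columns x, y
    radii_um: np.ndarray  # (N,)

    def __post_init__(self) -> None:
        self.centres = np.asarray(self.centres, float).reshape(-1, 2)
        self.radii_um = np.asarray(self.radii_um, float).reshape(-1)
        if len(self.centres) != len(self.radii_um):
            raise ValueError("centres and radii length mismatch")

    def __len__(self) -> int:
        return len(self.centres)


class NucleusDetector(BaseEstimator):
    """Reference nucleus detector (LoG proximity map + local maxima).

    Parameters
    ----------
    nucleus_radius_um : expected nucleus radius; sets the LoG scale
        (sigma = radius / 2, matching Gaussian-blob-like nuclei) and the
        constant size map.
    floor_quantile : detection floor as a quantile of the proximity map
        (robust to global intensity scaling).
    floor_rel : additional floor as a fraction of the peak proximity
        response; guards against noise maxima when nuclei cover far less
        than ``1 - floor_quantile`` of the image.  The effective floor is
        the larger of the two.
    floor_abs : absolute floor overriding both when given.
    separation_factor : multiple of the predicted radius within which a
        weaker maximum is suppressed by a stronger one.
    """

    def __init__(
        self,
        nucleus_radius_um: float = 4.0,
        floor_quantile: float = 0.99,
        floor_rel: float = 0.2,
        floor_abs: float | None = None,
        separation_factor: float = 1.0,
    ) -> None:
        self.nucleus_radius_um = nucleus_radius_um
        self.floor_quantile = floor_quantile
        self.floor_rel = floor_rel
        self.floor_abs = floor_abs
        self.separation_factor = separation_factor

    def fit(self, X=None, y=None) -> "NucleusDetector":
        return self

    def predict_maps(self, hoechst: ChannelImage) -> PredictionMaps:
        """Reference prediction maps for the two-map detection contract."""
        if hoechst.channel_name != HOECHST:
            raise ValueError("detector expects the Hoechst channel")
        ps = hoechst.pixel_size_um
        sigma_px = (self.nucleus_radius_um / 2.0) / ps
        # Scale-normalised negative LoG: positive peaks at blob centres.
        resp = -(sigma_px**2) * gaussian_laplace(hoechst.pixels, sigma=sigma_px)
        resp = np.clip(resp, 0.0, None)
        peak = resp.max()
        if peak > 0:
            resp = resp / peak
        size = np.full(resp.shape, float(self.nucleus_radius_um))
        return PredictionMaps(resp, size, ps)

    def detect(self, hoechst: ChannelImage) -> NucleusSet:
        maps = self.predict_maps(hoechst)
        return local_maxima_detect(
            maps,
            floor_quantile=self.floor_quantile,
            floor_rel=self.floor_rel,
            floor_abs=self.floor_abs,
            separation_factor=self.separation_factor,
        )

    def transform(self, X: ChannelImage) -> NucleusSet:
        return self.detect(X)


def reference_maps(hoechst: ChannelImage, **params) -> PredictionMaps:
    return NucleusDetector(**params).predict_maps(hoechst)


def local_maxima_detect(
    maps: PredictionMaps,
    floor_quantile: float = 0.99,
    floor_rel: float = 0.2,
    floor_abs: float | None = None,
    separation_factor: float = 1.0,
) -> NucleusSet:
    """Turn prediction maps into nucleus centres.

    All strict local maxima of the proximity map above the floor are ranked
    strongest first (ties in raster order) and accepted greedily; a candidate
    closer than ``separation_factor x predicted radius`` (of the already
    accepted, stronger centre) is suppressed.
    """
    prox = maps.proximity
    if floor_abs is not None:
        floor = float(floor_abs)
    else:
        floor = max(float(np.quantile(prox, floor_quantile)),
                    floor_rel * float(prox.max()))
    coords = peak_local_max(
        prox, min_distance=1, threshold_abs=np.nextafter(floor, np.inf), exclude_border=False
    )
    if len(coords) == 0:
        return NucleusSet(np.empty((0, 2)), np.empty(0))
    vals = prox[coords[:, 0], coords[:, 1]]
    order = np.lexsort((coords[:, 1], coords[:, 0], -vals))
    coords = coords[order]
    kept_rc: list[np.ndarray] = []
    kept_r_px: list[float] = []
    ps = maps.pixel_size_um
    for rc in coords:
        r_um = maps.size_um[rc[0], rc[1]]
        ok = True
        for krc, kr in zip(kept_rc, kept_r_px):
            if np.hypot(*(rc - krc)) < separation_factor * kr:
                ok = False
                break
        if ok:
            kept_rc.append(rc)
            kept_r_px.append(r_um / ps)
    kept = np.array(kept_rc, float)
    centres_xy = kept[:, ::-1]  # (row, col) -> (x, y)
    radii = maps.size_um[kept[:, 0].astype(int), kept[:, 1].astype(int)]
    return NucleusSet(centres_xy, radii)
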