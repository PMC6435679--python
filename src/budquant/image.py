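"""Fluorescence channel rasters and two-channel TIFF I/O.

A slide is represented as two aligned single-channel rasters: a PanCK
(pan-cytokeratin) channel highlighting epithelial/tumour cells and a Hoechst
channel highlighting nuclei.  Physical resolution travels with the pixels as
micrometres per pixel so that all downstream morphology (500 um bands,
0.785 mm^2 fields of view) can be expressed in physical units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import tifffile

PANCK = "PanCK"
HOECHST = "Hoechst"


@dataclass
class ChannelImage:
    """One fluorescence channel with physical pixel size.

    Parameters
    ----------
    pixels : 2-D float array, non-negative intensities.
    pixel_size_um : physical edge length of one pixel in micrometres.
    channel_name : ``"PanCK"`` or ``"Hoechst"``.
    """

    pixels: np.ndarray
    pixel_size_um: float
    channel_name: str

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D raster")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixel values must be finite")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        if self.channel_name not in (PANCK, HOECHST):
            raise ValueError(f"unknown channel_name {self.channel_name!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def extent_um(self) -> tuple[float, float]:
        """(width, height) of the imaged area in micrometres."""
        h, w = self.pixels.shape
        return (w * self.pixel_size_um, h * self.pixel_size_um)


def write_two_channel_tiff(path, panck: ChannelImage, hoechst: ChannelImage) -> None:
    """Write a (2, H, W) TIFF with micron resolution metadata (ImageJ style)."""
    if panck.shape != hoechst.shape:
        raise ValueError("channel shapes differ")
    if panck.pixel_size_um != hoechst.pixel_size_um:
        raise ValueError("channel pixel sizes differ")
    stack = np.stack([panck.pixels, hoechst.pixels]).astype(np.float32)
    ppu = 1.0 / panck.pixel_size_um  # pixels per micron
    tifffile.imwrite(
        path,
        stack,
        imagej=True,
        resolution=(ppu, ppu),
        metadata={"unit": "um", "axes": "CYX"},
    )


def read_two_channel_tiff(path, pixel_size_um: float | None = None) -> tuple[ChannelImage, ChannelImage]:
    """Read a 2-channel TIFF written by :func:`write_two_channel_tiff`.

    Resolution is taken from the TIFF tags; ``pixel_size_um`` overrides it and
    is required when the file carries no resolution metadata.
    """
    with tifffile.TiffFile(path) as tif:
        stack = tif.asarray()
        ps = _pixel_size_from_tags(tif)
    if ps is None:
        ps = pixel_size_um
    if ps is None:
        raise ValueError(
            f"{path}: no resolution metadata found; pass pixel_size_um explicitly"
        )
    if stack.ndim != 3 or stack.shape[0] != 2:
        raise ValueError(f"{path}: expected a (2, H, W) stack, got {stack.shape}")
    return (
        ChannelImage(stack[0], ps, PANCK),
        ChannelImage(stack[1], ps, HOECHST),
    )


def _pixel_size_from_tags(tif: "tifffile.TiffFile") -> float | None:
    """Micrometres per pixel from the TIFF tags, or None when the file
    records no physical unit (a unitless XResolution tag is ignored)."""
    page = tif.pages[0]
    tag = page.tags.get("XResolution")
    if tag is None:
        return None
    num, den = tag.value
    if num == 0:
        return None
    ppu = num / den  # pixels per unit
    meta = tif.imagej_metadata or {}
    unit = meta.get("unit")
    if unit is not None:
        scale = {"um": 1.0, "micron": 1.0, "µm": 1.0, "mm": 1e3, "cm": 1e4}.get(unit)
        return None if scale is None else scale / ppu
    res_unit = page.tags.get("ResolutionUnit")
    if res_unit is None:
        return None
    value = getattr(res_unit.value, "value", res_unit.value)
    if value == 3:  # centimetre
        return 1e4 / ppu
    if value == 2:  # inch
        return 25400.0 / ppu
    return None  # no physical unit recorded


def write_mask_tiff(path, mask: np.ndarray, pixel_size_um: float) -> None:
    """Write a binary mask as single-channel 8-bit TIFF (255 = foreground)."""
    ppu = 1.0 / pixel_size_um
    tifffile.imwrite(
        path,
        (np.asarray(mask, bool) * np.uint8(255)),
        imagej=True,
        resolution=(ppu, ppu),
        metadata={"unit": "um"},
    )


def write_label_tiff(path, labels: np.ndarray, pixel_size_um: float) -> None:
    ppu = 1.0 / pixel_size_um
    tifffile.imwrite(
        path,
        np.asarray(labels, dtype=np.uint16),
        imagej=True,
        resolution=(ppu, ppu),
        metadata={"unit": "um"},
    )
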