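"""End-to-end quantification of one slide and run manifests."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np

from .config import RunConfig
from .features import BudFeatureVector, compute_feature_vector
from .image import ChannelImage
from .nuclei import NucleusDetector, NucleusSet
from .regions import (
    ClusterSet,
    RegionPartition,
    build_partition,
    classify_buds,
    count_nuclei_per_cluster,
    extract_clusters,
)
from .segmentation import ReferenceSegmenter, TumourMask, ensemble_union


@dataclass
class QuantifyResult:
    features: BudFeatureVector
    mask: TumourMask
    nuclei: NucleusSet
    clusters: ClusterSet
    partition: RegionPartition


def quantify_image(
    panck: ChannelImage,
    hoechst: ChannelImage,
    config: RunConfig | None = None,
    segmenter=None,
    second_segmenter=None,
) -> QuantifyResult:
    """Segment, detect, classify and featurise one two-channel slide.

    ``segmenter``/``second_segmenter`` may be any objects with a
    ``segment(panck) -> TumourMask`` method; when two are given their masks
    are merged by union (the ensemble rule).  Defaults to the classical
    reference segmenter alone.
    """
    cfg = config or RunConfig(pixel_size_um=panck.pixel_size_um)
    if segmenter is None:
        segmenter = ReferenceSegmenter(
            smooth_sigma_um=cfg.smooth_sigma_um,
            threshold=cfg.threshold,
            min_area_um2=cfg.min_area_um2,
            max_hole_area_um2=cfg.max_hole_area_um2,
            opening_radius_um=cfg.opening_radius_um,
        )
    mask = segmenter.segment(panck)
    if second_segmenter is not None:
        mask = ensemble_union(mask, second_segmenter.segment(panck))
    detector = NucleusDetector(
        nucleus_radius_um=cfg.nucleus_radius_um,
        floor_quantile=cfg.floor_quantile,
        separation_factor=cfg.separation_factor,
    )
    nuclei = detector.detect(hoechst)
    clusters = extract_clusters(mask, connectivity=cfg.connectivity)
    clusters = count_nuclei_per_cluster(clusters, nuclei)
    clusters = classify_buds(clusters)
    partition = build_partition(
        mask,
        closing_radius_um=cfg.closing_radius_um,
        min_core_area_um2=cfg.min_core_area_um2,
        front_width_um=cfg.front_width_um,
        core_excludes_inner_front=cfg.core_excludes_inner_front,
    )
    features = compute_feature_vector(clusters, partition, fov_stride_um=cfg.fov_stride_um)
    return QuantifyResult(features, mask, nuclei, clusters, partition)


def file_checksum(path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()[:16]


def write_manifest(path, config: RunConfig, inputs: dict[str, str], outputs: list[str]) -> None:
    """Record config hash + input checksums so a run is reproducible."""
    import budquant

    manifest = {
        "budquant_version": budquant.__version__,
        "config_hash": config.hash(),
        "inputs": inputs,
        "outputs": outputs,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
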