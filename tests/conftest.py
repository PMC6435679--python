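"""Shared fixtures: synthetic slides and cohorts generated at test time."""

import numpy as np
import pytest

import budquant as bq

# Test-scale slide: 768 px at 2 um/px (1.54 mm field), nuclei of 8 um radius,
# morphology scaled consistently (closing 40 um, min core area 0.02 mm^2).
SLIDE_PARAMS = dict(
    width_px=768,
    height_px=768,
    pixel_size_um=2.0,
    n_masses=3,
    n_buds=10,
    nucleus_radius_um=8.0,
    closing_radius_um=40.0,
)

PIPELINE_KW = dict(
    pixel_size_um=2.0,
    nucleus_radius_um=8.0,
    closing_radius_um=40.0,
    min_core_area_um2=2e4,
    smooth_sigma_um=2.0,
)


@pytest.fixture(scope="session")
def slide():
    """Clean (noise-free, artefact-free) synthetic slide with ground truth."""
    params = bq.ImageSimParams(**SLIDE_PARAMS, seed=1)
    panck, hoechst, truth = bq.generate_if_image(params)
    return params, panck, hoechst, truth


@pytest.fixture(scope="session")
def pipeline_cfg():
    return bq.RunConfig(**PIPELINE_KW)


@pytest.fixture(scope="session")
def quantified(slide, pipeline_cfg):
    """Full pipeline result on the clean slide."""
    _, panck, hoechst, _ = slide
    return bq.quantify_image(panck, hoechst, pipeline_cfg)


@pytest.fixture(scope="session")
def cohort100():
    return bq.generate_cohort(bq.CohortSimParams(n_patients=100, seed=3))


@pytest.fixture(scope="session")
def fitted_tree(cohort100):
    """LOO pre-validated survival tree on the default synthetic cohort."""
    return bq.SurvivalTree().fit(cohort100)


def match_planted_clusters(truth, clusters):
    """Map planted cluster labels to detected labels via raster overlap.

    Returns {planted_label: detected_label}; asserts the mapping is a
    bijection (each planted cluster is one detected component).
    """
    mapping = {}
    for lab in truth.nucleus_counts:
        sel = truth.cluster_labels == lab
        det = np.unique(clusters.labels[sel])
        det = det[det > 0]
        assert len(det) == 1, f"planted cluster {lab} maps to {det}"
        mapping[lab] = int(det[0])
    assert len(set(mapping.values())) == len(mapping)
    return mapping
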