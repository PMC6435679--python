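"""Synthetic two-channel IF slides and survival cohorts with ground truth.

Every downstream stage of the package is testable without external data:

* :func:`generate_if_image` renders a PanCK + Hoechst channel pair with a
  planted tumour geometry.  Large masses (clusters with more than 4 nuclei)
  form the main tumour mass; buds (1-4 nuclei) are planted both *inside* the
  mass (sitting in punched-out concavities that morphological closing
  bridges, so they fall in the detected core) and in a peritumoural band
  outside it (so they fall in the invasive front).  Nuclei are isotropic
  Gaussian blobs (sigma = nucleus radius / 2); optional artefacts are
  high-intensity PanCK blobs containing no nuclei, exercising the rule that
  0-nucleus clusters are not buds.  Clusters are separated by at least two
  nucleus radii so connected components recover the planted cluster set
  exactly.

* :func:`generate_cohort` draws a per-patient table with the covariate
  prevalences of the modelled bladder-cancer cohort (TNM II 25% / IIIA 41% /
  IIIB 4% / IV 30%, metastasis iff stage IV, 54% disease-specific deaths),
  a budding burden that rises with stage (log-normal per stage), and
  proportional-hazards survival: hazard = baseline x exp(beta_met * 1[IV] +
  beta_tb * 1[TB > cutoff]) with uniform independent censoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import cohort as C
from .features import FEATURE_NAMES
from .image import HOECHST, PANCK, ChannelImage


class PlacementError(RuntimeError):
    """Image too small / too crowded to place the requested objects."""


@dataclass
class ImageSimParams:
    """Geometry and rendering parameters for one synthetic slide.

    Distances are physical (um).  ``closing_radius_um`` is carried here so
    the planted core/front ground truth and the analysis morphology agree:
    in-core buds sit in moats (width = 2 x nucleus radius) that closing
    bridges; peritumoural buds keep a gap wider than twice the closing
    radius so they never merge into the core.
    """

    width_px: int = 3072
    height_px: int = 3072
    pixel_size_um: float = 0.5  # 20x-objective scale; configurable
    n_masses: int = 3
    n_buds: int = 12
    bud_nucleus_range: tuple[int, int] = (1, 4)
    nucleus_radius_um: float = 4.0
    noise_sd: float = 0.0
    artefact_fraction: float = 0.0
    seed: int = 0
    core_bud_fraction: float = 0.5
    closing_radius_um: float = 40.0
    front_width_um: float = 500.0
    n_stromal_nuclei: int = 0
    mass_nucleus_range: tuple[int, int] = (6, 12)

    def __post_init__(self) -> None:
        lo, hi = self.bud_nucleus_range
        if not (1 <= lo <= hi <= 4):
            raise ValueError("bud_nucleus_range must lie within [1, 4]")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.n_masses < 0 or self.n_buds < 0:
            raise ValueError("object counts must be non-negative")
        if not 0 <= self.artefact_fraction <= 1:
            raise ValueError("artefact_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class ImageGroundTruth:
    """Planted truth for one synthetic slide.

    ``cluster_labels`` labels the planted tumour clusters (masses + buds) and
    coincides with the 8-connected components of ``tumour_mask``;
    ``nucleus_counts[label]`` is the planted nucleus count per cluster;
    ``bud_region[label]`` is ``"core"`` or ``"front"`` for planted buds.
    Artefact blobs appear in the PanCK channel only and are recorded in
    ``artefact_mask`` (not part of the tumour truth).
    """

    tumour_mask: np.ndarray
    nucleus_centres: np.ndarray  # (N, 2) float, columns x, y (px)
    nucleus_is_stromal: np.ndarray
    cluster_labels: np.ndarray
    bud_cluster_ids: set
    nucleus_counts: dict
    bud_region: dict
    artefact_mask: np.ndarray
    core_truth: np.ndarray | None = None  # closing of the planted mass union


def _paint_disc(mask: np.ndarray, cx: float, cy: float, r: float, value: bool = True) -> None:
    h, w = mask.shape
    x0, x1 = max(0, int(cx - r - 2)), min(w, int(cx + r + 3))
    y0, y1 = max(0, int(cy - r - 2)), min(h, int(cy + r + 3))
    yy, xx = np.mgrid[y0:y1, x0:x1]
    mask[y0:y1, x0:x1][(xx - cx) ** 2 + (yy - cy) ** 2 <= r * r] = value


def _add_gaussian(img: np.ndarray, cx: float, cy: float, sigma: float, amp: float) -> None:
    h, w = img.shape
    ext = 4 * sigma
    x0, x1 = max(0, int(cx - ext)), min(w, int(cx + ext + 1))
    y0, y1 = max(0, int(cy - ext)), min(h, int(cy + ext + 1))
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    img[y0:y1, x0:x1] += amp * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2))


def _bud_radius_px(k: int, r_nuc_px: float) -> float:
    """Smallest comfortable bud disc radius holding k ring-placed nuclei."""
    if k == 1:
        return 2.2 * r_nuc_px
    ring = r_nuc_px / math.sin(math.pi / k) if k > 1 else 0.0
    ring = max(ring, 1.2 * r_nuc_px)
    return ring + 2.0 * r_nuc_px


def _ring_points(cx: float, cy: float, k: int, ring_r: float, phase: float) -> list[tuple[float, float]]:
    if k == 1:
        return [(cx, cy)]
    return [
        (cx + ring_r * math.cos(phase + 2 * math.pi * j / k),
         cy + ring_r * math.sin(phase + 2 * math.pi * j / k))
        for j in range(k)
    ]


def generate_if_image(params: ImageSimParams) -> tuple[ChannelImage, ChannelImage, ImageGroundTruth]:
    """Render one synthetic PanCK/Hoechst slide with full ground truth.

    Deterministic for a fixed seed.  Raises :class:`PlacementError` when the
    geometry cannot accommodate the requested objects (300 rejection-sampling
    attempts per object).
    """
    rng = np.random.default_rng(params.seed)
    ps = params.pixel_size_um
    h, w = params.height_px, params.width_px
    r_nuc = params.nucleus_radius_um / ps
    sep = 2.0 * r_nuc  # minimum clearance between distinct clusters
    close_px = params.closing_radius_um / ps

    mask = np.zeros((h, w), bool)
    labels = np.zeros((h, w), np.int32)
    art_mask = np.zeros((h, w), bool)
    placed: list[tuple[float, float, float]] = []  # (cx, cy, outer radius)
    nuclei: list[tuple[float, float]] = []
    stromal_flags: list[bool] = []
    nucleus_counts: dict[int, int] = {}
    bud_region: dict[int, str] = {}
    bud_ids: set[int] = set()
    next_label = 1
    cx0, cy0 = w / 2.0, h / 2.0
    mass_zone = 0.28 * min(w, h)  # masses stay near the centre

    def try_place(radius, zone_fn, n_attempts=300):
        for _ in range(n_attempts):
            cx, cy = zone_fn()
            if not (radius + 2 <= cx <= w - radius - 2 and radius + 2 <= cy <= h - radius - 2):
                continue
            ok = all(
                math.hypot(cx - px_, cy - py_) >= radius + pr + sep
                for px_, py_, pr in placed
            )
            if ok:
                return cx, cy
        raise PlacementError(
            f"could not place an object of radius {radius:.1f}px "
            f"in a {w}x{h} image after {n_attempts} attempts"
        )

    def place_nuclei_in_disc(cx, cy, r_disc, k):
        """k nuclei inside a disc, pairwise >= 2 r_nuc apart, >= r_nuc from rim."""
        pts: list[tuple[float, float]] = []
        for _ in range(k):
            for _ in range(300):
                rad = (r_disc - 1.2 * r_nuc) * math.sqrt(rng.uniform())
                ang = rng.uniform(0, 2 * math.pi)
                x, y = cx + rad * math.cos(ang), cy + rad * math.sin(ang)
                if all(math.hypot(x - qx, y - qy) >= 2 * r_nuc for qx, qy in pts):
                    pts.append((x, y))
                    break
            else:
                raise PlacementError("could not place nuclei inside a mass")
        return pts

    # --- mass geometry (discs only; nuclei placed after hole punching) ----
    n_core_buds_planned = round(params.core_bud_fraction * params.n_buds) if params.n_masses else 0
    # size masses so each can host its share of in-core bud holes
    hole_max = _bud_radius_px(params.bud_nucleus_range[1], r_nuc) + sep
    if n_core_buds_planned and params.n_masses:
        bpm = math.ceil(n_core_buds_planned / params.n_masses)
        ring = (2 * hole_max + 3 * r_nuc) / (2 * math.sin(math.pi / max(bpm, 2)))
        r_mass_min = 1.35 * (ring + hole_max + 2.5 * r_nuc)
    else:
        r_mass_min = 0.0
    mass_geom = []
    mass_k: list[int] = []
    for _ in range(params.n_masses):
        k = int(rng.integers(params.mass_nucleus_range[0], params.mass_nucleus_range[1] + 1))
        r_mass = max(r_nuc * (3.0 + 2.8 * math.sqrt(k)), r_mass_min)
        cx, cy = try_place(
            r_mass,
            lambda: (cx0 + rng.uniform(-mass_zone, mass_zone),
                     cy0 + rng.uniform(-mass_zone, mass_zone)),
        )
        _paint_disc(mask, cx, cy, r_mass)
        _paint_disc(labels, cx, cy, r_mass, next_label)
        placed.append((cx, cy, r_mass))
        mass_geom.append((cx, cy, r_mass, next_label))
        mass_k.append(k)
        next_label += 1

    # --- in-core buds: punch a moated hole in a mass, drop the bud in -----
    n_core_buds = n_core_buds_planned
    n_front_buds = params.n_buds - n_core_buds
    moat = sep  # background ring around an in-core bud; bridged by closing
    holes: dict[int, list[tuple[float, float, float]]] = {i: [] for i in range(len(mass_geom))}
    core_bud_specs = []
    for b in range(n_core_buds):
        k = int(rng.integers(params.bud_nucleus_range[0], params.bud_nucleus_range[1] + 1))
        r_bud = _bud_radius_px(k, r_nuc)
        hole_r = r_bud + moat
        hosts = [i for i, (mcx, mcy, mr, ml) in enumerate(mass_geom)
                 if mr >= hole_r + 3 * r_nuc + 2]
        if not hosts:
            raise PlacementError("no mass large enough to host an in-core bud")
        # least-loaded hosts first so holes spread evenly over the masses
        hosts.sort(key=lambda i: (len(holes[i]), i))
        placed_hole = False
        for hi in hosts:
            mcx, mcy, mr, _ = mass_geom[hi]
            rad_max = mr - hole_r - 2.0 * r_nuc
            for attempt in range(200):
                # off-centre annulus, fully interior (the surrounding mass
                # ring stays >= 2 r_nuc thick); central positions would
                # block any further hole in the same mass
                rad = rad_max * (0.6 + 0.4 * rng.uniform())
                ang = rng.uniform(0, 2 * math.pi)
                cx, cy = mcx + rad * math.cos(ang), mcy + rad * math.sin(ang)
                if any(math.hypot(cx - hx, cy - hy) < hole_r + hr + 3 * r_nuc
                       for hx, hy, hr in holes[hi]):
                    continue
                placed_hole = True
                break
            if placed_hole:
                break
        if not placed_hole:
            raise PlacementError("could not punch a hole for an in-core bud")
        holes[hi].append((cx, cy, hole_r))
        _paint_disc(mask, cx, cy, hole_r, False)
        _paint_disc(labels, cx, cy, hole_r, 0)
        _paint_disc(mask, cx, cy, r_bud, True)
        _paint_disc(labels, cx, cy, r_bud, next_label)
        placed.append((cx, cy, r_bud))
        bud_region[next_label] = "core"
        core_bud_specs.append((cx, cy, k, next_label))
        next_label += 1

    # --- mass nuclei, avoiding the punched holes --------------------------
    for hi, ((mcx, mcy, mr, ml), k) in enumerate(zip(mass_geom, mass_k)):
        pts: list[tuple[float, float]] = []
        for _ in range(k):
            for _ in range(600):
                rad = (mr - 1.2 * r_nuc) * math.sqrt(rng.uniform())
                ang = rng.uniform(0, 2 * math.pi)
                x, y = mcx + rad * math.cos(ang), mcy + rad * math.sin(ang)
                if any(math.hypot(x - hx, y - hy) < hr + 1.2 * r_nuc
                       for hx, hy, hr in holes[hi]):
                    continue
                if all(math.hypot(x - qx, y - qy) >= 2 * r_nuc for qx, qy in pts):
                    pts.append((x, y))
                    break
            else:
                raise PlacementError("could not place nuclei inside a mass")
        nuclei.extend(pts)
        stromal_flags.extend([False] * k)
        nucleus_counts[ml] = k

    # --- nuclei of the in-core buds ---------------------------------------
    for (cx, cy, k, lab) in core_bud_specs:
        ring_r = max(r_nuc / math.sin(math.pi / k), 1.2 * r_nuc) if k > 1 else 0.0
        pts = _ring_points(cx, cy, k, ring_r, phase=rng.uniform(0, 2 * math.pi))
        nuclei.extend(pts)
        stromal_flags.extend([False] * k)
        nucleus_counts[lab] = k
        bud_ids.add(lab)

    # --- planted core: morphological closing of the mass-disc union ------
    # (holes/moats are narrower than the closing diameter, so they are
    # irrelevant to the closed outline; used to place peritumoural objects
    # relative to the *core* boundary, which can bulge past individual
    # masses where closing bridges their gaps)
    from scipy.ndimage import distance_transform_edt

    from .regions import closing_um

    mass_only = np.zeros((h, w), bool)
    for mcx, mcy, mr, _ in mass_geom:
        _paint_disc(mass_only, mcx, mcy, mr)
    core_truth = closing_um(mass_only, params.closing_radius_um, ps)
    dist_to_core = (distance_transform_edt(~core_truth)
                    if core_truth.any() else np.full((h, w), np.inf))
    front_px = params.front_width_um / ps

    def clear_of_core(cx, cy, radius) -> bool:
        """Far enough that closing cannot bridge the object into the core."""
        x_, y_ = int(round(cx)), int(round(cy))
        if not (0 <= y_ < h and 0 <= x_ < w):
            return False
        return dist_to_core[y_, x_] >= radius + 2 * close_px + 4

    # --- peritumoural buds ------------------------------------------------
    for b in range(n_front_buds):
        k = int(rng.integers(params.bud_nucleus_range[0], params.bud_nucleus_range[1] + 1))
        r_bud = _bud_radius_px(k, r_nuc)
        if mass_geom:
            gap_lo = 2 * close_px + 4
            gap_hi = max(gap_lo + 2 * r_bud, front_px - 2 * r_bud)

            def zone():
                mcx, mcy, mr, _ = mass_geom[int(rng.integers(len(mass_geom)))]
                gap = rng.uniform(gap_lo, gap_hi)
                ang = rng.uniform(0, 2 * math.pi)
                d = mr + gap + r_bud
                return (mcx + d * math.cos(ang), mcy + d * math.sin(ang))
        else:
            def zone():
                return (rng.uniform(0, w), rng.uniform(0, h))

        for attempt in range(600):
            try:
                cx, cy = try_place(r_bud, zone, n_attempts=1)
            except PlacementError:
                continue
            if mass_geom:
                if not clear_of_core(cx, cy, r_bud):
                    continue
                x_, y_ = int(round(cx)), int(round(cy))
                if dist_to_core[y_, x_] > front_px - 2:  # centroid inside the band
                    continue
            break
        else:
            raise PlacementError("could not place a peritumoural bud")
        _paint_disc(mask, cx, cy, r_bud)
        _paint_disc(labels, cx, cy, r_bud, next_label)
        placed.append((cx, cy, r_bud))
        bud_region[next_label] = "front" if mass_geom else "none"
        ring_r = max(r_nuc / math.sin(math.pi / k), 1.2 * r_nuc) if k > 1 else 0.0
        pts = _ring_points(cx, cy, k, ring_r, phase=rng.uniform(0, 2 * math.pi))
        nuclei.extend(pts)
        stromal_flags.extend([False] * k)
        nucleus_counts[next_label] = k
        bud_ids.add(next_label)
        next_label += 1

    # --- artefacts (PanCK-only blobs, no nuclei) --------------------------
    n_art = round(params.artefact_fraction * (params.n_masses + params.n_buds))
    for _ in range(n_art):
        r_art = r_nuc * rng.uniform(2.0, 5.0)
        for attempt in range(300):
            try:
                cx, cy = try_place(r_art, lambda: (rng.uniform(0, w), rng.uniform(0, h)),
                                   n_attempts=1)
            except PlacementError:
                continue
            if mass_geom and not clear_of_core(cx, cy, r_art):
                continue
            break
        else:
            raise PlacementError("could not place an artefact")
        _paint_disc(art_mask, cx, cy, r_art)
        placed.append((cx, cy, r_art))

    # --- stromal nuclei (Hoechst only, outside the tumour mask) -----------
    for _ in range(params.n_stromal_nuclei):
        cx, cy = try_place(r_nuc, lambda: (rng.uniform(0, w), rng.uniform(0, h)))
        nuclei.append((cx, cy))
        stromal_flags.append(True)
        placed.append((cx, cy, r_nuc))

    # --- render -----------------------------------------------------------
    panck = np.full((h, w), 10.0)
    panck[mask] = 100.0
    panck[art_mask] = 130.0
    hoechst = np.full((h, w), 5.0)
    sigma = r_nuc / 2.0
    for (x, y) in nuclei:
        _add_gaussian(hoechst, x, y, sigma, 120.0)
    if params.noise_sd > 0:
        panck = rng.poisson(panck).astype(float) + rng.normal(0, params.noise_sd, panck.shape)
        hoechst = rng.poisson(np.clip(hoechst, 0, None)).astype(float) \
            + rng.normal(0, params.noise_sd, hoechst.shape)
        panck = np.clip(panck, 0, None)
        hoechst = np.clip(hoechst, 0, None)

    truth = ImageGroundTruth(
        tumour_mask=mask,
        nucleus_centres=np.array(nuclei, float).reshape(-1, 2),
        nucleus_is_stromal=np.array(stromal_flags, bool),
        cluster_labels=labels,
        bud_cluster_ids=bud_ids,
        nucleus_counts=nucleus_counts,
        bud_region=bud_region,
        artefact_mask=art_mask,
        core_truth=core_truth,
    )
    return (
        ChannelImage(panck, ps, PANCK),
        ChannelImage(hoechst, ps, HOECHST),
        truth,
    )


# ---------------------------------------------------------------------------
# synthetic cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortSimParams:
    """Statistical structure of a synthetic survival cohort.

    Defaults mirror the modelled cohort: stage prevalences 25/41/4/30%,
    metastasis present iff stage IV, budding burden log-normal with a
    stage-dependent location (the TB-stage association), and exponential
    disease-specific survival under hazard = ``baseline_hazard`` x
    exp(beta_metastasis 1[IV] + beta_tb 1[TB > tb_cutoff_true]) with uniform
    censoring on (0, ``censor_time_max``].
    """

    n_patients: int = 100
    stage_probs: tuple[float, float, float, float] = (0.25, 0.41, 0.04, 0.30)
    tb_log_mean_by_stage: tuple[float, float, float, float] = (2.4, 2.9, 3.1, 3.4)
    tb_log_sd: float = 0.8
    beta_metastasis: float = math.log(5.5)
    beta_tb: float = math.log(2.6)
    tb_cutoff_true: float = 20.0
    baseline_hazard: float = 0.007  # per month; gives ~24 mo median DSS, ~54% deaths
    censor_time_max: float = 113.13  # months of follow-up
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 8:
            raise ValueError("n_patients must be at least 8 for survival analysis")
        if abs(sum(self.stage_probs) - 1.0) > 1e-9:
            raise ValueError("stage_probs must sum to 1")
        if self.baseline_hazard <= 0 or self.censor_time_max <= 0:
            raise ValueError("hazards and censoring horizon must be positive")


_STAGES = ("II", "IIIA", "IIIB", "IV")
_PT_PROBS = (0.09, 0.18, 0.19, 0.30, 0.13, 0.11)
_NODE_PROBS = (0.78, 0.14, 0.08)
_GRADE_PROBS = (0.11, 0.02, 0.87)
_GROWTH_PROBS = (0.70, 0.16, 0.12, 0.02)
_TREAT_PROBS = (0.11, 0.09, 0.13, 0.09, 0.50, 0.08)
_GENDER_PROBS = (0.59, 0.41)


def generate_cohort(params: CohortSimParams) -> pd.DataFrame:
    """Draw one synthetic cohort table (deterministic for a fixed seed)."""
    rng = np.random.default_rng(params.seed)
    n = params.n_patients
    stage_idx = rng.choice(4, size=n, p=params.stage_probs)
    tnm = np.array(_STAGES, object)[stage_idx]
    metastasis = (stage_idx == 3).astype(int)

    mu = np.array(params.tb_log_mean_by_stage)[stage_idx]
    n_tb_core = np.round(np.exp(rng.normal(mu, params.tb_log_sd))).astype(int)

    # Correlated but noisier companion features derived from the core
    # burden: in the emulated cohort the core count is the most informative
    # budding readout and the field-of-view counts are degraded versions.
    core_area = np.exp(rng.normal(np.log(8.0), 0.4, n))    # mm^2
    front_area = np.exp(rng.normal(np.log(5.0), 0.4, n))   # mm^2
    n_tb_front = rng.poisson(0.6 * n_tb_core + 2.0)
    ten_785 = rng.poisson(0.5 * n_tb_core + 0.25 * n_tb_front + 2.0)
    single_785 = np.minimum(ten_785, np.ceil(ten_785 * rng.uniform(0.2, 0.5, n))).astype(int)
    ten_238 = np.minimum(ten_785, rng.poisson(0.5 * ten_785 + 0.5))

    high_tb = n_tb_core > params.tb_cutoff_true
    log_h = (np.log(params.baseline_hazard)
             + params.beta_metastasis * metastasis
             + params.beta_tb * high_tb)
    t_event = rng.exponential(1.0 / np.exp(log_h))
    t_cens = rng.uniform(0.0, params.censor_time_max, n)
    t_cens = np.maximum(t_cens, 1e-3)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    time = np.maximum(time, 1e-3)

    df = pd.DataFrame({
        C.TIME_COL: time,
        C.EVENT_COL: event,
        "age_years": np.clip(rng.normal(66.0, 12.0, n), 29, 87).round(1),
        "gender": rng.choice(np.array(C.GENDER_CATEGORIES, object), size=n, p=_GENDER_PROBS),
        "tnm_stage": tnm,
        "pt_stage": rng.choice(np.array(list(C.PT_LEVELS), object), size=n, p=_PT_PROBS),
        "metastasis": metastasis,
        "nodes": rng.choice(np.array(list(C.NODE_LEVELS), object), size=n, p=_NODE_PROBS),
        "treatment": rng.choice(np.array(C.TREATMENT_CATEGORIES, object), size=n, p=_TREAT_PROBS),
        "grade": rng.choice(np.array(list(C.GRADE_LEVELS), object), size=n, p=_GRADE_PROBS),
        "growth_pattern": rng.choice(np.array(C.GROWTH_CATEGORIES, object), size=n, p=_GROWTH_PROBS),
        FEATURE_NAMES[0]: n_tb_core,
        FEATURE_NAMES[1]: n_tb_front,
        FEATURE_NAMES[2]: n_tb_core / core_area,
        FEATURE_NAMES[3]: n_tb_front / front_area,
        FEATURE_NAMES[4]: single_785,
        FEATURE_NAMES[5]: ten_785,
        FEATURE_NAMES[6]: ten_238,
    })
    return df
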