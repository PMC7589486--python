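"""Synthetic FA/ICGA image pairs and cohort tables with known ground truth.

No angiographic raw data ship with the study design this package serves, so
every pipeline stage is exercised on generated material:

* ``generate_image_pair`` renders a fovea-centred stereographic raster pair.
  The FA frame carries only a retinal vessel tree; the ICGA frame carries
  the union of the retinal tree and a coarser choroidal tree, mimicking the
  modality difference (ICGA shows medium/large choroidal vessels through the
  RPE).  Trees are recursive random binary branchings rasterised as thick
  polylines.  Choroidal calibres are rescaled per zone by bisection until
  the *true* choroidal density (area of choroid-minus-retina over zone
  area, both measured with the stereographic area map) hits the requested
  per-zone targets.  Ground-truth masks are frozen before vignetting, blur
  and Gaussian noise are applied, so the emitted truth is exactly consistent
  with the emitted rasters.
* ``generate_cohort`` draws per-eye clinical tables via a Gaussian copula:
  group-specific means/SDs for thicknesses and densities, a target
  correlation structure between densities and choroidal thickness, a binary
  hyperpermeability flag thresholded from a correlated latent normal, and
  responder labels from a logistic model on density and choroidal thickness.

All randomness flows from one integer seed through a named
``numpy.random.Generator``; the same seed reproduces byte-identical output.
Dye kinetics, leakage, polyps and other pathology phenotypes are not
simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import line

from .geometry import (DEFAULT_ZONE_BOUNDARIES_MM, EXCLUDED, EyeModel, ZonePartition,
                       area_map, assign_zones, geodesic_map)
from .segmentation import TrimMask

# Per-zone density targets default to the PCV-group regional means.
DEFAULT_CVD_TARGETS: dict[str, float] = {"MR": 25.80, "NPR": 25.72, "MPR": 28.67, "FPR": 29.39}


@dataclass(frozen=True)
class TreeParams:
    """Branching-tree controls: ``n_roots`` trunks recursing ``depth`` levels,
    segment length ``step_px``, calibre ``root_caliber_px`` tapering by
    ``taper`` per level, branch directions jittered by ``angle_sd_rad``."""

    n_roots: int
    depth: int
    root_caliber_px: float
    taper: float = 0.80
    step_px: float = 26.0
    angle_sd_rad: float = 0.35
    branch_angle_rad: float = 0.55


@dataclass(frozen=True)
class SyntheticImageSpec:
    """Study conditions for one synthetic eye.

    The 512 px grid at 0.09 mm/px spans a plane half-width of ~23 mm —
    enough to hold the far-peripheral ring (15 mm geodesic = 17.3 mm plane
    radius) and the default 18 mm gradable boundary.  Background, amplitude
    and noise give vessel SNR 10 by default; ``vignetting`` dims the
    periphery the way real fundus frames fall off.
    """

    seed: int = 0
    grid_shape: tuple[int, int] = (512, 512)
    pixel_pitch: float = 0.09
    axial_length: float = 24.0
    fovea_pixel: tuple[float, float] | None = None
    visible_radius_mm: float = 18.0
    zone_boundaries_mm: tuple[float, ...] = DEFAULT_ZONE_BOUNDARIES_MM
    retinal_tree: TreeParams = field(default_factory=lambda: TreeParams(
        n_roots=6, depth=7, root_caliber_px=2.6, taper=0.84))
    choroidal_tree: TreeParams = field(default_factory=lambda: TreeParams(
        n_roots=14, depth=6, root_caliber_px=5.0, taper=0.86, step_px=34.0))
    target_cvd_per_zone: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CVD_TARGETS))
    background: float = 40.0
    vessel_amplitude: float = 120.0
    noise_sd: float = 12.0
    vignetting: float = 0.30
    # PSF scaled to the down-sampled grid: on a full-resolution UWF raster the
    # optical blur is small relative to vessel calibre, so the 512 px stand-in
    # uses a proportionally small sigma
    blur_sigma: float = 0.4


@dataclass(frozen=True)
class SyntheticPair:
    """One generated eye: rasters, exact truth masks and achieved densities."""

    fa: np.ndarray
    icga: np.ndarray
    retinal_mask: np.ndarray
    total_mask: np.ndarray
    trim: TrimMask
    model: EyeModel
    zones: ZonePartition
    achieved_cvd: dict[str, float]


# --------------------------------------------------------------------------
# tree construction

def _grow_tree(rng: np.random.Generator, params: TreeParams, shape: tuple[int, int],
               roots: np.ndarray, headings: np.ndarray) -> list[tuple[tuple, tuple, float]]:
    """Recursive binary branching; returns segments (p0, p1, caliber_px)."""
    segments: list[tuple[tuple, tuple, float]] = []
    frontier = [(tuple(p), h, params.root_caliber_px, 0) for p, h in zip(roots, headings)]
    while frontier:
        p0, heading, caliber, level = frontier.pop()
        if level >= params.depth:
            continue
        step = params.step_px * float(rng.uniform(0.7, 1.3))
        h = heading + float(rng.normal(0.0, params.angle_sd_rad))
        p1 = (p0[0] + step * np.sin(h), p0[1] + step * np.cos(h))
        segments.append((p0, p1, caliber))
        if not (-shape[0] * 0.2 < p1[0] < shape[0] * 1.2
                and -shape[1] * 0.2 < p1[1] < shape[1] * 1.2):
            continue
        spread = params.branch_angle_rad * float(rng.uniform(0.6, 1.4))
        for sign in (-1.0, 1.0):
            frontier.append((p1, h + sign * spread, caliber * params.taper, level + 1))
    return segments


def _rasterize_centerlines(segments, shape) -> tuple[np.ndarray, np.ndarray]:
    """Burn centrelines into a raster; keep the max calibre seen per pixel."""
    caliber_im = np.zeros(shape, dtype=float)
    for p0, p1, caliber in segments:
        r0, c0 = int(round(p0[0])), int(round(p0[1]))
        r1, c1 = int(round(p1[0])), int(round(p1[1]))
        rr, cc = line(r0, c0, r1, c1)
        keep = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
        rr, cc = rr[keep], cc[keep]
        caliber_im[rr, cc] = np.maximum(caliber_im[rr, cc], caliber)
    return caliber_im > 0, caliber_im


def _width_distance_fields(caliber_im: np.ndarray, skeleton: np.ndarray,
                           n_levels: int = 6) -> list[tuple[float, np.ndarray]]:
    """EDT to the skeleton restricted to calibre bands, so a pixel joins the
    vessel when its distance to a band is within scale * band calibre."""
    calibers = caliber_im[skeleton]
    if calibers.size == 0:
        return []
    edges = np.quantile(calibers, np.linspace(0, 1, n_levels + 1))
    fields = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        band = skeleton & (caliber_im >= lo) & (caliber_im <= hi)
        if not band.any():
            continue
        dist = ndimage.distance_transform_edt(~band)
        fields.append((float(hi), dist))
    return fields


def _mask_at_scale(fields, scale: float | np.ndarray, shape,
                   jitter: np.ndarray | None = None) -> np.ndarray:
    """Thick-polyline mask: pixel joins when its distance to a centreline band
    is within scale * calibre / 2.  ``jitter`` is a frozen sub-pixel offset
    raster that anti-aliases the discrete distance staircase, making the
    zone density a continuous, monotone function of the scale."""
    mask = np.zeros(shape, dtype=bool)
    for caliber, dist in fields:
        d = dist if jitter is None else dist + jitter
        mask |= d <= scale * caliber / 2.0
    return mask


def _tree_mask(rng, params: TreeParams, model: EyeModel, inward: bool):
    """Grow + rasterise a tree; roots on a ring, growing outward (retinal,
    from near the posterior pole) or inward from the periphery (choroidal)."""
    shape = model.grid_shape
    fr, fc = model.fovea_pixel
    if inward:
        # choroidal: trunks scattered over the disc so every zone is reachable;
        # linear (not area-uniform) radii oversample the small central rings
        radius = 0.46 * min(shape) * rng.uniform(0.0, 1.0, params.n_roots)
        ang = rng.uniform(0, 2 * np.pi, params.n_roots)
        roots = np.stack([fr + radius * np.sin(ang), fc + radius * np.cos(ang)], axis=1)
        headings = rng.uniform(0, 2 * np.pi, params.n_roots)
    else:
        radius = 0.08 * min(shape)
        ang = rng.uniform(0, 2 * np.pi, params.n_roots)
        roots = np.stack([fr + radius * np.sin(ang), fc + radius * np.cos(ang)], axis=1)
        headings = ang + rng.normal(0, 0.3, params.n_roots)
    segments = _grow_tree(rng, params, shape, roots, headings)
    skeleton, caliber_im = _rasterize_centerlines(segments, shape)
    return _width_distance_fields(caliber_im, skeleton)


# --------------------------------------------------------------------------
# density targeting

def _zone_density(choroid: np.ndarray, retinal: np.ndarray, areas: np.ndarray,
                  zone_sel: np.ndarray) -> float:
    zone_area = areas[zone_sel].sum()
    cva = areas[zone_sel & choroid & ~retinal].sum()
    return 100.0 * cva / zone_area


def _fit_zone_scale(fields, retinal, areas, zone_sel, target_pct, shape, jitter,
                    tol_pp: float = 0.1, max_iter: int = 40) -> tuple[float, float]:
    """Bisection on the calibre scale until the zone's true choroidal density
    matches the target.  Density is monotone increasing in the scale."""
    lo, hi = 0.02, 8.0
    d_hi = _zone_density(_mask_at_scale(fields, hi, shape, jitter), retinal, areas, zone_sel)
    if d_hi < target_pct:
        raise ValueError(f"target density {target_pct}% unattainable (max {d_hi:.1f}%); "
                         "add roots or depth to the choroidal tree")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        d = _zone_density(_mask_at_scale(fields, mid, shape, jitter), retinal, areas, zone_sel)
        if abs(d - target_pct) <= tol_pp:
            return mid, d
        if d < target_pct:
            lo = mid
        else:
            hi = mid
    mid = 0.5 * (lo + hi)
    return mid, _zone_density(_mask_at_scale(fields, mid, shape, jitter), retinal, areas, zone_sel)


# --------------------------------------------------------------------------
# rendering

def _render(mask_r: np.ndarray, mask_c: np.ndarray | None, spec: SyntheticImageSpec,
            model: EyeModel, rng: np.random.Generator) -> np.ndarray:
    vessels = mask_r if mask_c is None else (mask_r | mask_c)
    im = np.full(model.grid_shape, spec.background, dtype=float)
    im += spec.vessel_amplitude * vessels
    if spec.blur_sigma > 0:
        im = ndimage.gaussian_filter(im, spec.blur_sigma)
    if spec.vignetting > 0:
        d = geodesic_map(model)
        fall = 1.0 - spec.vignetting * (d / d.max()) ** 2
        im *= fall
    im += rng.normal(0.0, spec.noise_sd, size=im.shape)
    return np.clip(im, 0.0, 255.0)


def generate_image_pair(spec: SyntheticImageSpec) -> SyntheticPair:
    """Render one FA/ICGA pair with exactly known vessel masks and densities.

    Targets above 60% are refused up front: the density of a plausible
    branching pattern saturates well below that, and higher requests only
    merge the tree into a blob.
    """
    for zone, target in spec.target_cvd_per_zone.items():
        if target > 60:
            raise ValueError(f"target CVD {target}% for {zone} exceeds the 60% ceiling")
    model = EyeModel(grid_shape=spec.grid_shape, pixel_pitch=spec.pixel_pitch,
                     fovea_pixel=spec.fovea_pixel, axial_length=spec.axial_length)
    areas = area_map(model)
    visible = geodesic_map(model) <= spec.visible_radius_mm
    zones = assign_zones(model, visible, spec.zone_boundaries_mm)
    rng = np.random.default_rng(spec.seed)

    retinal_fields = _tree_mask(rng, spec.retinal_tree, model, inward=False)
    choroid_fields = _tree_mask(rng, spec.choroidal_tree, model, inward=True)
    jitter = rng.uniform(-0.5, 0.5, model.grid_shape)
    retinal = _mask_at_scale(retinal_fields, 1.0, model.grid_shape, jitter)

    scale_im = np.zeros(model.grid_shape, dtype=float)
    achieved: dict[str, float] = {}
    zone_codes = {"MR": 1, "NPR": 2, "MPR": 3, "FPR": 4}
    for zone, target in spec.target_cvd_per_zone.items():
        sel = zones.mask(zone_codes[zone])
        s, d = _fit_zone_scale(choroid_fields, retinal, areas, sel, target,
                               model.grid_shape, jitter)
        achieved[zone] = d
        scale_im[sel] = s
    # continue the pattern smoothly outside the named zones
    inner = zones.labels == EXCLUDED
    scale_im[inner & (geodesic_map(model) < spec.zone_boundaries_mm[0])] = scale_im[
        zones.mask(1)].mean() if zones.mask(1).any() else 1.0
    scale_im[scale_im == 0] = scale_im[scale_im > 0].mean() if (scale_im > 0).any() else 1.0

    choroid = _mask_at_scale(choroid_fields, scale_im, model.grid_shape, jitter)
    total = retinal | choroid

    fa = _render(retinal, None, spec, model, rng)
    icga = _render(retinal, choroid, spec, model, rng)
    trim = TrimMask(visible=visible)
    return SyntheticPair(fa=fa, icga=icga, retinal_mask=retinal, total_mask=total,
                         trim=trim, model=model, zones=zones, achieved_cvd=achieved)


# --------------------------------------------------------------------------
# cohort generation

# Group-specific marginals: mean, SD per variable (thicknesses in um,
# densities in percent), defaults from the studied cohorts.
GROUP_MARGINALS: dict[str, dict[str, tuple[float, float]]] = {
    "PCV": {
        "age": (68.5, 9.8), "refractive_error": (0.24, 1.69), "bcva_logmar": (0.51, 0.34),
        "cmt_um": (417.97, 130.15), "haller_um": (242.50, 91.76),
        "inner_layer_um": (74.22, 22.68),
        "cvd_total": (27.15, 1.86), "cvd_mr": (25.80, 2.12), "cvd_npr": (25.72, 1.98),
        "cvd_mpr": (28.67, 2.40), "cvd_fpr": (29.39, 2.26),
    },
    "control": {
        "age": (64.8, 5.0), "refractive_error": (0.59, 0.96), "bcva_logmar": (0.06, 0.08),
        "cmt_um": (273.00, 45.59), "haller_um": (141.05, 36.51),
        "inner_layer_um": (91.00, 38.72),
        "cvd_total": (25.17, 2.05), "cvd_mr": (24.22, 2.50), "cvd_npr": (23.43, 1.98),
        "cvd_mpr": (26.95, 2.49), "cvd_fpr": (26.94, 3.51),
    },
}

#: observed PCV-group incidence of choroidal hyperpermeability
HYPERPERM_RATE = {"PCV": 0.344, "control": 0.05}

_LATENT_VARS = ["age", "refractive_error", "bcva_logmar", "cmt_um", "haller_um",
                "inner_layer_um", "cvd_total", "cvd_mr", "cvd_npr", "cvd_mpr",
                "cvd_fpr", "hyperperm_latent"]


def _default_latent_corr() -> pd.DataFrame:
    """Latent correlation structure: density-thickness links at the reported
    magnitudes (Haller 0.504, CMT 0.442, hyperpermeability 0.481), strong
    coherence between the zonal densities, and near-independence elsewhere."""
    corr = pd.DataFrame(np.eye(len(_LATENT_VARS)), index=_LATENT_VARS, columns=_LATENT_VARS)

    def put(a, b, r):
        corr.loc[a, b] = corr.loc[b, a] = r

    put("cvd_total", "haller_um", 0.504)
    put("cvd_total", "cmt_um", 0.442)
    put("cvd_total", "hyperperm_latent", 0.481)
    # SFCT is emitted as Haller + inner; with the reported SDs (91.76, 22.68)
    # a CVD-inner link of -0.172 makes the implied CVD-SFCT correlation land
    # on the target 0.448 given CVD-Haller = 0.504
    put("cvd_total", "inner_layer_um", -0.172)
    put("cmt_um", "haller_um", 0.45)
    put("haller_um", "hyperperm_latent", 0.40)
    put("cmt_um", "hyperperm_latent", 0.30)
    for z in ("cvd_mr", "cvd_npr", "cvd_mpr", "cvd_fpr"):
        put("cvd_total", z, 0.85)
        put(z, "haller_um", 0.40)
        put(z, "cmt_um", 0.35)
        put(z, "hyperperm_latent", 0.38)
    for i, a in enumerate(("cvd_mr", "cvd_npr", "cvd_mpr", "cvd_fpr")):
        for b in ("cvd_mr", "cvd_npr", "cvd_mpr", "cvd_fpr")[i + 1:]:
            put(a, b, 0.70)
    return corr


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Cohort-generator conditions: group sizes match the study (32 PCV /
    30 control), marginals and latent correlations default to the reported
    summary statistics, and responder labels follow a logistic model on
    standardised total density and choroidal thickness."""

    seed: int = 0
    n_per_group: dict[str, int] = field(default_factory=lambda: {"PCV": 32, "control": 30})
    marginals: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {g: dict(m) for g, m in GROUP_MARGINALS.items()})
    latent_corr: pd.DataFrame = field(default_factory=_default_latent_corr)
    # logit P(poor) = b0 + b_cvd * z(CVD) + b_sfct * z(SFCT)
    responder_coefs: tuple[float, float, float] = (-1.1, 1.1, 0.55)
    agents: tuple[str, ...] = ("bevacizumab", "ranibizumab", "aflibercept")


def generate_cohort(spec: SyntheticCohortSpec) -> pd.DataFrame:
    """Draw a per-eye cohort table via a Gaussian copula.

    SFCT is the sum of the generated Haller and inner-layer thicknesses, so
    the layer-arithmetic invariant holds by construction.  Hyperpermeability
    is the latent normal thresholded at the group incidence, which keeps its
    point-biserial link with density near the requested latent value.
    """
    corr = spec.latent_corr.loc[_LATENT_VARS, _LATENT_VARS].to_numpy(dtype=float)
    eigvals = np.linalg.eigvalsh(corr)
    if eigvals.min() <= 1e-10:
        raise ValueError("latent correlation matrix must be positive definite")
    chol = np.linalg.cholesky(corr)
    rng = np.random.default_rng(spec.seed)

    frames = []
    for group, n in spec.n_per_group.items():
        if n == 0:
            continue
        z = rng.standard_normal((n, len(_LATENT_VARS))) @ chol.T
        marg = spec.marginals[group]
        data: dict[str, np.ndarray] = {}
        for j, var in enumerate(_LATENT_VARS):
            if var == "hyperperm_latent":
                continue
            mean, sd = marg[var]
            data[var] = mean + sd * z[:, j]
        data["haller_um"] = np.clip(data["haller_um"], 5.0, None)
        data["inner_layer_um"] = np.clip(data["inner_layer_um"], 5.0, None)
        data["sfct_um"] = data["haller_um"] + data["inner_layer_um"]
        j_h = _LATENT_VARS.index("hyperperm_latent")
        thresh = float(np.quantile(z[:, j_h], 1.0 - HYPERPERM_RATE[group])) \
            if 0 < HYPERPERM_RATE[group] < 1 else np.inf
        data["hyperpermeability"] = z[:, j_h] > thresh
        df = pd.DataFrame(data)
        df.insert(0, "group", group)
        df["sex"] = rng.choice(["M", "F"], size=n, p=[0.69, 0.31])
        frames.append(df)
    cohort = pd.concat(frames, ignore_index=True)
    cohort.insert(0, "eye_id", [f"eye{str(i).zfill(3)}" for i in range(len(cohort))])

    # responder labels only for the PCV group, from the logistic model
    b0, b_cvd, b_sfct = spec.responder_coefs
    pcv_marg = spec.marginals["PCV"]
    mu_cvd, sd_cvd = pcv_marg["cvd_total"]
    mu_sfct = pcv_marg["haller_um"][0] + pcv_marg["inner_layer_um"][0]
    sd_sfct = float(np.hypot(pcv_marg["haller_um"][1], pcv_marg["inner_layer_um"][1]))
    is_pcv = cohort["group"] == "PCV"
    logit = (b0 + b_cvd * (cohort.loc[is_pcv, "cvd_total"] - mu_cvd) / sd_cvd
             + b_sfct * (cohort.loc[is_pcv, "sfct_um"] - mu_sfct) / sd_sfct)
    p_poor = 1.0 / (1.0 + np.exp(-logit))
    poor = rng.random(is_pcv.sum()) < p_poor
    cohort["responder"] = "NA"
    cohort.loc[is_pcv, "responder"] = np.where(poor, "poor", "good")
    cohort["agent"] = "NA"
    cohort.loc[is_pcv, "agent"] = rng.choice(spec.agents, size=int(is_pcv.sum()))
    return cohort
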