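"""Synthetic digitized-specimen generator.

Emulates the serial-dissection digitization protocol: per dissection layer
(layers ~1.5 mm apart) 10-60 fiber bundles, each digitized at 10-20 ordered
sites medial -> lateral with isotropic stylus noise; tendon periphery
outlines dotted ~2 mm apart at several depths; three bony landmarks; tear
geometry and category per specimen.

Architecture is imposed distributionally per (region, part, category) cell:
fiber bundle length is log-normal around the cell's target median
(positive, right-skewed), pennation angles folded-normal on [0, 90]
calibrated so the population median hits the cell target.  Default targets
are the published part-level medians of the cadaveric study the protocol
models, so superficial -> deep FBL shortening in retracted tears and the
category orderings (anterior FBL A > B > C; largest anterior lateral PA in
C) hold by construction.

Each bundle is realized as a smooth space curve with exactly the drawn arc
length and exact end-tangent angles to the tendon axis: the unit tangent
field t(s) = (cos a(s), sin a(s) cos phi(s), sin a(s) sin phi(s)) with a(s)
linear from the medial to the lateral angle and phi(s) a linear azimuth
twist is integrated over s in [0, L].  The twist bends the fiber out of
plane so arc length genuinely exceeds the chord (~1-3% at default), giving
the spline pipeline real curvature to recover.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import foldnorm

from .specimen import (
    DigitizedFiberBundle,
    LandmarkSet,
    Part,
    Region,
    Sex,
    Side,
    Specimen,
    TearCategory,
    TearRecord,
    ValidationError,
)

# (fbl median cm, lateral PA median deg, medial PA median deg)
# per (region, part, category); published part-level medians.
DEFAULT_CELL_TARGETS: dict[tuple[str, str, str], tuple[float, float, float]] = {
    ("anterior", "superficial", "A"): (7.56, 14.26, 15.58),
    ("anterior", "middle", "A"): (6.71, 15.71, 12.97),
    ("anterior", "deep", "A"): (6.24, 14.15, 13.87),
    ("anterior", "superficial", "B"): (5.58, 15.59, 19.22),
    ("anterior", "middle", "B"): (4.71, 12.73, 15.95),
    ("anterior", "deep", "B"): (5.16, 14.15, 11.52),
    ("anterior", "superficial", "C"): (2.95, 25.16, 28.40),
    ("anterior", "middle", "C"): (2.57, 22.92, 22.96),
    ("anterior", "deep", "C"): (2.50, 21.80, 19.99),
    ("posterior", "superficial", "A"): (5.89, 26.39, 17.85),
    ("posterior", "middle", "A"): (6.42, 25.60, 14.46),
    ("posterior", "deep", "A"): (5.85, 18.79, 16.54),
    ("posterior", "superficial", "B"): (4.88, 27.17, 14.06),
    ("posterior", "middle", "B"): (4.98, 23.43, 13.55),
    ("posterior", "deep", "B"): (4.65, 17.71, 10.71),
    ("posterior", "superficial", "C"): (2.96, 38.46, 19.40),
    ("posterior", "middle", "C"): (3.48, 35.25, 12.58),
    ("posterior", "deep", "C"): (2.80, 25.17, 13.89),
}

# tear-diameter target medians (coronal cm, sagittal cm) per category;
# category A is partial thickness, diameters not measured.
DEFAULT_TEAR_TARGETS = {"B": (1.44, 1.58), "C": (2.96, 3.72)}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters of the synthetic digitization.

    seed: master seed; named sub-streams are spawned per specimen and bundle
        so adding bundles does not perturb existing ones.
    cell_targets: per-(region, part, category) target medians.
    fbl_spread: log-normal sigma of FBL about the cell median.
    pa_spread_deg: normal sigma (deg) of the folded-normal PA draws.
    bundles_per_layer / points_per_bundle: inclusive uniform ranges.
    layers_per_part: dissection layers per superficial/middle/deep part.
    layer_spacing_mm: depth increment between layers.
    outline_dot_spacing_mm: paint-dot spacing along tendon outlines.
    digitization_noise_sd_cm: isotropic stylus noise, expressed as the RMS
        3D displacement of a digitized point (the convention of digitizer
        point-accuracy specifications); per-coordinate sd is value / sqrt(3).
    fiber_twist_rad: total azimuth twist of the tangent field (curvature;
        0 = planar/straight fibers).
    posterior_absent: force absence of the posterior region (category C).
    tear_targets: median (coronal, sagittal) tear diameters for B and C.
    tear_spread: log-normal sigma of the tear-diameter draws.
    """

    seed: int
    cell_targets: dict = field(default_factory=lambda: dict(DEFAULT_CELL_TARGETS))
    fbl_spread: float = 0.25
    pa_spread_deg: float = 9.0
    bundles_per_layer: tuple[int, int] = (10, 60)
    points_per_bundle: tuple[int, int] = (10, 20)
    layers_per_part: int = 3
    layer_spacing_mm: float = 1.5
    outline_dot_spacing_mm: float = 2.0
    digitization_noise_sd_cm: float = 0.02
    fiber_twist_rad: float = 2.0
    posterior_absent: bool = False
    posterior_absent_probability: float = 0.5
    tear_targets: dict = field(default_factory=lambda: dict(DEFAULT_TEAR_TARGETS))
    tear_spread: float = 0.15

    def __post_init__(self):
        if self.seed is None:
            raise ValidationError("GeneratorConfig requires a seed")
        for name in ("bundles_per_layer", "points_per_bundle"):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi):
                raise ValidationError(f"{name} range ({lo}, {hi}) is empty or invalid")
        lo, hi = self.points_per_bundle
        if lo < 4:
            raise ValidationError("points_per_bundle lower bound must be >= 4")
        if self.fbl_spread < 0 or self.pa_spread_deg < 0 or self.tear_spread < 0:
            raise ValidationError("spread parameters must be >= 0")
        if self.digitization_noise_sd_cm < 0:
            raise ValidationError("digitization noise must be >= 0")
        if self.layers_per_part < 1:
            raise ValidationError("layers_per_part must be >= 1")
        if not (0.0 <= self.posterior_absent_probability <= 1.0):
            raise ValidationError("posterior_absent_probability must be in [0, 1]")


def folded_normal_location(target_median: float, sigma: float) -> float:
    """Location mu such that |N(mu, sigma)| has the requested median.

    For sigma = 0 (or a target far above sigma) this is the target itself;
    otherwise solved numerically.  The smallest attainable folded-normal
    median at given sigma is ~0.6745 sigma (mu = 0); targets below that are
    matched by shrinking sigma instead, keeping the median exact.
    """
    if sigma == 0.0 or target_median > 8.0 * sigma:
        return target_median
    floor = float(foldnorm.median(c=0.0, scale=sigma))
    if target_median <= floor:
        return 0.0  # caller shrinks sigma; kept total
    f = lambda mu: float(foldnorm.median(c=mu / sigma, scale=sigma)) - target_median
    return float(brentq(f, 0.0, target_median + 8.0 * sigma))


def _draw_pa(rng: np.random.Generator, target_median: float, sigma: float, size: int) -> np.ndarray:
    """Folded-normal PA draws (deg) whose population median is the target, folded to [0, 90]."""
    if sigma == 0.0:
        return np.full(size, target_median)
    floor = float(foldnorm.median(c=0.0, scale=sigma))
    if target_median <= floor:
        sigma = max(target_median / floor * sigma * 0.999, 1e-6)
    mu = folded_normal_location(target_median, sigma)
    v = np.abs(rng.normal(mu, sigma, size))
    v = np.where(v > 90.0, 180.0 - v, v)  # fold the (vanishing) far tail
    return np.clip(v, 0.0, 90.0)


def _draw_fbl(rng: np.random.Generator, target_median: float, sigma: float, size: int) -> np.ndarray:
    """Log-normal FBL draws (cm) with the target as population median."""
    if sigma == 0.0:
        return np.full(size, target_median)
    return target_median * np.exp(rng.normal(0.0, sigma, size))


def _integrate_tangent_field(
    length_cm: float,
    medial_pa_deg: float,
    lateral_pa_deg: float,
    twist_rad: float,
    phi0: float,
    n_steps: int = 400,
) -> np.ndarray:
    """Curve with exact arc length and exact end-tangent angles to the x-axis.

    The polar angle of the unit tangent (to the medial->lateral x-axis)
    holds the end value constant over a terminal plateau of 10 % of arc
    length at each end — so the average tangent over the attachment region,
    which is what the pennation measurement uses, carries exactly the drawn
    angle — and ramps linearly in between.  The azimuth twists linearly by
    ``twist_rad``.  Positions are the cumulative trapezoidal integral of the
    unit tangent field, so arc length is exactly ``length_cm`` up to
    quadrature error ~ (L / n_steps)^2.
    """
    s = np.linspace(0.0, length_cm, n_steps + 1)
    # plateau matches the measurement's default terminal region fraction
    ramp = np.clip((s / length_cm - 0.1) / 0.8, 0.0, 1.0)
    a = np.radians(medial_pa_deg + (lateral_pa_deg - medial_pa_deg) * ramp)
    phi = phi0 + twist_rad * s / length_cm
    t = np.column_stack([np.cos(a), np.sin(a) * np.cos(phi), np.sin(a) * np.sin(phi)])
    ds = length_cm / n_steps
    steps = 0.5 * (t[:-1] + t[1:]) * ds
    pos = np.vstack([[0.0, 0.0, 0.0], np.cumsum(steps, axis=0)])
    return pos


def _digitize(
    curve: np.ndarray,
    length_cm: float,
    n_points: int,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample n ordered sites along the curve (jittered spacing) + stylus noise."""
    s_grid = np.linspace(0.0, length_cm, len(curve))
    s = np.linspace(0.0, length_cm, n_points)
    if n_points > 2:
        jitter = rng.uniform(-0.2, 0.2, n_points - 2) * (length_cm / (n_points - 1))
        s[1:-1] = np.sort(s[1:-1] + jitter)
    pts = np.column_stack([np.interp(s, s_grid, curve[:, k]) for k in range(3)])
    if noise_sd > 0:
        # noise_sd is the RMS 3D displacement (device point-accuracy figure),
        # so each coordinate gets sd / sqrt(3)
        pts = pts + rng.normal(0.0, noise_sd / np.sqrt(3.0), pts.shape)
    return pts


_PART_LIST = (Part.SUPERFICIAL, Part.MIDDLE, Part.DEEP)

# region placement (frame coords, cm): anterior tendon axis near ap=+1,
# posterior near ap=-1.5; lateral attachments spread near the tendon.
_REGION_AP_OFFSET = {Region.ANTERIOR: 1.0, Region.POSTERIOR: -1.5}


def _tendon_axis(region: Region, rng: np.random.Generator, noise_sd: float) -> np.ndarray:
    x = np.linspace(2.0, 10.0, 30)
    y = np.full_like(x, _REGION_AP_OFFSET[region])
    z = np.full_like(x, -0.3)
    pts = np.column_stack([x, y, z])
    if noise_sd > 0:
        pts = pts + rng.normal(0.0, noise_sd / np.sqrt(3.0), pts.shape)
    return pts


def _tendon_outlines(rng: np.random.Generator, spacing_mm: float) -> list:
    """Elliptical periphery outlines at a few depths, dots ~spacing_mm apart."""
    from .specimen import TendonOutline

    outlines = []
    for depth in (0.0, 3.5, 7.0):
        a, b = 1.8 - 0.08 * depth / 3.5, 1.0 - 0.05 * depth / 3.5
        theta = np.linspace(0.0, 2 * np.pi, 720)
        xy = np.column_stack([9.0 + a * np.cos(theta), 0.2 + b * np.sin(theta)])
        seg = np.linalg.norm(np.diff(xy, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        n_dots = max(3, int(cum[-1] / (spacing_mm / 10.0)))
        s = np.linspace(0.0, cum[-1], n_dots, endpoint=False)
        dots = np.column_stack(
            [np.interp(s, cum, xy[:, 0]), np.interp(s, cum, xy[:, 1]),
             np.full(len(s), -depth / 10.0)]
        )
        outlines.append(TendonOutline(depth_mm=depth, points=dots))
    return outlines


def _tear_geometry(
    category: TearCategory, config: GeneratorConfig, rng: np.random.Generator
) -> tuple[TearRecord, Optional[np.ndarray]]:
    if category is TearCategory.A:
        return TearRecord("partial", False), None
    cor_t, sag_t = config.tear_targets[category.value]
    cor = cor_t * np.exp(rng.normal(0.0, config.tear_spread))
    sag = sag_t * np.exp(rng.normal(0.0, config.tear_spread))
    # elliptical boundary in the transverse plane: ml extent = coronal
    # diameter, ap extent = sagittal diameter (caliper largest diameters)
    theta = np.linspace(0.0, 2 * np.pi, 48, endpoint=False)
    boundary = np.column_stack(
        [10.0 + cor / 2 * np.cos(theta), 0.5 + sag / 2 * np.sin(theta), np.zeros(48)]
    )
    tear = TearRecord(
        "full",
        spans_full_sagittal_width=(category is TearCategory.C),
        coronal_diameter_cm=float(cor),
        sagittal_diameter_cm=float(sag),
    )
    return tear, boundary


def _landmarks(rng: np.random.Generator) -> LandmarkSet:
    jitter = lambda: rng.normal(0.0, 0.15, 3)
    return LandmarkSet(
        scapular_spine=np.array([-1.0, -1.0, 0.5]) + jitter(),
        coracoid_process=np.array([9.5, 3.5, -0.5]) + jitter(),
        greater_tubercle=np.array([11.5, 0.0, -0.2]) + jitter(),
    )


def generate_specimen(
    category: TearCategory | str,
    config: GeneratorConfig,
    specimen_id: Optional[str] = None,
    seed_seq: Optional[np.random.SeedSequence] = None,
    posterior_absent: Optional[bool] = None,
) -> tuple[Specimen, pd.DataFrame]:
    """One synthetic digitized specimen plus its per-bundle ground truth.

    Deterministic given the config seed (or an explicit spawned
    ``seed_seq``).  Ground truth holds the drawn (not measured) FBL and end
    pennation angles of every bundle, relative to the region's true tendon
    axis, for parameter-recovery testing.
    """
    category = TearCategory(category)
    if seed_seq is None:
        seed_seq = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(seed_seq)
    if specimen_id is None:
        specimen_id = f"SYN-{category.value}-{seed_seq.entropy}"

    if posterior_absent is None:
        posterior_absent = config.posterior_absent
    regions = [Region.ANTERIOR]
    if not (posterior_absent and category is TearCategory.C):
        regions.append(Region.POSTERIOR)

    noise = config.digitization_noise_sd_cm
    landmarks = _landmarks(rng)
    tear, boundary = _tear_geometry(category, config, rng)
    axes = {r: _tendon_axis(r, rng, min(noise, 0.01)) for r in regions}
    outlines = _tendon_outlines(rng, config.outline_dot_spacing_mm)

    bundles = []
    truth_rows = []
    bundle_streams = iter(seed_seq.spawn(4096))
    for region in regions:
        ap_off = _REGION_AP_OFFSET[region]
        for part_idx, part in enumerate(_PART_LIST):
            key = (region.value, part.value, category.value)
            if key not in config.cell_targets:
                raise ValidationError(f"no architecture target configured for cell {key}")
            fbl_t, lat_t, med_t = config.cell_targets[key]
            for layer in range(config.layers_per_part):
                depth_mm = (part_idx * config.layers_per_part + layer) * config.layer_spacing_mm
                layer_rng = np.random.default_rng(next(bundle_streams))
                n_bundles = int(
                    layer_rng.integers(config.bundles_per_layer[0], config.bundles_per_layer[1] + 1)
                )
                fbls = _draw_fbl(layer_rng, fbl_t, config.fbl_spread, n_bundles)
                lats = _draw_pa(layer_rng, lat_t, config.pa_spread_deg, n_bundles)
                meds = _draw_pa(layer_rng, med_t, config.pa_spread_deg, n_bundles)
                for k in range(n_bundles):
                    # penniform (anterior): lateral ends converge onto the
                    # tendon axis; fusiform (posterior): parallel stacking.
                    if region is Region.ANTERIOR:
                        attach = np.array(
                            [layer_rng.uniform(6.5, 9.5), ap_off, -0.3 - depth_mm / 10.0]
                        )
                    else:
                        attach = np.array(
                            [layer_rng.uniform(7.0, 9.0),
                             ap_off - 0.8 + 1.6 * (k + 0.5) / n_bundles,
                             -0.3 - depth_mm / 10.0]
                        )
                    phi0 = layer_rng.uniform(0.0, 2 * np.pi)
                    curve = _integrate_tangent_field(
                        fbls[k], meds[k], lats[k], config.fiber_twist_rad, phi0
                    )
                    curve = curve + (attach - curve[-1])  # pin the lateral attachment
                    n_pts = int(
                        layer_rng.integers(config.points_per_bundle[0], config.points_per_bundle[1] + 1)
                    )
                    pts = _digitize(curve, fbls[k], n_pts, noise, layer_rng)
                    bid = f"{specimen_id}:{region.value[:1]}{part.value[:1]}{depth_mm:04.1f}-{k:03d}"
                    bundles.append(
                        DigitizedFiberBundle(
                            bundle_id=bid, region=region, part=part,
                            layer_depth_mm=depth_mm, points=pts,
                        )
                    )
                    truth_rows.append(
                        {
                            "specimen_id": specimen_id, "bundle_id": bid,
                            "region": region.value, "part": part.value,
                            "category": category.value, "layer_depth_mm": depth_mm,
                            "true_fbl_cm": float(fbls[k]),
                            "true_lat_pa_deg": float(lats[k]),
                            "true_med_pa_deg": float(meds[k]),
                        }
                    )

    specimen = Specimen(
        specimen_id=specimen_id,
        side=Side.RIGHT if rng.random() < 10 / 12 else Side.LEFT,
        sex=Sex.F if rng.random() < 9 / 12 else Sex.M,
        age_years=float(np.clip(np.round(rng.normal(82.0, 11.0)), 60, 100)),
        landmarks=landmarks,
        tear=tear,
        category=category,
        bundles=bundles,
        tendon_outlines=outlines,
        tendon_axis_points=axes,
        tear_boundary=boundary,
    )
    return specimen, pd.DataFrame(truth_rows)


def generate_cohort(
    n_per_category: int, config: GeneratorConfig
) -> list[tuple[Specimen, pd.DataFrame]]:
    """n specimens per tear category (default study: 4 x {A, B, C} = 12).

    Independent seeded sub-streams per specimen; each category-C specimen
    lacks a posterior region with ``posterior_absent_probability`` (half of
    them in the modeled study).
    """
    if n_per_category < 1:
        raise ValidationError("n_per_category must be >= 1")
    master = np.random.SeedSequence(config.seed)
    streams = master.spawn(3 * n_per_category + 1)
    flag_rng = np.random.default_rng(streams[-1])
    out = []
    i = 0
    for category in (TearCategory.A, TearCategory.B, TearCategory.C):
        for k in range(n_per_category):
            absent = (
                bool(flag_rng.random() < config.posterior_absent_probability)
                if category is TearCategory.C
                else False
            )
            spec, truth = generate_specimen(
                category, config,
                specimen_id=f"SYN-{category.value}{k + 1}",
                seed_seq=streams[i], posterior_absent=absent,
            )
            out.append((spec, truth))
            i += 1
    return out
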