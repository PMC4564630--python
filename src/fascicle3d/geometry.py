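"""Spline reconstruction of digitized fiber bundles and architecture measures.

Each digitized fascicle (an ordered 3D point sequence, medial attachment
first) is reconstructed into an interpolating cubic Catmull-Rom spline,
re-parameterized by arc length, and measured:

* fiber bundle length (FBL) — the entire arc length of the curve, cm;
* lateral / medial pennation angle (PA) — the acute angle (degrees) between
  the average end tangent over a terminal region of the curve and the
  muscle's line of force, the axis best approximating the intramuscular
  tendon (total-least-squares line through digitized tendon-axis points).

All measures are invariant under rigid motion and the angles under scaling.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.interpolate import CubicHermiteSpline

from .specimen import (
    DegenerateGeometryError,
    DigitizedFiberBundle,
    Region,
    Specimen,
    ValidationError,
    as_points,
)

_KNOT_EXPONENT = {"uniform": 0.0, "chordal": 1.0, "centripetal": 0.5}


@dataclass(frozen=True)
class GeometryConfig:
    """Numerical knobs of the measurement pipeline.

    n_samples: points in the uniform arc-length resampling (model export).
    region_fraction: terminal fraction of arc length over which end tangents
        are averaged (the "medial/lateral region" of the curve).
    knot_parameterization: Catmull-Rom knot spacing rule; centripetal avoids
        cusps and self-intersections on unevenly spaced digitized points.
    quadrature_subdivisions: dense samples per spline segment used for
        arc-length integration (cumulative chord summation).
    """

    n_samples: int = 100
    region_fraction: float = 0.10
    knot_parameterization: str = "centripetal"
    quadrature_subdivisions: int = 200
    tangent_average_samples: int = 20

    def __post_init__(self):
        if self.n_samples < 2:
            raise ValidationError("n_samples must be >= 2")
        if not (0.0 < self.region_fraction <= 0.5):
            raise ValidationError("region_fraction must be in (0, 0.5]")
        if self.knot_parameterization not in _KNOT_EXPONENT:
            raise ValidationError(
                f"unknown knot parameterization {self.knot_parameterization!r}"
            )
        if self.quadrature_subdivisions < 8:
            raise ValidationError("quadrature_subdivisions must be >= 8")


class SplineCurve:
    """Interpolating cubic Catmull-Rom spline with arc-length parameterization.

    Endpoint segments use reflected phantom points (P_-1 = 2 P_0 - P_1 and
    symmetrically at the far end), which makes the end tangent parallel to
    the terminal chord.  Arc length is accumulated over a dense per-segment
    sampling and inverted for arc-length lookup of points and tangents.
    """

    def __init__(
        self,
        points: np.ndarray,
        knot_parameterization: str = "centripetal",
        quadrature_subdivisions: int = 200,
    ):
        pts = as_points(points)
        if len(pts) < 4:
            raise ValidationError(f"spline needs >= 4 points, got {len(pts)}")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(seg == 0.0):
            idx = int(np.argmin(seg))
            raise ValidationError(f"duplicate consecutive point at index {idx}")
        alpha = _KNOT_EXPONENT[knot_parameterization]

        ext = np.vstack([2 * pts[0] - pts[1], pts, 2 * pts[-1] - pts[-2]])
        dt = np.linalg.norm(np.diff(ext, axis=0), axis=1) ** alpha
        dt = np.where(dt <= 0.0, 1e-12, dt)
        t_ext = np.concatenate([[0.0], np.cumsum(dt)])
        knots = t_ext[1:-1]
        # finite-difference Catmull-Rom tangents over phantom-extended points
        dydx = (ext[2:] - ext[:-2]) / (t_ext[2:] - t_ext[:-2])[:, None]

        self.control_points = pts
        self.knots = knots - knots[0]
        self._spline = CubicHermiteSpline(self.knots, pts, dydx, axis=0)
        self._deriv = self._spline.derivative()
        self.uniform_samples: Optional[np.ndarray] = None

        # dense arc-length table: quadrature_subdivisions samples per segment
        q = quadrature_subdivisions
        n_seg = len(pts) - 1
        params = np.empty(n_seg * q + 1)
        for i in range(n_seg):
            params[i * q : (i + 1) * q] = np.linspace(
                self.knots[i], self.knots[i + 1], q, endpoint=False
            )
        params[-1] = self.knots[-1]
        dense = self._spline(params)
        chord = np.linalg.norm(np.diff(dense, axis=0), axis=1)
        self._params = params
        self._cumlen = np.concatenate([[0.0], np.cumsum(chord)])

    @property
    def total_arc_length(self) -> float:
        return float(self._cumlen[-1])

    def _param_at_arclength(self, s) -> np.ndarray:
        s = np.clip(np.asarray(s, dtype=float), 0.0, self.total_arc_length)
        return np.interp(s, self._cumlen, self._params)

    def point_at_arclength(self, s) -> np.ndarray:
        """Curve point(s) at arc-length position(s) s in [0, L]."""
        return self._spline(self._param_at_arclength(s))

    def tangent_at_arclength(self, s) -> np.ndarray:
        """Unit tangent(s), oriented along the traversal (medial -> lateral)."""
        d = np.atleast_2d(self._deriv(self._param_at_arclength(s)))
        return np.squeeze(d / np.linalg.norm(d, axis=1, keepdims=True))


def fit_catmull_rom(points: np.ndarray, config: GeometryConfig = GeometryConfig()) -> SplineCurve:
    """Interpolating centripetal Catmull-Rom spline through the digitized points."""
    return SplineCurve(
        points,
        knot_parameterization=config.knot_parameterization,
        quadrature_subdivisions=config.quadrature_subdivisions,
    )


def arclength_resample(curve: SplineCurve, n_samples: int) -> SplineCurve:
    """Populate ``curve.uniform_samples`` with n points equally spaced in arc length."""
    if n_samples < 2:
        raise ValidationError("n_samples must be >= 2")
    s = np.linspace(0.0, curve.total_arc_length, n_samples)
    curve.uniform_samples = np.atleast_2d(curve.point_at_arclength(s))
    return curve


def fiber_bundle_length(curve: SplineCurve) -> float:
    """FBL: the entire arc length of the reconstructed curve, cm."""
    return curve.total_arc_length


def end_tangent(
    curve: SplineCurve,
    end: str,
    region_fraction: float = 0.10,
    n_average: int = 20,
) -> np.ndarray:
    """Average unit tangent over the terminal region of the curve.

    ``end`` is "medial" (start of traversal) or "lateral" (end).  Unit
    tangents at ``n_average`` evenly spaced arc positions within the terminal
    ``region_fraction`` of total arc length are averaged and re-normalized;
    the result points in the medial -> lateral traversal direction at both
    ends.  Averaging stabilizes the estimate against digitization noise at
    the attachment sites.
    """
    if not (0.0 < region_fraction <= 0.5):
        raise ValidationError("region_fraction must be in (0, 0.5]")
    L = curve.total_arc_length
    if end == "medial":
        s = np.linspace(0.0, region_fraction * L, n_average)
    elif end == "lateral":
        s = np.linspace((1.0 - region_fraction) * L, L, n_average)
    else:
        raise ValidationError(f"end must be 'medial' or 'lateral', got {end!r}")
    t = np.atleast_2d(curve.tangent_at_arclength(s))
    mean = t.mean(axis=0)
    n = np.linalg.norm(mean)
    if n <= 1e-12:
        raise DegenerateGeometryError("end tangents cancel; cannot define an orientation")
    return mean / n


@dataclass(frozen=True)
class LineOfForce:
    """Unit axis approximating the intramuscular tendon, oriented medial -> lateral."""

    anchor: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "anchor", np.asarray(self.anchor, dtype=float))
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n <= 1e-12:
            raise DegenerateGeometryError("line of force direction has zero norm")
        object.__setattr__(self, "direction", d / n)


def estimate_line_of_force(tendon_axis_points: np.ndarray) -> LineOfForce:
    """Total-least-squares line through the digitized tendon-axis points.

    The direction is the first principal axis of the centered points (left
    singular direction of the scatter), sign-oriented medial -> lateral by
    the input ordering; the anchor is the centroid.
    """
    pts = as_points(tendon_axis_points)
    if len(pts) < 2:
        raise ValidationError("line of force needs >= 2 points")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    if np.allclose(centered, 0.0, atol=1e-12):
        raise DegenerateGeometryError("all tendon-axis points coincide")
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    if direction @ (pts[-1] - pts[0]) < 0:
        direction = -direction
    return LineOfForce(anchor=centroid, direction=direction)


@dataclass(frozen=True)
class PennationPair:
    """Lateral and medial pennation angles of one fascicle, degrees in [0, 90]."""

    lateral_pa: float
    medial_pa: float

    def __post_init__(self):
        for name in ("lateral_pa", "medial_pa"):
            v = getattr(self, name)
            if not (0.0 <= v <= 90.0):
                raise ValidationError(f"{name} = {v} outside [0, 90] degrees")


def pennation_angle(tangent: np.ndarray, lof: LineOfForce) -> float:
    """Acute angle (degrees) between a fiber tangent and the line of force.

    Folded to [0, 90] via the absolute cosine, matching the convention that a
    pennation angle is reported as the acute angle between the fascicle and
    the axis of pull.
    """
    t = np.asarray(tangent, dtype=float)
    n = np.linalg.norm(t)
    if n <= 1e-12:
        raise ValidationError("zero-norm tangent vector")
    c = abs((t / n) @ lof.direction)
    return float(np.degrees(np.arccos(min(c, 1.0))))


def measure_bundle(
    bundle: DigitizedFiberBundle,
    lof: LineOfForce,
    config: GeometryConfig = GeometryConfig(),
) -> tuple[float, PennationPair]:
    """Fit, resample and measure one bundle: (FBL cm, pennation pair)."""
    curve = fit_catmull_rom(bundle.points, config)
    arclength_resample(curve, config.n_samples)
    fbl = fiber_bundle_length(curve)
    pa = PennationPair(
        lateral_pa=pennation_angle(
            end_tangent(curve, "lateral", config.region_fraction, config.tangent_average_samples), lof
        ),
        medial_pa=pennation_angle(
            end_tangent(curve, "medial", config.region_fraction, config.tangent_average_samples), lof
        ),
    )
    return fbl, pa


def lines_of_force(specimen: Specimen) -> dict[Region, LineOfForce]:
    """Region-specific lines of force from the specimen's tendon-axis points.

    The anterior and posterior regions attach to separate intramuscular
    tendons, so each region gets its own axis; a specimen carrying a single
    undifferentiated axis applies it to every region.
    """
    if not specimen.tendon_axis_points:
        raise ValidationError(f"specimen {specimen.specimen_id}: no tendon axis points")
    return {r: estimate_line_of_force(p) for r, p in specimen.tendon_axis_points.items()}


def measure_specimen(
    specimen: Specimen, config: GeometryConfig = GeometryConfig()
) -> pd.DataFrame:
    """Measure every bundle of a specimen against its regional line of force.

    Returns one row per bundle: specimen_id, bundle_id, region, part,
    layer_depth_mm, category, fbl_cm, lat_pa_deg, med_pa_deg.
    """
    lofs = lines_of_force(specimen)
    rows = []
    for b in specimen.bundles:
        lof = lofs.get(b.region)
        if lof is None:
            raise ValidationError(
                f"specimen {specimen.specimen_id}: no tendon axis for region {b.region.value}"
            )
        fbl, pa = measure_bundle(b, lof, config)
        rows.append(
            {
                "specimen_id": specimen.specimen_id,
                "bundle_id": b.bundle_id,
                "region": b.region.value,
                "part": b.part.value,
                "layer_depth_mm": b.layer_depth_mm,
                "category": specimen.category.value,
                "fbl_cm": fbl,
                "lat_pa_deg": pa.lateral_pa,
                "med_pa_deg": pa.medial_pa,
            }
        )
    columns = [
        "specimen_id", "bundle_id", "region", "part", "layer_depth_mm",
        "category", "fbl_cm", "lat_pa_deg", "med_pa_deg",
    ]
    return pd.DataFrame(rows, columns=columns)
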