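"""Domain model for digitized supraspinatus specimens.

A specimen is a cadaveric shoulder whose supraspinatus fiber bundles were
recorded *in situ* as ordered 3D point sequences (cm) during serial
dissection, together with tendon periphery outlines, three bony landmark
points (lateral scapular spine, coracoid process, greater tubercle) and
tear metadata.  Tears are categorized A (partial thickness), B
(full-thickness without retraction) or C (full-thickness with retraction,
i.e. the tear spans the tendon's entire sagittal width).
"""
from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import pdist


class DegenerateGeometryError(ValueError):
    """Raised when input geometry is collinear/coincident beyond repair."""


class ValidationError(ValueError):
    """Raised when domain invariants are violated."""


class Region(str, enum.Enum):
    ANTERIOR = "anterior"
    POSTERIOR = "posterior"


class Part(str, enum.Enum):
    SUPERFICIAL = "superficial"
    MIDDLE = "middle"
    DEEP = "deep"


class TearCategory(str, enum.Enum):
    A = "A"  # partial thickness
    B = "B"  # full thickness, no retraction
    C = "C"  # full thickness with retraction


class Side(str, enum.Enum):
    LEFT = "L"
    RIGHT = "R"


class Sex(str, enum.Enum):
    M = "M"
    F = "F"


def as_point(p: Sequence[float]) -> np.ndarray:
    """Validate and convert a length-3 coordinate (cm) to a float array."""
    arr = np.asarray(p, dtype=float)
    if arr.shape != (3,):
        raise ValidationError(f"a 3D point needs exactly 3 coordinates, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"non-finite coordinate in point {arr}")
    return arr


def as_points(pts) -> np.ndarray:
    """Validate an ordered (n, 3) coordinate array (cm)."""
    arr = np.asarray(pts, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValidationError(f"expected an (n, 3) point array, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValidationError("non-finite coordinates in point array")
    return arr


@dataclass(frozen=True)
class LandmarkSet:
    """The three bony reference points demarcated with screws before digitization."""

    scapular_spine: np.ndarray
    coracoid_process: np.ndarray
    greater_tubercle: np.ndarray

    def __post_init__(self):
        for name in ("scapular_spine", "coracoid_process", "greater_tubercle"):
            object.__setattr__(self, name, as_point(getattr(self, name)))
        a, b, c = self.scapular_spine, self.coracoid_process, self.greater_tubercle
        # triangle area > 0 <=> non-collinear; also guards coincident points
        area = 0.5 * np.linalg.norm(np.cross(b - a, c - a))
        scale = max(np.linalg.norm(b - a), np.linalg.norm(c - a), 1.0)
        if area <= 1e-9 * scale * scale:
            raise DegenerateGeometryError(
                "landmarks are collinear or coincident; cannot anchor a specimen frame"
            )


@dataclass(frozen=True)
class SpecimenFrame:
    """Right-handed orthonormal anatomical frame anchored on the landmarks.

    Axes: ``medial_lateral`` (spine -> greater tubercle), ``anterior_posterior``
    (toward the coracoid side), ``superior_inferior`` (their cross product).
    The coronal plane is spanned by (medial_lateral, superior_inferior); the
    sagittal plane by (anterior_posterior, superior_inferior).
    """

    origin: np.ndarray
    medial_lateral: np.ndarray
    anterior_posterior: np.ndarray
    superior_inferior: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "origin", as_point(self.origin))
        for name in ("medial_lateral", "anterior_posterior", "superior_inferior"):
            object.__setattr__(self, name, as_point(getattr(self, name)))
        R = self.rotation
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise ValidationError("frame axes are not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValidationError("frame is not right-handed")

    @property
    def rotation(self) -> np.ndarray:
        """3x3 matrix with the axes as rows (world -> frame rotation)."""
        return np.vstack([self.medial_lateral, self.anterior_posterior, self.superior_inferior])

    def to_frame(self, points: np.ndarray) -> np.ndarray:
        """Express world coordinates in frame coordinates (ml, ap, si)."""
        pts = np.atleast_2d(as_points(np.atleast_2d(points)))
        return (pts - self.origin) @ self.rotation.T

    def from_frame(self, coords: np.ndarray) -> np.ndarray:
        return np.atleast_2d(coords) @ self.rotation + self.origin


def build_specimen_frame(landmarks: LandmarkSet) -> SpecimenFrame:
    """Deterministic orthonormal frame from the three landmark screws.

    The medial-lateral axis points from the scapular spine landmark toward
    the greater tubercle; the anterior-posterior axis is the coracoid
    direction orthogonalized against it; superior-inferior completes a
    right-handed triad.  Equivariant under rigid motion of the landmarks.
    """
    ss, cp, gt = landmarks.scapular_spine, landmarks.coracoid_process, landmarks.greater_tubercle
    ml = gt - ss
    ml = ml / np.linalg.norm(ml)
    v = cp - ss
    ap = v - (v @ ml) * ml
    n = np.linalg.norm(ap)
    if n <= 1e-12:
        raise DegenerateGeometryError("coracoid landmark lies on the medial-lateral axis")
    ap = ap / n
    si = np.cross(ml, ap)
    return SpecimenFrame(origin=ss, medial_lateral=ml, anterior_posterior=ap, superior_inferior=si)


@dataclass
class DigitizedFiberBundle:
    """One fascicle digitized medial attachment first, lateral last.

    ``points`` is the ordered (n, 3) array of stylus coordinates in cm;
    ``layer_depth_mm`` is depth of the dissection layer below the
    superficial surface.  Typical digitization uses 10-20 sites per bundle;
    counts outside that range are accepted with a warning.
    """

    bundle_id: str
    region: Region
    part: Part
    layer_depth_mm: float
    points: np.ndarray

    def __post_init__(self):
        self.region = Region(self.region)
        self.part = Part(self.part)
        self.points = as_points(self.points)
        n = len(self.points)
        if n < 4:
            raise ValidationError(
                f"bundle {self.bundle_id}: needs >= 4 digitized points, got {n}"
            )
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(seg == 0.0):
            idx = int(np.argmin(seg))
            raise ValidationError(
                f"bundle {self.bundle_id}: consecutive duplicate point at index {idx}"
            )
        if not (10 <= n <= 20):
            warnings.warn(
                f"bundle {self.bundle_id}: {n} points is outside the typical 10-20 range",
                stacklevel=2,
            )


@dataclass
class TendonOutline:
    """Closed polyline of paint dots (~2 mm apart) around the tendon periphery."""

    depth_mm: float
    points: np.ndarray

    def __post_init__(self):
        self.points = as_points(self.points)
        if len(self.points) < 3:
            raise ValidationError("tendon outline needs >= 3 points")


@dataclass
class TearRecord:
    """Caliper record of a supraspinatus tendon tear."""

    thickness: str  # "partial" | "full"
    spans_full_sagittal_width: bool
    coronal_diameter_cm: Optional[float] = None
    sagittal_diameter_cm: Optional[float] = None

    def __post_init__(self):
        if self.thickness not in ("partial", "full"):
            raise ValidationError(f"tear thickness must be 'partial' or 'full', got {self.thickness!r}")
        for name in ("coronal_diameter_cm", "sagittal_diameter_cm"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValidationError(f"{name} must be > 0 when present, got {v}")


def classify_tear(tear: TearRecord) -> TearCategory:
    """A = partial thickness; B = full thickness without retraction; C = with.

    Retraction is defined as the tear involving the entire sagittal width of
    the tendon.  A partial-thickness tear flagged as spanning the full width
    is contradictory and rejected.
    """
    if tear.thickness == "partial":
        if tear.spans_full_sagittal_width:
            raise ValidationError(
                "a partial-thickness tear cannot span the full sagittal tendon width"
            )
        return TearCategory.A
    return TearCategory.C if tear.spans_full_sagittal_width else TearCategory.B


def measure_tear_dimensions(
    tear_boundary: np.ndarray, frame: SpecimenFrame
) -> tuple[float, float]:
    """Largest tear diameters (cm) in the coronal and sagittal planes.

    Each diameter is the maximum pairwise distance between boundary points
    after orthogonal projection onto the respective anatomical plane of the
    frame, mirroring a caliper's largest-diameter measurement.  A boundary
    that collapses to a point after projection yields 0 with a warning.
    """
    pts = as_points(tear_boundary)
    if len(pts) < 3:
        raise ValidationError("tear boundary needs >= 3 points")
    local = frame.to_frame(pts)
    coronal = local[:, [0, 2]]   # (ml, si)
    sagittal = local[:, [1, 2]]  # (ap, si)

    def _diameter(plane_pts: np.ndarray, label: str) -> float:
        d = float(pdist(plane_pts).max())
        if d == 0.0:
            warnings.warn(f"tear boundary degenerate in the {label} plane; diameter = 0", stacklevel=3)
        return d

    return _diameter(coronal, "coronal"), _diameter(sagittal, "sagittal")


@dataclass
class Specimen:
    """One digitized shoulder: metadata, landmarks, bundles, tendon geometry."""

    specimen_id: str
    side: Side
    sex: Sex
    age_years: float
    landmarks: LandmarkSet
    tear: TearRecord
    category: TearCategory
    bundles: list[DigitizedFiberBundle] = field(default_factory=list)
    tendon_outlines: list[TendonOutline] = field(default_factory=list)
    tendon_axis_points: dict[Region, np.ndarray] = field(default_factory=dict)
    tear_boundary: Optional[np.ndarray] = None

    def __post_init__(self):
        self.side = Side(self.side)
        self.sex = Sex(self.sex)
        self.category = TearCategory(self.category)
        expected = classify_tear(self.tear)
        if expected != self.category:
            raise ValidationError(
                f"specimen {self.specimen_id}: category {self.category.value} inconsistent "
                f"with tear record (classifies as {expected.value})"
            )
        self.tendon_axis_points = {
            Region(k): as_points(v) for k, v in self.tendon_axis_points.items()
        }
        if self.tear_boundary is not None:
            self.tear_boundary = as_points(self.tear_boundary)

    @property
    def frame(self) -> SpecimenFrame:
        return build_specimen_frame(self.landmarks)

    def posterior_region_present(self) -> bool:
        return any(b.region is Region.POSTERIOR for b in self.bundles)


def posterior_region_present(specimen: Specimen) -> bool:
    """True iff at least one bundle is labelled posterior."""
    return specimen.posterior_region_present()


def mirror_to_right(specimen: Specimen) -> Specimen:
    """Reflect a left-side specimen across its sagittal plane (canonical right frame).

    All point data are expressed in frame coordinates, the anterior-posterior
    component negated, and mapped back to world coordinates; pooled statistics
    then treat left and right shoulders identically.  Right-side specimens are
    returned unchanged.
    """
    if specimen.side is Side.RIGHT:
        return specimen
    frame = specimen.frame

    def _reflect(pts: np.ndarray) -> np.ndarray:
        local = frame.to_frame(pts)
        local[:, 1] *= -1.0
        return frame.from_frame(local)

    bundles = [
        DigitizedFiberBundle(
            bundle_id=b.bundle_id, region=b.region, part=b.part,
            layer_depth_mm=b.layer_depth_mm, points=_reflect(b.points),
        )
        for b in specimen.bundles
    ]
    outlines = [TendonOutline(o.depth_mm, _reflect(o.points)) for o in specimen.tendon_outlines]
    axes = {r: _reflect(p) for r, p in specimen.tendon_axis_points.items()}
    lm = LandmarkSet(
        scapular_spine=_reflect(specimen.landmarks.scapular_spine[None])[0],
        coracoid_process=_reflect(specimen.landmarks.coracoid_process[None])[0],
        greater_tubercle=_reflect(specimen.landmarks.greater_tubercle[None])[0],
    )
    boundary = None if specimen.tear_boundary is None else _reflect(specimen.tear_boundary)
    return Specimen(
        specimen_id=specimen.specimen_id, side=Side.RIGHT, sex=specimen.sex,
        age_years=specimen.age_years, landmarks=lm, tear=specimen.tear,
        category=specimen.category, bundles=bundles, tendon_outlines=outlines,
        tendon_axis_points=axes, tear_boundary=boundary,
    )
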