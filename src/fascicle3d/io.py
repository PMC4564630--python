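"""File formats: specimen manifests (JSON), point data (CSV), OBJ models.

Point-data CSV schema (one row per digitized point)::

    specimen_id,record_type,record_id,region,part,layer_depth_mm,point_index,x_cm,y_cm,z_cm

record_type in {fiber, tendon_outline, tendon_axis, tear_boundary}; points
of a record are ordered by point_index, fiber points medial -> lateral.
"""
from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .specimen import (
    DigitizedFiberBundle,
    LandmarkSet,
    Region,
    Specimen,
    TendonOutline,
    TearRecord,
    ValidationError,
)

POINT_COLUMNS = [
    "specimen_id", "record_type", "record_id", "region", "part",
    "layer_depth_mm", "point_index", "x_cm", "y_cm", "z_cm",
]


def load_table1() -> pd.DataFrame:
    """Packaged specimen-summary fixture (12 cadaveric shoulders).

    Columns: specimen_id, specimen_number, side, sex, age_years, category,
    rct_location, coronal_cm, sagittal_cm (NaN where not measured, i.e.
    partial-thickness tears), posterior_region ("yes"/"no").
    """
    with resources.files("fascicle3d.data").joinpath("table1.csv").open("r") as fh:
        return pd.read_csv(fh)


def specimen_to_tables(specimen: Specimen) -> tuple[dict, pd.DataFrame]:
    """Specimen -> (manifest dict, point-data DataFrame)."""
    manifest = {
        "specimen_id": specimen.specimen_id,
        "side": specimen.side.value,
        "sex": specimen.sex.value,
        "age": specimen.age_years,
        "tear": {
            "thickness": specimen.tear.thickness,
            "spans_full_sagittal_width": specimen.tear.spans_full_sagittal_width,
            "coronal_cm": specimen.tear.coronal_diameter_cm,
            "sagittal_cm": specimen.tear.sagittal_diameter_cm,
        },
        "category": specimen.category.value,
        "landmarks": {
            "scapular_spine": specimen.landmarks.scapular_spine.tolist(),
            "coracoid_process": specimen.landmarks.coracoid_process.tolist(),
            "greater_tubercle": specimen.landmarks.greater_tubercle.tolist(),
        },
    }

    rows = []

    def _emit(record_type, record_id, points, region="", part="", depth=np.nan):
        for i, p in enumerate(np.atleast_2d(points)):
            rows.append(
                (specimen.specimen_id, record_type, record_id, region, part,
                 depth, i, p[0], p[1], p[2])
            )

    for b in specimen.bundles:
        _emit("fiber", b.bundle_id, b.points, b.region.value, b.part.value, b.layer_depth_mm)
    for k, o in enumerate(specimen.tendon_outlines):
        _emit("tendon_outline", f"outline-{k}", o.points, depth=o.depth_mm)
    for region, pts in specimen.tendon_axis_points.items():
        _emit("tendon_axis", f"axis-{region.value}", pts, region=region.value)
    if specimen.tear_boundary is not None:
        _emit("tear_boundary", "tear", specimen.tear_boundary)
    return manifest, pd.DataFrame(rows, columns=POINT_COLUMNS)


def write_specimen(specimen: Specimen, out_dir: Path) -> tuple[Path, Path]:
    """Write <id>.manifest.json and <id>.points.csv; returns the two paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest, points = specimen_to_tables(specimen)
    mpath = out_dir / f"{specimen.specimen_id}.manifest.json"
    ppath = out_dir / f"{specimen.specimen_id}.points.csv"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    points.to_csv(ppath, index=False, float_format="%.6f")
    return mpath, ppath


def read_specimen(manifest_path: Path, points_path: Optional[Path] = None) -> Specimen:
    """Rebuild a Specimen from its manifest JSON + point-data CSV."""
    manifest_path = Path(manifest_path)
    if points_path is None:
        points_path = manifest_path.with_name(
            manifest_path.name.replace(".manifest.json", ".points.csv")
        )
    try:
        m = json.loads(manifest_path.read_text())
    except json.JSONDecodeError as e:
        raise ValidationError(f"{manifest_path}: invalid manifest JSON ({e})") from e
    pts = pd.read_csv(points_path)
    missing = set(POINT_COLUMNS) - set(pts.columns)
    if missing:
        raise ValidationError(f"{points_path}: missing columns {sorted(missing)}")

    bundles, outlines, axes = [], [], {}
    boundary = None
    for (rtype, rid), rec in pts.groupby(["record_type", "record_id"], sort=False):
        rec = rec.sort_values("point_index")
        coords = rec[["x_cm", "y_cm", "z_cm"]].to_numpy()
        if rtype == "fiber":
            row = rec.iloc[0]
            bundles.append(
                DigitizedFiberBundle(
                    bundle_id=str(rid), region=row["region"], part=row["part"],
                    layer_depth_mm=float(row["layer_depth_mm"]), points=coords,
                )
            )
        elif rtype == "tendon_outline":
            outlines.append(TendonOutline(float(rec.iloc[0]["layer_depth_mm"]), coords))
        elif rtype == "tendon_axis":
            axes[Region(rec.iloc[0]["region"])] = coords
        elif rtype == "tear_boundary":
            boundary = coords
        else:
            raise ValidationError(f"{points_path}: unknown record_type {rtype!r}")

    lm = m["landmarks"]
    tear = m["tear"]
    return Specimen(
        specimen_id=m["specimen_id"],
        side=m["side"],
        sex=m["sex"],
        age_years=float(m["age"]),
        landmarks=LandmarkSet(
            scapular_spine=lm["scapular_spine"],
            coracoid_process=lm["coracoid_process"],
            greater_tubercle=lm["greater_tubercle"],
        ),
        tear=TearRecord(
            thickness=tear["thickness"],
            spans_full_sagittal_width=bool(tear["spans_full_sagittal_width"]),
            coronal_diameter_cm=tear.get("coronal_cm"),
            sagittal_diameter_cm=tear.get("sagittal_cm"),
        ),
        category=m["category"],
        bundles=bundles,
        tendon_outlines=outlines,
        tendon_axis_points=axes,
        tear_boundary=boundary,
    )


def write_ground_truth(truths: pd.DataFrame, path: Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    truths.to_csv(path, index=False, float_format="%.6f")
    return path


def export_obj(
    specimen: Specimen,
    path: Path,
    n_samples: int = 100,
    config=None,
) -> Path:
    """Wavefront OBJ model: fibers as uniformly resampled polylines grouped by
    region_part, tendon outlines as closed polylines, lines of force as
    two-vertex segments (mirrors the color-coded 3D muscle model)."""
    from .geometry import GeometryConfig, arclength_resample, fit_catmull_rom, lines_of_force

    if config is None:
        config = GeometryConfig(n_samples=n_samples)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"# fascicle3d model of specimen {specimen.specimen_id}"]
    vertex_count = 0

    def _polyline(points, closed=False):
        nonlocal vertex_count
        for p in points:
            lines.append(f"v {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}")
        idx = [str(vertex_count + i + 1) for i in range(len(points))]
        if closed:
            idx.append(idx[0])
        lines.append("l " + " ".join(idx))
        vertex_count += len(points)

    for b in specimen.bundles:
        lines.append(f"g fiber_{b.region.value}_{b.part.value}")
        lines.append(f"o {b.bundle_id}")
        curve = arclength_resample(fit_catmull_rom(b.points, config), config.n_samples)
        _polyline(curve.uniform_samples)
    for k, o in enumerate(specimen.tendon_outlines):
        lines.append("g tendon_outline")
        lines.append(f"o outline_{k}_depth_{o.depth_mm:g}mm")
        _polyline(o.points, closed=True)
    if specimen.tendon_axis_points:
        for region, lof in lines_of_force(specimen).items():
            lines.append("g line_of_force")
            lines.append(f"o lof_{region.value}")
            pts = specimen.tendon_axis_points[region]
            span = np.linalg.norm(pts[-1] - pts[0])
            _polyline(
                [lof.anchor - lof.direction * span / 2, lof.anchor + lof.direction * span / 2]
            )
    path.write_text("\n".join(lines) + "\n")
    return path


def sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
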