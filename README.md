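# fascicle3d

Quantifies the three-dimensional fiber-bundle architecture of the
supraspinatus — the rotator-cuff muscle most often affected by tendon
tears — from digitized cadaveric data, and compares that architecture
across muscle regions, depths, and tear severities.

During serial dissection, each fascicle is recorded *in situ* as an ordered
sequence of 3D stylus coordinates (cm), medial attachment first. From these
point sequences the package computes the two architectural parameters that
govern muscle function:

- **Fiber bundle length (FBL)** — each digitized fascicle is reconstructed
  as an interpolating cubic Catmull–Rom spline (centripetal knots, reflected
  phantom endpoints), re-parameterized by arc length, and FBL is taken as the
  entire arc length of the curve. FBL is proportional to muscle excursion
  and contraction velocity.
- **Pennation angle (PA)** — the acute angle between the fascicle and the
  muscle's line of force. The line of force is the total-least-squares axis
  through digitized points along the intramuscular tendon (one per region);
  the fascicle orientation at each attachment is the average unit tangent
  d**r**/ds over the terminal 10 % of arc length, yielding a *lateral* and a
  *medial* PA per bundle, folded to [0°, 90°] via
  θ = arccos |t̂ · û|.

Specimens carry a tear record classified **A** (partial-thickness tear),
**B** (full-thickness, no retraction) or **C** (full-thickness with
retraction, i.e. the tear spans the tendon's entire sagittal width), with
largest tear diameters measured as maximum pairwise extents of the tear
boundary projected onto the coronal and sagittal planes of a landmark-based
anatomical frame (scapular spine, coracoid process, greater tubercle).

Group comparisons follow small-sample nonparametric practice: per-cell
median (min–max) summaries; Mann–Whitney *U* (tie-corrected normal
approximation *without* continuity correction by default, or exact
permutation by full enumeration); Kruskal–Wallis across ≥ 3 groups; and
Bonferroni-adjusted pairwise comparisons (α/m, e.g. 0.05/3 = 0.0167). The
statistical layer is exposed as a model object:
`ArchitectureModel(measurements).fit()` returns an `ArchitectureResults`
with `.summaries`, `.tests`, and a `summary()` text report.

Because raw cadaveric digitizations are not publicly distributable, the
package includes a synthetic specimen generator that emulates the
digitization protocol (10–60 bundles per dissection layer, 10–20 points per
bundle, layers ~1.5 mm apart, tendon outline dots ~2 mm apart, isotropic
stylus noise) with per-(region, part, tear-category) architecture targets,
plus per-bundle ground truth for parameter-recovery testing. A packaged
specimen-summary table carries the demographics and tear dimensions of the
12-shoulder reference cohort.

## Worked example

```python
import pandas as pd
from fascicle3d import (ArchitectureModel, GeneratorConfig,
                        generate_cohort, measure_specimen)

cohort = generate_cohort(4, GeneratorConfig(seed=11))        # 4 x {A, B, C}
meas = pd.concat([measure_specimen(s) for s, _ in cohort], ignore_index=True)
res = ArchitectureModel(meas).fit()

summ = res.summaries
print(summ[(summ.part == "all") & (summ.region == "anterior")]
      [["category", "n_bundles", "fbl_cm_median",
        "lat_pa_deg_median", "med_pa_deg_median"]].to_string(index=False))
```

```
category  n_bundles  fbl_cm_median  lat_pa_deg_median  med_pa_deg_median
       A       1329       6.870873          14.423492          14.351540
       B       1211       5.184594          14.486724          15.640937
       C       1187       2.670520          23.365254          23.606209
```

Anterior-region FBL shortens monotonically with tear severity (A > B > C)
while both pennation angles are largest with retracted tears (category C) —
the architectural signature of medial retraction of the musculotendinous
unit. The accompanying tests confirm it:

```python
t = res.tests
kw = t[(t.family == "category comparison") & (t.region == "anterior")
       & (t.metric == "fbl_cm")].iloc[0]
print(f"Kruskal-Wallis anterior FBL: H = {kw.statistic:.1f}, p = {kw.p_value:.3g}")
# Kruskal-Wallis anterior FBL: H = 2577.7, p = 0
```

with all three Bonferroni-adjusted pairwise Mann–Whitney comparisons
significant at p < 0.0167.

The same workflow runs from the shell:

```bash
fascicle3d generate --seed 11 --out runs/cohort
fascicle3d measure  --in runs/cohort --out runs/meas     # + OBJ models
fascicle3d report   --in runs/meas  --out runs/report
```

`measure` writes a per-bundle CSV (`fbl_cm`, `lat_pa_deg`, `med_pa_deg`) and
a Wavefront OBJ polyline model per specimen (fibers grouped by region/part,
tendon outlines, lines of force); `report` writes the summary tables, a
JSON-lines test log, and a plain-text report including the reference-cohort
demographic block.

## Layout

| Module | Contents |
| --- | --- |
| `fascicle3d.specimen` | domain types, tear classification, landmark frames, tear-diameter measurement |
| `fascicle3d.geometry` | Catmull–Rom splines, arc-length resampling, FBL, end tangents, line of force, pennation angles |
| `fascicle3d.stats` | descriptive stats, Mann–Whitney / Kruskal–Wallis / Bonferroni, `ArchitectureModel` |
| `fascicle3d.synthetic` | seeded synthetic digitized-specimen generator + ground truth |
| `fascicle3d.io` | manifest JSON, point-data CSV, OBJ export, packaged reference table |
| `fascicle3d.cli` | `fascicle3d generate / measure / report` |

See `docs/methods.md` for the modeling assumptions, parameter defaults and
known limitations.
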