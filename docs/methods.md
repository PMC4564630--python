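# Methods

## Measurement model

A digitized fascicle is an ordered sequence of n ≥ 4 stylus coordinates
(cm), medial attachment first. It is reconstructed as an interpolating
cubic Catmull–Rom spline: knots follow the centripetal rule
t_{i+1} = t_i + |ΔP_i|^0.5 (configurable to uniform or chordal), and the
curve is the cubic Hermite interpolant with the classic finite-difference
Catmull–Rom tangents m_i = (P_{i+1} − P_{i−1}) / (t_{i+1} − t_{i−1}).
Centripetal knots avoid cusps and self-intersections on unevenly spaced
digitized points; because every downstream quantity is computed after an
explicit arc-length re-parameterization, results are insensitive to the
knot rule. Endpoint segments use reflected phantom points
(P_{−1} = 2P_0 − P_1, symmetrically at the far end), which makes the spline's
end tangent parallel to the terminal chord — a stable convention, but one
that tilts the end tangent by roughly half a segment's turning angle on
strongly curved data (see Limitations).

Arc length is accumulated by dense per-segment sampling (default 200
subdivisions per segment) with cumulative chord summation; the resulting
monotone (parameter, arc-length) table is inverted by linear interpolation
for arc-length-indexed evaluation of points and tangents. **Fiber bundle
length (FBL)** is the entire arc length of the curve. Uniform arc-length
resampling (default 100 points) feeds the OBJ model export.

**Pennation angles.** The line of force of a region is the first principal
axis (total-least-squares line) of the digitized intramuscular tendon-axis
points, sign-oriented medial→lateral; each region (anterior, posterior) has
its own axis, since the two regions attach to separate intramuscular
tendons. A fascicle's orientation at an attachment is the mean of unit
tangents at 20 evenly spaced arc positions over the terminal 10 % of arc
length (`region_fraction`, configurable in (0, 0.5]); averaging over a
finite region stabilizes the estimate against digitization noise
concentrated at the attachment sites. The pennation angle is folded to the
acute range, θ = arccos |t̂ · û| ∈ [0°, 90°].

Invariances: FBL and both PAs are invariant under rigid motion of the
specimen (verified to 1e−6 over random rotations/translations); scaling all
coordinates by s scales FBL by s and leaves PAs unchanged.

## Anatomical frame and tear measurement

The three landmark screws (lateral scapular spine, coracoid process,
greater tubercle) define a deterministic right-handed orthonormal frame:
medial–lateral = unit(spine → tubercle); anterior–posterior = coracoid
direction orthogonalized against it; superior–inferior completes the triad.
The coronal plane is spanned by (ML, SI), the sagittal plane by (AP, SI).
This is a convention anchored on the only geometry available — the
digitization protocol does not record how the caliper was oriented — so
tear diameters computed here are frame-relative. The largest tear diameter
in a plane is the maximum pairwise distance between tear-boundary points
after orthogonal projection onto that plane, mirroring a caliper's
largest-diameter reading; a boundary that collapses to a point after
projection yields 0 with a warning rather than an error. Tear categories:
A = partial thickness; B = full thickness without retraction; C = full
thickness with retraction, retraction being defined as the tear spanning
the tendon's entire sagittal width. A partial-thickness record flagged as
spanning the full width is rejected as contradictory.

Left-side specimens can be mirrored across the frame's sagittal plane onto
a canonical right-side frame (`mirror_to_right`, optional), making pooled
statistics side-agnostic; FBL and PA are reflection-invariant, so this
affects only coordinates, not measurements.

## Statistical analysis

All architectural parameters are summarized per cell — (region, part or
whole region, tear category) — as median (minimum–maximum), with bundles
pooled across the specimens of a category; the unit of analysis is the
individual fascicle. This pooling choice matches the published min–max
ranges, which clearly span bundle-level variation; its cost is that
between-specimen correlation is ignored (see Limitations).

- **Mann–Whitney U** (two groups): U from midrank sums; the default
  asymptotic method uses z = (U − n₁n₂/2)/σ with the tie-corrected variance
  σ² = n₁n₂/12 · [(N+1) − Σ(t³−t)/(N(N−1))] and **no continuity
  correction**, two-sided p from the normal law. This default is
  deliberate: with two groups of four, the smallest attainable exact
  two-sided p is 2/70 ≈ 0.029, so reported p-values near 0.02 at those
  sizes can only come from the uncorrected normal approximation
  (SPSS-style). The exact method enumerates all C(n₁+n₂, n₁) labelings of
  the pooled midranks (ties handled exactly, practical to N = 20) with
  two-sided p = min(1, 2·min(tails)).
- **Kruskal–Wallis** (≥ 2 groups): H on midranks divided by the tie
  correction 1 − Σ(t³−t)/(N³−N), p from χ²(k−1). For two groups H equals
  z² of the tie-corrected Mann–Whitney exactly.
- **Pairwise comparisons**: all pairwise Mann–Whitney tests with a
  Bonferroni-adjusted threshold α/m (0.05/3 = 0.0167 for a triplet). No
  additional adjustment is made across the three metrics (FBL, lateral PA,
  medial PA) — multiplicity control applies to the three pairwise group
  comparisons only, matching the source protocol.
- Cells with fewer than `min_specimens` (default 3) specimens are
  summarized but excluded from hypothesis tests with a warning, as done for
  a two-specimen cell in the reference cohort.

Accuracy of the default approximation: across all attainable U at 8 vs 8
(untied), the asymptotic p tracks the exact p within 0.004 wherever the
exact p ≤ 0.05; near p = 1 the discrete exact p saturates and the two can
differ by several hundredths. The exact test's attainable level at nominal
α = 0.05 is below 0.05 (discreteness), which the calibration test accounts
for.

Display rounding uses half-up ties (3.715 → 3.72) to match the convention
of the printed reference tables; full precision is retained in CSV output.

## Synthetic specimen generator

The generator emulates the serial-dissection digitization protocol so that
every pipeline stage is testable without access to cadaveric data. Study
conditions (defaults): 4 specimens per tear category; per region, three
parts (superficial/middle/deep) of 3 dissection layers each, layers 1.5 mm
apart; 10–60 bundles per layer; 10–20 digitized points per bundle; tendon
periphery outlines dotted 2 mm apart at three depths; 30 tendon-axis points
per region; stylus noise 0.02 cm. `digitization_noise_sd_cm` is the RMS 3D
displacement of a digitized point — the convention in which digitizer
point-accuracy is specified — so each coordinate receives sd/√3.

Architecture is imposed distributionally per (region, part, category) cell:

- FBL ~ log-normal around the cell's target median (positive,
  right-skewed; σ_log default 0.25, chosen so generated min–max spans
  resemble the published part-level ranges);
- lateral and medial PA ~ folded normal on [0°, 90°], with the location
  solved numerically so the *population median* equals the cell target
  (σ default 9°); when a target sits below the folded-normal floor
  0.674σ, σ is shrunk to keep the median exact.

Default cell targets are the published part-level medians of the cadaveric
reference study, so the qualitative findings hold in the synthetic
population by construction: anterior FBL ordering A > B > C, largest
anterior PAs in category C, and progressive superficial→deep FBL shortening
with tear severity (the part-level targets encode the depth gradient
directly — no separate gradient multiplier exists). Tear-diameter targets
(medians, cm): B (1.44 coronal, 1.58 sagittal), C (2.96, 3.72), drawn
log-normally (σ 0.15); these are the reference table's column medians.
Category-C specimens lack a posterior region with probability 0.5 (half of
the reference category-C specimens).

Each bundle is realized as a smooth space curve built from its drawn
(L, α_med, α_lat): the unit tangent field
t(s) = (cos α(s), sin α(s) cos φ(s), sin α(s) sin φ(s)) is integrated over
s ∈ [0, L], so arc length is exactly L. The polar angle α(s) holds each end
value constant over a terminal 10 % plateau and ramps linearly in between —
the terminal plateau matches the measurement's default averaging region, so
the average end tangent carries exactly the drawn angle. The azimuth φ
twists linearly (default 2 rad total), bending the fiber out of plane so
that arc length genuinely exceeds the chord (~1–3 % at typical angles) and
the spline pipeline is exercised on real curvature. Anterior bundles are
pinned by their lateral ends onto the anterior tendon axis (penniform
convergence); posterior bundles stack in parallel (fusiform). Digitization
samples 10–20 arc positions with jittered spacing and adds stylus noise.

Seeding: a master seed spawns named sub-streams per specimen and per layer,
so enlarging one layer does not perturb other specimens; the same seed
reproduces byte-identical output files.

What the generator does **not** emulate: fat infiltration and atrophy,
fascicle branching and partial fascicles, spatially correlated digitization
error, between-specimen anatomical covariance (a free parameter nowhere
reported — between-cadaver variation enters only through per-layer sampling
variability), or any mechanical model of retraction (category effects are
distributional, not biomechanical). Passing recovery tests therefore shows
that the *measurement pipeline* is unbiased and stable under the stated
noise model — not that it would be unbiased under every pathology of real
dissection data.

## Problem sizes and numerical choices

- Default cohort: 12 specimens, ~7000 bundles, ~400 bundles per
  (region, part, category) cell; generation plus full measurement runs in
  well under a minute on one CPU. Parameter-recovery checks use cells with
  ≥ 200 bundles (cells below that — posterior cells of category C when
  posterior regions are absent — are summarized but not held to recovery
  tolerances, just as they are excluded from hypothesis testing).
  At ~400 bundles the sampling SE of a PA cell median is ~0.55°, so the
  2° recovery tolerance sits at ~3.6 SE; observed maxima over several seeds
  are 1.4–1.8° for PA and 2.6–4.0 % for FBL (tolerance 5 %).
- Quadrature: 200 subdivisions per segment makes the arc-length error of a
  15-point quarter circle ~0.005 % — quadrature is never the limiting
  error; spline interpolation of sparse points is (0.3 % at 15 points on a
  90° arc, converging as density grows).
- Degenerate inputs: coincident consecutive points, collinear landmarks,
  coincident tendon-axis points, and zero tangents raise typed errors
  (`ValidationError`, `DegenerateGeometryError`); a tear boundary that
  projects to a point yields (0, 0) with a warning.
- Ties in rank tests are handled by midranks everywhere; two-sided p-values
  are 2·min(tail, 0.5) capped at 1.

## Known limitations

- Region and part labels are inputs: no automatic anatomical segmentation
  of anterior/posterior or superficial/middle/deep from raw geometry.
- No muscle-volume or physiological cross-sectional area estimation, and no
  force prediction from PA.
- The reflected-phantom endpoint convention makes the spline's end tangent
  equal to the terminal chord direction; on strongly curved fascicles the
  instantaneous end tangent is therefore biased by about half a segment's
  turning angle, which the terminal-region averaging largely absorbs but a
  region_fraction → 0 limit exposes.
- Pooling fascicles across specimens ignores specimen-level clustering;
  p-values are anti-conservative to the extent that specimens differ
  systematically. Mixed models are out of scope.
- The landmark-based coronal/sagittal planes are a convention; tear
  diameters are comparable within this package but not guaranteed to match
  a caliper oriented by eye on the bench.
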