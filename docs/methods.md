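# Methods

## The virtual facebow construction

A lateral cephalogram taken with the facebow's skin markers in place shows
four usable landmarks: porion inferior (Pi), the nasal support of the
facebow (Ns), the upper incisor edge (Ie) and the distobuccal cusp of the
first upper molar (Dc), plus a radio-opaque scaling pair (Ref0/Ref1) a known
physical distance apart. All coordinates use the right-lateral convention
x anterior-positive, y superior-positive; calibration multiplies every point
by `ref_distance_mm / |Ref0 − Ref1|`.

The axis-orbital plane (AOP) appears in this 2D view as a line through the
Pi-derived anchor running at perpendicular distance `d_ns_mm` below the
nasal support; `b` is the foot of the perpendicular from Ns. Two tangent
lines satisfy the distance constraint; the anatomically oriented one is the
line whose foot lies on the same side of the Pi–Ns segment as the dentition
(Ie). In patient orientation this is exactly "b anterior to Pi and inferior
to Ns", but the side-of-line formulation is intrinsic to the landmark set,
which makes the whole construction invariant under rigid motions of the
cephalogram — a property the test suite enforces at 1e-9.

The arbitrary hinge axis Ax sits at configurable offsets (along/perpendicular
to the AOP) from the anchor. The mounting triple is then

- α: the signed angle between the upper occlusal plane (Ie–Dc) and the AOP,
  positive when the occlusal plane ascends posteriorly toward the AOP
  (α is reported signed so that per-patient negatives — common in the
  horizontal-face phenotype — average correctly);
- AxV: the unsigned distance from Ax to its orthogonal projection Ax′ on the
  occlusal plane;
- AxH: the distance from Ie to Ax′ along the occlusal plane.

`FacebowSpec` makes the physical dimensions explicit configuration rather
than constants, because they belong to the specific facebow hardware. The
test fixtures use `d_ns_mm = 23`, axis offsets `(0, 0)`; these exercise the
geometry and are not claimed as the dimensions of any commercial facebow.
Every geometric invariant holds for any finite spec.

`invert_mounting` synthesises a landmark set realising a given triple (used
by the generator and the round-trip tests). A triple is realisable only when
the incisor edge lands below the AOP, which works out to
α > −atan(AxV/AxH) (i.e. α above the negative Balkwill angle); outside that
region the function raises an infeasibility error rather than returning an
anatomically impossible configuration.

Derived articulator values: Ax, Ie and Ax′ form a right triangle with the
right angle at Ax′, so the Bonwill-arm equivalent is
Ie–Ax = √(AxH² + AxV²) and the Balkwill-angle equivalent is
atan2(AxV, AxH). Norms used for flagging: 101.6 mm for the Bonwill arm,
18–25° for the Balkwill angle.

Presets are rounded half-up (commercial rounding, 26.5 → 27); banker's
rounding would change the vertical-phenotype AxV preset.

## 3D mounting of an intraoral scan

Frame: x transverse (patient left positive), y anterior, z superior; the
scan is pre-oriented with the occlusal plane on the ground plane and Ie at
the origin. The hinge axis starts as the transverse line through
(0, −AxH, +AxV); the whole scene is then rotated by α about the transverse
axis through Ie. The rotation sense is chosen so the posterior side moves
superiorly, matching the cephalometric relation in which the occlusal plane
and the AOP converge posteriorly; it is flippable via
`posterior_rotates_superiorly=False`. Ie is a fixed point and stays on the
ground plane — the grid height vs. the anatomical AOP offset is left exactly
as the procedure states it, and the distance from Ie to the mounted hinge
axis always equals the Bonwill-arm equivalent (cross-module consistency,
tested to 1e-9).

## Cohort pipeline

Inclusion filtering drops rows with a non-empty exclusion reason, then keeps
only the latest plan (largest `plan_index`) of any patient planned twice;
which plan entered the original analysis is not recorded, and "latest plan"
is the clinically sensible reading. The accounting report carries eligible /
excluded / superseded / included counts.

Clustering: variables are z-scored with the n−1 SD denominator (the R
convention); k-means is Lloyd's algorithm with k-means++ seeding, best of 25
restarts, default seed 20230521, squared Euclidean distance, ties in
assignment broken toward the lowest cluster index (scikit-learn's
behaviour). The elbow criterion is operationalised as the k maximising the
perpendicular distance from the WSS curve to the chord joining its endpoints
(kmax = 10 by default); ties break toward the smallest k, and the choice is
invariant to positive rescaling of the curve. Phenotype labels for k = 3:
largest AxH → balanced, smallest AxV → vertical face class II, smallest α →
horizontal face class III; a collision of these rules raises an explicit
labelling-ambiguity error.

## Statistics

- Sex×cluster association: Pearson χ² without continuity correction (the
  table is 2×3; the Yates device is a 2×2 correction), Cramér's V =
  √(χ² / (n·(min(rows, cols) − 1))).
- ANOVA + Tukey HSD with the Tukey–Kramer unequal-n correction via the
  studentized-range distribution. The variable-selection rule keeps a
  cephalometric variable only when all three pairwise adjusted p-values are
  below α = 0.05 (the conventional level; variables separating only two of
  three clusters are excluded).
- Mann–Whitney U: mid-rank ties, normal approximation with tie-corrected
  variance and 0.5 continuity correction (the convention of mainstream
  commercial statistics packages); identical pooled samples return p = 1 by
  convention. The exhaustive-permutation p agrees within 0.02 at n = 5 + 5.
- No multiple-testing correction is applied across the 22 variables beyond
  Tukey within each variable.

## The synthetic cohort generator

The generator emulates the study conditions: 514 patients in three clusters
of 128 / 204 / 182 with sex splits 36+92, 171+33 and 116+66, mounting
Gaussians (α, AxV, AxH) = (7.8±3.4°, 36.2±4.6, 98.9±5.5 mm),
(11.1±3.3°, 26.5±3.8, 88.1±5.4 mm) and (2.4±4.0°, 35.9±4.5, 85.6±5.6 mm),
per-sex age distributions, and 22 cephalometric variables — nine with all
three cluster means separated (the published per-cluster profiles, with the
maxillo-mandibular length ratio at 1.42/1.32/1.38, consistent with the
one-decimal rounding of the printed profiles and with all pairwise
differences being significant) and thirteen synthetic ones with a
two-clusters-equal pattern so the selection rule excludes them.

Within a cluster, variables are independent Gaussians: within-cluster
covariances of (α, AxV, AxH) are not published, so independence is the
explicit modelling choice (a correlation hook would slot into
`VariableSpec` if estimates became available). Positive-valued quantities
(AxV, AxH, age) are truncated by resampling, not clipping, to avoid point
masses. Landmark-level synthesis runs each patient's triple through
`invert_mounting` under a randomised rigid pose, so the landmark route and
the tabular route are provably equivalent end to end.

What passing tests on these cohorts do **not** show: real cephalograms carry
landmark-placement error, digitisation noise and within-patient correlations
between mounting and cephalometric variables, none of which the generator
models. Recovery results on synthetic cohorts therefore bound the method's
behaviour under the stated mixture, not its clinical accuracy.

## Numerical behaviour of cluster recovery

Hard-assignment k-means on overlapping Gaussian components is a biased
estimator of the component means: boundary points are reassigned to the
nearer center, pushing recovered centers apart. Under the default mixture
the vertical-II α center is essentially unbiased (recovered 11.07 ± 0.28°
across seeds against a generating 11.1°), but the horizontal-III center is
displaced by about −0.6° in α and −0.8 mm in AxH in expectation, because
that component overlaps the vertical-II component heavily in AxH. The
module property test therefore freezes the per-seed center-recovery
tolerance at 2.0 raw units (covering ≥95% of seeds), and the partition
agreement with ground truth is frozen at adjusted Rand ≥ 0.6 (measured
0.64–0.81 over seeds); both calibrations were made once against the
generating parameters and are documented here rather than tuned per test
run. The elbow criterion selects k = 3 at every seed examined, and the
largest recovered cluster stays within 204 ± 25 across seeds.

Problem sizes: all simulation-backed tests and the acceptance script run at
the study scale (n = 514, 20 seeded replicates), which completes in seconds.

## Known limitations

- The physical facebow dimensions are configuration, not shipped constants;
  results depend on supplying the dimensions of the hardware actually used.
- The 2D construction ignores cephalogram projection distortion beyond the
  linear scaling pair.
- Cluster labels are rule-based on center geometry; pathological center
  configurations raise rather than guess.
- The generator's independence assumption understates within-cluster
  structure; adjusted-Rand and center-recovery figures would change under
  correlated components.
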