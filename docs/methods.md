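# Methods

`pollenifc` analyses label-free impedance flow cytometry (IFC) measurements
of pollen.  In IFC, particles in suspension cross a microfluidic channel
carrying an AC field; each transit perturbs the complex impedance
Z(ω) = Zr + i·Zi, summarised per event as an amplitude |Z| = √(Zr² + Zi²)
and a phase θ = atan2(Zi, Zr).  At low frequency (~2 MHz) |Z| tracks
particle volume; at ~8 MHz θ reports membrane integrity, which separates
viable from dead pollen.  Sterile pollen — small, anomalous grains without
cytoplasmic content — forms a third, low-amplitude population that is
unaffected by heat inactivation.

This note records the model assumptions, the default parameters and why
they were chosen, the numerical decisions, and what the synthetic-data
tests do and do not establish.

## Impedance primitives

Phase is stored and reported in degrees (scatter plots, gates and
population modes are conventionally quoted in degrees); radians exist only
inside the trigonometric calls.  The cartesian→polar conversion uses
`atan2`, not a bare arctangent: pollen events sit around 180–210°, where a
two-quadrant arctangent would be ambiguous.  Amplitudes stay in arbitrary
instrument units; no calibration to ohms is attempted.

All regressions in the package are simple (one-predictor) ordinary least
squares; the adjusted coefficient of determination therefore uses the
p = 1 formula, Radj² = 1 − (1 − R²)(n − 1)/(n − 2).  A constant response is
handled explicitly (slope 0, R² = 0) rather than propagating a 0/0.

## The synthetic event generator

No public event-level pollen IFC data exist, so the generator is
first-class, tested code that emulates the study designs end-to-end.
Populations are independent bivariate Gaussians in (phase, amplitude) per
channel — the instrument clouds are roughly elliptical and only marginal
means ± sd are documented, so no phase–amplitude correlation is introduced
(the profiles accept one if needed).  Amplitudes are truncated below at the
chip trigger level, since sub-trigger transits never register.

Defaults for the 80 μm chip (heat-inactivation / mixing validation, 8 MHz)
are the measured population parameters: viable 200° ± 1.35°, amplitude
0.9 ± 0.23; dead 188° ± 0.72°, amplitude 0.9 ± 0.25; sterile 190° ± 1.1°,
amplitude 0.364 ± 0.11.  For the 120 μm chip (hydration course and
genotype panel) the modes are 198° (viable) and 188° (fully hydrated
dead), with the same phase spreads as the 80 μm chip.  The 120 μm
amplitude spreads are set tight (0.08 a.u.): the panel's sterility
replicate sds go down to 0.08 percentage points, which is only possible if
the sterile population separates essentially without ambiguity on this
chip.  The two chips are modelled as separate profiles; the 200°-vs-198°
viable offset between them is carried as-is, not unified.

Other defaults, each a single documented choice:

* **Class fractions** (hydration experiments): viable 0.45, dead 0.25,
  sterile 0.15, intermediate 0.15.  The "intermediate" class formalises
  grains that classify as neither viable nor dead immediately after cold
  storage; it starts at the initial dead mode (192°).
* **Hydration drift**: the dead-population phase mode moves linearly from
  192° at 0 min to 188° at 330 min (5.5 h) and then holds; only the two
  endpoints are documented, linearity is the minimal assumption.  Dead
  amplitude declines at 2·10⁻⁴ a.u./min (grains shrink as membranes fail).
* **Intermediate recovery**: each intermediate grain converts with
  probability t/330 by time t; a fraction 0.3 of converting grains
  rehydrates successfully and joins the viable class, the rest join dead.
  The 0.3 split is a free parameter — the source observation is only that
  overall viability "slightly" increases while the intermediate signal
  disappears.
* **Mixing series**: untreated sterile-excluded viability v₀ = 0.95
  (untreated field-collected pollen is not perfectly viable) and a sterile
  fraction of 0.30, constant across ratios because heat treatment does not
  affect grains that have no compartments to damage.
* **Buffer decay**: non-rehydrated pollen loses viability as exp(−λt) with
  λ = 0.02 min⁻¹; the qualitative observation is a "quick drop" within
  1.5 h, and λ = 0.02 puts the half-life at ~35 min.
* **Size–sterility coupling** (panel): the viable-class 2 MHz amplitude
  mean is offset by +0.002 a.u. per percentage point of sterility relative
  to the panel mean (≈ +15 % size over the observed sterility range), the
  sterile class by −0.001; this reproduces the reported positive viable
  and negative sterile size trends.

**Seeding.** One master seed; per-unit streams come from
`numpy.random.SeedSequence(seed).spawn(...)` in the iteration order of
(condition, sample, replica).  Identical seed + config gives byte-identical
tables; replicas are statistically independent.

## Gating

Events are classified by polygon gates in (phase, amplitude) space with
fixed precedence sterile → dead → viable (sterile is defined primarily by
amplitude, so it is tested first; precedence makes overlapping hand-drawn
gates deterministic).  Boundary points count as inside — no event is lost
to an edge.  Membership uses exact geometric predicates (`shapely.covers`).

Hand-drawn gates can be supplied as JSON.  The automated derivation is a
two-stage univariate split: optimal 2-cluster k-means on amplitude isolates
the sterile population, then 2-cluster k-means on phase splits dead from
viable among the remaining events.  Two numerical decisions matter here:

* **Threshold placement.**  Each stage's threshold is the midpoint of the
  two cluster means — the nearest-centroid decision boundary of the
  optimal univariate k-means partition.  The alternative (midpoint of the
  adjacent cluster *edges*) tracks the empty valley between the separated
  clouds, which in a hydration course sits exactly where the
  not-yet-hydrated dead population (192°) lives; a centroid-midpoint
  boundary (~193° for 188/198 clouds) leaves that population room to
  drift, mirroring how operators draw generous dead gates.
* **Unimodality guard.**  The k-means objective happily bisects a single
  Gaussian (the split of a pure normal scores ≈ 2.65 pooled-sd separation,
  more than a genuine weak mixture), so a separation threshold alone
  cannot detect one-population data.  A split is accepted only if the
  kernel density at the boundary falls below 0.85 of the density at both
  cluster means — a real valley.  Otherwise the stage degrades to a
  single-class gate set with a warning.

Large event tables are thinned to ≤ 4096 evenly spaced order statistics
before the exact O(n²k) dynamic program; the thinning is deterministic and
preserves the split location to quantile resolution.

For multi-genotype panels the default is one gate set derived from the
pooled events and applied to every genotype.  Deriving from a single
genotype is ill-posed when its sterile or dead fraction approaches zero
(with 1 % sterile events the optimal amplitude split lands inside the
dominant viable cloud); population positions do not vary across genotypes,
so pooling is both robust and faithful to the fixed-gate protocol.
Per-genotype derivation remains available (`gates="per-genotype"`).

Viability is viable/(viable + dead) with sterile excluded for the mixing
validation (matching that experiment's convention), and sterile is included
in the denominator for panel percentages, where viable + dead + sterile
sums to 100.

## Hydration mode tracking

Per time step the gated dead and viable phase distributions are summarised
by the global mode of a Gaussian kernel density estimate (Silverman
bandwidth by default, user-overridable; none is documented for the source
analysis).  The evaluation grid has ≤ 0.05° resolution and spans the data
range ± 5 bandwidths — wide enough that the trapezoidal integral of the
density is 1 to ~10⁻⁶.  Exact mode ties resolve to the lower phase (the
grid argmax convention).  Modes, not means, are the headline statistic:
the stated stabilised values (198/192/188°) are modes, and modes are
robust to the asymmetric tails that gate truncation introduces.

The separation Δ(t) = |mode_viable − mode_dead| grows from ~6° to ~10° over
the course.  The viability–separation relation is exposed in two forms:
levels (viability on Δ) and first differences (step-to-step changes, the
default).  At desk scale the differenced variant is underpowered — the
per-step drift signal (~0.36°) is comparable to mode-estimation and
counting noise — so the differenced slope is rarely significant on a
single synthetic course, while the levels regression is strongly positive
essentially always.  Both are computed; tests assert the levels form and
the sign behaviour of the differenced form.  The published strength of
this relation (Radj² = 0.83) is a property of the real multi-genotype data
set and is not treated as reproducible from synthetic data.

The recommended pre-hydration time is the earliest step whose viability is
within one standard error of the series maximum, with the standard error
estimated from the series' own short-scale noise (median absolute
successive difference / √2).  On the defaults this lands at ~330 min,
consistent with the ~6 h recommendation.

## Sterility clustering

The panel reduces each genotype to its average sterile percentage, so the
cluster analysis is univariate:

* `ckmeans_1d` — exact optimal k-means by dynamic programming over
  contiguous partitions of the sorted values (O(n²k), inner loop
  vectorised; panel sizes make the linear-time refinement unnecessary).
  Ties break toward fewer elements in higher clusters.  Equality with
  exhaustive enumeration is tested for all small instances.
* `bic_select` — for each k the optimal partition induces a Gaussian
  mixture (weights = cluster proportions, per-cluster mean and variance,
  variance floored at ε = 10⁻⁴ to keep near-singleton clusters finite);
  BIC = 2 ln L − (3k − 1) ln n, reported per observation (BIC/n).  On the
  37 panel averages this selects k = 5 deterministically.  On synthetic
  replica-level panels (3 replicas per genotype drawn from the documented
  mean ± sd) the selection is seed-sensitive — k = 2 and k = 5 each win
  roughly half the seeds, insensitive to ε over 10⁻⁶…10⁻² — because the
  two middle groups (≈ 44 % and 54 %) overlap heavily at the documented
  replicate spreads.  The five-group *partition at fixed k = 5* is stable;
  the automatic choice of k is not, and is documented as such.
* `hclust_1d` / `hclust_cut` — agglomerative clustering (scipy) on absolute
  differences; average linkage by default.  The two-group split of the
  panel (means 6.7 % and 48.1 %) is identical under single, complete,
  average and ward linkage — the 15.05 → 37.08 gap dominates.
* `silhouette_width` (singletons score 0) and `gap_statistic` (uniform
  reference over the data range, B = 100, seeded; standard error includes
  the √(1 + 1/B) factor; smallest k with gap(k) ≥ gap(k+1) − se(k+1))
  both select k = 2 on the panel averages.

Cluster indices are always ordered by ascending cluster mean, so labels are
comparable across methods.  The acceptance checks run on the 37 packaged
per-genotype averages — the only published values; replica-level clustering
is exercised through the synthetic panel.

## Imaging validation arm

The dye-exclusion microscopy arm is simulated at the level that matters for
method comparison: per-class size and stain contrast.  Micrographs are
8-bit grayscale ("dark pink" staining is a one-channel contrast decision):
background 128, unstained classes ~195–200, stained dead ~60, ≥ 30 gray
levels from background.  Viable and dead grains are ellipses (aspect
0.85–1) with maximum Feret diameters Normal(38, 4) and Normal(34, 3) μm;
sterile grains are subtriangular, Normal(27, 3) μm.  Rendered Feret draws
are floored at 21 μm — smaller objects would be debris-filtered in any
real pipeline.  Pixel scale defaults to 0.5 μm/px (4× objective regime).
Placement is rejection sampling with non-overlap enforced on per-object
bounding circles (triangles use their circumradius feret/√3) plus a 3 px
margin; the image side is chosen so bounding circles fill ≤ 25 % of the
area.  Non-overlap makes segmentation recall exactly 100 % by
construction — which is precisely what it is used for: isolating the
classification and measurement steps from the touching-object problem this
package does not address.

Segmentation: median-background subtraction, Otsu threshold on the
absolute deviation (dark and bright objects segment symmetrically),
8-connected components, minimum-area filter at a 15 μm circle.  The
maximum Feret diameter of a region is the maximum pairwise distance over
the convex hull of its pixel corners (computed as the hull of the
pixel-center hull's corners — identical by the Minkowski-sum identity, and
cheap).  The corner convention reads a rasterised object ~1 px large,
within the estimator's stated 1-pixel tolerance.

Classification is a transparent two-rule surrogate for a trained
classifier: mean intensity below 130 → dead (stain); else Feret below
31 μm (midpoint of the 27 and 34–38 μm regimes) → sterile; else viable.
At the documented class sizes the rule's Bayes error is ~4 %, so agreement
with truth is ≥ 95 %, not 100 % — the overlap is a property of the real
size distributions, not of the implementation.

## What the synthetic tests do and do not show

Passing tests establish that the pipeline recovers known inputs under the
generator's assumptions: Gaussian clouds, linear mode drift, independent
replicas, non-overlapping rendered grains, genotype-independent population
positions.  Real data violate several of these (drifting instrument
baselines, debris and doublets, touching grains in images, per-cultivar
gate adjustments), so the validation regressions here (Radj² ≈ 0.999) are
upper bounds on, not estimates of, real-world agreement — the published
real-data values (0.96–0.97 for the mixing and method-agreement
regressions) are correspondingly lower.  The deterministic panel
clustering results, by contrast, are exact reproductions computed from the
published per-genotype averages.

## Problem sizes

Default test and acceptance runs use the documented experiment sizes:
mixing 5 ratios × 2 samples × 3 replicas × 20 000 events, hydration 15
steps × 10 000 events, panel 37 genotypes × 3 replicas × 20 000 events.
The image arm renders ~4 000 objects per replica in the acceptance script
and 1 200 per replica in the test suite; image-arm viability is a ratio of
object counts, so its estimate is unbiased at any count and only its
variance shrinks with more objects.

## Known limitations

* No doublet/coincidence events, debris class, or position-dependent
  amplitude artifacts in the event generator.
* The gate-derivation surrogate assumes at most three populations with the
  sterile population lowest in amplitude.
* Replica-level BIC cluster-count selection is seed-sensitive (above).
* The imaging arm does not attempt colour, touching-object splitting, or
  real micrograph quality; its classifier is deliberately minimal.
* Ploidy/volume interpretations of the size–sterility coupling are out of
  scope; the coupling is reproduced phenomenologically.
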