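# Methods

## Scope and units of analysis

engramkit computes derived statistics from three already-extracted data
classes: bout-level exploration logs, slice-level cell-count tables, and
per-spine morphometric tables.  Segmentation, pose estimation and filament
tracing are upstream of the package; their outputs are its inputs.  In
every group-level quantity the animal is the statistical unit: slice
statistics are averaged (unweighted) within animal, and per-animal values
feed the group mean ± SEM and the hypothesis tests.  Spine tables can
alternatively be aggregated per neuron via a flag on
`per_segment_counts`, since densities are sometimes reported per neuron
rather than per segment.

## Behavioral scoring

A bout is an interval during which the animal explores one object.  The
discrimination index DI = (t_novel − t_familiar)/(t_novel + t_familiar) is
computed from raw summed bout durations.  Decisions where the convention
was genuinely open:

- **Zero exploration** makes the DI undefined; the package returns NaN for
  the trial, excludes it from group means, and counts it in QC output
  rather than imputing 0 — a zero would assert "no preference" on no
  evidence.
- **Overlapping bouts** (a manual-scoring artifact) are tolerated with a
  warning and summed as recorded, because the DI is defined on raw summed
  times.
- **Degenerate group t-tests**: an all-zero DI sample returns t = 0,
  p = 1; a constant non-zero sample has an infinite t and is flagged with
  a warning instead of erroring, so batch reports survive pathological
  groups.

Occupancy heatmaps bin nose coordinates into an n×n grid over the arena
(origin at a corner, cm units) and are normalized to sum to exactly 100;
out-of-arena samples are clipped to the boundary with a warning.
Locomotion distance is the summed frame-to-frame Euclidean step length of
the body-center marker.

## Reactivation statistics

Per slice with counts D (DAPI⁺), C (c-Fos⁺), M (mCherry⁺), O (overlap):
co-localization = 100·O/M, chance = (C/D)(M/D), enrichment = (O/D)/chance.
Chance is computed from *that slice's own* counts, and enrichment is
averaged over slices within animal.  The estimator is a ratio of counts,
so it is scale-free (invariant to multiplying all counts by a constant)
and, in expectation, invariant to uniform subsampling of cells.  As a
ratio estimator it carries a finite-sample Jensen bias of order
Var(M)/E[M]² + Var(C)/E[C]²; at 2000 cells per slice and a 5% tagged
fraction this is about +1%, well inside the Monte-Carlo tolerances the
tests use.

Division-by-zero policy: a slice with M = 0 has undefined co-localization;
a slice with zero chance and zero overlap has undefined enrichment.  Both
are excluded with a warning (never imputed); zero chance with positive
overlap is rejected as impossible input.  Animals with no valid slice for
a statistic are flagged and excluded.

Home-cage normalization divides each encoding animal's c-Fos density by
the scalar mean density of the matched (same genotype and region)
home-cage group; by construction the home-cage group normalized against
itself has mean exactly 1.

Single-cell fluorescence summaries average per-cell mean intensities within
slice first, then over slices within animal, so slices are equally
weighted regardless of cell count.  Intensities are treated as raw
background-comparable arbitrary units; no normalization is applied by
default because the appropriate reference (slice median, section control)
is acquisition-specific.

## Spine morphometry

**Refinement.**  Records lacking a neck (missing minimum neck diameter)
are dropped by default, as are spines whose head max diameter falls below
the minimum reconstructable spine diameter (0.4 µm); when a dendrite
diameter column is present, spines on dendrites outside 1–5 µm are also
dropped.  The rejection report counts removals by first failing rule.

**Geometry.**  The spine is modelled as a conical frustum plus terminal
hemisphere minus attachment hemisphere.  Parameterization (the solids are
standard, the mapping from measured features to them was open):
attachment radius r_a = attachment_diameter/2, terminal radius
r_t = head_max_diameter/2, frustum height h = length − r_t (the terminal
hemisphere caps the frustum), floored at 1e-6 µm so degenerate
length ≈ r_t records yield vanishing volumes instead of negative heights.
With r_a = r_t the formulas collapse exactly to cylinder volume πr²h and
lateral surface 2πrh.  When r_a ≫ r_t the hemisphere subtraction can make
the closed-form area negative; it is then floored at the frustum lateral
surface (the physical lower bound for the side wall) with a warning.

**Classification.**  The five-category thresholds act on length, head max
diameter, and LWR = length/width.  The raw criteria overlap (a short
big-headed spine satisfies both the stubby and mushroom rules), so a fixed
precedence makes the rule set total and single-valued:
mushroom (head ≥ 0.6 µm) → stubby (LWR ≤ 1) → filopodia (length > 2 µm) →
long thin (1 < length ≤ 2 µm) → thin (length ≤ 1 µm).
Head-size dominance reflects that the mushroom class is defined by its
head diameter; the boundary head = 0.6 µm therefore belongs to mushroom.
The width convention in LWR defaults to the head max diameter (the same
quantity the class rules use) and can be switched to the head mean
diameter.  Spine length is measured attachment-to-tip along the spine
axis, head included.

**Densities.**  Per-class counts per segment are scaled to per-20-µm
(default traced segment length 20 µm); the per-class counts sum to the
total density exactly, by construction.

**Clustering.**  The 16-feature matrix comprises the nine measured
features (length, head max/mean diameter, head length, neck min/mean
diameter, neck length, attachment diameter, straightness), the LWR, the
two geometry outputs (area, volume), and four derived shape descriptors
(head/neck diameter ratio, head length fraction, neck aspect ratio,
taper); the roster is declared in `FEATURE_COLUMNS` — it is a package
design choice, not an inference.  Features are z-scored (mean 0, sd 1 on
the fitted set), projected by PCA retaining all components (the first two
are used for display), and clustered by k-means on the full score matrix
with 10 restarts, relative inertia tolerance 1e-6, and a fixed seed, so a
fixed seed gives identical assignments across runs.  k defaults to 5 (one
candidate cluster per morphological class); when unset it is chosen by
the elbow method, implemented as the knee of the inertia-vs-k curve — the
k in 2..10 whose point on the normalized curve lies farthest below the
chord joining the endpoints, ties toward smaller k.  A curvature
(second-difference) maximizer was considered and rejected: on
well-separated mixtures the inertia drop from k=1 to 2 dominates the
differences and the maximizer lands one below the true cluster count,
while the chord criterion recovers it.

## Synthetic-data generators

The generators define the closed testing loop; their defaults are the
study conditions the estimators are validated under.

- **Trials**: bout labels i.i.d. Bernoulli(preference_novel); durations
  i.i.d. log-normal (positive, right-skewed; arithmetic mean 2 s, log-sd
  0.6 — plausible for object-exploration bouts, as bout-level statistics
  are rarely published); onsets placed by distributing the free time over
  inter-bout gaps with ordered uniform spacings, so bouts never overlap
  and lie inside the trial.  E[DI] = 2p − 1 under identical duration
  distributions, which the tests verify by Monte Carlo.
- **Slice populations**: per slice of 2000 DAPI cells, mCherry⁺ count ~
  Binomial(cells, tag_fraction 0.05); tagged cells c-Fos⁺ with
  p_react_tagged, untagged with p_active_untagged.  The implied
  ground-truth enrichment is p_react_tagged / P(c-Fos⁺), exposed on the
  config.  Counts are generated at slice level only — every downstream
  statistic is a count ratio, so spatial rendering adds nothing.
  Optional intensity fields simulate per-c-Fos⁺-cell fluorescence with a
  tagged-cell shift for the intensity-recovery tests.
- **Spines**: a five-class mixture (default weights 0.27/0.33/0.21/0.03/
  0.16 for thin/long-thin/mushroom/stubby/filopodia, the composition
  implied by published per-class densities); per-class truncated-normal
  length and head-diameter distributions centered well inside each class's
  decision region, so the threshold classifier recovers the generating
  class with probability ≥ 0.95; head diameters kept above 0.4 µm so
  refinement removes only the deliberately injected neckless fraction.
  The generating class is always emitted in a `true_class` sidecar column.

All substreams derive deterministically from one integer seed
(`child_seed`, via numpy `SeedSequence`); fixed seed means bit-identical
tables.

What the generators do **not** emulate: within-animal slice
heterogeneity beyond binomial sampling (no overdispersion between
sections), spatial clustering of labeled cells, segmentation and
co-localization adjudication errors, correlated spine features within
dendrites, or scorer noise in bout boundaries.  Passing recovery tests
therefore validates the estimators and the pipeline plumbing under the
stated sampling model, not robustness to those real-data effects.

## Problem sizes and determinism

The validation suite uses 30 slices × 2000 cells with 60 Monte-Carlo
seeds for enrichment recovery, 100 synthetic animals for the independence
null, 10⁴ simulated groups of n = 6 for the type-I-error calibration of
the DI test, 100 random shapes for the geometry oracle (closed form vs
numerical solid-of-revolution integration, agreement < 0.1%), and 10⁵
random feature vectors for classifier totality — sizes at which the
Monte-Carlo error is comfortably below the tolerances being checked while
the whole suite runs in seconds.  The pipeline writes a manifest with a
SHA-256 hash of every output table; reruns with the same seed are
byte-identical.

## Known limitations

- The chance-corrected overlap estimator's small positive ratio bias is
  not corrected; at realistic counts it is an order of magnitude below
  the biological effect sizes of interest.
- The rule classifier's thresholds are fixed biology-derived constants;
  no data-driven calibration is attempted.
- Group-level omnibus statistics (ANOVA + multiple-comparison
  correction) are deliberately thin wrappers over standard routines and
  not re-validated here.
- The elbow selector assumes a monotone decreasing inertia curve; on
  structureless data it still returns some k in range — cluster counts on
  such data are not meaningful.
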