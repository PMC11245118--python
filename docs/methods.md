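# Methods

`orgdyn` quantifies three things from multi-channel fluorescence
time-lapses of vesicular organelles (endosomes, lysosomes) and
mitochondria: **fission events** and whether an ER-actin reporter (AC-ER)
is enriched at their sites, **morphology** (size, shape, skeleton
branching), and **mobility** (object tracking and a segmentation-free
autocorrelation readout).  Because suitable public microscopy datasets
with per-event ground truth do not exist, the package ships a synthetic
generator whose output carries exhaustive truth, and every analysis stage
is validated by parameter recovery against it.

## 1. Synthetic time-lapses (`orgdyn.synthgen`)

**What it emulates.** A single-plane Airyscan-style movie: 40 nm pixels,
5 s frame interval, 60 frames (5 min), with an organelle channel and an
AC-ER channel.  The default cell contains 30 disc-shaped organelles of
mean radius 0.4 µm (log-normal, CV 0.2, clipped to 0.5–2.5× the mean);
`tubule` and `network` shapes (capsules and capsule stars) support the
mitochondrial pipelines.

**Dynamics.** Objects move by 2-D Brownian motion with per-axis step SD
`sqrt(2 D Δt)` plus optional constant drift, reflecting at the field
boundary.  Defaults: `D = 5e-4 µm²/s`, no drift.  Two deliberate
departures from free diffusion:

* *Step cap.* Brownian step norms are capped at 3σ.  Organelles in
  crowded cytoplasm do not make unbounded excursions between frames, and
  the cap guarantees every object overlaps its own previous footprint at
  the default sampling, which any overlap-based lineage (or human
  scorer) implicitly requires.  The cap costs ~3–5 % of the theoretical
  MSD slope; the generator's MSD test budgets for this.
* *Hard core.* Distinct objects keep a minimum clearance of 3 PSF sigmas
  (steps that would violate it are rejected), so distinct organelles
  remain resolvable in the rendered image.  Newborn fission daughters are
  exempt: they are placed adjacent (3 px apart along the split axis,
  chosen to maximise clearance from neighbours and walls) and drift apart
  at 0.005 µm/s during the post-fission window.

**Events.** Fission and kiss-and-run counts are Poisson with mean
`n_organelles × rate × schedulable_window`, assigned to distinct parents
at frames drawn uniformly from the window where the persistence rule can
hold (parent present ≥ `min_pre_s` before, daughters ≥ `min_post_s`
after; with the default 5 s interval the 30 s windows are an exact 6
frames).  This makes the realised event rate linear in the configured
rate, which the rate-recovery test exploits.  A parent splits into two
area-conserving daughters (`r/√2`).  Kiss-and-run events re-merge after
20 s by default — inside the persistence window, so a correct detector
must reject them.  Contact-triggered fusion (off by default) merges
colliding objects area-conservingly.  One fission per organelle per
movie keeps the truth bookkeeping exact.

**AC-ER channel.** A static field: dim ER texture (smooth Gaussian field,
amplitude 0.15) overlaid (max-composition) with uniform-height puncta.
The punctum count solves the Poisson-union identity
`f = 1 − exp(−n π r_e² / A)` so that, after top-25 % masking of the
rendered frame, the puncta cover `acer_background_fraction` of the field
— and hence, being independent of organelle positions, of the organelle
area.  `r_e` is the radius of the post-PSF top-fraction contour of one
punctum, including a deterministic correction for the shot-noise
inflation of the frame maximum (~3.5 σ at the default field size).  With
probability `acer_enrichment_prob` an extra hotspot is painted at the
fission site during the 30 s before the split — the constriction period
in which ER-actin enrichment is reported to appear.

**Rendering.** Footprints are Gaussian-blurred (PSF σ 0.08 µm), scaled to
`photon_scale` photons (default 200 at unit intensity), Poisson-sampled,
plus Gaussian read noise (SD 2 photons), clipped at zero.
`photon_scale=None` disables noise for oracle tests.

**What it does not emulate** (so what passing tests do *not* show):
3-D structure and defocus, the structured Airyscan PSF, photobleaching,
intensity heterogeneity within organelles, organelle deformation, ER
dynamics, and motor-driven saltatory transport.  Recovery results
transfer to real data only to the extent these omissions are benign for
the statistic in question.

## 2. Morphology (`orgdyn.segmental`)

The vesicle route mirrors a standard ImageJ-macro workflow: rolling-ball
background subtraction (radius 50 px, computed on the conventional 0–255
intensity scale — on a unit-scaled float image a radius-50 ball would
envelop every object — with 4× downsampling for large radii), 3×3 median
despeckle, percentile contrast stretch (0.35 % saturated), 3×3 median,
moment-preserving ("Moments"/Tsai) global threshold, removal of objects
below 0.06 µm² (the size cut carries no unit in its source; µm² is the
only physically sensible reading at 40 nm pixels and is configurable),
and marker-controlled watershed splitting of touching objects.

*Moments threshold.* The unique `(p0, z0, z1)` preserving the first three
grey-level moments of the 256-bin histogram is found in closed form; the
cut is placed at the bin whose cumulative fraction is closest to `p0`.
The exhaustive-search oracle in the tests re-derives the moment system
with independent numerics and scans all 256 cuts.

*Watershed seeds.* The image is h-reconstructed at a prominence of 20 %
of the frame dynamic range and the regional maxima of the reconstruction
are taken as seeds — maxima separated by dips shallower than the
prominence merge, the tolerance behaviour of interactive maxima finders.
(Taking instead the pixels that stand ≥ h above the reconstruction
fragments plateau tops into multiple seeds and over-splits objects.)

*Measurements.* Area = pixel count × pixel size²; perimeter by the
Crofton estimate; circularity `4πA/P²` clamped to [0, 1]; 8-connectivity
throughout; 0-based, row-down pixel coordinates reported in µm.

The mitochondrial route swaps the global threshold for an adaptive
local-mean threshold (block 31 px, offset 5 % of range, plus a permissive
global floor at 10 % of max) and adds skeleton morphometrics: topological
skeleton by thinning; a pixel graph with √2-weighted diagonals, dropping
diagonal edges shortcut by orthogonal neighbours (they create spurious
triangles); terminal twigs under 0.2 µm hanging off junctions are pruned
(thinning artifacts of finite tube width); branches are maximal paths
between nodes of degree ≠ 2, counted by union–find.  A straight bar
yields one branch with ~2 px of thinning retraction per end; a
single-pixel skeleton reports one pixel of length and zero branches by
convention.  Branch counts on dense capsule-star renders remain
approximate (junction-cluster geometry); the exact assertions are made on
analytic shapes.

`top_fraction_mask` keeps pixels ≥ (1 − f) × frame maximum (default
f = 0.25), per frame — the AC-ER convention of masking only the top 25 %
of signal.

## 3. Fission detection (`orgdyn.fissionscan`)

Per-frame labels are linked into a lineage graph by pixel overlap between
consecutive frames.  Edges carry the overlap as a fraction of the smaller
object; edges at ≥ 25 % are *strong*.  Continuity (chains) follows any
overlap; branching decisions use strong edges only — grazing overlaps
from organelles passing each other therefore neither break chains nor
fake splits.

An event is emitted at a node with ≥ 2 strong successors when

1. its unbranched strong ancestry spans ≥ `min_pre_s` (30 s),
2. every daughter is < 95 % of the parent's area (a parent continuation
   plus a passer-by is not a split),
3. every daughter chain survives ≥ `min_post_s` (30 s) without stepping
   into a label that anything else strongly feeds (merge), and
4. no two daughter chains share a node (kiss-and-run exclusion).

Durations are frame counts × Δt; a movie ending inside the window
disqualifies the candidate (persistence cannot be verified).  The site is
the centroid of the inter-daughter interface inside the parent footprint
(daughter masks dilated by 2 px, intersected pairwise, restricted to the
dilated parent), falling back to the daughter-centroid midpoint.

Marker presence: an event is positive if any pixel of the marker mask
(top-25 % by default) lies within `radius_um` (default 0.25 µm, roughly
the ER-tubule contact scale at 40 nm pixels) of the site in any frame of
the 30 s pre-split window.  A second marker channel (e.g. DRP1) goes
through the same operation.

Rates are reported per cell per 5-minute window (the field's convention)
and per organelle-minute.

## 4. Observed-vs-chance statistics (`orgdyn.chancestat`)

The null expectation for marker presence at fission sites is the fraction
of the organelle mask (IsoData binarisation) overlapped by the marker
mask — "integrated density" of the intersection over that of the
organelle, computed on binary masks by default (pixel counts), with an
intensity-weighted variant by config since the phrase can also denote
sums of intensities.

The headline comparison forms a 2×2 table — observed (present, absent)
versus expected-by-chance (`round(p·n)` half-up, `n − round(p·n)`) — and
applies a two-sided Fisher's exact test: conditioning on margins, the
two-sided p sums hypergeometric probabilities of all tables no more
probable than the observed one (ties at 1e-7 relative tolerance),
computed with log-stable mass.  Any zero margin gives p = 1 with a
warning.

Two caveats of that construction are handled explicitly:

* **One-sample alternative.** Comparing a random count against a
  *constant* expected row with a two-sample test over-disperses the null;
  under the null the Fisher route is strongly conservative (its p-values
  concentrate near 1).  An exact one-sample binomial test is therefore
  computed alongside — never silently substituted — and is the test used
  for null-calibration checks.
* **Scorer-matched chance.** The automated scorer asks "is marker within
  radius r of the site in any frame of the window?".  For a punctate
  marker that probability exceeds the plain area fraction (union/dilation
  inflation).  `site_chance_probability` computes the matching null — the
  organelle-mask fraction within r of the union of the marker masks over
  a window of the same length — and the pipeline reports it alongside the
  plain ratio, which remains the headline convention.

Curves are compared with `X² = Σ_t (ȳ_A − ȳ_B)² / (SEM_A² + SEM_B²)`,
df = number of shared timepoints, p from the χ² upper tail.  This is a
reconstruction from the cited description of the "modified chi-squared"
curve comparison; with ~24 cells per condition its simulated null
rejection sits near the nominal 5 % (estimated SEMs make it slightly
liberal at small cell counts).  Group comparisons use ordinary one-way
ANOVA on per-cell means; aggregation always treats the **cell** as the
unit of analysis (cells weigh equally regardless of how many organelles
or events they contribute), condition spread reported as SD across cells.

## 5. Mobility (`orgdyn.mobility`)

*Tracking.* Per-frame centroids are linked by deterministic greedy
globally-nearest-pair assignment with a distance gate (default 1 µm per
frame) and optional gap closing; ties break by (track id, detection id).
This replaces a proprietary autoregressive-motion tracker; its acceptance
standard is ground-truth recovery on synthetic data, not parity with any
particular software.  Tracks shorter than 10 s are dropped as noise.
Mean straight velocity = Euclidean start-to-end displacement / duration
(2-D; imaging is single-plane).

*Autocorrelation.* Each frame t ≥ 1 is compared with frame 0 by
thresholded Manders coefficients (per-frame IsoData thresholds by
default; fixed thresholds supported): M1 = fraction of frame-0
above-threshold intensity lying where frame t is above threshold, M2
symmetric.  The curve value is the mean of M1 and M2 (both retained; the
choice is a config switch — the source names a single "Manders'
Correlation Coefficient" from a function that outputs several).  Manders
overlap rather than intensity covariance makes the readout robust to
photobleaching.  A static stack gives 1 at every offset; the decay rate
increases monotonically with D, in agreement with the tracking readout
(joint Spearman checks).

## 6. Pipeline, determinism, outputs (`orgdyn.pipeline`, `orgdyn.cli`)

`run_pipeline(RunConfig)` chains simulate/load → segment → lineage →
events → marker scoring → chance statistics → tracking → autocorrelation
and returns a `ResultBundle` (regions, events, tracks, curve tables plus
an enrichment report and a provenance block with config hash, seed and
versions).  All randomness flows from the single config seed; identical
config + seed reproduce byte-identical tables (checked by content hash).
Output CSV schemas are fixed; areas in µm², lengths µm, durations s,
velocities µm/s.  A thin `orgdyn` CLI exposes the stages
(`simulate`, `segment`, `fission`, `chance`, `track`, `autocorr`,
`run-all`, `demo`).

## 7. Validation problem sizes

The test suite and `scripts/acceptance.py` choose sizes that make each
check informative at desk scale: 25-object frames (×8–10 seeds) for
segmentation recovery; 40-object movies (×8) with both genuine and
kiss-and-run events for detection fidelity; 60-object movies (×20 seeds,
≥ 50 events each) for enrichment power; ~60 half-length movies for null
calibration (~55 events each, where the exact binomial's attainable size
is close to 5 %); 4 diffusion levels × 12–20 seeds for mobility
monotonicity; 500 numpy-level replicates for the curve-comparison null;
1000-step trajectories for the MSD check.

## 8. Known limitations

* The generator's dynamics are the simplest processes exhibiting the
  measured phenomena; none of its defaults are claims about any
  particular cell type.
* Overlap-based lineage requires adequate temporal sampling (step ≪
  object size per frame); the generator respects this by construction,
  real movies may not.
* The Fisher-vs-expected construction is conservative under the null by
  design of its source procedure; the binomial route exists for
  calibration-sensitive use.
* Skeleton branch counts on thick, dense networks carry junction-cluster
  ambiguity inherent to thinning.
* Costes-style threshold regression for colocalization is deliberately
  not implemented.
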