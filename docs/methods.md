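# Methods

## Problem setting

Connectivity-guided TMS targeting selects a stimulation site whose
resting-state BOLD signal has the most favourable coupling with a deep seed
region — most negative for the depression workflow (DLPFC sites
anticorrelated with the sACC), most positive for circuit maps defined the
other way (e.g., anxiosomatic targeting, where the search mask is a 30 mm
sphere in dorsal PFC and the direction flips). Because stimulation
intensity decays with distance, and because deep sulcal sites require
higher intensity with worse tolerability, proximity to the scalp is a
second objective. All computation is volumetric: every map lives on a 3D
voxel grid with a voxel→world-mm affine taken verbatim from the NIfTI
header, and all distances are Euclidean millimetres in that frame.

## The tree-consensus algorithm

**Inputs.** An individual network parcellation (integer labels, treated as
a precomputed input), a voxelwise seed-connectivity map (Pearson r), a
near-scalp map where *smaller is better* (distance-to-scalp in mm, or
FreeSurfer-style sulcal depth/average convexity as a proxy), an anatomical
search mask, and the set of target-network labels.

**Phase 1.** The personalized ROI is the voxelwise intersection of the
target-network labels with the search mask. An empty ROI is a degenerate
subject and raises rather than silently returning nothing.

**Phase 2.** For each depth percentile d (default 5–10 % in steps of 1),
the ROI is reduced to its top-d% shallowest voxels by the nearest-rank
rule. The connectivity percentile p then sweeps 5–100 % in steps of 5,
stringent → lenient, within that near-scalp ROI. The retained voxel sets
are nested in p by construction, so each connected component at one level
is wholly contained in exactly one component at the next; components form
trees with the strictest-level components as leaves. Parent–child linkage
is decided by exact voxel-subset testing (components can only grow under
nested thresholds; an assertion guards the impossible split case).
Candidate targets are the component centroids of leaves and of parents
with at least two children. Centroids are unweighted means of member voxel
centres, not snapped to the component (a `snap_to_component` option
exists); for non-convex components the centroid can fall outside the
component, which is intentional and matches how the candidates behave as
consensus votes. Candidates rediscovered at multiple depth thresholds are
deduplicated within half a voxel (configurable) so they vote once.

**Phase 3.** The target is the candidate minimizing the mean Euclidean
distance to all other candidates. Exact ties are broken by the more
favourable connectivity value recorded on the candidate, then by
lexicographic voxel index. Phases 1–3 contain no randomness; identical
inputs give bit-identical targets.

## Baseline algorithms

**Cluster.** Threshold the connectivity map inside the search mask
(percentile dialect by default, matching the cross-validated search space;
an absolute-r cutoff mode is provided because both readings exist in the
literature), label components, return the centroid of the largest
(size ties → lowest voxel index). The retention percent is tuned per
subject by leave-one-individual-out cross-validation: for each held-out
subject, every candidate percent is scored on the remaining subjects by
the seed FC of the resulting targets evaluated on a held-out run, and the
percent with the most favourable mean is assigned. Thresholds that fail
for any training subject are skipped with a log entry.

**Cone.** Candidate sites are brain-surface voxels (mask voxels on the
exterior face-adjacency boundary of the brain) thinned to 4 mm spacing by
deterministic greedy farthest-point selection starting at the lowest voxel
index. Each site is scored by a distance-weighted mean of defined
connectivity values within a 12 mm sphere. The weight profile decays
linearly from the centre to zero at the outer radius — a continuous
reading of the documented concentric shells at 2, 4, 7, 9 and 12 mm — and
realized voxel weights are normalised to mean one over the sphere (the
normalisation cancels in the weighted mean but is preserved as the
documented kernel contract). The profile is a callable and can be swapped
for a per-shell-constant variant. By construction the winning site is on
the brain surface, hence near the scalp.

## Evaluation metrics

All per-subject metrics follow the session-swap contract: derive targets
from session A, evaluate on session B's data, reverse, average.

- **Scalp proximity** — the depth map value at the target (nearest defined
  voxel when the centroid falls just off the gray ribbon), averaged over
  the two sessions.
- **Intensity conversion** — Δintensity(%) = (d_ref − d_new) × 3 %/mm ×
  RMT-fraction. At 90 % RMT the effective slope is 2.7 %/mm. Linear,
  antisymmetric, no clamping.
- **Reliability** — intra = ‖t_ses1 − t_ses2‖; inter = mean distance from
  the session-1 target to the other subjects' session-1 targets (averaging
  over others' sessions is a config option; the default uses session 1
  because the choice is not pinned down by convention). Ratio = inter/intra,
  larger is better. intra = 0 (the "group target" degeneracy) flags the
  ratio infinite and excludes it from summaries rather than rewarding it.
- **Held-out seed FC** — Pearson r between the mean series of a 5 mm
  sphere at the target and the evaluation session's seed time course. The
  5 mm radius is a package default (the seed-region extent used for this
  metric is not standardised); it is recorded in outputs and configurable.
  Swapped-session values are combined by plain arithmetic mean (a
  Fisher-z option is available but not default).
- **E-field metrics** (field maps are external inputs, e.g., SimNIBS
  output): hotspot = top-X% of field magnitude under the same nearest-rank
  rule; network specificity = percent of hotspot area labelled with target
  networks (area weights optional, uniform for isotropic voxels); hotspot
  seed FC = field-weighted mean hotspot time course correlated with the
  seed; E-field reliability = inter-/intra-individual map correlation
  ratio, for which **smaller** is better — the output schema records the
  favourable direction explicitly so it cannot be silently inverted.
  Maps are accepted on voxel grids or as (coordinate, value) vertex lists;
  computation is location-set based so both behave identically.

## Numerical conventions

- **Percentile semantics**: nearest-rank with ceiling, relative to the ROI
  the threshold is applied within (depth within the personalized ROI, FC
  within the depth-surviving ROI). Exactly ⌈p/100·N⌉ voxels are kept; ties
  at the cutoff break by value then flat voxel index, so masks are
  deterministic and nested in p. A 1e-9 backoff keeps exactly-integral
  ranks from being pushed up by floating error.
- **Component connectivity**: 26-neighbourhood by default (face + edge +
  corner), configurable to 6 or 18. Lenient connectivity matches the
  "components merge as thresholds loosen" behaviour the tree exploits.
  Labels order by decreasing size, then lowest voxel index.
- **Surface extraction** (scalp surface, brain-surface seeds): exterior
  *face-adjacency* boundary — the tightest one-voxel surface layer. The
  thicker corner-adjacency boundary includes voxels up to a voxel diagonal
  below the true surface and measurably degrades distance-to-scalp
  accuracy on an analytic sphere (3.36 mm vs 1.93 mm worst-case error at
  2 mm voxels), so face adjacency is the default and the invariant "error
  ≤ one voxel edge on a sphere phantom" holds.
- **Distance-to-scalp**: exact nearest-neighbour distance (KD-tree) from
  gray voxel centres to scalp-surface voxel centres, valid for any affine
  including oblique ones; straight-line, not geodesic.
- **Constant series**: voxels whose time series has exactly zero range are
  undefined in correlation maps (never silently zero); this is detected on
  the raw series, not after mean-centering, so rounding residuals cannot
  resurrect them.
- **Cone score ties**: scores within a 1e-12 relative tolerance count as
  ties and resolve to the earliest seed in canonical order, so constant
  fields give reproducible winners across summation orders.

## The phantom

The phantom generates everything the algorithms consume, with known ground
truth. Anatomy: a spherical head (radius 36 mm on a 40³ grid of 2 mm
voxels), a 10 mm cortical shell whose outer surface lies 6 ± 3 mm below
the scalp, modulated by a smooth sinusoidal fold field (4 angular cycles,
tapered at the poles) creating gyral (shallow) and sulcal (deep) cortex.
The analytic distance-to-scalp of an interior point at radius r is R − r,
stored as the depth map and used to bound the computed distance transform.

Signals: the seed course is a unit-variance white Gaussian process (an
AR(1) option adds temporal smoothness; the algorithms are insensitive to
it, since Pearson correlation ignores autocorrelation structure in the
large-T limit). Each gray voxel's series is coupling(x)·seed + σ·noise
with σ = 1 and T = 240 frames, where coupling is a sum of signed Gaussian
bumps (σ_spatial = 6 mm). The planted depression-like blob has coupling
−0.8 at its centre, giving a population correlation of
c/√(c² + σ²) ≈ −0.62 at the centre — a strong but realistic individual
peak — and this closed-form attenuation law is verified empirically in the
tests. A positively coupled region (+0.9) on the far side of the shell
stands in for the deep seed structure: its indicator serves as the
group-level weight map, and the search mask is excluded from the weighted
average exactly as a stimulation-site mask would be.

Between-subject variability is a rigid jitter (uniform ±3 mm per axis,
projected onto the tangent plane of each blob's radial direction so blobs
shift along the cortical sheet instead of drifting out of the tissue) plus
a ~10 % amplitude rescaling, shared across a subject's sessions; sessions
differ only in fresh noise. Registration across phantom subjects is the
identity (one shared grid), so cross-subject metrics need no transforms.
The single-blob configuration plants the truth on a gyral crown ~1 voxel
below the outer cortical surface — in the shallow band the depth
thresholds retain, which is what "near-scalp target" means here. The
two-blob configuration adds a *stronger* blob (−0.95) deep in a sulcal
fundus: connectivity alone prefers it, so it separates algorithms that
respect scalp proximity (tree, cone) from one that does not (cluster).

What the phantom does **not** emulate: BOLD autocorrelation and
physiological noise, motion, spatial noise correlations, realistic
cortical geometry (gyrification is a smooth radial modulation, not folded
sheets), partial-volume effects, and non-identity cross-subject
registration. Passing tests therefore demonstrate algorithmic correctness
and the qualitative depth/connectivity trade-off, not performance on real
MRI.

Problem sizes in the test and acceptance suites (20-subject cohorts on the
40³ default grid; a 28³ scaled-down variant for unit tests) were chosen to
make the statistical checks stable while keeping a full run in the tens of
seconds.

## Known limitations and open choices

- Whether candidate centroids should be snapped onto cortex before
  reporting is left off by default (the literal "centroid" reading); the
  option exists because a centroid can fall marginally off the ribbon.
- Whether duplicate candidates across depth thresholds should vote once or
  multiply in the consensus is not standardised; this implementation
  deduplicates within half a voxel so rediscovery does not bias the
  medoid, and the tolerance is configurable (0 disables deduplication).
- The cluster algorithm's threshold dialect (percentile vs absolute r) is
  genuinely ambiguous in the literature; both are implemented, percentile
  is default.
- Group-level statistics across subjects (significance testing, FDR) are
  out of scope; the workflow emits per-subject metric tables for external
  statistical analysis.
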