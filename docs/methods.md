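# Methods

This note documents the models, numerical choices and limitations behind
`sdtrack`. It complements the README, which states what the package does;
here is *how* and *why*.

## The propagation model

An SD wave-front is modelled as a circular arc on the discretized cortical
surface. Its curvature center is the latent state; the observables are the
onset times at the electrodes the wave passes. Four assumptions restrict the
model class: tangential arc propagation, near-constant arc radius,
near-constant center velocity, and geodesic center motion between
electrodes. The fourth is deliberately strong — it selects the slowest
trajectory consistent with each TOAD; without it arbitrarily fast detours
would explain any data.

Admissibility of a candidate segment (center `a` near electrode `A`, center
`b` near electrode `B`, hit in succession with time lag `TOAD`):

* segment velocity `d(a,b)/TOAD` lies in the active velocity subrange
  intersected with the global window `[v_min, v_max] = [0, 15]` mm/min;
* radius near-constancy `|d(a,A) − d(b,B)| ≤ R_diff`.

Radius continuity across segments is automatic because consecutive segments
share the center vertex, so enforcing `R_diff` per segment also bounds the
radius drift at joins. Velocity near-constancy across segments is enforced
structurally: all segments of one trajectory must fit a single subrange.

### Velocity subranges

Fifteen subranges are centered at 1..15 mm/min. `V_diff` is the half-width,
so `V_diff = 1` gives 2 mm/min-wide intervals with 50 % overlap between
neighbours. Intervals are closed; a velocity on a shared boundary belongs to
both neighbours. A geometric trajectory admissible in two overlapping
subranges is counted in both — totals are deliberately un-deduplicated
(consistent with reporting the raw size of the model class); an exact
deduplicating counter (`count_distinct_solutions`) exists for instances
small enough to enumerate.

### Parameters

| name | default | unit | meaning |
|---|---|---|---|
| `r_max` | 5 | mm | max wave-front curvature radius; bounds candidate disks |
| `R_diff` (`r_diff`) | 1 (also 0.5) | mm | max radius change per segment |
| `V_diff` (`v_diff`) | 1 (also 0.5, 0.25) | mm/min | velocity subrange half-width |
| `v_min, v_max` | 0, 15 | mm/min | accepted velocity window |
| `patch_radius` | 30 | mm | geodesic patch margin around every electrode |
| subrange centers | 1..15 step 1 | mm/min | quantization grid for velocities |

The six canonical tolerance combinations swept by the pipeline are
(R_diff, V_diff) ∈ {1, 0.5} × {1, 0.5, 0.25}. Lowering either tolerance can
only shrink the admissible set, so success indicators and counts are
monotone in the tolerances (a property the tests assert exactly).

## The layered search

Partial trajectories are grown in electrode hit order and grouped by their
end vertex. Layer 0 seeds every vertex of the first electrode's candidate
disk with count 1; the count at layer N is the sum over admissible
predecessors at layer N−1. Counts are exact Python integers: real instances
reach ~10¹⁶ trajectories, far beyond both enumeration and double-precision
integer safety. Everything downstream reuses the count tables:

* **total count** — sum of final-layer counts over subranges;
* **heatmaps** — the number of trajectories through a vertex is
  forward × backward count at its layer; in `paths` mode the canonical
  geodesic of every admissible segment pair is walked and credited with
  forward(a) × backward(b). Each non-revisiting trajectory credits each of
  its vertices exactly once (segment paths skip their start vertex);
  a self-revisiting trajectory would credit a vertex once per visit;
* **uniform sampling** — subrange ∝ its total, first center ∝ its
  completion count, each transition ∝ the successor's completion count, with
  exact big-integer inverse-CDF draws, so uniformity over the full solution
  set holds at any magnitude.

## Velocity estimation

Within one subrange every admissible segment velocity quantizes to the
subrange's central value. The per-segment estimate averages those centers
over participating *(pair, subrange)* instances — a pair being a candidate
segment that belongs to at least one complete trajectory. The alternative of
weighting each subrange by its complete-trajectory count was rejected:
chain counts grow multiplicatively with segment multiplicity, which skews
the weight toward longer (hence faster) zig-zag chains and inflates the
estimate by up to ~2 mm/min at the top of the velocity range on synthetic
waves; pair weighting keeps the recovery error within the subrange
half-width plus graph-metric allowance across 2–9 mm/min. A residual upward
bias remains in both schemes because lateral center offsets can only
lengthen a segment: there are simply more admissible geometries above the
true velocity than below it.

The SD velocity is the TOAD-weighted arithmetic mean of the per-segment
estimates — segments that took longer carry proportionally more weight.

## Leave-one-out validation

For every interior electrode of a consecutive triad, its hit is withheld,
the search re-runs on the reduced sequence (which may have only two hits —
one segment), and trajectories are sampled. Each sample is converted to a
moving front: the center walks the canonical geodesic between consecutive
sampled centers at constant segment speed; the front radius interpolates
linearly in time between the segment's endpoint radii. The withheld
electrode is *reached* if the front comes within `radius + tolerance` of it,
with tolerance one mean edge length of the patch (the resolution floor of
the discrete front). The predicted hit time is the first true front crossing
(distance ≤ radius) when one exists, else the closest-approach time; using
the tolerance itself as the crossing level would systematically predict one
edge length early. The spatial error is
`v_sample · (t_predicted − t_observed)` — positive when the model predicts a
later hit than observed. Per-SD success defaults to a majority rule (mean
reach fraction ≥ 0.5 across steps); an any-sample-reaches rule is available.

A caveat on unreachable contacts: candidate centers may sit up to `r_max`
off the strip axis and carry fronts of radius up to `r_max`, so a contact
must lie more than `2·r_max` plus the reach tolerance off the trajectory
corridor before a zero reach fraction is guaranteed. The off-path test
fixture places the withheld contact 16 mm laterally for this reason; at
10 mm, admissible fronts can legitimately graze it.

## Geometry

**Geodesics.** Distances are shortest paths on the vertex–edge graph
(Dijkstra), matching the discretization the search operates on. Canonical
single-source maps (used for path extraction) break ties toward the smallest
predecessor id so paths are deterministic; bulk distance tables use scipy's
compiled Dijkstra on the same weighted graph. The edge-graph metric
overestimates the surface metric anisotropically — on a near-equilateral
triangulation the worst-direction stretch is ~15 % and the mean over random
directions ~7 %. This stretch largely cancels in the pipeline because
simulated onsets and reconstruction use the same graph metric; against
analytic sphere geodesics it is the dominant error term and does not vanish
with refinement.

**Up-sampling.** The interpolating 4-split: one new vertex per edge, each
triangle into four, original vertices unmoved, so V' = V + E and F' = 4F. New
vertices are placed by the butterfly spline stencil (8-point, weights 1/2,
1/8, −1/16) where the edge is regular, by a 4-point boundary stencil on
boundary chains, and at the plain midpoint elsewhere; a pure-midpoint mode
is available. Both modes reproduce planar input exactly. On curved surfaces
the butterfly bulge slightly rounds the mesh and measurably (if modestly)
reduces the mean graph-metric error, and refinement shrinks the
short-range rounding error that matters at candidate-disk scale.

**Smoothing.** Edge-length-preserving Laplacian smoothing alternates an
umbrella step (interior vertices only, boundary fixed, step ≤ 1) with an
iterative per-edge projection back toward the original lengths (stopping at
0.25 % mean relative error). Angles change, the intrinsic metric is
retained; mean edge-length drift stays below 1 % and the run aborts if any
edge drifts more than 10 %. The default pipeline order is patch → smooth →
up-sample: smoothing the coarse patch is cheaper and the interpolating
subdivision then refines already-smoothed geometry; the reverse order is
exposed for comparison since neither order is canonical.

**Patch extraction.** The patch is the union of geodesic disks
(`patch_radius` = 30 mm) around the electrodes, dilated by one vertex ring so
every boundary vertex is strictly beyond the radius — candidate disks and
bipartite paths never feel the cut. An electrode within the radius of the
parent mesh boundary is an error, not a silent clip.

## Synthetic data: what it emulates, what it does not

The generators mirror the study conditions: a collinear strip of six disk
electrodes at 10 mm spacing on a cortical patch; SD waves as circular arcs
of constant radius and velocity; CT volumes with tissue-range background
(20–120 HU) and metal-bright contacts (3500 HU, segmented at the 3000 HU
threshold).

* `plane` — flat triangulated grid; default resolution 1.25 mm so the 10 mm
  spacing is an exact grid multiple.
* `gyral` — the plane displaced by a single-frequency sinusoid (default
  amplitude 4 mm, wavelength 25 mm, resolution 1.0 mm): the simplest surface
  on which Euclidean and geodesic distances diverge, enough to exercise the
  patch and geodesic machinery. Strip placement requires consecutive
  geodesic spacings within 5 % of nominal and refuses otherwise.
* waves — `moving_center` (center path along or parallel to the strip,
  extended beyond both ends so fronts fully cross every contact) and
  `concentric` (point source; sources placed a few mm off an interior
  electrode produce the branching hit sequences the reduction step targets).
  Onsets are exact by default because onset marking noise is a property of
  human labelling, not of the model; Gaussian onset jitter is available to
  probe robustness.

What passing tests on these fixtures does **not** show: real cortical
surfaces have multi-scale folding, FreeSurfer meshes have unequal triangles,
real SDs violate the constant-radius/velocity assumptions to varying
degrees, and real onset times carry labelling uncertainty. The synthetic
results validate the algorithmic machinery (exact counting, recovery under
the model's own assumptions), not clinical performance.

## Degenerate inputs and tie-breaking

* Tied onsets are rejected (a zero TOAD implies infinite velocity); callers
  may jitter by a documented epsilon if they accept the distortion.
* Branch reduction removes the branch with fewer hits; on a length tie, the
  branch whose final hit occurs later. Sequences not decomposable into at
  most two monotone runs are flagged non-reducible and passed through —
  the search is then allowed to fail, and that failure is itself a result
  the pipeline reports.
* Nearest-vertex snapping breaks distance ties toward the smallest vertex
  id; two centroids snapping to one vertex is an error (contacts must stay
  distinct).
* Electrode ordering after CT segmentation is never guessed silently: it is
  either supplied or inferred from the principal-axis projection of the
  centroids, and the inference is recorded on the result.

## Problem sizes

The bundled verification runs use: tiny 3-electrode instances on ≤300-vertex
patches for oracle equivalence (20 randomized instances), 8 velocities × 2
surface kinds for recovery, a 6-event cohort (3 straight + 3 branching) for
the tolerance sweep, 100 samples per leave-one-out step, 100 random vertex
pairs on a subdivision-4 icosphere for geodesic accuracy, 6000 draws for
sampling uniformity, and 0.5 mm voxels for the CT round trip. These sizes
were chosen as the smallest at which each property is non-trivially
exercised; all scale up linearly via the generator parameters.
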