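"""SD velocity estimation and leave-one-electrode-out validation.

The velocity of an SD is a TOAD-weighted arithmetic mean of per-segment
velocities. Within one velocity subrange every admissible segment velocity is
quantized toward that subrange's central value, so the per-segment estimate
is a count-weighted mean of subrange centers.

Validation withholds the middle electrode of each consecutive electrode
triad, re-runs the search on the reduced hit sequence, and asks, over a
random selection of the proposed trajectories, whether the reconstructed
wave (center moving along the trajectory with linearly interpolated front
radius) would still have reached the withheld electrode — and if so, how far
(in mm, via the sample's velocity) the predicted hit time lies from the
observed one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import SearchError
from .events import HitSequence
from .mesh import Patch, geodesic_distances, geodesic_from, shortest_path
from .search import (
    SearchParams,
    SolutionDP,
    TrajectorySample,
    count_solutions,
    grow_solutions,
    sample_trajectories,
)

__all__ = [
    "VelocityEstimate",
    "ValidationStep",
    "ValidationOutcome",
    "segment_velocity",
    "sd_velocity",
    "estimate_velocity",
    "validate_loo",
]


@dataclass
class VelocityEstimate:
    """Per-segment quantized velocities, their TOAD weights, and the overall
    TOAD-weighted SD velocity (mm/min)."""

    segment_velocities: np.ndarray
    toads: np.ndarray
    velocity: float


def segment_velocity(dp: SolutionDP, segment: int, subrange: float) -> float:
    """Count-weighted mean quantized velocity on one segment within one
    subrange.

    Every admissible sub-trajectory velocity in the subrange quantizes to the
    subrange's central value, so with a single subrange this equals that
    center exactly; the function still verifies that the segment carries
    solutions.
    """
    if not (0 <= segment < dp.n_segments):
        raise IndexError("segment out of range")
    if subrange not in dp.totals:
        raise SearchError(f"subrange {subrange} not searched")
    if dp.totals[subrange] == 0:
        raise SearchError(f"no solutions in subrange {subrange}")
    # weight of the segment = number of complete trajectories crossing it,
    # which equals the subrange total; quantization maps them all to `subrange`
    return float(subrange)


def segment_velocity_overall(dp: SolutionDP, segment: int) -> float:
    """Quantized segment velocity aggregated over all subranges.

    Each admissible sub-trajectory (candidate pair) on the segment that
    participates in at least one complete trajectory contributes its
    subrange's central value once per subrange it is active in; the segment
    velocity is the arithmetic mean of those quantized values. Weighting by
    participating pairs rather than by complete-trajectory counts keeps the
    estimate from being dominated by the combinatorial multiplicity of long,
    fast zig-zag chains.
    """
    if count_solutions(dp) == 0:
        raise SearchError("no solutions")
    back = dp.backward()
    num = 0.0
    den = 0
    for c in dp.params.subrange_centers:
        if dp.totals[c] == 0:
            continue
        fwd = dp.forward[c]
        bwd = back[c]
        active = (
            (fwd[segment][:, None] > 0)
            & dp.masks[c][segment]
            & (bwd[segment + 1][None, :] > 0)
        )
        n_pairs = int(active.sum())
        num += n_pairs * c
        den += n_pairs
    return num / den


def sd_velocity(segment_velocities, toads) -> float:
    """TOAD-weighted arithmetic mean of segment velocities:
    Σ v_k·TOAD_k / Σ TOAD_k."""
    v = np.asarray(segment_velocities, dtype=np.float64)
    w = np.asarray(toads, dtype=np.float64)
    if v.shape != w.shape:
        raise ValueError("segment_velocities and toads length mismatch")
    if (w <= 0).any():
        raise ValueError("TOAD weights must be positive")
    return float((v * w).sum() / w.sum())


def estimate_velocity(dp: SolutionDP) -> VelocityEstimate:
    """Overall SD velocity from a successful search."""
    seg = np.array(
        [segment_velocity_overall(dp, k) for k in range(dp.n_segments)]
    )
    toads = dp.seq.toads
    return VelocityEstimate(
        segment_velocities=seg,
        toads=toads,
        velocity=sd_velocity(seg, toads),
    )


# ---------------------------------------------------------------------------
# Leave-one-electrode-out validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationStep:
    """One withheld middle electrode: reach fraction over the samples and the
    spatial errors of the reaching samples (positive = predicted later than
    observed)."""

    withheld: str
    failed: bool
    reach_fraction: float = np.nan
    spatial_errors: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def mean_spatial_error(self) -> float:
        return float(self.spatial_errors.mean()) if len(self.spatial_errors) else np.nan


@dataclass
class ValidationOutcome:
    """Per-SD aggregate over validation steps (equal weights)."""

    steps: list[ValidationStep]
    reach_fraction: float
    success: bool
    mean_spatial_error: float


def _sample_front(
    patch: Patch,
    sample: TrajectorySample,
    times: np.ndarray,
    gmap_cache: dict,
):
    """Discretize one sampled wave: vertices along the canonical center path
    with their passage times and linearly interpolated front radii."""
    verts: list[int] = []
    t_list: list[float] = []
    r_list: list[float] = []
    for k in range(len(sample.centers) - 1):
        a, b = sample.centers[k], sample.centers[k + 1]
        if a not in gmap_cache:
            gmap_cache[a] = geodesic_from(patch.mesh, a)
        path = shortest_path(gmap_cache[a], b)
        seg_len = sample.distances[k]
        t0, t1 = times[k], times[k + 1]
        r0, r1 = sample.radii[k], sample.radii[k + 1]
        # cumulative arc length along the path
        P = patch.mesh.vertices
        s = np.concatenate(
            [[0.0], np.cumsum(np.linalg.norm(np.diff(P[path], axis=0), axis=1))]
        )
        frac = s / seg_len if seg_len > 0 else np.zeros_like(s)
        tt = t0 + frac * (t1 - t0)
        rr = r0 + frac * (r1 - r0)
        start = 1 if verts else 0       # avoid duplicating shared centers
        verts.extend(path[start:])
        t_list.extend(tt[start:])
        r_list.extend(rr[start:])
    return np.array(verts), np.array(t_list), np.array(r_list)


def validate_loo(
    patch: Patch,
    seq: HitSequence,
    params: SearchParams,
    n_samples: int = 100,
    seed: int = 0,
    reach_tolerance: float | None = None,
    success_rule: str = "majority",
) -> ValidationOutcome:
    """Leave-one-out validation over every middle electrode of a triad.

    For each interior hit, the hit is withheld, the search is re-run on the
    reduced sequence and ``n_samples`` trajectories are sampled. A sample
    *reaches* the withheld electrode when its reconstructed front (center
    path, radius linearly interpolated within segments) comes within
    radius + tolerance of it; the spatial error converts the predicted-vs-
    observed hit-time difference into mm with the sample's own velocity.
    A reduced search with zero solutions marks the step failed (reach
    fraction 0), never raises. ``success_rule``: "majority" (reach fraction
    ≥ 0.5) or "any".
    """
    if len(seq) < 3:
        raise SearchError("need at least 3 hits for a validation triad")
    if reach_tolerance is None:
        reach_tolerance = patch.mesh.mean_edge_length()

    steps: list[ValidationStep] = []
    for i in range(1, len(seq) - 1):
        withheld = seq.electrodes[i]
        t_obs = float(seq.times[i])
        keep = [j for j in range(len(seq)) if j != i]
        red = HitSequence(
            event_id=seq.event_id,
            electrodes=[seq.electrodes[j] for j in keep],
            times=seq.times[keep],
            reduced=seq.reduced,
            removed=list(seq.removed),
        )
        try:
            dp = grow_solutions(patch, red, params, min_hits=2)
        except SearchError:
            steps.append(ValidationStep(withheld=withheld, failed=True,
                                        reach_fraction=0.0))
            continue
        if count_solutions(dp) == 0:
            steps.append(ValidationStep(withheld=withheld, failed=True,
                                        reach_fraction=0.0))
            continue

        samples = sample_trajectories(dp, n_samples, seed=seed + 1009 * i)
        ev = patch.electrodes[withheld]
        d_with = geodesic_distances(patch.mesh, ev)[0]
        gmap_cache: dict = {}
        n_reached = 0
        errors = []
        for s in samples:
            verts, tt, rr = _sample_front(patch, s, red.times, gmap_cache)
            margin = d_with[verts] - rr
            if margin.min() > reach_tolerance:
                continue
            n_reached += 1
            # predicted hit time: first true front crossing (margin <= 0)
            # when the front actually covers the electrode; otherwise the
            # closest-approach time (the tolerance only decides reach).
            crossing = margin <= 0
            if crossing.any():
                j = int(np.argmax(crossing))
                if j == 0:
                    t_pred = tt[0]
                else:
                    m0, m1 = margin[j - 1], margin[j]
                    frac = m0 / (m0 - m1) if m0 != m1 else 1.0
                    t_pred = tt[j - 1] + frac * (tt[j] - tt[j - 1])
            else:
                t_pred = tt[int(np.argmin(margin))]
            v_sample = sd_velocity(s.velocities, red.toads)
            errors.append(v_sample * (t_pred - t_obs))
        steps.append(
            ValidationStep(
                withheld=withheld,
                failed=False,
                reach_fraction=n_reached / n_samples,
                spatial_errors=np.array(errors),
            )
        )

    fractions = np.array([s.reach_fraction for s in steps])
    reach = float(fractions.mean())
    if success_rule == "majority":
        success = reach >= 0.5
    elif success_rule == "any":
        success = bool((fractions > 0).any())
    else:
        raise ValueError(f"unknown success_rule {success_rule!r}")
    all_err = np.concatenate(
        [s.spatial_errors for s in steps if len(s.spatial_errors)]
    ) if any(len(s.spatial_errors) for s in steps) else np.array([])
    return ValidationOutcome(
        steps=steps,
        reach_fraction=reach,
        success=success,
        mean_spatial_error=float(all_err.mean()) if len(all_err) else np.nan,
    )
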