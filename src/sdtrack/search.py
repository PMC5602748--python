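"""The 'could fit' trajectory search.

The SD wave-front is modelled as a circular arc of fairly constant radius
whose curvature center travels on surface geodesics at fairly constant
velocity. When the center passes electrode ``E_k`` at its observed onset
time, the center position is some vertex within ``r_max`` geodesic mm of
``E_k`` (the candidate disk). A pair (a at E_{k-1}, b at E_k) is admissible
iff

* the segment velocity  v = d(a, b) / TOAD_k  lies inside the active velocity
  subrange (clipped to the global [v_min, v_max] window), and
* the wave-front radii nearly match: |d(a, E_{k-1}) − d(b, E_k)| ≤ r_diff.

Trajectories are grown layer by layer in hit order, grouping partial
trajectories by their endpoint: the count of partial trajectories ending at
``b`` is the sum of counts over admissible predecessors ``a``. The counts are
exact arbitrary-precision integers — real instances reach ~1e16 solutions, so
enumeration is impossible but counting, uniform sampling and per-vertex
inclusion heatmaps all follow from the forward/backward count tables.

The fifteen velocity subranges (centers 1..15 mm/min, half-width ``v_diff``)
are searched independently; requiring all segments of one trajectory to share
a subrange is what enforces near-constant velocity. Overlapping subranges may
count one geometric trajectory more than once; totals are reported
un-deduplicated by default (an exact dedup exists for tiny instances).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import numpy as np

from .errors import SearchError
from .events import HitSequence
from .mesh import Patch, geodesic_distances, geodesic_from, shortest_path

__all__ = [
    "SearchParams",
    "CandidateDisk",
    "SolutionDP",
    "Heatmap",
    "TrajectorySample",
    "candidate_disk",
    "bipartite_distances",
    "grow_solutions",
    "count_solutions",
    "count_distinct_solutions",
    "enumerate_trajectories",
    "heatmap",
    "sample_trajectories",
    "verify_admissibility",
]

CANONICAL_COMBINATIONS = (
    (1.0, 1.0), (1.0, 0.5), (1.0, 0.25),
    (0.5, 1.0), (0.5, 0.5), (0.5, 0.25),
)


@dataclass(frozen=True)
class SearchParams:
    """Tolerances and ranges of the trajectory search.

    ``r_diff`` (mm) bounds the radius change between consecutive candidate
    centers; ``v_diff`` (mm/min) is the half-width of each velocity subrange;
    segment velocities must lie in [v_min, v_max] = [0, 15] mm/min and
    wave-front radii in [0, r_max] = [0, 5] mm; subrange centers default to
    1..15 mm/min in 1 mm/min steps.
    """

    r_diff: float = 1.0
    v_diff: float = 1.0
    v_min: float = 0.0
    v_max: float = 15.0
    r_max: float = 5.0
    patch_radius: float = 30.0
    subrange_centers: tuple = tuple(float(c) for c in range(1, 16))
    seed: int = 0

    def __post_init__(self):
        if self.r_diff <= 0 or self.v_diff <= 0:
            raise ValueError("r_diff and v_diff must be positive")
        if self.v_max <= self.v_min:
            raise ValueError("v_max must exceed v_min")
        if self.r_max >= self.patch_radius:
            raise ValueError("r_max must be smaller than patch_radius")

    def subrange(self, center: float) -> tuple[float, float]:
        """Closed velocity interval for one subrange, clipped to the global
        window. A velocity on a shared boundary belongs to both neighbours."""
        return (max(center - self.v_diff, self.v_min),
                min(center + self.v_diff, self.v_max))


@dataclass
class CandidateDisk:
    """All patch vertices within geodesic ``r_max`` of one electrode; the
    stored radii d(vertex, electrode) are the candidate wave-front radii."""

    electrode: str
    electrode_vertex: int
    members: np.ndarray     # patch vertex ids
    radii: np.ndarray       # geodesic distance to the electrode vertex

    def __len__(self) -> int:
        return len(self.members)


def candidate_disk(patch: Patch, electrode: str, r_max: float = 5.0) -> CandidateDisk:
    """Geodesic disk of radius ``r_max`` around an electrode's patch vertex."""
    try:
        ev = patch.electrodes[electrode]
    except KeyError:
        raise SearchError(f"electrode {electrode} not in patch") from None
    d = geodesic_distances(patch.mesh, ev, limit=r_max * (1 + 1e-12))[0]
    inside = np.where(d <= r_max)[0]
    order = np.argsort(d[inside], kind="stable")
    members = inside[order]
    return CandidateDisk(
        electrode=electrode,
        electrode_vertex=int(ev),
        members=members.astype(np.int64),
        radii=d[members],
    )


def bipartite_distances(
    patch: Patch, diskA: CandidateDisk, diskB: CandidateDisk
) -> np.ndarray:
    """Geodesic distances d(a, b) for every candidate pair, shape (|A|, |B|).

    Unreachable pairs hold +inf and are excluded downstream by the velocity
    window.
    """
    if len(diskA) == 0 or len(diskB) == 0:
        raise SearchError("empty candidate disk")
    full = geodesic_distances(patch.mesh, diskA.members)
    return full[:, diskB.members]


@dataclass
class SolutionDP:
    """Endpoint-grouped dynamic program over one hit sequence.

    For every velocity subrange: ``forward[c][k][i]`` counts partial
    trajectories from the first disk to member ``i`` of disk ``k`` (exact
    ints); ``masks[c][k]`` is the admissibility matrix between disks k and
    k+1; ``totals[c]`` sums the final layer. The SD is successfully simulated
    iff some subrange has a positive total.
    """

    seq: HitSequence
    params: SearchParams
    disks: list[CandidateDisk]
    dist_tables: list[np.ndarray]
    forward: dict[float, list[np.ndarray]]
    masks: dict[float, list[np.ndarray]]
    totals: dict[float, int]
    _backward: dict[float, list[np.ndarray]] | None = field(default=None, repr=False)

    @property
    def success(self) -> bool:
        return any(t > 0 for t in self.totals.values())

    @property
    def n_segments(self) -> int:
        return len(self.dist_tables)

    def backward(self) -> dict[float, list[np.ndarray]]:
        """Counts of completions from each candidate to the last layer."""
        if self._backward is None:
            out = {}
            for c, masks in self.masks.items():
                layers = [None] * (self.n_segments + 1)
                layers[-1] = np.array([1] * len(self.disks[-1]), dtype=object)
                for k in range(self.n_segments - 1, -1, -1):
                    layers[k] = masks[k].astype(object) @ layers[k + 1]
                out[c] = layers
            self._backward = out
        return self._backward


def grow_solutions(
    patch: Patch,
    seq: HitSequence,
    params: SearchParams,
    min_hits: int = 3,
) -> SolutionDP:
    """Run the layered search for one hit sequence.

    Layer 0 seeds every vertex of the first electrode's disk with count 1;
    layer k+1 counts are mask-propagated sums over admissible predecessors.
    All arithmetic is exact (Python ints), so totals are valid at any
    magnitude.
    """
    if len(seq) < min_hits:
        raise SearchError(
            f"hit sequence has {len(seq)} hits; at least {min_hits} required"
        )
    toads = seq.toads
    if (toads <= 0).any():
        raise SearchError("non-positive TOAD")
    disks = [candidate_disk(patch, e, params.r_max) for e in seq.electrodes]
    for d in disks:
        if len(d) == 0:
            raise SearchError(f"empty candidate disk at {d.electrode}")
    dist_tables = [
        bipartite_distances(patch, disks[k], disks[k + 1])
        for k in range(len(disks) - 1)
    ]

    forward: dict[float, list[np.ndarray]] = {}
    masks: dict[float, list[np.ndarray]] = {}
    totals: dict[float, int] = {}
    for c in params.subrange_centers:
        v_lo, v_hi = params.subrange(c)
        layer = np.array([1] * len(disks[0]), dtype=object)
        layers = [layer]
        cmasks = []
        for k, D in enumerate(dist_tables):
            with np.errstate(invalid="ignore"):
                V = D / toads[k]
            adm = (V >= v_lo) & (V <= v_hi)
            adm &= (
                np.abs(disks[k].radii[:, None] - disks[k + 1].radii[None, :])
                <= params.r_diff
            )
            cmasks.append(adm)
            layer = adm.astype(object).T @ layer
            layers.append(layer)
        forward[c] = layers
        masks[c] = cmasks
        totals[c] = int(layers[-1].sum())
    return SolutionDP(
        seq=seq,
        params=params,
        disks=disks,
        dist_tables=dist_tables,
        forward=forward,
        masks=masks,
        totals=totals,
    )


def count_solutions(dp: SolutionDP) -> int:
    """Total 'could fit' trajectory count over all subranges (exact)."""
    return sum(dp.totals.values())


def enumerate_trajectories(dp: SolutionDP, limit: int = 1_000_000):
    """Yield (subrange_center, center-vertex tuple) for every solution.

    Test/diagnostic tool for tiny instances only; raises once ``limit``
    trajectories have been produced.
    """
    produced = 0
    for c in dp.params.subrange_centers:
        masks = dp.masks[c]
        back = dp.backward()[c]

        def rec(k, i, prefix):
            nonlocal produced
            if k == dp.n_segments:
                produced += 1
                if produced > limit:
                    raise SearchError("enumeration limit exceeded")
                yield (c, tuple(prefix))
                return
            nxt = np.where(masks[k][i] & (back[k + 1] > 0))[0]
            for j in nxt:
                yield from rec(k + 1, int(j),
                               prefix + [int(dp.disks[k + 1].members[j])])

        for i in range(len(dp.disks[0])):
            if back[0][i] > 0:
                yield from rec(0, i, [int(dp.disks[0].members[i])])


def count_distinct_solutions(dp: SolutionDP, limit: int = 1_000_000) -> int:
    """Exact count of geometrically distinct trajectories (dedup across
    overlapping subranges). Tiny instances only."""
    return len({traj for _, traj in enumerate_trajectories(dp, limit=limit)})


# ---------------------------------------------------------------------------
# Heatmap
# ---------------------------------------------------------------------------

@dataclass
class Heatmap:
    """Per-patch-vertex trajectory-inclusion counts and percentages of the
    total 'could fit' count."""

    counts: np.ndarray          # object dtype, exact ints
    percent: np.ndarray
    total: int


def heatmap(dp: SolutionDP, patch: Patch, mode: str = "paths") -> Heatmap:
    """Count, for every patch vertex, the trajectories that include it.

    ``mode="keypoints"`` counts only the per-layer center vertices (weight =
    forward × backward count at that layer); ``mode="paths"`` additionally
    walks the canonical geodesic path of every admissible segment pair so
    vertices between centers are included. A vertex on every solution scores
    100 %.
    """
    total = count_solutions(dp)
    if total == 0:
        raise SearchError("no trajectories")
    n = patch.mesh.n_vertices
    counts = np.array([0] * n, dtype=object)
    back = dp.backward()

    if mode == "keypoints":
        for c in dp.params.subrange_centers:
            fwd = dp.forward[c]
            bwd = back[c]
            for k, disk in enumerate(dp.disks):
                w = fwd[k] * bwd[k]
                for i, v in enumerate(disk.members):
                    counts[v] += w[i]
    elif mode == "paths":
        gmaps: dict[int, object] = {}

        def canonical_path(a: int, b: int) -> list[int]:
            if a not in gmaps:
                gmaps[a] = geodesic_from(patch.mesh, a)
            return shortest_path(gmaps[a], b)

        for c in dp.params.subrange_centers:
            fwd = dp.forward[c]
            bwd = back[c]
            # layer-0 key points (with both endpoints of later segments,
            # each trajectory vertex is credited exactly once when the
            # trajectory does not revisit vertices)
            for i, v in enumerate(dp.disks[0].members):
                counts[v] += fwd[0][i] * bwd[0][i]
            for k in range(dp.n_segments):
                mask = dp.masks[c][k]
                A, B = dp.disks[k], dp.disks[k + 1]
                for i in range(len(A)):
                    if fwd[k][i] == 0:
                        continue
                    js = np.where(mask[i] & (bwd[k + 1] > 0))[0]
                    for j in js:
                        w = fwd[k][i] * bwd[k + 1][j]
                        pa, pb = int(A.members[i]), int(B.members[j])
                        path = canonical_path(pa, pb)
                        for v in path[1:]:      # skip pa: credited at layer k
                            counts[v] += w
    else:
        raise ValueError(f"unknown heatmap mode {mode!r}")

    percent = np.array([100.0 * int(x) / total for x in counts])
    return Heatmap(counts=counts, percent=percent, total=total)


# ---------------------------------------------------------------------------
# Uniform trajectory sampling
# ---------------------------------------------------------------------------

@dataclass
class TrajectorySample:
    """One sampled trajectory: center vertex per layer plus per-segment
    geodesic distances, velocities and endpoint radii."""

    subrange: float
    centers: list[int]              # patch vertex ids, one per layer
    center_indices: list[int]       # indices into the disks' member arrays
    distances: np.ndarray
    velocities: np.ndarray
    radii: np.ndarray               # per-layer d(center, electrode)


def sample_trajectories(dp: SolutionDP, n: int, seed: int) -> list[TrajectorySample]:
    """Draw ``n`` trajectories uniformly (with replacement) from the full
    solution set, reproducibly under ``seed``.

    A subrange is chosen with probability proportional to its exact total,
    the first center proportional to its completion count, and each
    transition proportional to the successor's completion count — exact
    big-integer arithmetic throughout, so uniformity holds at any magnitude.
    """
    total = count_solutions(dp)
    if total == 0:
        raise SearchError("no trajectories to sample")
    rng = random.Random(seed)
    back = dp.backward()
    centers_list = list(dp.params.subrange_centers)

    samples = []
    for _ in range(n):
        r = rng.randrange(total)
        for c in centers_list:
            if r < dp.totals[c]:
                break
            r -= dp.totals[c]
        bwd = back[c]
        # first layer: uniform over completions
        idx = None
        for i in range(len(dp.disks[0])):
            w = int(bwd[0][i])
            if r < w:
                idx = i
                break
            r -= w
        chain = [idx]
        for k in range(dp.n_segments):
            mask = dp.masks[c][k]
            r = rng.randrange(int(bwd[k][chain[-1]]))
            js = np.where(mask[chain[-1]])[0]
            nxt = None
            for j in js:
                w = int(bwd[k + 1][j])
                if r < w:
                    nxt = int(j)
                    break
                r -= w
            chain.append(nxt)
        centers = [int(dp.disks[k].members[i]) for k, i in enumerate(chain)]
        dists = np.array(
            [dp.dist_tables[k][chain[k], chain[k + 1]]
             for k in range(dp.n_segments)]
        )
        vels = dists / dp.seq.toads
        radii = np.array(
            [dp.disks[k].radii[i] for k, i in enumerate(chain)]
        )
        samples.append(
            TrajectorySample(
                subrange=float(c),
                centers=centers,
                center_indices=[int(i) for i in chain],
                distances=dists,
                velocities=vels,
                radii=radii,
            )
        )
    return samples


def verify_admissibility(sample: TrajectorySample, dp: SolutionDP) -> bool:
    """Check a sample against every constraint of its DP: segment velocities
    inside the subrange ∩ [v_min, v_max], radii ≤ r_max, |Δradius| ≤ r_diff."""
    p = dp.params
    v_lo, v_hi = p.subrange(sample.subrange)
    if not ((sample.velocities >= v_lo) & (sample.velocities <= v_hi)).all():
        return False
    if (sample.radii > p.r_max + 1e-12).any():
        return False
    if (np.abs(np.diff(sample.radii)) > p.r_diff + 1e-12).any():
        return False
    return True
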