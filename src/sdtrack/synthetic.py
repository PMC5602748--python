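"""Synthetic ground-truth generators.

Everything the reconstruction pipeline consumes can be generated here:
cortical-patch-like meshes (flat, folded "gyral", icosphere), a collinear
six-electrode strip with 10 mm spacing, forward-simulated SD waves of known
constant velocity and front radius producing electrode hit times, and
CT-like volumes with metal-bright spheres at the electrode positions. The
generators write the same formats the pipeline reads, so the whole method is
testable without patient data.

The forward wave model mirrors the reconstruction's assumptions exactly: a
circular-arc front whose curvature center travels along a surface geodesic
path at constant velocity; an electrode's onset is the first time the front
(geodesic distance from center ≤ radius) covers it. Onsets are exact by
default; optional Gaussian jitter probes robustness to subjective onset
marking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .electrodes import ElectrodeSet, Volume3D
from .errors import InsufficientRoomError
from .events import SDEvent
from .mesh import TriMesh, geodesic_distances, geodesic_from, shortest_path

__all__ = [
    "WaveSpec",
    "SimulatedWave",
    "SyntheticDataset",
    "make_mesh",
    "place_strip",
    "geodesic_path_through",
    "strip_wave_path",
    "simulate_wave",
    "make_ct_volume",
    "make_dataset",
]


# ---------------------------------------------------------------------------
# Meshes
# ---------------------------------------------------------------------------

def make_mesh(kind: str = "plane", **params) -> TriMesh:
    """Generate a test surface.

    ``plane(width, height, spacing, diagonal)``: triangulated grid in the
    z=0 plane; ``diagonal="fixed"`` uses one diagonal direction,
    ``"alternating"`` flips it per cell parity (mirror-symmetric
    triangulation). ``gyral(...)`` additionally displaces
    z = amplitude·sin(2π·x/wavelength) — the simplest folded surface on which
    geodesic and Euclidean distances diverge. ``icosphere(subdivision,
    radius)``: closed sphere with V = 10·4^n + 2.
    """
    if kind == "plane":
        return _grid_mesh(amplitude=0.0, wavelength=1.0, **params)
    if kind == "gyral":
        return _grid_mesh(**params)
    if kind == "icosphere":
        import trimesh

        sub = params.get("subdivision", 4)
        radius = params.get("radius", 50.0)
        ico = trimesh.creation.icosphere(subdivisions=sub, radius=radius)
        return TriMesh(np.asarray(ico.vertices), np.asarray(ico.faces))
    raise ValueError(f"unknown mesh kind {kind!r}")


def _grid_mesh(
    width: float = 100.0,
    height: float = 60.0,
    spacing: float = 1.0,
    amplitude: float = 0.0,
    wavelength: float = 20.0,
    diagonal: str = "fixed",
) -> TriMesh:
    if width <= 0 or height <= 0 or spacing <= 0 or wavelength <= 0:
        raise ValueError("dimensions must be positive")
    nx = int(round(width / spacing))
    ny = int(round(height / spacing))
    xs = np.arange(nx + 1) * spacing
    ys = np.arange(ny + 1) * spacing
    X, Y = np.meshgrid(xs, ys)              # shape (ny+1, nx+1)
    Z = amplitude * np.sin(2 * np.pi * X / wavelength)
    verts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def vid(ix, iy):
        return iy * (nx + 1) + ix

    faces = []
    for iy in range(ny):
        for ix in range(nx):
            a = vid(ix, iy)
            b = vid(ix + 1, iy)
            c = vid(ix + 1, iy + 1)
            d = vid(ix, iy + 1)
            flip = diagonal == "alternating" and (ix + iy) % 2 == 1
            if flip:
                faces.append((a, b, d))
                faces.append((b, c, d))
            else:
                faces.append((a, b, c))
                faces.append((a, c, d))
    return TriMesh(verts, np.array(faces, dtype=np.int64))


# ---------------------------------------------------------------------------
# Electrode strip placement
# ---------------------------------------------------------------------------

def _strip_frame(mesh: TriMesh, origin: int, direction) -> tuple[np.ndarray, np.ndarray]:
    d = np.asarray(direction, dtype=np.float64)[:2]
    n = np.linalg.norm(d)
    if n == 0:
        raise ValueError("direction must be non-zero")
    d = d / n
    rel = mesh.vertices[:, :2] - mesh.vertices[origin, :2]
    forward = rel @ d
    lateral = np.abs(rel @ np.array([-d[1], d[0]]))
    return forward, lateral


def _march(mesh, origin, forward, lateral, target_forward, arc_target, lateral_tol):
    """Pick the vertex nearest ``arc_target`` geodesic mm from ``origin``
    among vertices on the strip axis past ``target_forward``."""
    dg = geodesic_distances(mesh, origin)[0]
    cand = (lateral <= lateral_tol) & (np.sign(arc_target) * forward > target_forward)
    if not cand.any():
        return None, np.inf
    idx = np.where(cand)[0]
    dev = np.abs(dg[idx] - abs(arc_target))
    best = idx[np.argmin(dev)]
    return int(best), float(dev.min())


def place_strip(
    mesh: TriMesh,
    origin: int,
    direction=(1.0, 0.0),
    n: int = 6,
    spacing: float = 10.0,
    lateral_tol: float | None = None,
) -> ElectrodeSet:
    """Place n electrodes at successive geodesic arc length ≈ ``spacing``
    along the surface from ``origin`` in ``direction`` (in-plane).

    Consecutive geodesic spacings are required within 5 % of nominal;
    otherwise the strip has run off the mesh ("insufficient room").
    """
    if lateral_tol is None:
        lateral_tol = 0.05 * spacing
    forward, lateral = _strip_frame(mesh, origin, direction)
    vids = [origin]
    for _ in range(n - 1):
        cur = vids[-1]
        best, dev = _march(
            mesh, cur, forward, lateral,
            target_forward=forward[cur] + 1e-9,
            arc_target=spacing, lateral_tol=lateral_tol,
        )
        if best is None or dev > 0.05 * spacing:
            raise InsufficientRoomError(
                f"insufficient room: cannot place electrode {len(vids) + 1} "
                f"at {spacing} mm (best deviation {dev:.2f} mm)"
            )
        vids.append(best)
    vids = np.array(vids, dtype=np.int64)
    return ElectrodeSet(
        labels=[f"E{i + 1}" for i in range(n)],
        centroids=mesh.vertices[vids],
        vertex_ids=vids,
        snap_distances=np.zeros(n),
        spacing=spacing,
    )


def geodesic_path_through(mesh: TriMesh, waypoints) -> list[int]:
    """Concatenate canonical geodesic paths through successive waypoints."""
    path = [int(waypoints[0])]
    for a, b in zip(waypoints[:-1], waypoints[1:]):
        gmap = geodesic_from(mesh, int(a))
        seg = shortest_path(gmap, int(b))
        path.extend(seg[1:])
    return path


def strip_wave_path(
    mesh: TriMesh,
    electrodes: ElectrodeSet,
    direction=(1.0, 0.0),
    margin: float = 8.0,
    lateral_offset: float = 0.0,
) -> list[int]:
    """Center path along (or parallel to) the strip axis, extended ``margin``
    mm beyond both ends so fronts of radius < margin fully cross every
    electrode. ``lateral_offset`` shifts the path sideways (for fixtures
    whose wave misses the strip)."""
    d = np.asarray(direction, dtype=np.float64)[:2]
    d = d / np.linalg.norm(d)
    perp = np.array([-d[1], d[0]])
    first_xy = electrodes.centroids[0, :2] + lateral_offset * perp
    # anchor: vertex closest to the (possibly offset) first electrode
    rel = mesh.vertices[:, :2] - first_xy
    anchor = int(np.argmin(np.einsum("ij,ij->i", rel, rel)))

    forward, lateral = _strip_frame(mesh, anchor, d)
    strip_len = (len(electrodes.labels) - 1) * electrodes.spacing

    start, dev0 = _march(mesh, anchor, forward, lateral,
                         target_forward=0.0, arc_target=-margin,
                         lateral_tol=0.05 * electrodes.spacing)
    end, dev1 = _march(mesh, anchor, forward, lateral,
                       target_forward=0.0, arc_target=strip_len + margin,
                       lateral_tol=0.05 * electrodes.spacing)
    if start is None or end is None:
        raise InsufficientRoomError("insufficient room for the wave path")
    waypoints = [start]
    if lateral_offset == 0.0:
        waypoints += [int(v) for v in electrodes.vertex_ids]
    waypoints.append(end)
    return geodesic_path_through(mesh, waypoints)


# ---------------------------------------------------------------------------
# Forward wave simulation
# ---------------------------------------------------------------------------

@dataclass
class WaveSpec:
    """Forward wave: ``moving_center`` (center path + front radius) or
    ``concentric`` (point source). Velocity in mm/min, radius in mm."""

    mode: str
    velocity: float
    radius: float = 0.0
    path: list[int] | None = None
    source: int | None = None
    start_time: float = 0.0

    def __post_init__(self):
        if self.mode not in ("moving_center", "concentric"):
            raise ValueError(f"unknown wave mode {self.mode!r}")
        if self.velocity <= 0:
            raise ValueError("velocity must be positive")
        if self.radius < 0:
            raise ValueError("radius must be non-negative")
        if self.mode == "moving_center" and not self.path:
            raise ValueError("moving_center needs a path")
        if self.mode == "concentric" and self.source is None:
            raise ValueError("concentric needs a source vertex")


@dataclass
class SimulatedWave:
    """Forward-simulation result: the SD event plus full ground truth.
    ``event`` is None when the wave missed every electrode."""

    event: SDEvent | None
    spec: WaveSpec
    onsets: dict[str, float]
    absent: list[str]


def simulate_wave(
    mesh: TriMesh,
    spec: WaveSpec,
    electrodes: ElectrodeSet,
    event_id: str = "sd1",
    day: int = 0,
    onset_jitter_sigma: float = 0.0,
    seed: int = 0,
) -> SimulatedWave:
    """Compute per-electrode SD onset times for a specified wave.

    moving_center: the curvature center advances along ``spec.path`` at
    constant speed; an electrode's onset is the first time its geodesic
    distance to the center drops to the front radius (linear interpolation
    between path vertices). concentric: onset = d(source, e)/velocity +
    start. Electrodes never covered are recorded absent.
    """
    ev_vertices = electrodes.vertex_ids
    onsets: dict[str, float] = {}
    absent: list[str] = []

    if spec.mode == "concentric":
        d = geodesic_distances(mesh, spec.source)[0][ev_vertices]
        for lab, dist in zip(electrodes.labels, d):
            if np.isfinite(dist):
                onsets[lab] = spec.start_time + dist / spec.velocity
            else:
                absent.append(lab)
    else:
        path = np.asarray(spec.path, dtype=np.int64)
        P = mesh.vertices
        s = np.concatenate(
            [[0.0], np.cumsum(np.linalg.norm(np.diff(P[path], axis=0), axis=1))]
        )
        times = spec.start_time + s / spec.velocity
        dmat = geodesic_distances(mesh, ev_vertices)     # (nE, N)
        for lab, row in zip(electrodes.labels, dmat):
            d = row[path]
            covered = d <= spec.radius + 1e-12
            if not covered.any():
                absent.append(lab)
                continue
            j = int(np.argmax(covered))
            if j == 0:
                onsets[lab] = float(times[0])
            else:
                d0, d1 = d[j - 1], d[j]
                frac = (d0 - spec.radius) / (d0 - d1) if d0 != d1 else 1.0
                onsets[lab] = float(times[j - 1] + frac * (times[j] - times[j - 1]))

    if onset_jitter_sigma > 0:
        rng = np.random.default_rng(seed)
        for lab in list(onsets):
            onsets[lab] = max(0.0, onsets[lab] + rng.normal(0, onset_jitter_sigma))

    event = (
        SDEvent(event_id=event_id, onsets=dict(onsets), day=day)
        if onsets
        else None
    )
    return SimulatedWave(event=event, spec=spec, onsets=onsets, absent=absent)


# ---------------------------------------------------------------------------
# CT-like volume
# ---------------------------------------------------------------------------

def make_ct_volume(
    electrodes: ElectrodeSet,
    voxel: float = 0.5,
    sphere_radius: float = 2.0,
    metal_hu: float = 3500.0,
    background: tuple[float, float] = (20.0, 120.0),
    margin: float = 10.0,
    seed: int = 0,
) -> Volume3D:
    """CT-like volume: tissue-range background noise with metal-bright
    spheres centered on the electrode centroids. Deterministic under
    ``seed``. Warns when spheres would overlap (spacing < 2·radius)."""
    if voxel <= 0:
        raise ValueError("voxel size must be positive")
    c = electrodes.centroids
    if len(c) > 1:
        from scipy.spatial.distance import pdist

        if pdist(c).min() < 2 * sphere_radius:
            warnings.warn("electrode spheres overlap; components will merge")
    lo = c.min(axis=0) - margin
    hi = c.max(axis=0) + margin
    shape = np.ceil((hi - lo) / voxel).astype(int) + 1
    rng = np.random.default_rng(seed)
    data = rng.integers(int(background[0]), int(background[1]) + 1,
                        size=shape).astype(np.float32)
    affine = np.eye(4)
    affine[:3, :3] *= voxel
    affine[:3, 3] = lo

    grids = [np.arange(shape[i]) * voxel + lo[i] for i in range(3)]
    for center in c:
        sl = []
        for i in range(3):
            j0 = max(0, int(np.floor((center[i] - sphere_radius - lo[i]) / voxel)))
            j1 = min(shape[i] - 1,
                     int(np.ceil((center[i] + sphere_radius - lo[i]) / voxel)))
            sl.append((j0, j1))
        gx = grids[0][sl[0][0]: sl[0][1] + 1]
        gy = grids[1][sl[1][0]: sl[1][1] + 1]
        gz = grids[2][sl[2][0]: sl[2][1] + 1]
        DX, DY, DZ = np.meshgrid(gx - center[0], gy - center[1], gz - center[2],
                                 indexing="ij")
        inside = DX**2 + DY**2 + DZ**2 <= sphere_radius**2
        block = data[sl[0][0]: sl[0][1] + 1,
                     sl[1][0]: sl[1][1] + 1,
                     sl[2][0]: sl[2][1] + 1]
        block[inside] = metal_hu
    return Volume3D(data=data, affine=affine)


# ---------------------------------------------------------------------------
# Bundled datasets
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    """A full synthetic study: mesh, strip, simulated events and their ground
    truth, reproducible from ``seed`` and the stored parameters."""

    mesh: TriMesh
    electrodes: ElectrodeSet
    events: list[SDEvent]
    waves: list[SimulatedWave]
    params: dict = field(default_factory=dict)
    seed: int = 0


def make_dataset(
    kind: str = "plane",
    velocities=(2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0),
    radius: float = 2.0,
    n_electrodes: int = 6,
    spacing: float = 10.0,
    mesh_spacing: float | None = None,
    fold_amplitude: float = 4.0,
    fold_wavelength: float = 25.0,
    onset_jitter_sigma: float = 0.0,
    branching: int = 0,
    branching_velocities=(3.0, 4.0, 5.0),
    seed: int = 0,
) -> SyntheticDataset:
    """Plane or gyral patch with a centered strip and one moving-center wave
    per requested velocity. The mesh is sized so a 30 mm patch radius fits
    around every electrode.

    ``branching > 0`` appends that many concentric waves whose source lies a
    few millimetres off an interior electrode, so the wave first arrives in
    the middle of the strip and runs outward in both directions — the
    branching hit-sequence pattern that the branch-reduction step removes.

    Default mesh resolution: 1.25 mm on the plane (the 10 mm inter-electrode
    spacing is then an exact multiple of the grid) and 1.0 mm on the gyral
    surface (fold arc-length stretching needs the finer grid to place the
    strip within 5 % of nominal spacing).
    """
    if mesh_spacing is None:
        mesh_spacing = 1.0 if kind == "gyral" else 1.25
    strip_len = (n_electrodes - 1) * spacing
    pad = 35.0
    width = strip_len + 2 * pad
    height = 2 * pad
    kw = dict(width=width, height=height, spacing=mesh_spacing)
    if kind == "gyral":
        kw.update(amplitude=fold_amplitude, wavelength=fold_wavelength)
    mesh = make_mesh("gyral" if kind == "gyral" else "plane", **kw)

    # origin: vertex nearest (pad, height/2)
    target = np.array([pad, height / 2])
    rel = mesh.vertices[:, :2] - target
    origin = int(np.argmin(np.einsum("ij,ij->i", rel, rel)))
    electrodes = place_strip(mesh, origin, (1.0, 0.0),
                             n=n_electrodes, spacing=spacing)
    path = strip_wave_path(mesh, electrodes, margin=max(8.0, radius + 3.0))

    events, waves = [], []
    for i, v in enumerate(velocities):
        spec = WaveSpec(mode="moving_center", velocity=float(v),
                        radius=radius, path=path)
        wave = simulate_wave(
            mesh, spec, electrodes, event_id=f"sd{i + 1}", day=i // 4,
            onset_jitter_sigma=onset_jitter_sigma, seed=seed + i,
        )
        events.append(wave.event)
        waves.append(wave)
    for i in range(branching):
        e_idx = 2 + (i % 2)                       # E3 or E4
        # offset chosen never to land midway between contacts (tied onsets)
        pos = electrodes.centroids[e_idx, :2] + np.array([2.0 + i, 0.0])
        rel = mesh.vertices[:, :2] - pos
        source = int(np.argmin(np.einsum("ij,ij->i", rel, rel)))
        v = float(branching_velocities[i % len(branching_velocities)])
        spec = WaveSpec(mode="concentric", velocity=v, source=source)
        wave = simulate_wave(
            mesh, spec, electrodes, event_id=f"sdb{i + 1}",
            day=(len(velocities) + i) // 4,
            onset_jitter_sigma=onset_jitter_sigma,
            seed=seed + 1000 + i,
        )
        events.append(wave.event)
        waves.append(wave)
    return SyntheticDataset(
        mesh=mesh,
        electrodes=electrodes,
        events=events,
        waves=waves,
        params=dict(kind=kind, velocities=tuple(velocities), radius=radius,
                    n_electrodes=n_electrodes, spacing=spacing,
                    mesh_spacing=mesh_spacing,
                    onset_jitter_sigma=onset_jitter_sigma),
        seed=seed,
    )
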