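import numpy as np
import pytest

from sdtrack import synthetic
from sdtrack.events import build_hit_sequence
from sdtrack.mesh import TriMesh, extract_patch
from sdtrack.pipeline import prepare_patch


@pytest.fixture
def tetrahedron():
    verts = np.array(
        [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
    )
    faces = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return TriMesh(verts, faces)


@pytest.fixture(scope="session")
def plane_grid():
    """20 x 20 mm plane, 1 mm spacing."""
    return synthetic.make_mesh("plane", width=20, height=20, spacing=1.0)


@pytest.fixture(scope="session")
def plane_dataset():
    """Plane patch, 6-electrode strip, one moving-center wave at 5 mm/min."""
    return synthetic.make_dataset(kind="plane", velocities=(5.0,), seed=7)


@pytest.fixture(scope="session")
def plane_patch(plane_dataset):
    ds = plane_dataset
    return prepare_patch(ds.mesh, ds.electrodes.as_dict())


@pytest.fixture(scope="session")
def plane_seq(plane_dataset):
    return build_hit_sequence(plane_dataset.events[0])


def make_tiny_instance(seed=0, n_electrodes=3, spacing=10.0, grid=2.0,
                       toad=2.0, width=36.0, height=14.0):
    """A searchable instance on a patch small enough to enumerate: coarse
    plane grid, electrodes along the middle row, synthetic hit times."""
    rng = np.random.default_rng(seed)
    mesh = synthetic.make_mesh("plane", width=width, height=height, spacing=grid)
    ny = int(round(height / grid))
    nx = int(round(width / grid))
    row = ny // 2
    x0 = int(round((width - (n_electrodes - 1) * spacing) / 2 / grid))
    step = int(round(spacing / grid))
    vids = [row * (nx + 1) + x0 + k * step for k in range(n_electrodes)]
    electrodes = {f"E{k + 1}": v for k, v in enumerate(vids)}
    toads = toad * (1 + 0.2 * rng.uniform(-1, 1, size=n_electrodes - 1))
    times = np.concatenate([[0.0], np.cumsum(toads)])
    from sdtrack.events import HitSequence

    seq = HitSequence(
        event_id=f"tiny{seed}",
        electrodes=list(electrodes),
        times=times,
    )
    patch = extract_patch(mesh, electrodes, radius=5.0)
    return patch, seq


@pytest.fixture(scope="session")
def tiny_instance():
    return make_tiny_instance(seed=1)


def oracle_counts(patch, seq, params):
    """Independent exhaustive enumeration oracle: recurse over all candidate
    center tuples, checking every admissibility constraint per tuple.
    Distances come from the hand-rolled single-source Dijkstra, not from the
    DP's bulk distance tables."""
    from sdtrack.mesh import geodesic_from

    gmaps = {}

    def gmap(v):
        if v not in gmaps:
            gmaps[v] = geodesic_from(patch.mesh, v)
        return gmaps[v]

    disks = []
    for lab in seq.electrodes:
        ev = patch.electrodes[lab]
        g = gmap(ev)
        members = np.where(g.dist <= params.r_max)[0]
        disks.append([(int(m), float(g.dist[m])) for m in members])
    toads = seq.toads

    counts = {}
    for c in params.subrange_centers:
        lo, hi = params.subrange(c)

        def count_from(k, v_prev, r_prev):
            if k == len(disks):
                return 1
            total = 0
            for v, r in disks[k]:
                if abs(r - r_prev) > params.r_diff:
                    continue
                d = gmap(v_prev).dist[v] if v_prev != v else 0.0
                vel = d / toads[k - 1]
                if lo <= vel <= hi:
                    total += count_from(k + 1, v, r)
            return total

        counts[c] = sum(count_from(1, v, r) for v, r in disks[0])
    return counts
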