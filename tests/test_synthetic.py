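import numpy as np
import pytest

from sdtrack import synthetic
from sdtrack.errors import InsufficientRoomError
from sdtrack.mesh import geodesic_distances


class TestMakeMesh:
    def test_plane_vertex_count(self):
        mesh = synthetic.make_mesh("plane", width=100, height=60, spacing=1.0)
        assert mesh.n_vertices == 101 * 61 == 6161
        mesh.validate()

    @pytest.mark.parametrize("sub", [1, 2, 3])
    def test_icosphere_closed_form(self, sub):
        mesh = synthetic.make_mesh("icosphere", subdivision=sub, radius=50.0)
        assert mesh.n_vertices == 10 * 4**sub + 2

    def test_gyral_zero_amplitude_is_plane(self):
        plane = synthetic.make_mesh("plane", width=30, height=20, spacing=1.0)
        gyral = synthetic.make_mesh("gyral", width=30, height=20, spacing=1.0,
                                    amplitude=0.0, wavelength=20.0)
        assert np.abs(plane.vertices - gyral.vertices).max() < 1e-12
        assert (plane.faces == gyral.faces).all()

    def test_degenerate_dimensions(self):
        with pytest.raises(ValueError):
            synthetic.make_mesh("plane", width=0.0, height=10, spacing=1.0)


class TestPlaceStrip:
    def test_plane_spacing(self):
        mesh = synthetic.make_mesh("plane", width=80, height=30, spacing=1.0)
        origin = 15 * 81 + 10
        eset = synthetic.place_strip(mesh, origin, n=6, spacing=10)
        d = geodesic_distances(mesh, eset.vertex_ids)
        spacings = [d[i, eset.vertex_ids[i + 1]] for i in range(5)]
        assert all(abs(s - 10.0) <= 0.5 for s in spacings)

    def test_gyral_euclidean_below_geodesic(self):
        mesh = synthetic.make_mesh("gyral", width=120, height=70, spacing=1.0,
                                   amplitude=4.0, wavelength=25.0)
        target = np.array([35.0, 35.0])
        rel = mesh.vertices[:, :2] - target
        origin = int(np.argmin((rel**2).sum(1)))
        eset = synthetic.place_strip(mesh, origin, n=6, spacing=10)
        d = geodesic_distances(mesh, eset.vertex_ids)
        for i in range(5):
            geo = d[i, eset.vertex_ids[i + 1]]
            euc = np.linalg.norm(eset.centroids[i + 1] - eset.centroids[i])
            assert euc < geo

    def test_insufficient_room(self):
        mesh = synthetic.make_mesh("plane", width=30, height=20, spacing=1.0)
        origin = 10 * 31 + 25  # 5 mm from the +x boundary
        with pytest.raises(InsufficientRoomError, match="insufficient room"):
            synthetic.place_strip(mesh, origin, n=6, spacing=10)


@pytest.fixture(scope="module")
def setup():
    mesh = synthetic.make_mesh("plane", width=100, height=40, spacing=1.0)
    origin = 20 * 101 + 25
    eset = synthetic.place_strip(mesh, origin, n=6, spacing=10)
    return mesh, eset


class TestSimulateWave:

    def test_moving_center_toads(self, setup):
        mesh, eset = setup
        path = synthetic.strip_wave_path(mesh, eset, margin=8.0)
        spec = synthetic.WaveSpec(mode="moving_center", velocity=5.0,
                                  radius=2.0, path=path)
        wave = synthetic.simulate_wave(mesh, spec, eset)
        assert not wave.absent
        times = [wave.onsets[f"E{k}"] for k in range(1, 7)]
        toads = np.diff(times)
        assert np.allclose(toads, 2.0, atol=1e-9)

    def test_concentric_distance_over_velocity(self, setup):
        mesh, eset = setup
        spec = synthetic.WaveSpec(mode="concentric", velocity=4.0,
                                  source=int(eset.vertex_ids[0]))
        wave = synthetic.simulate_wave(mesh, spec, eset)
        for k in range(6):
            assert wave.onsets[f"E{k + 1}"] == pytest.approx(10.0 * k / 4.0)

    def test_offset_path_misses_strip(self, setup):
        mesh, eset = setup
        path = synthetic.strip_wave_path(mesh, eset, margin=8.0,
                                         lateral_offset=10.0)
        spec = synthetic.WaveSpec(mode="moving_center", velocity=5.0,
                                  radius=2.0, path=path)
        wave = synthetic.simulate_wave(mesh, spec, eset)
        assert len(wave.absent) == 6  # front never comes within 2 mm

    def test_concentric_matches_moving_center_on_axis(self, setup):
        # same TOAD pattern when the source lies on the strip axis ahead
        # of the electrodes
        mesh, eset = setup
        path = synthetic.strip_wave_path(mesh, eset, margin=8.0)
        conc = synthetic.simulate_wave(
            mesh,
            synthetic.WaveSpec(mode="concentric", velocity=5.0,
                               source=int(path[0])),
            eset,
        )
        mov = synthetic.simulate_wave(
            mesh,
            synthetic.WaveSpec(mode="moving_center", velocity=5.0,
                               radius=0.0, path=path),
            eset,
        )
        t_c = np.diff([conc.onsets[f"E{k}"] for k in range(1, 7)])
        t_m = np.diff([mov.onsets[f"E{k}"] for k in range(1, 7)])
        assert np.allclose(t_c, t_m, atol=1e-6)

    def test_onset_jitter_reproducible(self, setup):
        mesh, eset = setup
        spec = synthetic.WaveSpec(mode="concentric", velocity=4.0,
                                  source=int(eset.vertex_ids[0]))
        a = synthetic.simulate_wave(mesh, spec, eset,
                                    onset_jitter_sigma=0.1, seed=5)
        b = synthetic.simulate_wave(mesh, spec, eset,
                                    onset_jitter_sigma=0.1, seed=5)
        assert a.onsets == b.onsets


class TestCTVolume:
    def test_seed_bit_identical(self):
        from sdtrack.electrodes import ElectrodeSet

        eset = ElectrodeSet(
            labels=["E1", "E2"],
            centroids=np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0]]),
            vertex_ids=np.array([0, 1]),
        )
        a = synthetic.make_ct_volume(eset, voxel=1.0, seed=9)
        b = synthetic.make_ct_volume(eset, voxel=1.0, seed=9)
        assert (a.data == b.data).all()

    def test_sub_threshold_metal_invisible(self):
        from sdtrack.electrodes import ElectrodeSet, segment_metal

        eset = ElectrodeSet(
            labels=["E1"],
            centroids=np.array([[0.0, 0.0, 0.0]]),
            vertex_ids=np.array([0]),
        )
        vol = synthetic.make_ct_volume(eset, voxel=1.0, metal_hu=100.0, seed=0)
        with pytest.warns(UserWarning):
            assert segment_metal(vol, threshold=3000) == []


class TestDatasetRegeneration:
    def test_same_seed_same_events(self):
        a = synthetic.make_dataset(kind="plane", velocities=(3.0, 6.0), seed=2)
        b = synthetic.make_dataset(kind="plane", velocities=(3.0, 6.0), seed=2)
        for ea, eb in zip(a.events, b.events):
            assert ea.onsets == eb.onsets
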