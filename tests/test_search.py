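import numpy as np
import pytest
from scipy.stats import chisquare

from sdtrack import synthetic
from sdtrack.errors import SearchError
from sdtrack.events import HitSequence
from sdtrack.mesh import extract_patch, geodesic_from
from sdtrack.search import (
    SearchParams,
    bipartite_distances,
    candidate_disk,
    count_solutions,
    enumerate_trajectories,
    grow_solutions,
    heatmap,
    sample_trajectories,
    verify_admissibility,
)

from conftest import make_tiny_instance, oracle_counts


class TestCandidateDisk:
    def test_plane_disk_contents(self, tiny_instance):
        patch, seq = tiny_instance
        disk = candidate_disk(patch, "E1", r_max=5.0)
        assert disk.radii[0] == 0.0
        assert disk.members[0] == patch.electrodes["E1"]
        # brute force: full geodesic map scan
        g = geodesic_from(patch.mesh, patch.electrodes["E1"])
        expected = set(np.where(g.dist <= 5.0)[0].tolist())
        assert set(disk.members.tolist()) == expected

    def test_tiny_radius_single_vertex(self, tiny_instance):
        patch, seq = tiny_instance
        disk = candidate_disk(patch, "E2", r_max=0.5)  # < 2 mm grid edge
        assert len(disk) == 1

    def test_unknown_electrode(self, tiny_instance):
        patch, _ = tiny_instance
        with pytest.raises(SearchError):
            candidate_disk(patch, "E99")


class TestBipartiteDistances:
    def test_matches_single_source_dijkstra(self, tiny_instance):
        patch, seq = tiny_instance
        dA = candidate_disk(patch, "E1", 3.0)
        dB = candidate_disk(patch, "E2", 3.0)
        table = bipartite_distances(patch, dA, dB)
        for i, a in enumerate(dA.members):
            g = geodesic_from(patch.mesh, int(a))
            assert np.allclose(table[i], g.dist[dB.members])

    def test_single_vertex_disks(self, tiny_instance):
        patch, _ = tiny_instance
        d = candidate_disk(patch, "E1", 0.5)
        table = bipartite_distances(patch, d, d)
        assert table.shape == (1, 1) and table[0, 0] == 0.0


class TestGrowSolutions:
    def test_true_velocity_subranges_populated(self, tiny_instance):
        patch, seq = make_tiny_instance(seed=0, toad=2.0)
        # exact TOADs: electrodes 10 mm apart, hit every 2 min -> v = 5
        seq = HitSequence("ev", seq.electrodes, np.array([0.0, 2.0, 4.0]))
        dp = grow_solutions(patch, seq, SearchParams(r_max=3.0))
        assert dp.success
        for c in (4.0, 5.0, 6.0):  # closed subranges containing v = 5
            assert dp.totals[c] > 0

    def test_velocity_cap_kills_search(self):
        patch, seq = make_tiny_instance(seed=0)
        fast = HitSequence("ev", seq.electrodes, np.array([0.0, 0.5, 1.0]))
        dp = grow_solutions(patch, fast, SearchParams(r_max=3.0))
        assert not dp.success and count_solutions(dp) == 0

    def test_insufficient_hits(self, tiny_instance):
        patch, seq = tiny_instance
        short = HitSequence("ev", seq.electrodes[:2], seq.times[:2])
        with pytest.raises(SearchError, match="at least 3"):
            grow_solutions(patch, short, SearchParams())

    @pytest.mark.parametrize("seed", range(6))
    def test_dp_equals_oracle(self, seed):
        patch, seq = make_tiny_instance(seed=seed)
        params = SearchParams(r_diff=1.0, v_diff=1.0, r_max=3.0, patch_radius=5.0)
        dp = grow_solutions(patch, seq, params)
        assert dp.totals == oracle_counts(patch, seq, params)

    def test_monotone_in_tolerances(self):
        patch, seq = make_tiny_instance(seed=3)
        combos = [(0.5, 0.25), (0.5, 0.5), (0.5, 1.0),
                  (1.0, 0.25), (1.0, 0.5), (1.0, 1.0)]
        counts = {}
        for r, v in combos:
            dp = grow_solutions(
                patch, seq,
                SearchParams(r_diff=r, v_diff=v, r_max=3.0, patch_radius=5.0),
            )
            counts[(r, v)] = count_solutions(dp)
        for (r1, v1), c1 in counts.items():
            for (r2, v2), c2 in counts.items():
                if r1 <= r2 and v1 <= v2:
                    assert c1 <= c2


@pytest.fixture(scope="module")
def single_chain_instance():
    """r_max below the grid edge length makes every disk a single vertex, so
    exactly one geometric trajectory exists (repeated in each subrange whose
    interval admits v = 5)."""
    patch, seq = make_tiny_instance(seed=0)
    seq = HitSequence("ev", seq.electrodes, np.array([0.0, 2.0, 4.0]))
    params = SearchParams(r_max=0.5, patch_radius=5.0)
    return patch, seq, params, grow_solutions(patch, seq, params)


class TestHeatmap:
    def test_single_solution_path_at_100(self, single_chain_instance):
        patch, seq, params, dp = single_chain_instance
        hm = heatmap(dp, patch, mode="paths")
        evs = [patch.electrodes[lab] for lab in seq.electrodes]
        g = geodesic_from(patch.mesh, evs[0])
        assert (hm.percent <= 100.0 + 1e-9).all()
        for v in evs:
            assert hm.percent[v] == pytest.approx(100.0)
        on = np.where(hm.percent > 0)[0]
        # vertices with 100%: exactly the canonical chain through the strip
        assert (hm.percent[on] == 100.0).all()

    def test_mirror_symmetry_keypoints(self):
        # symmetric triangulation + symmetric TOADs -> exactly symmetric counts
        mesh = synthetic.make_mesh("plane", width=36, height=16, spacing=2.0,
                                   diagonal="alternating")
        nx, ny = 18, 8
        row = 4
        vids = {f"E{k+1}": row * (nx + 1) + 4 + 5 * k for k in range(3)}
        patch = extract_patch(mesh, vids, radius=5.0)
        seq = HitSequence("ev", list(vids), np.array([0.0, 2.0, 4.0]))
        params = SearchParams(r_max=3.0, patch_radius=5.0)
        dp = grow_solutions(patch, seq, params)
        hm = heatmap(dp, patch, mode="keypoints")

        # mirror about the strip row in the parent grid
        parent = patch.parent_vertices
        inv = {int(p): i for i, p in enumerate(parent)}
        for i, p in enumerate(parent):
            iy, ix = divmod(int(p), nx + 1)
            mirrored = (2 * row - iy) * (nx + 1) + ix
            j = inv.get(mirrored)
            assert j is not None
            assert hm.counts[i] == hm.counts[j]

    def test_zero_solutions_error(self):
        patch, seq = make_tiny_instance(seed=0)
        fast = HitSequence("ev", seq.electrodes, np.array([0.0, 0.5, 1.0]))
        dp = grow_solutions(patch, fast, SearchParams(r_max=3.0))
        with pytest.raises(SearchError, match="no trajectories"):
            heatmap(dp, patch)


class TestSampling:
    def test_single_solution_everywhere(self, single_chain_instance):
        patch, seq, params, dp = single_chain_instance
        samples = sample_trajectories(dp, 100, seed=5)
        assert len(samples) == 100
        assert len({tuple(s.centers) for s in samples}) == 1

    def test_seed_determinism(self, tiny_instance):
        patch, seq = tiny_instance
        dp = grow_solutions(patch, seq,
                            SearchParams(r_max=3.0, patch_radius=5.0))
        a = sample_trajectories(dp, 50, seed=11)
        b = sample_trajectories(dp, 50, seed=11)
        assert [(s.subrange, s.centers) for s in a] == [
            (s.subrange, s.centers) for s in b
        ]

    def test_uniform_over_enumerable_set(self):
        patch, seq = make_tiny_instance(seed=2)
        params = SearchParams(r_max=2.0, patch_radius=5.0)
        dp = grow_solutions(patch, seq, params)
        solutions = list(enumerate_trajectories(dp))
        assert 2 <= len(solutions) <= 400
        n = 6000
        samples = sample_trajectories(dp, n, seed=123)
        keys = [(s.subrange, tuple(s.centers)) for s in samples]
        counts = {sol: 0 for sol in solutions}
        for k in keys:
            counts[k] += 1
        stat, p = chisquare(list(counts.values()))
        assert p > 0.01

    def test_samples_verify_admissibility(self, tiny_instance):
        patch, seq = tiny_instance
        dp = grow_solutions(patch, seq,
                            SearchParams(r_max=3.0, patch_radius=5.0))
        for s in sample_trajectories(dp, 200, seed=3):
            assert verify_admissibility(s, dp)

    def test_zero_solutions_error(self):
        patch, seq = make_tiny_instance(seed=0)
        fast = HitSequence("ev", seq.electrodes, np.array([0.0, 0.5, 1.0]))
        dp = grow_solutions(patch, fast, SearchParams(r_max=3.0))
        with pytest.raises(SearchError):
            sample_trajectories(dp, 10, seed=0)
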