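import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ssbdsb import synth, tunnels
from ssbdsb.structure_io import AtomRecord, ProteinChain


def _chain(coords, radius):
    return synth.chain_from_atoms(np.asarray(coords, float), radius)


class TestClearanceGraph:
    def test_regular_tetrahedron_gives_centroid_vertex(self):
        # circumradius of a regular tetrahedron with edge a is a*sqrt(6)/4
        a = 6.0
        verts = np.array([
            [1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], float)
        verts *= a / (2 * math.sqrt(2))
        g = tunnels.build_clearance_graph(_chain(verts, 1.0))
        assert len(g) == 1
        np.testing.assert_allclose(g.vertices[0], verts.mean(axis=0), atol=1e-9)
        circumradius = a * math.sqrt(6) / 4
        assert g.clearance[0] == pytest.approx(circumradius - 1.0, abs=1e-9)

    def test_fully_occluded_cluster_gives_empty_graph(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(-0.5, 0.5, (12, 3))
        g = tunnels.build_clearance_graph(_chain(coords, 1.7))
        assert len(g) == 0

    def test_too_few_atoms_raises(self):
        with pytest.raises(tunnels.GeometryError):
            tunnels.build_clearance_graph(_chain([[0, 0, 0], [3, 0, 0], [0, 3, 0]], 1.5))

    def test_degenerate_coplanar_atoms_raise(self):
        coords = [[0, 0, 0], [3, 0, 0], [0, 3, 0], [3, 3, 0], [1, 1, 0]]
        with pytest.raises(tunnels.GeometryError):
            tunnels.build_clearance_graph(_chain(coords, 1.0))

    def test_channel_phantom_has_axis_path(self, straight_phantom):
        chain, _ = straight_phantom
        g = tunnels.build_clearance_graph(chain)
        r = np.linalg.norm(g.vertices[:, :2], axis=1)
        on_axis = (r < 0.5) & (g.vertices[:, 2] > 5) & (g.vertices[:, 2] < 25)
        assert on_axis.sum() >= 10
        assert g.clearance[on_axis].min() > 2.0


class TestPointClearance:
    def test_matches_bruteforce_over_all_atoms(self, straight_phantom):
        chain, _ = straight_phantom
        coords, radii = chain.coords, chain.radii
        rng = np.random.default_rng(42)
        pts = rng.uniform(-12, 32, (1000, 3))
        fast = tunnels.point_clearance(pts, coords, radii)
        for p, f in zip(pts[::37], fast[::37]):
            brute = min(np.linalg.norm(p - c) - r for c, r in zip(coords, radii))
            assert f == pytest.approx(brute, abs=1e-9)
        # full vectorised brute force over every probe point
        d = np.linalg.norm(pts[:, None, :] - coords[None], axis=2) - radii[None]
        np.testing.assert_allclose(fast, d.min(axis=1), atol=1e-9)


class TestStartPoint:
    def test_hollow_sphere_start_near_cavity_center(self):
        chain, _ = synth.make_phantom(
            synth.PhantomSpec(kind="hollow_sphere", wall_radius=8.0, seed=0))
        g = tunnels.build_clearance_graph(chain)
        s = tunnels.find_start_point(g)
        assert np.linalg.norm(g.vertices[s]) < 2.0

    def test_channel_start_on_axis(self, straight_phantom):
        chain, _ = straight_phantom
        g = tunnels.build_clearance_graph(chain)
        s = tunnels.find_start_point(g)
        assert np.linalg.norm(g.vertices[s][:2]) < 1.0

    def test_single_vertex_graph_returns_it(self):
        a = 6.0
        verts = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], float)
        verts *= a / (2 * math.sqrt(2))
        g = tunnels.build_clearance_graph(_chain(verts, 1.0))
        assert tunnels.find_start_point(g) == 0

    def test_user_start_point_overrides(self, straight_phantom):
        chain, _ = straight_phantom
        params = tunnels.TunnelParams(start_point=(0.0, 0.0, 25.0))
        g = tunnels.build_clearance_graph(chain, params)
        s = tunnels.find_start_point(g, params)
        assert abs(g.vertices[s][2] - 25.0) < 2.0


class TestComputeIndexes:
    def test_collinear_points(self):
        line = tuple(
            tunnels.ClearanceSphere((0.0, 0.0, float(z)), c)
            for z, c in [(0, 2.0), (10, 1.0), (20, 3.0)])
        length, distance, curvature, bottleneck = tunnels.compute_indexes(line)
        assert (length, distance, curvature, bottleneck) == (20.0, 20.0, 1.0, 1.0)

    def test_semicircle_curvature_is_half_pi(self):
        ang = np.radians(np.arange(0, 181))
        pts = np.column_stack([10 * np.cos(ang), 10 * np.sin(ang), np.zeros_like(ang)])
        line = tuple(tunnels.ClearanceSphere(tuple(p), 1.0) for p in pts)
        length, distance, curvature, _ = tunnels.compute_indexes(line)
        assert length == pytest.approx(math.pi * 10, rel=1e-4)
        assert distance == pytest.approx(20.0)
        assert curvature == pytest.approx(math.pi / 2, rel=1e-4)

    def test_coincident_endpoints_give_nan_curvature(self):
        ang = np.radians(np.arange(0, 361, 10))
        pts = np.column_stack([np.cos(ang), np.sin(ang), np.zeros_like(ang)])
        line = tuple(tunnels.ClearanceSphere(tuple(p), 1.0) for p in pts)
        _, _, curvature, _ = tunnels.compute_indexes(line)
        assert math.isnan(curvature)

    def test_short_centerline_raises(self):
        with pytest.raises(ValueError):
            tunnels.compute_indexes((tunnels.ClearanceSphere((0, 0, 0), 1.0),))


class TestDetectTunnels:
    def test_straight_channel_recovers_ground_truth(self, straight_phantom, straight_tunnels):
        _, truth = straight_phantom
        best = tunnels.select_largest_tunnel(straight_tunnels)
        assert best.bottleneck_radius == pytest.approx(truth.bottleneck_radius, abs=0.3)
        assert best.curvature == pytest.approx(1.0, abs=0.1)
        lo, hi = truth.length_range
        assert lo <= best.length <= hi

    def test_bent_channel_curvature_exceeds_one(self, bent_phantom):
        chain, truth = bent_phantom
        best = tunnels.select_largest_tunnel(tunnels.detect_tunnels(chain))
        assert best.curvature == pytest.approx(truth.curvature, abs=0.1)
        assert best.bottleneck_radius == pytest.approx(truth.bottleneck_radius, abs=0.4)

    def test_solid_ball_has_no_wide_tunnel(self):
        chain, _ = synth.make_phantom(synth.PhantomSpec(kind="solid_ball", wall_radius=7.0))
        ts = tunnels.detect_tunnels(chain)
        probe = tunnels.TunnelParams().probe_radius
        assert all(t.bottleneck_radius <= probe for t in ts)

    def test_detected_tunnels_satisfy_invariants(self, straight_tunnels):
        assert len(straight_tunnels) >= 1
        for t in straight_tunnels:
            cls = [s.clearance for s in t.centerline]
            assert t.bottleneck_radius == min(cls)
            assert t.length >= t.distance - 1e-9
            if not math.isnan(t.curvature):
                assert t.curvature >= 1 - 1e-9
        assert [t.id for t in straight_tunnels] == list(range(1, len(straight_tunnels) + 1))

    def test_rigid_motion_leaves_indexes_unchanged(self, straight_phantom, straight_tunnels):
        chain, _ = straight_phantom
        moved = synth.perturb_chain(chain, rigid_seed=5, noise_sigma=0.0)
        b1 = tunnels.select_largest_tunnel(straight_tunnels)
        b2 = tunnels.select_largest_tunnel(tunnels.detect_tunnels(moved))
        assert b2.length == pytest.approx(b1.length, rel=1e-6)
        assert b2.curvature == pytest.approx(b1.curvature, rel=1e-6)
        assert b2.bottleneck_radius == pytest.approx(b1.bottleneck_radius, rel=1e-6)


class TestSelectLargestTunnel:
    def test_1a73_profile_selects_tunnel_25(self):
        profile = tunnels.load_1a73_profile()
        assert len(profile) == 27
        best = tunnels.select_largest_tunnel(profile)
        assert best.id == 25
        runner_up = max((t for t in profile if t.id != 25), key=lambda t: t.selection_key)
        assert runner_up.id == 21
        assert best.selection_key > runner_up.selection_key

    def test_single_tunnel_returns_itself(self):
        ts = tunnels.TunnelSet((tunnels.Tunnel(1, 10.0, 1.2, 0.8),))
        assert tunnels.select_largest_tunnel(ts).id == 1

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.tuples(st.floats(0.1, 100), st.floats(0.1, 5)),
                    min_size=1, max_size=40))
    def test_agrees_with_bruteforce_argmax(self, pairs):
        ts = tunnels.TunnelSet(tuple(
            tunnels.Tunnel(i + 1, ln, 1.1, bn) for i, (ln, bn) in enumerate(pairs)))
        best = tunnels.select_largest_tunnel(ts)
        brute = max(range(len(pairs)),
                    key=lambda i: (pairs[i][0] * pairs[i][1], -i))
        assert best.id == brute + 1

    def test_empty_set_raises(self):
        with pytest.raises(tunnels.GeometryError):
            tunnels.select_largest_tunnel(tunnels.TunnelSet(()))

    def test_nan_curvature_tunnels_excluded(self):
        ts = tunnels.TunnelSet((
            tunnels.Tunnel(1, 100.0, float("nan"), 5.0),
            tunnels.Tunnel(2, 10.0, 1.2, 0.5),
        ))
        assert tunnels.select_largest_tunnel(ts).id == 2


class TestProfileIO:
    def test_roundtrip(self, tmp_path, straight_tunnels):
        p = tmp_path / "profile.tsv"
        tunnels.write_tunnel_profile(straight_tunnels, p)
        back = tunnels.read_tunnel_profile(p)
        assert len(back) == len(straight_tunnels)
        for a, b in zip(back, straight_tunnels):
            assert a.length == pytest.approx(b.length, abs=0.01)

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("tunnel\tbottleneck_radius\tlength\tcurvature\n1\tx\t2\t1.5\n")
        with pytest.raises(ValueError, match="2"):
            tunnels.read_tunnel_profile(p)
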