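"""Ring frames, angle folding, contact detectors vs brute force, KDE."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pibridge.ringgeom import (
    CationSite,
    ContactRecord,
    RingGroup,
    bridging_motifs,
    contact_summary,
    detect_cation_pi,
    detect_pi_pi,
    nh3_pi_distances,
    plane_angle,
    ring_frame,
    stacking_distribution,
)
from pibridge.synthetic import ideal_ring_coords

from conftest import make_cation, make_ring, random_cations, random_rings


def brute_force_pi_pi(rings_a, rings_b, cutoff):
    """Exhaustive 36-atom-pair oracle, plain loops."""
    same = rings_a is rings_b
    found = set()
    for i, ra in enumerate(rings_a):
        for j, rb in enumerate(rings_b):
            if same and j <= i:
                continue
            if ra.snapshot_index != rb.snapshot_index or ra.ring_id == rb.ring_id:
                continue
            dmin = min(
                math.dist(p, q)
                for p in ra.atom_coords.tolist()
                for q in rb.atom_coords.tolist()
            )
            if dmin < cutoff:
                found.add((ra.ring_id, rb.ring_id))
    return found


def brute_force_cation_pi(rings, cations, cutoff):
    found = set()
    for ring in rings:
        centroid = [sum(col) / 6.0 for col in zip(*ring.atom_coords.tolist())]
        for cat in cations:
            if ring.snapshot_index != cat.snapshot_index:
                continue
            if math.dist(centroid, cat.coord.tolist()) < cutoff:
                found.add((ring.ring_id, cat.site_id))
    return found


def rigid_transform(coords, rotation, translation):
    return coords @ rotation.T + translation


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


class TestRingFrame:
    def test_planar_ring_in_xy(self):
        ring = make_ring([0, 0, 0], [0, 0, 1])
        frame = ring_frame(ring)
        assert frame.centroid == pytest.approx([0, 0, 0], abs=1e-12)
        assert frame.normal == pytest.approx([0, 0, 1], abs=1e-12)

    def test_translation_equivariance(self):
        ring = make_ring([1, 2, 3], [0, 0, 1])
        frame = ring_frame(ring)
        assert frame.centroid == pytest.approx([1, 2, 3], abs=1e-12)
        assert frame.normal == pytest.approx([0, 0, 1], abs=1e-12)

    def test_rotation_equivariance(self):
        theta = math.radians(30)
        rot = np.array(
            [
                [1, 0, 0],
                [0, math.cos(theta), -math.sin(theta)],
                [0, math.sin(theta), math.cos(theta)],
            ]
        )
        coords = ideal_ring_coords(np.zeros(3), [0, 0, 1]) @ rot.T
        frame = ring_frame(RingGroup(coords, ring_id="rot"))
        expected = rot @ np.array([0, 0, 1.0])
        assert abs(float(frame.normal @ expected)) > 1 - 1e-9

    def test_degenerate_ring_rejected(self):
        coords = np.outer(np.arange(6.0), [1.0, 0, 0])  # collinear
        with pytest.raises(ValueError, match="degenerate|planar"):
            RingGroup(coords, ring_id="bad")

    def test_planarity_warning_and_error(self):
        coords = ideal_ring_coords(np.zeros(3), [0, 0, 1])
        bumped = coords.copy()
        bumped[0, 2] += 1.2
        with pytest.warns(UserWarning, match="out-of-plane"):
            ring = RingGroup(bumped, ring_id="warn")
        assert ring.planarity_warning
        # chair-distorted wide hexagon: best-fit plane cannot absorb +-2 A
        chair = ideal_ring_coords(np.zeros(3), [0, 0, 1], radius=10.0)
        chair[:, 2] += np.array([2.0, -2.0, 2.0, -2.0, 2.0, -2.0])
        with pytest.raises(ValueError, match="not planar"):
            RingGroup(chair, ring_id="err")


class TestPlaneAngle:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ([0, 0, 1], [0, 0, 1], 0.0),
            ([0, 0, 1], [1, 0, 0], 90.0),
            ([0, 0, 1], [0, math.sin(math.radians(120)), math.cos(math.radians(120))], 60.0),
        ],
    )
    def test_folding(self, a, b, expected):
        assert plane_angle(a, b) == pytest.approx(expected, abs=1e-9)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            plane_angle([0, 0, 0], [0, 0, 1])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        a=st.lists(st.floats(-1, 1), min_size=3, max_size=3),
        b=st.lists(st.floats(-1, 1), min_size=3, max_size=3),
    )
    def test_symmetry_and_sign_invariance(self, a, b):
        a, b = np.array(a), np.array(b)
        if np.linalg.norm(a) < 1e-6 or np.linalg.norm(b) < 1e-6:
            return
        ang = plane_angle(a, b)
        assert 0.0 <= ang <= 90.0
        assert ang == pytest.approx(plane_angle(b, a), abs=1e-9)
        assert ang == pytest.approx(plane_angle(-a, b), abs=1e-9)


class TestDetectors:
    def test_parallel_rings_contact(self):
        lower = make_ring([0, 0, 0], [0, 0, 1], ring_id="L", layer="lower")
        upper = make_ring([0, 0, 3.5], [0, 0, 1], ring_id="U", layer="upper")
        contacts = detect_pi_pi([lower], [upper])
        assert len(contacts) == 1
        c = contacts[0]
        assert c.metric_distance == pytest.approx(3.5, abs=1e-9)
        assert c.plane_angle == pytest.approx(0.0, abs=1e-9)
        assert c.span == "inter_plane"

    def test_distant_rings_no_contact(self):
        a = make_ring([0, 0, 0], [0, 0, 1], ring_id="A")
        b = make_ring([0, 0, 12.0], [0, 0, 1], ring_id="B")
        assert detect_pi_pi([a], [b]) == []

    def test_cation_on_axis(self):
        ring = make_ring([0, 0, 0], [0, 0, 1], ring_id="R")
        cat = make_cation([0, 0, 5.0])
        contacts = detect_cation_pi([ring], [cat])
        assert len(contacts) == 1
        assert contacts[0].metric_distance == pytest.approx(5.0)

    def test_strict_cutoff_boundary(self):
        ring = make_ring([0, 0, 0], [0, 0, 1], ring_id="R")
        assert detect_cation_pi([ring], [make_cation([0, 0, 10.0])]) == []
        assert len(detect_cation_pi([ring], [make_cation([0, 0, 9.999])])) == 1

    def test_self_pairs_excluded(self):
        rings = [
            make_ring([0, 0, 0], [0, 0, 1], ring_id="A"),
            make_ring([0, 0, 3.5], [0, 0, 1], ring_id="B"),
        ]
        contacts = detect_pi_pi(rings, rings)
        assert len(contacts) == 1  # one unordered pair, no self-contacts

    @pytest.mark.parametrize("seed", range(8))
    def test_pi_pi_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        rings = random_rings(rng, 20, box=18.0)
        contacts = detect_pi_pi(rings, rings)
        got = {(c.partner_a, c.partner_b) for c in contacts}
        assert got == brute_force_pi_pi(rings, rings, 4.5)
        for c in contacts:
            ra = next(r for r in rings if r.ring_id == c.partner_a)
            rb = next(r for r in rings if r.ring_id == c.partner_b)
            dmin = min(
                math.dist(p, q)
                for p in ra.atom_coords.tolist()
                for q in rb.atom_coords.tolist()
            )
            assert c.metric_distance == pytest.approx(dmin, abs=1e-9)

    @pytest.mark.parametrize("seed", range(8))
    def test_cation_pi_matches_brute_force(self, seed):
        rng = np.random.default_rng(100 + seed)
        rings = random_rings(rng, 20, box=30.0)
        cations = random_cations(rng, 10, box=30.0)
        got = {(c.partner_a, c.partner_b) for c in detect_cation_pi(rings, cations)}
        assert got == brute_force_cation_pi(rings, cations, 10.0)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(7)
        rings = random_rings(rng, 15, box=15.0)
        cations = random_cations(rng, 8, box=15.0)
        rot = random_rotation(rng)
        shift = rng.uniform(-50, 50, 3)
        rings2 = [
            RingGroup(
                rigid_transform(r.atom_coords, rot, shift),
                ring_id=r.ring_id,
                layer=r.layer,
                snapshot_index=r.snapshot_index,
            )
            for r in rings
        ]
        cations2 = [
            CationSite(
                rot @ c.coord + shift,
                species=c.species,
                site_id=c.site_id,
                layer=c.layer,
                snapshot_index=c.snapshot_index,
            )
            for c in cations
        ]
        before = {
            (c.partner_a, c.partner_b): (c.metric_distance, c.plane_angle)
            for c in detect_pi_pi(rings, rings)
        }
        after = {
            (c.partner_a, c.partner_b): (c.metric_distance, c.plane_angle)
            for c in detect_pi_pi(rings2, rings2)
        }
        assert before.keys() == after.keys()
        for key in before:
            assert before[key][0] == pytest.approx(after[key][0], abs=1e-9)
            assert before[key][1] == pytest.approx(after[key][1], abs=1e-9)
        b_cat = {
            (c.partner_a, c.partner_b): c.metric_distance
            for c in detect_cation_pi(rings, cations)
        }
        a_cat = {
            (c.partner_a, c.partner_b): c.metric_distance
            for c in detect_cation_pi(rings2, cations2)
        }
        assert b_cat.keys() == a_cat.keys()
        for key in b_cat:
            assert b_cat[key] == pytest.approx(a_cat[key], abs=1e-9)


class TestBridging:
    def test_order_two_inter_plane_bridge(self):
        lower = make_ring([0, 0, 0], [0, 0, 1], ring_id="L", layer="lower")
        upper = make_ring([0, 0, 8.0], [0, 0, 1], ring_id="U", layer="upper")
        cat = make_cation([0, 0, 4.0])
        motifs = bridging_motifs(detect_cation_pi([lower, upper], [cat]))
        assert len(motifs) == 1
        assert motifs[0].order == 2
        assert motifs[0].is_bridge

    def test_order_one_is_not_a_bridge(self):
        ring = make_ring([0, 0, 0], [0, 0, 1], ring_id="R", layer="lower")
        motifs = bridging_motifs(detect_cation_pi([ring], [make_cation([0, 0, 4.0])]))
        assert motifs[0].order == 1 and not motifs[0].is_bridge

    def test_order_three_hand_count(self):
        rings = [
            make_ring([0, 0, 0], [0, 0, 1], ring_id="A", layer="lower"),
            make_ring([5, 0, 4], [0, 0, 1], ring_id="B", layer="upper"),
            make_ring([-5, 0, 4], [0, 0, 1], ring_id="C", layer="upper"),
        ]
        cat = make_cation([0, 0, 4.0])
        motifs = bridging_motifs(detect_cation_pi(rings, [cat]))
        assert motifs[0].order == 3
        assert set(motifs[0].ring_ids) == {"A", "B", "C"}
        assert motifs[0].is_bridge


class TestStackingDistribution:
    def test_point_mass_mode(self):
        pairs = [(7.5, 90.0)] * 10
        surface = stacking_distribution(pairs)
        d_mode, a_mode = surface.mode()
        assert d_mode == pytest.approx(7.5, abs=0.2)
        assert a_mode == pytest.approx(90.0, abs=1.0)

    def test_two_clusters_two_modes(self):
        rng = np.random.default_rng(0)
        c1 = np.column_stack([rng.normal(4.0, 0.1, 50), rng.normal(10.0, 1.0, 50)])
        c2 = np.column_stack([rng.normal(9.0, 0.1, 50), rng.normal(80.0, 1.0, 50)])
        pts = np.vstack([c1, c2])
        d_grid = np.linspace(2, 11, 91)
        a_grid = np.linspace(0, 90, 91)
        surface = stacking_distribution(pts, grid=(d_grid, a_grid))
        # density at each cluster center exceeds the saddle between them
        def dens_at(d, a):
            i = np.argmin(np.abs(d_grid - d))
            j = np.argmin(np.abs(a_grid - a))
            return surface.density[i, j]

        assert dens_at(4, 10) > dens_at(6.5, 45)
        assert dens_at(9, 80) > dens_at(6.5, 45)

    def test_integral_is_one(self):
        rng = np.random.default_rng(1)
        pts = np.column_stack([rng.uniform(3, 9, 200), rng.uniform(0, 90, 200)])
        surface = stacking_distribution(pts)
        assert surface.integral() == pytest.approx(1.0, abs=0.01)

    def test_requires_two_pairs(self):
        with pytest.raises(ValueError):
            stacking_distribution([(5.0, 45.0)])

    def test_accepts_ring_pairs_and_contacts(self):
        a = make_ring([0, 0, 0], [0, 0, 1], ring_id="A", layer="lower")
        b = make_ring([0, 0, 3.5], [0, 0, 1], ring_id="B", layer="upper")
        surface = stacking_distribution([(a, b), (a, b)])
        assert surface.mode()[0] == pytest.approx(3.5, abs=0.2)
        contacts = detect_pi_pi([a], [b]) * 2
        surface2 = stacking_distribution(contacts)
        assert surface2.integral() == pytest.approx(1.0, abs=0.01)


class TestNh3Pi:
    def test_single_site(self):
        ring = make_ring([0, 0, 0], [0, 0, 1], ring_id="R")
        site = make_cation([0, 0, 4.0], species="NH3+")
        res = nh3_pi_distances([site], [ring])
        assert res.distances == pytest.approx([4.0])
        assert res.summary["min"] == res.summary["max"] == pytest.approx(4.0)

    def test_two_sites_summary(self):
        ring = make_ring([0, 0, 0], [0, 0, 1], ring_id="R")
        sites = [
            make_cation([0, 0, 3.0], species="NH3+", site_id="a"),
            make_cation([0, 0, 6.0], species="NH3+", site_id="b"),
        ]
        res = nh3_pi_distances(sites, [ring])
        assert res.summary == {"n": 2, "min": 3.0, "max": 6.0, "mean": 4.5}

    def test_histogram_matches_brute_force_binning(self, rng):
        ring = make_ring([0, 0, 0], [0, 0, 1], ring_id="R")
        sites = [
            make_cation([0, 0, z], species="NH3+", site_id=f"s{i}")
            for i, z in enumerate(rng.uniform(1.0, 9.9, 50))
        ]
        res = nh3_pi_distances(sites, [ring], max_distance=10.0, bin_width=0.5)
        expected, _ = np.histogram(res.distances, bins=np.arange(0, 10.5, 0.5))
        assert np.array_equal(res.hist_counts, expected)
        assert res.hist_counts.sum() == 50

    def test_non_nh3_sites_ignored_and_empty_ok(self):
        ring = make_ring([0, 0, 0], [0, 0, 1], ring_id="R")
        res = nh3_pi_distances([make_cation([0, 0, 3.0], species="K+")], [ring])
        assert res.summary["n"] == 0
        empty = nh3_pi_distances([], [])
        assert empty.distances.size == 0


class TestContactSummary:
    def test_empty(self):
        table = contact_summary([])
        assert list(table.columns) == ["kind", "span", "species", "snapshot_index", "count"]
        assert len(table) == 0

    def test_counts_by_span(self):
        recs = [
            ContactRecord("pi_pi", "A", "B", 3.5, 0.0, "inter_plane")
            for _ in range(3)
        ] + [ContactRecord("pi_pi", "A", "C", 4.0, 10.0, "intra_plane") for _ in range(2)]
        table = contact_summary(recs)
        counts = dict(zip(table["span"], table["count"]))
        assert counts == {"inter_plane": 3, "intra_plane": 2}
        assert table["count"].sum() == 5

    def test_mixed_fixture_hand_count(self):
        recs = [
            ContactRecord("pi_pi", "A", "B", 3.5, 0.0, "inter_plane"),
            ContactRecord("cation_pi", "A", "c1", 5.0, None, "intra_plane", species="K+"),
            ContactRecord("cation_pi", "B", "c1", 5.0, None, "intra_plane", species="K+"),
            ContactRecord("cation_pi", "B", "c2", 6.0, None, "inter_plane", species="Y3+"),
        ]
        table = contact_summary(recs)
        assert table["count"].sum() == len(recs)
        y_rows = table[table["species"] == "Y3+"]
        assert y_rows["count"].tolist() == [1]
        k_rows = table[table["species"] == "K+"]
        assert k_rows["count"].sum() == 2
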