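import numpy as np
import pytest
from shapely.geometry import Polygon

from conftest import build_linked, honeycomb
from epigraph.graph import (CellNode, Division, SpatioTemporalGraph,
                            build_frame_graph, cells_from_polygons,
                            link_frames)
from epigraph.analysis import (InsufficientObservationError, T1Event,
                               cell_geometry, classify_populations,
                               classify_t1, detect_t1, division_orientation,
                               junction_series, polygon_distribution, t1_rate)
from epigraph.synthetic import division_microfixture, generate_tissue
from oracles import neighbor_distribution_from_ridges


def node_from_polygon(poly, frame=0, cell_id=0):
    return CellNode(frame=frame, cell_id=cell_id, polygon=poly,
                    centroid=(poly.centroid.y, poly.centroid.x),
                    area=poly.area, on_border=False)


class TestCellGeometry:
    def test_unit_square(self):
        area, ratio, _ = cell_geometry(node_from_polygon(
            Polygon([(0, 0), (1, 0), (1, 1), (0, 1)])))
        assert area == pytest.approx(1.0)
        assert ratio == pytest.approx(1.0)

    def test_circle_32gon_is_round(self):
        th = np.linspace(0, 2 * np.pi, 33)[:-1]
        poly = Polygon(np.column_stack([10 * np.cos(th), 10 * np.sin(th)]))
        _, ratio, _ = cell_geometry(node_from_polygon(poly))
        assert ratio == pytest.approx(1.0, abs=0.02)

    @pytest.mark.parametrize("angle", [0.0, 30.0, 117.0])
    def test_2to1_rectangle_ratio_and_axis(self, angle):
        a = np.deg2rad(angle)
        R = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        rect = np.array([[-2, -1], [2, -1], [2, 1], [-2, 1]], float) @ R.T
        _, ratio, axis = cell_geometry(node_from_polygon(Polygon(rect)))
        assert ratio == pytest.approx(2.0, rel=0.05)
        diff = abs(axis - angle) % 180
        assert min(diff, 180 - diff) < 1.0

    def test_degenerate_polygon_rejected(self):
        poly = Polygon([(0, 0), (1, 0), (2, 0), (0, 0)])
        with pytest.raises(ValueError):
            cell_geometry(node_from_polygon(poly))


class TestPolygonDistribution:
    def test_honeycomb_interior_all_hexagons(self):
        polys = honeycomb(n_rings=3)
        fg = build_frame_graph(cells_from_polygons(polys, 0))
        # flag the outer two rings as border surrogates
        interior = {i for i, p in polys.items()
                    if fg.adjacency.degree(i) == 6}
        for cid, cell in fg.cells.items():
            cell.on_border = cid not in interior
        g = SpatioTemporalGraph([fg])
        dist = polygon_distribution(g, 0)
        assert dist == {6: 1.0}

    def test_distribution_sums_to_one(self, big_tessellation):
        tissue, g = big_tessellation
        dist = polygon_distribution(g, 0)
        assert sum(dist.values()) == pytest.approx(1.0)

    def test_matches_ridge_counting_oracle(self, big_tessellation):
        tissue, g = big_tessellation
        dist = polygon_distribution(g, 0)
        oracle = neighbor_distribution_from_ridges(tissue, 0)
        classes = set(dist) | set(oracle)
        for k in classes:
            assert dist.get(k, 0) == pytest.approx(oracle.get(k, 0), abs=0.02)

    def test_empty_frame_flagged(self):
        import networkx as nx
        from epigraph.graph import FrameGraph
        g = SpatioTemporalGraph([FrameGraph(0, {}, nx.Graph())])
        assert polygon_distribution(g, 0) == {}


class TestPopulations:
    def test_static_fixture_all_stable(self):
        polys = honeycomb(n_rings=2)
        fgs = [build_frame_graph(cells_from_polygons(polys, t))
               for t in range(12)]
        g = link_frames(fgs)
        labels = classify_populations(g, min_observation=10)
        assert set(labels.values()) == {"stable"}
        assert len(labels) == len(polys)

    def test_division_and_elimination_classes(self, events_tissue,
                                              events_graph):
        labels = classify_populations(events_graph, min_observation=5)
        mothers = {d.mother for d in events_tissue.divisions}
        daughters = {c for d in events_tissue.divisions for c in d.daughters}
        eliminated = {e.cell for e in events_tissue.eliminations}
        by_cell = {root[1]: lab for root, lab in labels.items()}
        for m in mothers:
            assert by_cell[m] == "dividing"
        for c in daughters:
            assert by_cell.get(c, "daughter") == "daughter"
        for c in eliminated:
            assert by_cell[c] == "eliminated"

    def test_short_tracks_excluded(self, events_graph):
        labels = classify_populations(events_graph, min_observation=1000)
        assert labels == {}


class TestDivisionOrientation:
    def test_perpendicular_division_is_90(self):
        g, e = division_microfixture(0.0, 90.0)
        r = division_orientation(e, g)
        assert r.angle_deg == pytest.approx(90.0, abs=1e-6)
        assert r.n_combinations == 25

    def test_parallel_division_is_0(self):
        g, e = division_microfixture(0.0, 0.0)
        assert division_orientation(e, g).angle_deg == pytest.approx(0.0,
                                                                     abs=1e-6)

    def test_planted_angle_recovered_under_jitter(self):
        g, e = division_microfixture(20.0, 83.0, jitter_deg=3.0,
                                     rng=np.random.default_rng(5))
        assert division_orientation(e, g).angle_deg == pytest.approx(63.0,
                                                                     abs=3.0)

    def test_insufficient_history_skipped_with_reason(self):
        g, e = division_microfixture(0.0, 45.0, n_pre=4)
        with pytest.raises(InsufficientObservationError):
            division_orientation(e, g)

    def test_daughter_segment_perpendicular_in_tissue(self):
        tissue = generate_tissue(150, 8, rng_seed=17, jitter=0.05,
                                 divisions=[{"frame": 4, "angle": 45.0}])
        d = tissue.divisions[0]
        fr = tissue.frames[d.frame]
        c1 = fr.polygons[d.daughters[0]].centroid
        c2 = fr.polygons[d.daughters[1]].centroid
        seg = np.rad2deg(np.arctan2(c2.y - c1.y, c2.x - c1.x)) % 180
        diff = abs(seg - (45.0 + 90.0)) % 180
        assert min(diff, 180 - diff) < 2.0


class TestT1:
    def test_static_fixture_zero_events(self):
        polys = honeycomb(n_rings=2)
        fgs = [build_frame_graph(cells_from_polygons(polys, t))
               for t in range(5)]
        g = link_frames(fgs)
        assert detect_t1(g) == []

    def test_division_does_not_masquerade_as_t1(self):
        tissue = generate_tissue(
            150, 12, rng_seed=31, jitter=0.05,
            divisions=[{"frame": 4, "angle": 10.0},
                       {"frame": 7, "angle": 100.0}])
        g = build_linked(tissue)
        assert len(tissue.divisions) == 2
        assert detect_t1(g) == []

    def test_scripted_quartets_recovered(self, t1_suite):
        for tissue, g in t1_suite:
            planted = {frozenset(e.losers) | frozenset(e.winners)
                       for e in tissue.t1_events}
            detected = {frozenset(c for pair in (e.losers, e.winners)
                                  for _, c in pair): e
                        for e in detect_t1(g)}
            assert set(detected) == planted
            for e in tissue.t1_events:
                d = detected[frozenset(e.losers) | frozenset(e.winners)]
                assert {c for _, c in d.losers} == set(e.losers)
                assert {c for _, c in d.winners} == set(e.winners)

    def test_scripted_classes_recovered(self, t1_suite):
        for tissue, g in t1_suite:
            planted = {frozenset(e.losers) | frozenset(e.winners): e.template
                       for e in tissue.t1_events}
            for e in detect_t1(g):
                q = frozenset(c for pair in (e.losers, e.winners)
                              for _, c in pair)
                assert classify_t1(e) == planted[q]

    @pytest.mark.parametrize("series,expected", [
        ([5, 3, 1, 0, -2, -4, -5], "fast"),
        ([5, 1, 0.2, 0.1, 0, 0.1, 0, -0.2, -1, -3], "slow"),
        ([3, 0, -1, 0, 2, 0, -2], "transient"),
        ([5, 4, 3, 2, 1, 0.5], "censored"),
    ])
    def test_classification_rule_on_reference_series(self, series, expected):
        e = T1Event(frame_of_exchange=0, losers=((0, 1), (0, 2)),
                    winners=((0, 3), (0, 4)),
                    junction_length_series=series,
                    frames=list(range(len(series))))
        assert classify_t1(e, eps=1.0, k_fast=2) == expected


class TestJunctionSeries:
    def test_static_fixture_constant_length(self):
        polys = honeycomb(n_rings=2)
        fgs = [build_frame_graph(cells_from_polygons(polys, t))
               for t in range(4)]
        g = link_frames(fgs)
        a, b = next(iter(fgs[0].adjacency.edges()))
        track = junction_series(g, ((0, a), (0, b)))
        assert len(track.frames) == 4
        assert np.ptp(track.lengths) < 1e-9

    def test_shrinking_junction_strictly_decreasing_to_exchange(self,
                                                                t1_suite):
        tissue, g = t1_suite[0]
        ev = tissue.t1_events[0]
        track = junction_series(g, ((0, ev.losers[0]), (0, ev.losers[1])))
        upto = [l for f, l in zip(track.frames, track.lengths)
                if ev.frame_start <= f < ev.frame_of_exchange]
        assert all(a > b for a, b in zip(upto, upto[1:]))

    def test_never_adjacent_pair_empty(self):
        polys = honeycomb(n_rings=2)
        fgs = [build_frame_graph(cells_from_polygons(polys, t))
               for t in range(3)]
        g = link_frames(fgs)
        far = ((0, 0), (0, len(polys) - 1))
        deg = fgs[0].adjacency
        if deg.has_edge(far[0][1], far[1][1]):
            pytest.skip("fixture cells unexpectedly adjacent")
        assert junction_series(g, far).is_empty

    def test_uniform_image_constant_intensity(self):
        from epigraph.graph import FrameGraph
        polys = honeycomb(n_rings=1)
        img = np.full((60, 60), 42.0)
        cells = cells_from_polygons(
            {i: p for i, p in
             ((i, Polygon(np.asarray(p.exterior.coords) + 30))
              for i, p in polys.items())}, 0)
        fgs = [build_frame_graph(cells, image=img) for _ in range(2)]
        fgs = [FrameGraph(t, fg.cells, fg.adjacency, image=img)
               for t, fg in enumerate(fgs)]
        g = link_frames(fgs)
        a, b = next(iter(fgs[0].adjacency.edges()))
        track = junction_series(g, ((0, a), (0, b)))
        assert all(v == pytest.approx(42.0) for v in track.intensities)


class TestT1Rate:
    def test_zero_events_zero_rate(self, events_graph):
        assert t1_rate([], events_graph) == 0.0

    def test_rate_arithmetic(self):
        """10 events, 500 interior cells, 5 h -> 4 per 1,000 per hour."""
        import networkx as nx
        from epigraph.graph import FrameGraph
        cells = {i: CellNode(0, i, Polygon([(0, 0), (1, 0), (1, 1)]),
                             (0.3, 0.3), 0.5, on_border=False)
                 for i in range(500)}
        fgs = [FrameGraph(t, cells, nx.Graph()) for t in range(51)]
        g = SpatioTemporalGraph(fgs, frame_interval=6.0)
        events = [T1Event(1, ((0, 0), (0, 1)), ((0, 2), (0, 3)), [1, -1],
                          [0, 1]) for _ in range(10)]
        assert t1_rate(events, g) == pytest.approx(4.0)

    def test_zero_duration_rejected(self):
        import networkx as nx
        from epigraph.graph import FrameGraph
        g = SpatioTemporalGraph([FrameGraph(0, {}, nx.Graph())],
                                frame_interval=6.0)
        with pytest.raises(ValueError):
            t1_rate([], g)
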