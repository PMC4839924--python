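"""Live-wire segmentation: cost map, shortest paths, contours, masks."""

import numpy as np
import pytest
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra as scipy_dijkstra

from _oracles import brute_force_min_cost, random_cost_map
from renasl.phantom import default_seed_points
from renasl.scissors import (
    OFFSETS,
    Contour,
    build_cost_map,
    close_contour,
    contour_to_mask,
    gradient_cost,
    live_wire_path,
    path_cost,
    trace_contour,
)


def _scipy_min_cost(cost_map, seed, target):
    """Second independent route: sparse-graph Dijkstra."""
    rows, cols = cost_map.shape
    n = rows * cols
    data, ri, ci = [], [], []
    for k, (dr, dc) in enumerate(OFFSETS):
        w = cost_map.link_costs[k]
        rr, cc = np.nonzero(np.isfinite(w))
        data.extend(w[rr, cc])
        ri.extend(rr * cols + cc)
        ci.extend((rr + dr) * cols + (cc + dc))
    graph = csr_matrix((data, (ri, ci)), shape=(n, n))
    d = scipy_dijkstra(graph, indices=seed[0] * cols + seed[1])
    return d[target[0] * cols + target[1]]


class TestCostMap:
    def test_constant_image_has_unit_gradient_cost(self):
        assert np.all(gradient_cost(np.full((5, 5), 3.0)) == 1.0)
        cm = build_cost_map(np.full((8, 8), 3.0))
        assert np.isfinite(cm.link_costs[3, 2, 2])

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            build_cost_map(np.zeros((5, 5)), weights=(0.5, 0.5, 0.5))

    def test_default_weights_sum_to_one(self):
        from renasl.scissors import DEFAULT_WEIGHTS

        assert sum(DEFAULT_WEIGHTS) == pytest.approx(1.0)

    def test_components_bounded(self):
        rng = np.random.default_rng(0)
        cm = build_cost_map(rng.normal(size=(12, 12)))
        finite = cm.link_costs[np.isfinite(cm.link_costs)]
        assert finite.min() >= 0.0
        assert finite.max() <= 1.0 + 1e-12

    def test_step_edge_links_cheapest_along_edge(self):
        img = np.zeros((9, 9))
        img[:, 5:] = 100.0
        cm = build_cost_map(img)
        # stepping down along the bright-side edge column must be cheaper
        # than stepping down in the flat interior
        k_down = OFFSETS.index((1, 0))
        edge_cost = cm.link_costs[k_down, 2:6, 5].mean()
        flat_cost = cm.link_costs[k_down, 2:6, 0].mean()
        assert edge_cost < flat_cost


class TestLiveWire:
    def test_degenerate_seed_equals_target(self):
        cm = random_cost_map((4, 4), np.random.default_rng(0))
        assert live_wire_path(cm, (2, 2), (2, 2)) == [(2, 2)]

    def test_out_of_bounds_points_raise(self):
        cm = random_cost_map((4, 4), np.random.default_rng(0))
        with pytest.raises(ValueError, match="outside"):
            live_wire_path(cm, (0, 0), (4, 0))

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_brute_force_on_random_4x4(self, trial):
        rng = np.random.default_rng(100 + trial)
        cm = random_cost_map((4, 4), rng)
        seed, target = (0, 0), (3, 3)
        path = live_wire_path(cm, seed, target)
        assert path_cost(cm, path) == pytest.approx(
            brute_force_min_cost(cm, seed, target), abs=1e-12
        )

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_scipy_dijkstra_on_random_6x6(self, trial):
        rng = np.random.default_rng(200 + trial)
        cm = random_cost_map((6, 6), rng)
        seed = tuple(rng.integers(0, 6, 2))
        target = tuple(rng.integers(0, 6, 2))
        path = live_wire_path(cm, seed, target)
        assert path_cost(cm, path) == pytest.approx(_scipy_min_cost(cm, seed, target), abs=1e-10)

    def test_uniform_costs_give_chebyshev_geodesic(self):
        cm = random_cost_map((7, 7), np.random.default_rng(0))
        cm.link_costs = np.where(np.isfinite(cm.link_costs), 1.0, np.inf)
        path = live_wire_path(cm, (0, 0), (4, 6))
        assert len(path) - 1 == max(4, 6)  # Chebyshev distance in steps

    def test_symmetry_on_symmetric_costs(self):
        """Equal forward/backward costs whenever the link costs are symmetric."""
        rng = np.random.default_rng(7)
        cm = random_cost_map((6, 6), rng)
        lc = cm.link_costs
        rows, cols = cm.shape
        for k, (dr, dc) in enumerate(OFFSETS):
            rk = OFFSETS.index((-dr, -dc))
            for r in range(rows):
                for c in range(cols):
                    if 0 <= r + dr < rows and 0 <= c + dc < cols:
                        lc[rk, r + dr, c + dc] = lc[k, r, c]
        a = path_cost(cm, live_wire_path(cm, (0, 1), (5, 4)))
        b = path_cost(cm, live_wire_path(cm, (5, 4), (0, 1)))
        assert a == pytest.approx(b, abs=1e-12)


class TestContour:
    def test_contour_requires_adjacent_simple_chain(self):
        with pytest.raises(ValueError):
            Contour(points=np.array([[0, 0], [0, 1]]))
        with pytest.raises(ValueError, match="adjacent"):
            Contour(points=np.array([[0, 0], [0, 3], [3, 3]]))

    def test_close_contour_from_two_arcs(self):
        top = [(0, 0), (0, 1), (0, 2), (1, 3)]
        bottom = [(1, 3), (2, 2), (2, 1), (1, 0), (0, 0)]
        contour = close_contour([top, bottom])
        assert len(contour) == 7
        assert {tuple(p) for p in contour.points} == set(top) | set(bottom)

    def test_close_contour_order_independent(self):
        top = [(0, 0), (0, 1), (0, 2), (1, 3)]
        bottom = [(1, 3), (2, 2), (2, 1), (1, 0), (0, 0)]
        a = close_contour([top, bottom])
        b = close_contour([bottom, top])
        assert {tuple(p) for p in a.points} == {tuple(p) for p in b.points}

    def test_close_contour_rejects_gap(self):
        with pytest.raises(ValueError, match="chain|close"):
            close_contour([[(0, 0), (0, 1)], [(3, 3), (3, 4)]])

    def test_square_mask_on_grid(self):
        pts = [(1, 1), (1, 2), (1, 3), (2, 3), (3, 3), (3, 2), (3, 1), (2, 1)]
        mask = contour_to_mask(Contour(points=np.array(pts)), (5, 5))
        assert mask.sum() == 9
        assert mask[1:4, 1:4].all()


class TestPhantomTrace:
    def test_noiseless_phantom_trace_dice(self, noiseless_phantom):
        """A 4-seed live-wire trace recovers the kidney mask, Dice >= 0.98."""
        spec, series, truth = noiseless_phantom
        contour = trace_contour(series.m0, default_seed_points(spec))
        mask = contour_to_mask(contour, series.m0.shape)
        dice = 2 * (mask & truth.kidney_mask).sum() / (mask.sum() + truth.kidney_mask.sum())
        assert dice >= 0.98

    def test_traced_mask_area_close_to_truth(self, noiseless_phantom):
        spec, series, truth = noiseless_phantom
        contour = trace_contour(series.m0, default_seed_points(spec))
        mask = contour_to_mask(contour, series.m0.shape)
        assert mask.sum() == pytest.approx(truth.kidney_mask.sum(), rel=0.02)
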