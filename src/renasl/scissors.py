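"""Live-wire (intelligent scissors) kidney delineation.

The user supplies a handful of seed points on the kidney edge; between
consecutive seeds the boundary snaps onto the minimum-cost path of a local
link-cost graph built from three edge features: Laplacian zero-crossings
(f_Z), gradient direction smoothness (f_D) and inverted gradient magnitude
(f_G).  The default weights (w_z, w_d, w_g) = (0.43, 0.43, 0.14) follow
the classic formulation of the method.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon
from skimage.draw import polygon as draw_polygon

__all__ = [
    "CostMap",
    "Contour",
    "build_cost_map",
    "gradient_cost",
    "live_wire_path",
    "close_contour",
    "contour_to_mask",
    "trace_contour",
]

# Neighbor offsets: direct (N, S, W, E) before diagonals; this ordering also
# fixes deterministic tie-breaks wherever neighbors are scanned.
OFFSETS: tuple[tuple[int, int], ...] = (
    (-1, 0),
    (1, 0),
    (0, -1),
    (0, 1),
    (-1, -1),
    (-1, 1),
    (1, -1),
    (1, 1),
)

DEFAULT_WEIGHTS: tuple[float, float, float] = (0.43, 0.43, 0.14)  # (w_z, w_d, w_g)


def gradient_cost(image: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """Inverted normalized gradient magnitude, f_G = 1 - |grad| / max|grad|.

    Low values sit on strong edges.  A constant image has zero gradient
    everywhere and yields f_G = 1 (the maximum is treated as 1).
    """
    sm = ndimage.gaussian_filter(np.asarray(image, dtype=float), sigma)
    gy, gx = np.gradient(sm)
    gm = np.hypot(gx, gy)
    mx = gm.max()
    if mx == 0:
        return np.ones_like(gm)
    return 1.0 - gm / mx


def _shift(arr: np.ndarray, dr: int, dc: int, fill: float) -> np.ndarray:
    """Array of neighbor values: out[p] = arr[p + (dr, dc)], fill outside."""
    out = np.full_like(arr, fill)
    rows, cols = arr.shape
    out_rs = slice(max(-dr, 0), rows - max(dr, 0))
    out_cs = slice(max(-dc, 0), cols - max(dc, 0))
    in_rs = slice(max(dr, 0), rows + min(dr, 0))
    in_cs = slice(max(dc, 0), cols + min(dc, 0))
    out[out_rs, out_cs] = arr[in_rs, in_cs]
    return out


def _zero_crossing(lap: np.ndarray) -> np.ndarray:
    """Mark one pixel of every 4-adjacent sign change of the Laplacian.

    Of the two pixels straddling a crossing, the negative-Laplacian side
    is marked consistently.  For a bright object on a dark background that
    is the interior side of the edge, so a traced boundary keeps the
    object's outermost pixel ring instead of wandering onto the
    background.
    """
    mark = np.zeros(lap.shape, dtype=bool)
    # column-adjacent pairs
    a, b = lap[:, :-1], lap[:, 1:]
    cross = a * b < 0
    mark[:, :-1] |= cross & (a < 0)
    mark[:, 1:] |= cross & (b < 0)
    # row-adjacent pairs
    a, b = lap[:-1, :], lap[1:, :]
    cross = a * b < 0
    mark[:-1, :] |= cross & (a < 0)
    mark[1:, :] |= cross & (b < 0)
    return mark


@dataclass
class CostMap:
    """Directed 8-neighbor link costs, shape (8, rows, cols).

    ``link_costs[k, r, c]`` is the cost of stepping from (r, c) to
    (r, c) + OFFSETS[k]; links leaving the image are infinite.
    """

    link_costs: np.ndarray
    weights: tuple[float, float, float]

    @property
    def shape(self) -> tuple[int, int]:
        return self.link_costs.shape[1:]


def build_cost_map(
    image: np.ndarray,
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
    sigma: float = 1.0,
) -> CostMap:
    """Local link costs l(p, q) = w_z f_Z(q) + w_d f_D(p, q) + w_g f_G(q).

    Each component lies in [0, 1] before weighting; the f_G term of a
    diagonal link is scaled by 1/sqrt(2).  The weights must sum to 1.
    """
    w_z, w_d, w_g = weights
    if not np.isclose(w_z + w_d + w_g, 1.0):
        raise ValueError("cost weights must sum to 1")
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    sm = ndimage.gaussian_filter(img, sigma)
    gy, gx = np.gradient(sm)
    gm = np.hypot(gx, gy)
    mx = gm.max()
    f_g = 1.0 - gm / mx if mx > 0 else np.ones_like(gm)
    f_z = np.where(_zero_crossing(ndimage.laplace(sm)), 0.0, 1.0)

    # Unit vectors perpendicular to the gradient (zero where flat).
    with np.errstate(invalid="ignore", divide="ignore"):
        dpx = np.where(gm > 0, gy / gm, 0.0)
        dpy = np.where(gm > 0, -gx / gm, 0.0)

    costs = np.full((len(OFFSETS),) + img.shape, np.inf)
    two_over_3pi = 2.0 / (3.0 * np.pi)
    for k, (dr, dc) in enumerate(OFFSETS):
        length = np.hypot(dr, dc)
        lx, ly = dc / length, dr / length
        dot_p = dpx * lx + dpy * ly
        s = np.where(dot_p >= 0, 1.0, -1.0)
        dqx = _shift(dpx, dr, dc, 0.0)
        dqy = _shift(dpy, dr, dc, 0.0)
        dot_q = (dqx * lx + dqy * ly) * s
        f_d = two_over_3pi * (
            np.arccos(np.clip(np.abs(dot_p), -1.0, 1.0))
            + np.arccos(np.clip(dot_q, -1.0, 1.0))
        )
        fz_q = _shift(f_z, dr, dc, 1.0)
        fg_q = _shift(f_g, dr, dc, 1.0)
        if length > 1:
            fg_q = fg_q / np.sqrt(2.0)
        cost_k = w_z * fz_q + w_d * f_d + w_g * fg_q
        # invalidate links leaving the image
        if dr == -1:
            cost_k[0, :] = np.inf
        if dr == 1:
            cost_k[-1, :] = np.inf
        if dc == -1:
            cost_k[:, 0] = np.inf
        if dc == 1:
            cost_k[:, -1] = np.inf
        costs[k] = cost_k
    return CostMap(link_costs=costs, weights=(w_z, w_d, w_g))


def live_wire_path(
    cost_map: CostMap, seed: tuple[int, int], target: tuple[int, int]
) -> list[tuple[int, int]]:
    """Minimum-cumulative-cost 8-connected path from seed to target.

    Dijkstra's algorithm with (cost, row, col) heap keys, so ties are
    broken by lexicographic (row, col) order of expansion and the result
    is deterministic across platforms.
    """
    rows, cols = cost_map.shape
    for name, (r, c) in (("seed", seed), ("target", target)):
        if not (0 <= r < rows and 0 <= c < cols):
            raise ValueError(f"{name} point {(r, c)} is outside the image")
    seed = (int(seed[0]), int(seed[1]))
    target = (int(target[0]), int(target[1]))
    if seed == target:
        return [seed]
    dist = np.full((rows, cols), np.inf)
    dist[seed] = 0.0
    prev: dict[tuple[int, int], tuple[int, int]] = {}
    done = np.zeros((rows, cols), dtype=bool)
    heap: list[tuple[float, int, int]] = [(0.0, seed[0], seed[1])]
    lc = cost_map.link_costs
    while heap:
        d, r, c = heapq.heappop(heap)
        if done[r, c]:
            continue
        done[r, c] = True
        if (r, c) == target:
            break
        for k, (dr, dc) in enumerate(OFFSETS):
            w = lc[k, r, c]
            if not np.isfinite(w):
                continue
            nr, nc = r + dr, c + dc
            if done[nr, nc]:
                continue
            nd = d + w
            if nd < dist[nr, nc]:
                dist[nr, nc] = nd
                prev[(nr, nc)] = (r, c)
                heapq.heappush(heap, (nd, nr, nc))
    if not np.isfinite(dist[target]):
        raise ValueError("target unreachable from seed")
    path = [target]
    while path[-1] != seed:
        path.append(prev[path[-1]])
    path.reverse()
    return path


def path_cost(cost_map: CostMap, path: list[tuple[int, int]]) -> float:
    """Cumulative link cost along an explicit 8-connected path."""
    total = 0.0
    offset_index = {off: k for k, off in enumerate(OFFSETS)}
    for (r0, c0), (r1, c1) in zip(path[:-1], path[1:]):
        k = offset_index[(r1 - r0, c1 - c0)]
        total += cost_map.link_costs[k, r0, c0]
    return float(total)


def _clean_chain(points: np.ndarray) -> np.ndarray:
    """Drop consecutive duplicates and immediate backtracks (p, q, p)."""
    pts = [tuple(p) for p in np.asarray(points, dtype=int)]
    out: list[tuple[int, int]] = []
    for p in pts:
        if out and p == out[-1]:
            continue
        if len(out) >= 2 and p == out[-2]:
            out.pop()
            continue
        out.append(p)
    return np.array(out, dtype=int)


@dataclass
class Contour:
    """Closed, ordered, simple pixel contour (row, col); last connects to first."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=int)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
            raise ValueError("a contour needs at least 3 (row, col) points")
        closed = np.vstack([pts, pts[:1]])
        steps = np.abs(np.diff(closed, axis=0)).max(axis=1)
        if (steps > 1).any() or (steps == 0).any():
            raise ValueError("consecutive contour points must be distinct and 8-adjacent")
        poly = Polygon([(c, r) for r, c in pts])
        if not poly.is_valid:
            raise ValueError("contour must be simple (non-self-intersecting)")
        self.points = pts

    def __len__(self) -> int:
        return len(self.points)

    @property
    def centroid(self) -> tuple[float, float]:
        return tuple(self.points.mean(axis=0))


def close_contour(segments: list[np.ndarray | list[tuple[int, int]]]) -> Contour:
    """Chain live-wire segments into one closed contour.

    Segments may be listed in any order and either orientation; they must
    share endpoints pairwise (no gaps).  Duplicate junction pixels are
    removed; the result must be simple.
    """
    segs = [np.asarray(s, dtype=int) for s in segments]
    if not segs or any(len(s) < 2 for s in segs):
        raise ValueError("need non-trivial segments to close a contour")
    remaining = list(range(1, len(segs)))
    chain = [tuple(p) for p in segs[0]]
    while remaining:
        for idx in list(remaining):
            s = segs[idx]
            first, last = tuple(s[0]), tuple(s[-1])
            if first == chain[-1]:
                chain.extend(tuple(p) for p in s[1:])
            elif last == chain[-1]:
                chain.extend(tuple(p) for p in s[-2::-1])
            else:
                continue
            remaining.remove(idx)
            break
        else:
            raise ValueError("segments do not chain: disconnected endpoints")
    if chain[-1] == chain[0]:
        chain.pop()
    pts = _clean_chain(np.array(chain))
    if max(abs(pts[-1][0] - pts[0][0]), abs(pts[-1][1] - pts[0][1])) > 1:
        raise ValueError("chained segments do not close (gap between last and first point)")
    return Contour(points=pts)


def contour_to_mask(contour: Contour, image_shape: tuple[int, int]) -> np.ndarray:
    """Rasterize: pixels strictly inside or on the contour are True."""
    mask = np.zeros(image_shape, dtype=bool)
    rr, cc = draw_polygon(contour.points[:, 0], contour.points[:, 1], image_shape)
    mask[rr, cc] = True
    pts = contour.points
    inside = (
        (pts[:, 0] >= 0)
        & (pts[:, 0] < image_shape[0])
        & (pts[:, 1] >= 0)
        & (pts[:, 1] < image_shape[1])
    )
    mask[pts[inside, 0], pts[inside, 1]] = True
    return mask


def trace_contour(
    image: np.ndarray,
    seeds: list[tuple[int, int]],
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
    sigma: float = 1.0,
) -> Contour:
    """Full semiautomatic delineation: live-wire between consecutive seeds.

    The boundary is traced seed_0 -> seed_1 -> ... -> seed_{n-1} -> seed_0
    and closed.  Seeds should sit on (or very near) the desired edge.
    """
    if len(seeds) < 3:
        raise ValueError("need at least 3 seed points to delineate a closed boundary")
    cm = build_cost_map(image, weights=weights, sigma=sigma)
    segments = []
    for a, b in zip(seeds, seeds[1:] + seeds[:1]):
        segments.append(np.array(live_wire_path(cm, tuple(a), tuple(b))))
    return close_contour(segments)
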