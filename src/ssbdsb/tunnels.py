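"""Surface-tunnel detection on the Voronoi diagram of a protein's atom spheres.

A tunnel (cleft) is a path of empty space from a buried interior point to the
protein surface. We follow the channel-finding approach of CAVER-style tools:
Voronoi vertices of the atom centers are locally maximal-clearance positions;
edges between Voronoi-adjacent vertices are weighted by a clearance-penalised
length, and least-cost paths from a deep start vertex to surface exits become
tunnel centerlines. Each tunnel carries three indexes:

* **length** — arc length of the centerline polyline (Å),
* **curvature** — length / straight-line start-to-end distance (≥ 1),
* **bottleneck radius** — the smallest clearance sphere along the centerline,
  i.e. the radius of the largest ball that can pass through the tunnel.

The "largest" tunnel of a protein is the one maximising
``length × bottleneck_radius``; its indexes feed the feature vector used to
discriminate single- from double-stranded DNA binders.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import ConvexHull, QhullError, Voronoi, cKDTree

from .structure_io import ProteinChain

logger = logging.getLogger(__name__)


class GeometryError(ValueError):
    """Raised when the input geometry is too small or degenerate."""


@dataclass(frozen=True)
class ClearanceSphere:
    center: tuple[float, float, float]
    clearance: float

    def __post_init__(self) -> None:
        if self.clearance < 0:
            raise ValueError("negative clearance")


@dataclass(frozen=True)
class Tunnel:
    """One detected tunnel: ordered centerline plus derived indexes.

    ``curvature`` is NaN (the undefined sentinel) when the endpoints
    coincide; such tunnels are excluded from largest-tunnel selection.
    """

    id: int
    length: float
    curvature: float
    bottleneck_radius: float
    distance: float = float("nan")
    centerline: tuple[ClearanceSphere, ...] = ()

    def __post_init__(self) -> None:
        if self.centerline:
            bn = min(s.clearance for s in self.centerline)
            if abs(bn - self.bottleneck_radius) > 1e-9:
                raise ValueError("bottleneck_radius is not the centerline minimum")

    @property
    def selection_key(self) -> float:
        return self.length * self.bottleneck_radius


@dataclass(frozen=True)
class TunnelSet:
    tunnels: tuple[Tunnel, ...]
    parameters: "TunnelParams | None" = None

    def __post_init__(self) -> None:
        ids = [t.id for t in self.tunnels]
        if ids != list(range(1, len(ids) + 1)):
            raise ValueError("tunnel ids must be contiguous from 1")

    def __len__(self) -> int:
        return len(self.tunnels)

    def __iter__(self):
        return iter(self.tunnels)


@dataclass(frozen=True)
class TunnelParams:
    """Detection configuration.

    probe_radius: clearance a vertex needs to count as a surface exit (Å).
    burial_depth: erosion depth of the atom-center convex hull; vertices
        deeper than this are "buried" start candidates, shallower ones can
        be exits (Å).
    outside_margin: vertices farther outside the hull than this are dropped
        from the search graph (Å).
    min_bottleneck: tunnels narrower than this are discarded (a
        water-molecule-sized passability probe, Å).
    step: centerline resampling step (Å).
    cost_exponent: edge cost is d / min(clearance)^cost_exponent.
    exit_cluster_dist: exits whose truncated endpoints are closer than this
        collapse to one tunnel (Å).
    centerline_cluster_dist: tunnels whose centerlines stay closer than this
        on average also collapse (Å).
    smooth_window: odd moving-average window applied to the raw vertex
        polyline before resampling (suppresses Voronoi zigzag).
    start_point: optional user-supplied start coordinate overriding the
        automatic deepest-vertex rule.
    """

    probe_radius: float = 3.0
    burial_depth: float = 4.0
    shell_depth: float = 2.0
    outside_margin: float = 6.0
    min_bottleneck: float = 0.9
    step: float = 0.5
    cost_exponent: float = 2.0
    exit_cluster_dist: float = 5.0
    centerline_cluster_dist: float = 3.0
    smooth_window: int = 5
    max_tunnels: int = 50
    start_point: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        for name in ("probe_radius", "burial_depth", "outside_margin", "step"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ValueError("smooth_window must be odd and >= 1")


@dataclass
class ClearanceGraph:
    """Positive-clearance Voronoi vertices + adjacency of a chain."""

    vertices: np.ndarray        # (n, 3)
    clearance: np.ndarray       # (n,)
    depth: np.ndarray           # (n,) signed hull depth, positive inside
    adjacency: csr_matrix       # symmetric edge costs
    open_boundary: np.ndarray | None = None  # (n,) cells extending to infinity

    def __len__(self) -> int:
        return len(self.vertices)


def point_clearance(points: np.ndarray, coords: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """Exact clearance min_i(|p - c_i| - r_i) for each point, chunked."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    out = np.empty(len(points))
    chunk = max(1, int(4e6 / max(len(coords), 1)))
    for lo in range(0, len(points), chunk):
        d = np.linalg.norm(points[lo:lo + chunk, None, :] - coords[None, :, :], axis=2)
        out[lo:lo + chunk] = (d - radii[None, :]).min(axis=1)
    return out


def hull_depth(points: np.ndarray, hull: ConvexHull) -> np.ndarray:
    """Signed depth inside the convex hull (positive inside, Å)."""
    eq = hull.equations  # A x + b <= 0 inside
    return -(points @ eq[:, :3].T + eq[:, 3]).max(axis=1)


def build_clearance_graph(chain: ProteinChain, params: TunnelParams | None = None) -> ClearanceGraph:
    """Voronoi clearance graph of a chain's atom spheres.

    Nodes are Voronoi vertices of the atom centers with positive clearance
    that lie within ``outside_margin`` of the atom-center convex hull; edges
    connect Voronoi-adjacent vertices with cost strictly decreasing in the
    edge's minimum clearance.
    """
    params = params or TunnelParams()
    coords = chain.coords
    radii = chain.radii
    if len(coords) < 4:
        raise GeometryError("need at least 4 atoms for a Voronoi diagram")
    try:
        vor = Voronoi(coords)
        hull = ConvexHull(coords)
    except QhullError as exc:
        raise GeometryError(f"degenerate atom geometry: {exc}") from exc

    verts = vor.vertices
    clear = point_clearance(verts, coords, radii)
    depth = hull_depth(verts, hull)
    keep = (clear > 0) & (depth > -params.outside_margin) & np.isfinite(verts).all(axis=1)
    index = -np.ones(len(verts), dtype=int)
    index[keep] = np.arange(keep.sum())

    pairs: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    open_boundary = np.zeros(int(keep.sum()), dtype=bool)
    for ridge in vor.ridge_vertices:
        m = len(ridge)
        if -1 in ridge:
            # endpoints of infinite Voronoi edges (polygon neighbours of -1)
            # sit on the structure's open boundary
            for k, v in enumerate(ridge):
                if v != -1:
                    continue
                for nb in (ridge[k - 1], ridge[(k + 1) % m]):
                    if nb >= 0 and index[nb] >= 0:
                        open_boundary[index[nb]] = True
        for k in range(m):
            a, b = ridge[k], ridge[(k + 1) % m]
            if a < 0 or b < 0:
                continue
            ia, ib = index[a], index[b]
            if ia < 0 or ib < 0 or ia == ib:
                continue
            key = (min(ia, ib), max(ia, ib))
            if key in seen:
                continue
            seen.add(key)
            pairs.append((a, b))

    n = int(keep.sum())
    rows, cols, costs = [], [], []
    if pairs:
        pa = np.array([p[0] for p in pairs])
        pb = np.array([p[1] for p in pairs])
        A, B = verts[pa], verts[pb]
        # an edge is only as wide as its narrowest interior point: sample
        # along the segment so edges squeezing between atoms get their true
        # (possibly non-positive) clearance
        edge_clear = np.minimum(clear[pa], clear[pb])
        for t in (1 / 6, 1 / 3, 0.5, 2 / 3, 5 / 6):
            edge_clear = np.minimum(edge_clear, point_clearance(A + t * (B - A), coords, radii))
        lengths = np.linalg.norm(A - B, axis=1)
        for (a, b), d, c in zip(pairs, lengths, edge_clear):
            if c <= 0:
                continue
            ia, ib = index[a], index[b]
            cost = (float(d) + 1e-12) / float(c) ** params.cost_exponent
            rows += [ia, ib]
            cols += [ib, ia]
            costs += [cost, cost]
    adj = csr_matrix((costs, (rows, cols)), shape=(n, n))
    vertices, clearance, depth_k = verts[keep], clear[keep], depth[keep]
    # isolated vertices floating outside the hull cannot carry a path;
    # dropping them leaves a fully occluded structure with an empty graph
    degree = np.asarray(adj.getnnz(axis=1))
    keep2 = (degree > 0) | (depth_k > 0)
    if not keep2.all():
        adj = adj[keep2][:, keep2]
        vertices, clearance = vertices[keep2], clearance[keep2]
        depth_k = depth_k[keep2]
        open_boundary = open_boundary[keep2]
    return ClearanceGraph(vertices, clearance, depth_k, adj, open_boundary)


def find_start_point(graph: ClearanceGraph, params: TunnelParams | None = None) -> int:
    """Index of the tunnel-search start vertex.

    The buried vertex (hull depth ≥ burial_depth) of maximal clearance;
    ties broken by lowest index. With no buried vertex, falls back to the
    maximal-clearance non-exit vertex with a logged warning. A user-supplied
    ``params.start_point`` snaps to the nearest graph vertex instead.
    """
    params = params or TunnelParams()
    if len(graph) == 0:
        raise GeometryError("empty clearance graph")
    if params.start_point is not None:
        return int(cKDTree(graph.vertices).query(np.asarray(params.start_point, float))[1])
    buried = graph.depth >= params.burial_depth
    if buried.any():
        cand = np.flatnonzero(buried)
    else:
        logger.warning("no vertex deeper than %.1f A; falling back to max clearance",
                       params.burial_depth)
        exits = _exit_mask(graph, params)
        cand = np.flatnonzero(~exits) if (~exits).any() else np.arange(len(graph))
    cmax = graph.clearance[cand].max()
    # clearances of nearby cavity vertices differ by less than atomic
    # position noise; resolve such near-ties toward the deepest vertex
    near = cand[graph.clearance[cand] >= cmax - 0.15]
    return int(near[np.argmax(graph.depth[near])])


def _exit_mask(graph: ClearanceGraph, params: TunnelParams) -> np.ndarray:
    """Surface exits: wide shallow vertices, or open-boundary vertices
    (endpoints of infinite Voronoi edges) within the surface shell."""
    wide = (graph.clearance > params.probe_radius) & (graph.depth < params.burial_depth)
    if graph.open_boundary is not None:
        wide = wide | (graph.open_boundary & (graph.depth < params.shell_depth))
    return wide


def _smooth_polyline(pts: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or len(pts) <= 2:
        return pts
    half = window // 2
    out = pts.copy()
    for i in range(1, len(pts) - 1):
        lo, hi = max(0, i - half), min(len(pts), i + half + 1)
        out[i] = pts[lo:hi].mean(axis=0)
    return out


def _resample_polyline(pts: np.ndarray, step: float) -> np.ndarray:
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    total = arclen[-1]
    if total < step:
        return pts[[0, -1]]
    n = int(np.floor(total / step)) + 1
    targets = np.linspace(0.0, total, n)
    res = np.empty((n, 3))
    for dim in range(3):
        res[:, dim] = np.interp(targets, arclen, pts[:, dim])
    return res


def compute_indexes(centerline: tuple[ClearanceSphere, ...]) -> tuple[float, float, float, float]:
    """(length, distance, curvature, bottleneck) of an ordered centerline.

    Curvature is NaN when the endpoints coincide (distance < 1e-9).
    """
    if len(centerline) < 2:
        raise ValueError("centerline needs at least 2 points")
    pts = np.array([s.center for s in centerline], dtype=float)
    length = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
    distance = float(np.linalg.norm(pts[-1] - pts[0]))
    curvature = length / distance if distance >= 1e-9 else float("nan")
    bottleneck = min(s.clearance for s in centerline)
    return length, distance, curvature, bottleneck


def detect_tunnels(chain: ProteinChain, params: TunnelParams | None = None) -> TunnelSet:
    """Detect tunnels of a chain and compute their indexes.

    Least-cost paths run from the start vertex to every reachable surface
    exit; each path is truncated at its first exit vertex, near-duplicate
    exits collapse to the lowest-cost representative, and the surviving
    centerlines are smoothed, resampled at ``params.step`` and annotated
    with exact clearances. Tunnels are sorted by descending
    ``length × bottleneck_radius`` and numbered from 1.
    """
    params = params or TunnelParams()
    try:
        graph = build_clearance_graph(chain, params)
    except GeometryError:
        raise
    if len(graph) == 0:
        logger.info("no positive-clearance vertex: returning empty tunnel set")
        return TunnelSet((), params)

    start = find_start_point(graph, params)
    dist, pred = dijkstra(graph.adjacency, indices=start, return_predecessors=True)
    exits = _exit_mask(graph, params)
    reachable = np.flatnonzero(exits & np.isfinite(dist))
    reachable = reachable[reachable != start]
    if len(reachable) == 0:
        logger.info("no surface exit reachable from start vertex")
        return TunnelSet((), params)
    order = reachable[np.argsort(dist[reachable], kind="stable")]

    coords, radii = chain.coords, chain.radii
    hull = ConvexHull(coords)
    accepted_pts: list[np.ndarray] = []
    accepted_ends: list[np.ndarray] = []
    tunnels: list[Tunnel] = []
    seen_ends: set[int] = set()
    for exit_idx in order:
        if len(tunnels) >= params.max_tunnels:
            break
        path = _walk_back(pred, start, int(exit_idx))
        if path is None or len(path) < 2:
            continue
        # truncate at the first exit vertex along the path
        for j, v in enumerate(path):
            if exits[v] and j > 0:
                path = path[: j + 1]
                break
        end_vertex = path[-1]
        if end_vertex in seen_ends:
            continue
        seen_ends.add(end_vertex)
        # an open-boundary arrival vertex is an arbitrary surface-cell
        # corner (often squeezed against a surface atom); end the
        # centerline just inside instead
        wide_end = graph.clearance[end_vertex] > params.probe_radius
        if not wide_end and len(path) > 2:
            path = path[:-1]
        pts = graph.vertices[path]
        end = pts[-1]
        if any(np.linalg.norm(end - e) < params.exit_cluster_dist for e in accepted_ends):
            continue
        if any(_mean_centerline_dist(pts, p) < params.centerline_cluster_dist
               for p in accepted_pts):
            continue
        smooth = _smooth_polyline(pts, params.smooth_window)
        res = _resample_polyline(smooth, params.step)
        clear = point_clearance(res, coords, radii)
        if (clear <= 0).any():
            # smoothing pushed the line into an atom; fall back to raw
            res = _resample_polyline(pts, params.step)
            clear = np.maximum(point_clearance(res, coords, radii), 0.0)
        # the rim itself (inside the surface shell) is not part of the
        # channel: Voronoi vertices there hug surface atoms and would fake
        # the bottleneck, so the centerline ends at the shell boundary
        res_depth = hull_depth(res, hull)
        deep = np.flatnonzero(res_depth >= params.shell_depth)
        if len(deep) >= 2 and deep[-1] >= 1:
            res = res[: deep[-1] + 1]
            clear = clear[: deep[-1] + 1]
        spheres = tuple(ClearanceSphere(tuple(p), float(c)) for p, c in zip(res, clear))
        if len(spheres) < 4:
            # sub-step-scale path: a surface dimple, not a channel
            continue
        length, distance, curvature, bottleneck = compute_indexes(spheres)
        if bottleneck < params.min_bottleneck:
            # narrower than a water-sized probe: not a passable channel
            continue
        accepted_pts.append(pts)
        accepted_ends.append(end)
        tunnels.append(Tunnel(0, length, curvature, bottleneck, distance, spheres))

    tunnels.sort(key=lambda t: (-t.selection_key, t.length))
    numbered = tuple(
        Tunnel(i + 1, t.length, t.curvature, t.bottleneck_radius, t.distance, t.centerline)
        for i, t in enumerate(tunnels)
    )
    return TunnelSet(numbered, params)


def _walk_back(pred: np.ndarray, start: int, end: int) -> list[int] | None:
    path = [end]
    while path[-1] != start:
        p = pred[path[-1]]
        if p < 0:
            return None
        path.append(int(p))
    return path[::-1]


def _mean_centerline_dist(a: np.ndarray, b: np.ndarray, n: int = 20) -> float:
    ra = _resample_polyline(a, max(_polyline_len(a) / n, 1e-6))
    tree = cKDTree(b)
    return float(tree.query(ra)[0].mean())


def _polyline_len(pts: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def select_largest_tunnel(tunnels: TunnelSet) -> Tunnel:
    """The tunnel maximising length × bottleneck radius.

    NaN-curvature (degenerate) tunnels are excluded; ties break to the
    lower tunnel id.
    """
    candidates = [t for t in tunnels if np.isfinite(t.curvature)]
    if not candidates:
        raise GeometryError("no tunnel with defined curvature to select from")
    return max(candidates, key=lambda t: (t.selection_key, -t.id))


def write_tunnel_profile(tunnels: TunnelSet, path) -> None:
    """Tunnel index table as TSV: id, bottleneck radius, length, curvature."""
    with open(path, "w") as fh:
        fh.write("tunnel\tbottleneck_radius\tlength\tcurvature\n")
        for t in tunnels:
            fh.write(f"{t.id}\t{t.bottleneck_radius:.2f}\t{t.length:.2f}\t{t.curvature:.2f}\n")


def read_tunnel_profile(path) -> TunnelSet:
    """Read a tunnel index TSV (as written by :func:`write_tunnel_profile`)."""
    tunnels = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "tunnel")):
                continue
            try:
                tid, bn, ln, cv = line.split("\t")
                tunnels.append(Tunnel(int(tid), float(ln), float(cv), float(bn)))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed tunnel row") from exc
    tunnels.sort(key=lambda t: t.id)
    return TunnelSet(tuple(tunnels))


def load_1a73_profile() -> TunnelSet:
    """The 27-tunnel CAVER 3.0 index profile of PDB entry 1A73.

    Bundled as package data; the classic worked example for the
    largest-tunnel criterion (tunnel 25 wins with 62.01 × 0.74).
    """
    ref = importlib.resources.files("ssbdsb.data") / "tunnels_1a73.tsv"
    with importlib.resources.as_file(ref) as p:
        return read_tunnel_profile(p)
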