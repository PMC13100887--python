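"""Movement graphs over resistance surfaces and pairwise landscape distances.

A resistance surface becomes an undirected graph with one node per traversable
cell and edges between 8- (or 4-) neighbours.  Edge conductance is the mean of
the two cell conductances (1/resistance) divided by the centre-to-centre
distance, so diagonal steps are geometrically corrected.  Two distances are
computed between georeferenced points:

* least-cost-path (LCP) distance — the minimal cumulative cost (sum of
  1/conductance along a route), the single best corridor;
* commute distance — the expected number of steps of a random walk from one
  point to the other and back, ``2 * (total edge conductance) * R_eff`` with
  the effective resistance obtained from sparse solves on the graph Laplacian.
  The random walk integrates over *all* routes, not just the best one.

For commute/passage computations an optional epsilon repair adds a small
conductance between every pair of adjacent traversable cells so that isolated
clusters created by high-resistance mosaics do not disconnect the graph; LCP
never uses the repair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.sparse.linalg import factorized
from scipy.spatial import distance_matrix as _euclid_matrix

from .resistance import GridError, ResistanceSurface

# deterministic neighbour ordering: N, NE, E, SE, S, SW, W, NW
NEIGHBOURS_8 = ((-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1))
NEIGHBOURS_4 = ((-1, 0), (0, 1), (1, 0), (0, -1))


class ConnectivityError(RuntimeError):
    pass


@dataclass
class TransitionGraph:
    """Sparse conductance graph over the traversable cells of a surface."""

    conductance: sparse.csr_matrix  # symmetric, node x node
    node_rc: np.ndarray  # (n_nodes, 2) row/col of each node
    node_index: np.ndarray  # grid of node ids, -1 on barriers
    resolution: float
    origin: tuple[float, float]
    neighbours: int = 8
    epsilon: float = 0.0

    @property
    def n_nodes(self) -> int:
        return self.node_rc.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.node_index.shape

    def total_conductance(self) -> float:
        """Sum of edge conductances, each undirected edge counted once."""
        return float(self.conductance.sum()) / 2.0

    def node_at(self, row: int, col: int) -> int:
        return int(self.node_index[row, col])

    def cell_center(self, node: int) -> tuple[float, float]:
        r, c = self.node_rc[node]
        x0, y0 = self.origin
        return (x0 + (c + 0.5) * self.resolution, y0 - (r + 0.5) * self.resolution)


def build_transition_graph(
    rs: ResistanceSurface,
    epsilon: float = 0.0,
    neighbours: int = 8,
) -> TransitionGraph:
    """Convert a resistance surface into a conductance graph.

    Edge conductance between traversable neighbours i, j is
    ``((1/r_i + 1/r_j) / 2) / d`` with d the centre distance; ``epsilon > 0``
    adds a constant to every adjacent traversable pair's conductance.
    """
    if neighbours not in (4, 8):
        raise ValueError("neighbours must be 4 or 8")
    offsets = NEIGHBOURS_8 if neighbours == 8 else NEIGHBOURS_4
    trav = ~rs.barrier
    nr, nc = rs.shape
    node_index = np.full((nr, nc), -1, dtype=np.int64)
    rr, cc = np.nonzero(trav)
    node_index[rr, cc] = np.arange(rr.size)
    node_rc = np.column_stack([rr, cc])
    cond = 1.0 / rs.resistance  # nan on barriers, never dereferenced there

    rows, cols, data = [], [], []
    for dr, dc in offsets:
        # build each directed offset once; matrix symmetrised below by
        # including every offset pair (offsets contain both directions)
        r0s, r0e = max(0, -dr), min(nr, nr - dr)
        c0s, c0e = max(0, -dc), min(nc, nc - dc)
        src = node_index[r0s:r0e, c0s:c0e]
        dst = node_index[r0s + dr : r0e + dr, c0s + dc : c0e + dc]
        ok = (src >= 0) & (dst >= 0)
        if not ok.any():
            continue
        d = rs.resolution * (np.hypot(dr, dc))
        ci = cond[r0s:r0e, c0s:c0e][ok]
        cj = cond[r0s + dr : r0e + dr, c0s + dc : c0e + dc][ok]
        w = (ci + cj) / 2.0 / d + epsilon
        rows.append(src[ok])
        cols.append(dst[ok])
        data.append(w)
    n = node_rc.shape[0]
    if rows:
        mat = sparse.coo_matrix(
            (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n),
        ).tocsr()
    else:
        mat = sparse.csr_matrix((n, n))
    return TransitionGraph(mat, node_rc, node_index, rs.resolution, rs.origin, neighbours, epsilon)


def snap_points(
    g: TransitionGraph,
    points: pd.DataFrame,
    max_cells: float = 3.0,
) -> np.ndarray:
    """Snap (id, x, y) points to their nearest traversable cell's node.

    Raises if a point's containing cell neighbourhood has no traversable cell
    within ``max_cells`` cell widths of the point.
    """
    x0, y0 = g.origin
    centers_x = x0 + (g.node_rc[:, 1] + 0.5) * g.resolution
    centers_y = y0 - (g.node_rc[:, 0] + 0.5) * g.resolution
    nodes = np.empty(len(points), dtype=np.int64)
    for i, (pid, px, py) in enumerate(zip(points["id"], points["x"], points["y"])):
        d2 = (centers_x - px) ** 2 + (centers_y - py) ** 2
        j = int(np.argmin(d2))
        if d2[j] > (max_cells * g.resolution) ** 2:
            raise ConnectivityError(
                f"point {pid!r} is more than {max_cells} cells from any traversable cell"
            )
        nodes[i] = j
    return nodes


@dataclass
class PairwiseDistanceMatrix:
    """Symmetric individual-by-individual distance matrix of one kind."""

    kind: str  # genetic | euclidean | lcp | commute
    ids: list[str]
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path, kind: str) -> "PairwiseDistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(kind, [str(i) for i in df.index], df.to_numpy())


@dataclass
class PathSet:
    """One least-cost route per point pair: ordered cells and total cost."""

    ids: list[str]
    paths: dict[tuple[str, str], list[tuple[int, int]]] = field(default_factory=dict)
    costs: dict[tuple[str, str], float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (a, b), cells in self.paths.items():
            for step, (r, c) in enumerate(cells):
                rows.append({"id_a": a, "id_b": b, "step": step, "row": r, "col": c})
        return pd.DataFrame(rows)

    def to_geojson(self, g: TransitionGraph) -> dict:
        feats = []
        for (a, b), cells in self.paths.items():
            coords = [list(g.cell_center(g.node_index[r, c])) for r, c in cells]
            feats.append(
                {
                    "type": "Feature",
                    "properties": {"id_a": a, "id_b": b, "cost": self.costs[(a, b)]},
                    "geometry": {"type": "LineString", "coordinates": coords},
                }
            )
        return {"type": "FeatureCollection", "features": feats}


def _cost_matrix(g: TransitionGraph) -> sparse.csr_matrix:
    m = g.conductance.tocoo()
    return sparse.csr_matrix((1.0 / m.data, (m.row, m.col)), shape=m.shape)


def lcp_distance(
    g: TransitionGraph,
    points: pd.DataFrame,
    return_paths: bool = False,
) -> PairwiseDistanceMatrix | tuple[PairwiseDistanceMatrix, PathSet]:
    """Least-cost-path distances (and optionally explicit routes).

    Step cost is 1/conductance; disconnected pairs get ``inf`` with a warning.
    Route traceback breaks ties deterministically, scanning neighbours in the
    order N, NE, E, SE, S, SW, W, NW.
    """
    ids = [str(i) for i in points["id"]]
    nodes = snap_points(g, points)
    cost = _cost_matrix(g)
    dist_all = dijkstra(cost, directed=False, indices=nodes)
    vals = dist_all[:, nodes]
    vals = (vals + vals.T) / 2.0  # symmetrise exact ties of float error
    np.fill_diagonal(vals, 0.0)
    if np.isinf(vals).any():
        warnings.warn("some point pairs are disconnected; LCP distance is inf")
    pdm = PairwiseDistanceMatrix("lcp", ids, vals, units="cost*m")
    if not return_paths:
        return pdm

    offsets = NEIGHBOURS_8 if g.neighbours == 8 else NEIGHBOURS_4
    ps = PathSet(ids)
    for i in range(len(ids)):
        d_from_i = dist_all[i]
        for j in range(i + 1, len(ids)):
            if np.isinf(vals[i, j]):
                continue
            # walk back from j towards i along optimal predecessors
            cur = int(nodes[j])
            cells = [tuple(g.node_rc[cur])]
            guard = g.n_nodes + 1
            while cur != nodes[i] and guard:
                guard -= 1
                r, c = g.node_rc[cur]
                best = None
                for dr, dc in offsets:
                    rr, cc = r + dr, c + dc
                    if not (0 <= rr < g.shape[0] and 0 <= cc < g.shape[1]):
                        continue
                    nb = g.node_index[rr, cc]
                    if nb < 0:
                        continue
                    w = cost[cur, nb]
                    if w == 0:
                        continue
                    if np.isclose(d_from_i[nb] + w, d_from_i[cur], rtol=1e-9, atol=1e-9):
                        best = int(nb)
                        break
                if best is None:
                    raise ConnectivityError("path traceback failed")
                cur = best
                cells.append(tuple(g.node_rc[cur]))
            cells.reverse()
            ps.paths[(ids[i], ids[j])] = [(int(r), int(c)) for r, c in cells]
            ps.costs[(ids[i], ids[j])] = float(vals[i, j])
    return pdm, ps


def _restrict_to_component(g: TransitionGraph, nodes: np.ndarray):
    """Restrict the graph to the component holding ``nodes``.

    Barrier cells can wall off regions that no epsilon repair reconnects;
    random-walk quantities are then defined on the points' own component.
    Raises if the points span more than one component.
    """
    ncomp, labels = connected_components(g.conductance, directed=False)
    if ncomp == 1:
        return g.conductance, np.arange(g.n_nodes), nodes
    comps = set(labels[nodes])
    if len(comps) > 1:
        raise ConnectivityError(
            "points fall in disconnected regions of the surface; no epsilon "
            "repair can join regions separated by absolute barriers"
        )
    comp = comps.pop()
    keep = np.nonzero(labels == comp)[0]
    remap = -np.ones(g.n_nodes, dtype=np.int64)
    remap[keep] = np.arange(keep.size)
    sub = g.conductance[keep][:, keep]
    return sub, keep, remap[nodes]


def _laplacian_solver(conductance: sparse.spmatrix, ground: int):
    """Factorised solver for the Laplacian with one grounded node removed."""
    c = conductance.tocsc()
    n = c.shape[0]
    deg = np.asarray(c.sum(axis=1)).ravel()
    lap = sparse.diags(deg) - c
    keep = np.ones(n, dtype=bool)
    keep[ground] = False
    lap_g = lap[keep][:, keep].tocsc()
    solve = factorized(lap_g)
    idx = np.cumsum(keep) - 1  # node -> reduced index (ground invalid)
    return solve, keep, idx


def commute_distance(g: TransitionGraph, points: pd.DataFrame) -> PairwiseDistanceMatrix:
    """Random-walk commute distances between points, in expected steps.

    ``C_ij = 2 * m * R_eff(i, j)`` with m the total edge conductance of the
    points' connected component and the effective resistance from one sparse
    Laplacian solve per source point.
    """
    ids = [str(i) for i in points["id"]]
    raw_nodes = snap_points(g, points)
    cond, _, nodes = _restrict_to_component(g, raw_nodes)
    ground = int(nodes[0])
    solve, keep, idx = _laplacian_solver(cond, ground)
    n_pts = len(ids)
    # potentials[k] solves L x = e_{node_k} with the ground node removed
    pots = {}
    for k in range(n_pts):
        if nodes[k] == ground:
            continue
        b = np.zeros(keep.sum())
        b[idx[nodes[k]]] = 1.0
        pots[k] = solve(b)
    vals = np.zeros((n_pts, n_pts))
    two_m = float(cond.sum())  # each undirected edge counted twice, x2 for commute
    for i in range(n_pts):
        for j in range(i + 1, n_pts):
            ni, nj = int(nodes[i]), int(nodes[j])
            if ni == nj:
                reff = 0.0
            elif ni == ground:
                reff = pots[j][idx[nj]]
            elif nj == ground:
                reff = pots[i][idx[ni]]
            else:
                reff = (
                    pots[i][idx[ni]]
                    + pots[j][idx[nj]]
                    - pots[i][idx[nj]]
                    - pots[j][idx[ni]]
                )
            vals[i, j] = vals[j, i] = two_m * reff
    return PairwiseDistanceMatrix("commute", ids, vals, units="expected steps")


@dataclass
class PassageMap:
    """Per-cell expected net random-walk passages, averaged over pairs."""

    values: np.ndarray  # grid, 0 on barriers
    resolution: float
    origin: tuple[float, float]


def passage_map(g: TransitionGraph, points: pd.DataFrame, pairs=None) -> PassageMap:
    """Expected net passages through each cell for the absorbing walk between
    each origin-destination pair, averaged over the supplied pairs.

    For unit current injected at the origin and extracted at the destination,
    a cell's net passage is half the sum of absolute net currents on its
    incident edges; interior cells of a single corridor carry 1.
    """
    ids = [str(i) for i in points["id"]]
    raw_nodes = snap_points(g, points)
    cond, keep_nodes, nodes = _restrict_to_component(g, raw_nodes)
    if pairs is None:
        pairs = [(i, j) for i in range(len(ids)) for j in range(i + 1, len(ids))]
    coo = cond.tocoo()
    n_sub = cond.shape[0]
    ground = 0
    solve, keep, idx = _laplacian_solver(cond, ground)
    acc = np.zeros(n_sub)
    n_used = 0
    for i, j in pairs:
        ni, nj = int(nodes[i]), int(nodes[j])
        if ni == nj:
            continue
        b = np.zeros(keep.sum())
        if ni != ground:
            b[idx[ni]] += 1.0
        if nj != ground:
            b[idx[nj]] -= 1.0
        v = np.zeros(n_sub)
        v[keep] = solve(b)
        flow = coo.data * (v[coo.row] - v[coo.col])
        node_flow = np.zeros(n_sub)  # sum of |net current| over incident edges
        np.add.at(node_flow, coo.row, np.abs(flow))
        acc += node_flow / 2.0  # a unit passage enters and leaves a cell once each
        n_used += 1
    if n_used == 0:
        raise ConnectivityError("no distinct pairs to average over")
    grid = np.zeros(g.shape)
    rc = g.node_rc[keep_nodes]
    grid[rc[:, 0], rc[:, 1]] = acc / n_used
    return PassageMap(grid, g.resolution, g.origin)


def euclidean_distance(points: pd.DataFrame) -> PairwiseDistanceMatrix:
    """Straight-line distances in metres between projected points."""
    ids = [str(i) for i in points["id"]]
    xy = points[["x", "y"]].to_numpy(dtype=float)
    return PairwiseDistanceMatrix("euclidean", ids, _euclid_matrix(xy, xy), units="m")
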