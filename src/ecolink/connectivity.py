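"""Corridor and connectivity analysis on a resistance raster.

The resistance raster is turned into an 8-neighbour lattice graph: one node
per valid cell, edge cost = mean of the two cell resistances × centre-to-
centre distance (×√2 for diagonals).  On this graph the module computes

- cost-weighted distance (CWD) fields from source patches (multi-source
  Dijkstra, patch cells at CWD 0) and least-cost paths (LCPs) between patch
  pairs by predecessor backtracking;
- corridor swaths — cells where ``CWD_A + CWD_B − lcp_cost`` is below a
  threshold — and fixed-width buffered LCPs;
- circuit-theory current maps: each cell is a resistor network node with
  edge conductance = 1/edge cost; injecting 1 A between two patches
  (collapsed to supernodes) and solving the Kirchhoff/Laplacian system
  yields per-cell current density and the effective resistance between the
  patches.  Pinch points are high-current cells inside corridor swaths;
- current-flow centrality of the coarse source network (nodes = patches,
  link resistance = corridor LCP cost), accumulated over all-pairs unit
  injections;
- barrier detection by a moving-window restoration scan: lowering a window
  to the landscape's minimum resistance and measuring the least-cost
  improvement per metre of window diameter;
- corridor prioritization: quantile levels of improvement potential and
  current-based priority, cross-tabulated into the L/M/H/V composite labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse import csgraph
from scipy.sparse.linalg import spsolve
from shapely.geometry import LineString

from .grid import RasterGrid, quantile_classify
from .sources import SourcePatch

log = logging.getLogger(__name__)

__all__ = [
    "CostGraph",
    "CorridorRecord",
    "CurrentSolution",
    "BarrierResult",
    "PinchPoint",
    "cost_weighted_distance",
    "least_cost_corridors",
    "circuit_solve",
    "current_centrality",
    "pinch_points",
    "barrier_scan",
    "composite_priority",
    "quantile_levels",
]

LEVELS = ("L", "M", "H", "V")
_SQRT2 = float(np.sqrt(2.0))
_NO_PRED = -9999


class CostGraph:
    """8-neighbour lattice graph over the valid cells of a resistance raster."""

    def __init__(self, resistance: RasterGrid):
        res = resistance.values.astype(float)
        valid = resistance.valid_mask & np.isfinite(res)
        if np.any(res[valid] <= 0):
            raise ValueError("resistance must be positive on valid cells")
        self.resistance = resistance
        self.valid = valid
        nrow, ncol = resistance.shape
        self.shape = (nrow, ncol)
        self.cell_size = resistance.cell_size

        self.node_of = np.full((nrow, ncol), -1, dtype=np.int64)
        rows, cols = np.nonzero(valid)
        self.n_nodes = rows.size
        self.node_of[rows, cols] = np.arange(self.n_nodes)
        self.cells = np.stack([rows, cols], axis=1)  # node -> (row, col)

        ei, ej, ec = [], [], []
        offsets = [(0, 1, 1.0), (1, 0, 1.0), (1, 1, _SQRT2), (1, -1, _SQRT2)]
        for dr, dc, mult in offsets:
            r0 = slice(max(0, -dr), nrow - max(0, dr))
            c0 = slice(max(0, -dc), ncol - max(0, dc))
            r1 = slice(max(0, dr), nrow + min(0, dr))
            c1 = slice(max(0, dc), ncol + min(0, dc))
            ok = valid[r0, c0] & valid[r1, c1]
            a = self.node_of[r0, c0][ok]
            b = self.node_of[r1, c1][ok]
            cost = 0.5 * (res[r0, c0][ok] + res[r1, c1][ok]) * self.cell_size * mult
            ei.append(a)
            ej.append(b)
            ec.append(cost)
        self.edge_i = np.concatenate(ei) if ei else np.empty(0, dtype=np.int64)
        self.edge_j = np.concatenate(ej) if ej else np.empty(0, dtype=np.int64)
        self.edge_cost = np.concatenate(ec) if ec else np.empty(0, dtype=float)

        n = self.n_nodes
        self.costs = sparse.coo_matrix(
            (self.edge_cost, (self.edge_i, self.edge_j)), shape=(n, n)
        ).tocsr()
        self.costs = self.costs + self.costs.T  # symmetric
        self.min_resistance = float(res[valid].min()) if self.n_nodes else np.nan

    # conductance view for circuit analysis
    @property
    def edge_conductance(self) -> np.ndarray:
        return 1.0 / self.edge_cost

    def nodes_of_mask(self, mask: np.ndarray) -> np.ndarray:
        nodes = self.node_of[np.asarray(mask, dtype=bool)]
        return nodes[nodes >= 0]

    def grid_from_nodes(self, values: np.ndarray, fill=np.nan) -> RasterGrid:
        out = np.full(self.shape, fill, dtype=float)
        out[self.cells[:, 0], self.cells[:, 1]] = values
        return self.resistance.with_values(out, ~self.valid)


@dataclass
class CorridorRecord:
    """One source-pair corridor and its prioritization attributes."""

    source_a: int
    source_b: int
    path_cells: list[tuple[int, int]]
    polyline: LineString
    lcp_cost: float
    length_km: float
    swath_mask: np.ndarray
    buffer_mask: np.ndarray
    centrality: float = float("nan")
    improvement_score: float = float("nan")
    priority_score: float = float("nan")
    improvement_level: str | None = None
    priority_level: str | None = None

    @property
    def pair(self) -> tuple[int, int]:
        return (self.source_a, self.source_b)


@dataclass
class CurrentSolution:
    """Result of one pairwise circuit solve."""

    current: RasterGrid          # per-cell current density
    effective_resistance: float  # potential difference per unit injected current
    potentials: np.ndarray       # per-node potentials (ground = patch B)
    kcl_residual: float          # max |net current| at non-terminal nodes


@dataclass
class BarrierResult:
    """A restoration window: centre cell, radius (m), improvement score per m."""

    cell: tuple[int, int]
    radius_m: float
    score: float
    pair: tuple[int, int]


@dataclass
class PinchPoint:
    """A high-current corridor cell whose loss would cut connectivity."""

    cell: tuple[int, int]
    score: float
    rank: int


# -- cost-weighted distance and corridors -----------------------------------


def cost_weighted_distance(
    graph: CostGraph, patch: SourcePatch, return_predecessors: bool = False
):
    """Multi-source least-cost distance from all patch cells (patch at CWD 0)."""
    src = graph.nodes_of_mask(patch.mask)
    if src.size == 0:
        raise ValueError(f"source patch {patch.id} has no valid cells on the grid")
    if return_predecessors:
        dist, pred, _ = csgraph.dijkstra(
            graph.costs, directed=False, indices=src, min_only=True,
            return_predecessors=True,
        )
        return graph.grid_from_nodes(dist), dist, pred
    dist = csgraph.dijkstra(graph.costs, directed=False, indices=src, min_only=True)
    return graph.grid_from_nodes(dist), dist


def _backtrack(pred: np.ndarray, node: int) -> list[int]:
    path = [node]
    while pred[path[-1]] != _NO_PRED:
        path.append(int(pred[path[-1]]))
    return path


def _polyline_of(graph: CostGraph, nodes: list[int]) -> LineString:
    cs = graph.cell_size
    x0, y0 = graph.resistance.origin
    pts = [
        (x0 + (graph.cells[n, 1] + 0.5) * cs, y0 - (graph.cells[n, 0] + 0.5) * cs)
        for n in nodes
    ]
    return LineString(pts)


def default_swath_threshold(graph: CostGraph, width_m: float = 1000.0) -> float:
    """Swath cost threshold targeting a corridor of roughly ``width_m``.

    Stepping half the corridor width off the optimal path and back on the
    lattice adds about ``2(√2−1) · width/2`` metres of travel at the most
    permeable resistance, so that detour cost is used as the cutoff.
    """
    return 2.0 * (_SQRT2 - 1.0) * (width_m / 2.0) * graph.min_resistance


def least_cost_corridors(
    graph: CostGraph,
    sources: list[SourcePatch],
    pairing: str = "adjacent",
    swath_threshold: float | None = None,
    corridor_width_m: float = 1000.0,
) -> tuple[list[CorridorRecord], dict[int, np.ndarray]]:
    """Least-cost corridors between source patches.

    ``pairing="adjacent"`` keeps each patch's mutually-nearest neighbour
    pairs plus every pair whose LCP does not cross a third patch;
    ``"all"`` keeps every reachable pair.  Returns the corridor records and
    the per-source CWD node arrays (reused by barrier/pinch-point stages).

    Unreachable pairs are excluded with a warning.
    """
    if len(sources) < 2:
        raise ValueError("need at least 2 source patches")
    if pairing not in ("adjacent", "all"):
        raise ValueError("pairing must be 'adjacent' or 'all'")
    if swath_threshold is None:
        swath_threshold = default_swath_threshold(graph, corridor_width_m)

    cwd: dict[int, np.ndarray] = {}
    pred: dict[int, np.ndarray] = {}
    for p in sources:
        _, dist, pr = cost_weighted_distance(graph, p, return_predecessors=True)
        cwd[p.id], pred[p.id] = dist, pr

    patch_nodes = {p.id: graph.nodes_of_mask(p.mask) for p in sources}
    occupied = np.full(graph.n_nodes, 0, dtype=int)  # node -> patch id (0 = none)
    for p in sources:
        occupied[patch_nodes[p.id]] = p.id

    # pair costs
    ids = [p.id for p in sources]
    cost_of: dict[tuple[int, int], float] = {}
    end_node: dict[tuple[int, int], int] = {}
    for a in sources:
        for b in sources:
            if b.id <= a.id:
                continue
            d = cwd[a.id][patch_nodes[b.id]]
            k = int(np.argmin(d))
            if not np.isfinite(d[k]):
                log.warning("sources %d and %d are disconnected; corridor skipped", a.id, b.id)
                continue
            cost_of[(a.id, b.id)] = float(d[k])
            end_node[(a.id, b.id)] = int(patch_nodes[b.id][k])

    # nearest neighbour of each patch by lcp cost
    nearest: dict[int, int] = {}
    for i in ids:
        best, best_c = None, np.inf
        for (a, b), c in cost_of.items():
            if i in (a, b) and c < best_c:
                best, best_c = (b if a == i else a), c
        if best is not None:
            nearest[i] = best

    records: list[CorridorRecord] = []
    for (a, b), c in sorted(cost_of.items()):
        path_nodes = _backtrack(pred[a], end_node[(a, b)])
        crosses_third = any(
            occupied[n] not in (0, a, b) for n in path_nodes
        )
        mutual = nearest.get(a) == b and nearest.get(b) == a
        if pairing == "adjacent" and crosses_third and not mutual:
            continue
        cells = [(int(graph.cells[n, 0]), int(graph.cells[n, 1])) for n in path_nodes]
        line = _polyline_of(graph, path_nodes)
        swath_nodes = cwd[a] + cwd[b] - c <= swath_threshold
        swath = np.zeros(graph.shape, dtype=bool)
        swath[graph.cells[swath_nodes, 0], graph.cells[swath_nodes, 1]] = True
        path_mask = np.zeros(graph.shape, dtype=bool)
        pr, pc = zip(*cells)
        path_mask[list(pr), list(pc)] = True
        dist_to_path = ndimage.distance_transform_edt(~path_mask, sampling=graph.cell_size)
        buffer_mask = (dist_to_path <= corridor_width_m / 2.0) & graph.valid
        records.append(CorridorRecord(
            source_a=a, source_b=b, path_cells=cells, polyline=line,
            lcp_cost=c, length_km=line.length / 1000.0,
            swath_mask=swath, buffer_mask=buffer_mask,
        ))
    return records, cwd


# -- circuit theory ----------------------------------------------------------


def circuit_solve(
    graph: CostGraph, patch_a: SourcePatch, patch_b: SourcePatch, injection: float = 1.0
) -> CurrentSolution:
    """Solve the Kirchhoff system for ``injection`` amps from patch A to B.

    Patches are collapsed to supernodes; per-cell current is half the sum of
    absolute currents on incident edges; effective resistance is the
    potential difference between the patches per amp injected.
    """
    na = graph.nodes_of_mask(patch_a.mask)
    nb = graph.nodes_of_mask(patch_b.mask)
    if na.size == 0 or nb.size == 0:
        raise ValueError("patch has no valid cells on the grid")
    if np.intersect1d(na, nb).size:
        raise ValueError("patches overlap")

    n = graph.n_nodes
    # contracted index: 0..m-1 free nodes, m = supernode A, ground = B
    role = np.zeros(n, dtype=np.int8)
    role[na] = 1
    role[nb] = 2
    free = np.nonzero(role == 0)[0]
    m = free.size
    cidx = np.full(n, -1, dtype=np.int64)
    cidx[free] = np.arange(m)
    cidx[na] = m
    GROUND = -1
    cidx[nb] = GROUND

    g = graph.edge_conductance
    ci, cj = cidx[graph.edge_i], cidx[graph.edge_j]
    keep = ci != cj  # intra-supernode edges carry no current
    ci, cj, ge = ci[keep], cj[keep], g[keep]

    rows, cols, vals = [], [], []
    # diagonal terms (including edges to ground)
    for a, b in ((ci, cj), (cj, ci)):
        ok = a != GROUND
        rows.append(a[ok]); cols.append(a[ok]); vals.append(ge[ok])
    # off-diagonal terms
    ok = (ci != GROUND) & (cj != GROUND)
    rows.append(ci[ok]); cols.append(cj[ok]); vals.append(-ge[ok])
    rows.append(cj[ok]); cols.append(ci[ok]); vals.append(-ge[ok])
    L = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(m + 1, m + 1),
    ).tocsc()

    b_vec = np.zeros(m + 1)
    b_vec[m] = injection
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", sparse.linalg.MatrixRankWarning)
        try:
            v = spsolve(L, b_vec)
        except Exception as exc:  # pragma: no cover - singular systems
            raise ValueError("singular circuit system (disconnected patches?)") from exc
    if not np.all(np.isfinite(v)):
        raise ValueError("circuit system is singular: patches are disconnected")

    potentials = np.zeros(n)
    potentials[free] = v[:m]
    potentials[na] = v[m]
    potentials[nb] = 0.0

    i_edge = g * (potentials[graph.edge_i] - potentials[graph.edge_j])
    node_current = np.zeros(n)
    np.add.at(node_current, graph.edge_i, np.abs(i_edge))
    np.add.at(node_current, graph.edge_j, np.abs(i_edge))
    node_current *= 0.5

    divergence = np.zeros(n)
    np.add.at(divergence, graph.edge_i, -i_edge)
    np.add.at(divergence, graph.edge_j, i_edge)
    residual = float(np.abs(divergence[role == 0]).max(initial=0.0))

    return CurrentSolution(
        current=graph.grid_from_nodes(node_current),
        effective_resistance=float(v[m]) / injection,
        potentials=potentials,
        kcl_residual=residual,
    )


def current_centrality(
    sources: list[SourcePatch], corridors: list[CorridorRecord]
) -> tuple[dict[int, float], dict[tuple[int, int], float]]:
    """Current-flow centrality of the coarse source network.

    Nodes are source patches; each corridor is a resistor equal to its LCP
    cost.  For every node pair in a connected component 1 A is injected and
    withdrawn; absolute currents through nodes and links accumulate into the
    centrality scores.  Corridor records get their ``centrality`` filled in.
    """
    if len(sources) < 2:
        raise ValueError("need at least 2 nodes for centrality")
    import networkx as nx

    G = nx.Graph()
    G.add_nodes_from(p.id for p in sources)
    for c in corridors:
        G.add_edge(c.source_a, c.source_b, resistance=c.lcp_cost, record=c)

    node_cent = {p.id: 0.0 for p in sources}
    link_cent = {c.pair: 0.0 for c in corridors}

    for comp in nx.connected_components(G):
        nodes = sorted(comp)
        if len(nodes) < 2:
            continue
        idx = {u: i for i, u in enumerate(nodes)}
        k = len(nodes)
        L = np.zeros((k, k))
        edges = []
        for u, v, data in G.subgraph(comp).edges(data=True):
            g = 1.0 / data["resistance"]
            iu, iv = idx[u], idx[v]
            L[iu, iu] += g
            L[iv, iv] += g
            L[iu, iv] -= g
            L[iv, iu] -= g
            edges.append((u, v, g))
        Lplus = np.linalg.pinv(L)
        for i in range(k):
            for j in range(i + 1, k):
                b = np.zeros(k)
                b[i], b[j] = 1.0, -1.0
                pot = Lplus @ b
                for u, v, g in edges:
                    cur = abs(g * (pot[idx[u]] - pot[idx[v]]))
                    key = (min(u, v), max(u, v))
                    if key in link_cent:
                        link_cent[key] += cur
                    node_cent[u] += 0.5 * cur
                    node_cent[v] += 0.5 * cur

    for c in corridors:
        c.centrality = link_cent[c.pair]
    return node_cent, link_cent


# -- prioritization ----------------------------------------------------------


def quantile_levels(scores: list[float], n_classes: int = 4) -> list[str]:
    """Quantile class label (L/M/H/V) per score; ties share the lower level."""
    arr = np.asarray(scores, dtype=float)
    order = np.sort(arr)
    n = arr.size
    min_rank = np.searchsorted(order, arr, side="left") + 1
    cls = np.clip(np.floor((min_rank - 1) * n_classes / n).astype(int) + 1, 1, n_classes)
    return [LEVELS[c - 1] for c in cls]


def _nms_top(
    score_grid: np.ndarray, valid: np.ndarray, top_n: int, radius_m: float, cell_size: float
) -> list[tuple[tuple[int, int], float]]:
    """Greedy non-maximum suppression: top cells pairwise >= radius apart."""
    sc = np.where(valid, score_grid, -np.inf)
    flat = sc.ravel()
    cand = np.nonzero(flat > 0)[0]
    # sort by descending score, then ascending cell index (deterministic ties)
    cand = cand[np.lexsort((cand, -flat[cand]))]
    ncol = score_grid.shape[1]
    picked: list[tuple[tuple[int, int], float]] = []
    r_cells = radius_m / cell_size
    for k in cand:
        if len(picked) >= top_n:
            break
        r, c = divmod(int(k), ncol)
        if all(np.hypot(r - pr, c - pc) >= r_cells for (pr, pc), _ in picked):
            picked.append(((r, c), float(flat[k])))
    return picked


def pinch_points(
    current_maps: dict[tuple[int, int], RasterGrid],
    corridors: list[CorridorRecord],
    top_n: int = 40,
    nms_radius_m: float = 1000.0,
) -> tuple[list[PinchPoint], RasterGrid]:
    """Top pinch points: per-cell max pairwise current inside corridor swaths.

    Non-maximum suppression keeps returned points at least one suppression
    radius apart.  Each corridor's ``priority_score`` (zonal max current in
    its swath) and quantile ``priority_level`` are filled in.
    """
    if not corridors:
        raise ValueError("no corridors given")
    ref = next(iter(current_maps.values()))
    score = np.zeros(ref.shape, dtype=float)
    in_swath = np.zeros(ref.shape, dtype=bool)
    for c in corridors:
        cm = current_maps.get(c.pair)
        if cm is None:
            continue
        vals = np.nan_to_num(cm.values, nan=0.0)
        swath_vals = np.where(c.swath_mask, vals, 0.0)
        score = np.maximum(score, swath_vals)
        in_swath |= c.swath_mask
        c.priority_score = float(swath_vals.max())
    picked = _nms_top(score, in_swath, top_n, nms_radius_m, ref.cell_size)
    points = [PinchPoint(cell=cell, score=s, rank=i + 1) for i, (cell, s) in enumerate(picked)]
    for c, lev in zip(corridors, quantile_levels([c.priority_score for c in corridors])):
        c.priority_level = lev
    score_grid = ref.with_values(np.where(in_swath, score, np.nan), ~in_swath)
    return points, score_grid


def barrier_scan(
    graph: CostGraph,
    corridors: list[CorridorRecord],
    cwd: dict[int, np.ndarray],
    r_min_m: float = 200.0,
    r_max_m: float = 1000.0,
    top_n: int = 40,
    nms_radius_m: float = 1000.0,
) -> tuple[list[BarrierResult], RasterGrid]:
    """Moving-window barrier detection.

    For window radii at every multiple of the cell size in
    ``[r_min_m, r_max_m]``, restoring a window to the landscape's minimum
    resistance would let movement reach the window at the lowest CWD on its
    rim and cross it at minimum cost, so the restored least-cost distance at
    centre ``c`` is ``min_w(CWD_A) + min_w(CWD_B) + 2r·R_min`` (window
    minima via separable square filters).  The improvement score is
    ``IS = max(0, lcp_cost − restored)/(2r)`` — cost units saved per metre
    of restored diameter; each cell keeps its best score over radii and
    corridor pairs.  Also fills each corridor's ``improvement_score``
    (zonal mean IS over its swath) and quantile ``improvement_level``.
    """
    cs = graph.cell_size
    if r_min_m < cs:
        raise ValueError("minimum search radius must be at least one cell size")
    k_min = int(np.ceil(r_min_m / cs))
    k_max = int(np.floor(r_max_m / cs))
    if k_max < k_min:
        raise ValueError("no window radius fits in [r_min_m, r_max_m]")
    radii = [k * cs for k in range(k_min, k_max + 1)]
    r_land = graph.min_resistance

    is_grid = np.zeros(graph.shape, dtype=float)
    radius_grid = np.zeros(graph.shape, dtype=float)
    pair_best: dict[tuple[int, int], np.ndarray] = {}
    for c in corridors:
        a, b = c.pair
        cwd_a = np.full(graph.shape, np.inf)
        cwd_b = np.full(graph.shape, np.inf)
        cwd_a[graph.cells[:, 0], graph.cells[:, 1]] = cwd[a]
        cwd_b[graph.cells[:, 0], graph.cells[:, 1]] = cwd[b]
        best = np.zeros(graph.shape, dtype=float)
        for r in radii:
            size = 2 * int(round(r / cs)) + 1
            min_a = ndimage.minimum_filter(cwd_a, size=size, mode="nearest")
            min_b = ndimage.minimum_filter(cwd_b, size=size, mode="nearest")
            restored = min_a + min_b + 2.0 * r * r_land
            imp = (c.lcp_cost - restored) / (2.0 * r)
            imp = np.where(np.isfinite(imp), np.maximum(imp, 0.0), 0.0)
            better = imp > best
            best = np.where(better, imp, best)
            radius_grid = np.where(better & (imp > is_grid), r, radius_grid)
        pair_best[c.pair] = best
        is_grid = np.maximum(is_grid, best)

    picked = _nms_top(is_grid, graph.valid, top_n, nms_radius_m, cs)
    barriers = []
    for i, (cell, s) in enumerate(picked):
        pair = max(pair_best, key=lambda p: pair_best[p][cell])
        barriers.append(BarrierResult(cell=cell, radius_m=float(radius_grid[cell]),
                                      score=s, pair=pair))

    for c in corridors:
        sel = c.swath_mask & graph.valid
        c.improvement_score = float(pair_best[c.pair][sel].mean()) if sel.any() else 0.0
    levels = quantile_levels([c.improvement_score for c in corridors])
    for c, lev in zip(corridors, levels):
        c.improvement_level = lev

    out = graph.resistance.with_values(np.where(graph.valid, is_grid, np.nan), ~graph.valid)
    return barriers, out


def composite_priority(corridors: list[CorridorRecord]) -> dict[tuple[int, int], str]:
    """Cross-tabulate improvement × priority levels into "X&Y" labels.

    Corridors labelled ``"V&V"`` are the priority corridors: very high
    improvement potential and very high conservation priority.
    """
    labels: dict[tuple[int, int], str] = {}
    for c in corridors:
        if c.improvement_level is None or c.priority_level is None:
            raise ValueError("run barrier_scan and pinch_points before composite_priority")
        labels[c.pair] = f"{c.improvement_level}&{c.priority_level}"
    return labels
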