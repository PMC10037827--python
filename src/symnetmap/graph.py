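"""Global graph properties of sparsity-thresholded binary networks.

A subject's Fisher-z FC matrix is binarized at each sparsity level on a
fixed grid (default 0.15 to 0.45, step 0.01: 31 points) by keeping the
strongest edges, and eight global properties are computed per level:
assortativity, hierarchy, synchronization, small-world sigma, clustering
coefficient (Cp), characteristic path length (Lp), global efficiency
(Eglobal), and local efficiency (Elocal). Each metric curve is summarized
by its area under the curve (AUC) over the grid, giving one scalar per
subject and metric for group statistics.

Conventions (surfaced here because reporting differs across toolboxes):
synchronization is the Laplacian eigenratio lambda_2 / lambda_max of the
largest connected component; hierarchy is the exponent beta of
C_i ~ k_i^(-beta) fit by least squares on log-log over nodes with degree
>= 2 and positive clustering; sigma uses degree-preserving edge-rewiring
null graphs; Lp averages shortest-path lengths over connected node pairs
only; degenerate cases yield NaN sentinels that the AUC step skips.
"""

from __future__ import annotations

import math
from collections.abc import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from ._errors import DegenerateInputError

__all__ = [
    "sparsity_grid",
    "binarize_at_sparsity",
    "clustering_coefficient",
    "characteristic_path_length",
    "global_efficiency",
    "local_efficiency",
    "assortativity",
    "hierarchy",
    "hierarchy_exponent",
    "synchronization",
    "sigma",
    "metric_curves",
    "auc_over_sparsity",
    "auc_table",
    "GLOBAL_METRICS",
]

GLOBAL_METRICS = (
    "assortativity", "hierarchy", "synchronization", "sigma",
    "Cp", "Lp", "Eglobal", "Elocal",
)


def sparsity_grid(smin: float = 0.15, smax: float = 0.45, step: float = 0.01) -> np.ndarray:
    """The sparsity grid; defaults give the canonical 31-point grid."""
    n = int(round((smax - smin) / step)) + 1
    return np.round(smin + step * np.arange(n), 10)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def binarize_at_sparsity(fc, s: float) -> nx.Graph:
    """Binarize a symmetric weight matrix at sparsity ``s``.

    Keeps the ``round(s * n(n-1)/2)`` largest off-diagonal weights
    (round half away from zero) as undirected edges. Ties break by
    weight descending, then lexicographic node-index pair, so the result
    is deterministic. Node labels follow the DataFrame index when one is
    given, else integer positions.
    """
    if isinstance(fc, pd.DataFrame):
        labels = list(fc.index)
        W = fc.to_numpy(dtype=float)
    else:
        W = np.asarray(fc, dtype=float)
        labels = list(range(W.shape[0]))
    n = W.shape[0]
    if W.shape != (n, n):
        raise ValueError("FC matrix must be square")
    if not 0.0 < s <= 1.0:
        raise ValueError(f"sparsity must be in (0, 1], got {s}")
    off = ~np.eye(n, dtype=bool)
    if not np.allclose(np.where(off, W, 0.0), np.where(off, W.T, 0.0), equal_nan=True):
        raise ValueError("FC matrix must be symmetric off the diagonal")
    m_total = n * (n - 1) // 2
    k = _round_half_away(s * m_total)
    if k == 0:
        raise DegenerateInputError(f"sparsity {s} on {n} nodes retains zero edges")
    iu, ju = np.triu_indices(n, 1)
    w = W[iu, ju]
    order = sorted(range(len(w)), key=lambda t: (-w[t], iu[t], ju[t]))
    g = nx.Graph()
    g.add_nodes_from(labels)
    for t in order[:k]:
        g.add_edge(labels[iu[t]], labels[ju[t]])
    g.graph["sparsity"] = s
    return g


# ---------------------------------------------------------------------------
# individual metrics
# ---------------------------------------------------------------------------

def clustering_coefficient(g: nx.Graph) -> float:
    """Mean nodal clustering; nodes with degree < 2 contribute 0."""
    _require_nodes(g, 2)
    return float(nx.average_clustering(g, count_zeros=True))


def characteristic_path_length(g: nx.Graph) -> float:
    """Mean shortest-path length over connected unordered node pairs."""
    _require_nodes(g, 2)
    total, count = 0, 0
    for _, lengths in nx.all_pairs_shortest_path_length(g):
        for d in lengths.values():
            if d > 0:
                total += d
                count += 1
    if count == 0:
        return float("nan")
    return total / count  # each unordered pair counted twice; ratio unchanged


def global_efficiency(g: nx.Graph) -> float:
    """Mean inverse shortest-path length over ordered pairs (1/inf = 0)."""
    _require_nodes(g, 2)
    return float(nx.global_efficiency(g))


def local_efficiency(g: nx.Graph) -> float:
    """Mean over nodes of the global efficiency of the neighbor subgraph."""
    _require_nodes(g, 2)
    return float(nx.local_efficiency(g))


def assortativity(g: nx.Graph) -> float:
    """Degree-degree Pearson correlation over edge endpoints (both
    orientations). NaN when endpoint degrees carry no variance."""
    if g.number_of_edges() < 2:
        return float("nan")
    deg = dict(g.degree())
    x, y = [], []
    for u, v in g.edges():
        x.extend((deg[u], deg[v]))
        y.extend((deg[v], deg[u]))
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.std() == 0.0 or y.std() == 0.0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def hierarchy_exponent(degrees, clusterings) -> float:
    """beta from the least-squares fit of log C on log k (C ~ k^-beta)."""
    k = np.asarray(degrees, float)
    c = np.asarray(clusterings, float)
    keep = (k >= 2) & (c > 0)
    if keep.sum() < 3:
        return float("nan")
    lk, lc = np.log(k[keep]), np.log(c[keep])
    if np.ptp(lk) == 0.0:
        return float("nan")
    slope = np.cov(lk, lc, bias=True)[0, 1] / np.var(lk)
    return float(-slope)


def hierarchy(g: nx.Graph) -> float:
    """Hierarchy exponent of the graph; NaN with < 3 eligible nodes."""
    nodes = list(g.nodes())
    deg = np.array([g.degree(v) for v in nodes], float)
    clu = nx.clustering(g)
    return hierarchy_exponent(deg, [clu[v] for v in nodes])


def synchronization(g: nx.Graph) -> float:
    """Laplacian eigenratio lambda_2 / lambda_max of the largest component."""
    if g.number_of_nodes() == 0:
        return float("nan")
    comp = max(nx.connected_components(g), key=len)
    if len(comp) < 3:
        return float("nan")
    sub = g.subgraph(comp)
    L = nx.laplacian_matrix(sub).toarray().astype(float)
    ev = np.linalg.eigvalsh(L)
    return float(ev[1] / ev[-1])


def _rewire(g: nx.Graph, rng: np.random.Generator, attempts: int) -> nx.Graph:
    """Degree-preserving double-edge swaps; ``attempts`` attempted swaps."""
    h = g.copy()
    edges = list(h.edges())
    m = len(edges)
    if m < 2:
        return h
    for _ in range(attempts):
        i, j = rng.integers(0, m, size=2)
        if i == j:
            continue
        (u, v), (x, y) = edges[i], edges[j]
        if rng.random() < 0.5:
            x, y = y, x
        # proposed: (u, x), (v, y)
        if len({u, v, x, y}) < 4:
            continue
        if h.has_edge(u, x) or h.has_edge(v, y):
            continue
        h.remove_edge(u, v)
        h.remove_edge(x, y)
        h.add_edge(u, x)
        h.add_edge(v, y)
        edges[i], edges[j] = (u, x), (v, y)
    return h


def sigma(g: nx.Graph, n_null: int = 100, rng_seed: int = 0) -> float:
    """Small-world index (Cp/<Cp_rand>) / (Lp/<Lp_rand>).

    Null graphs preserve the degree sequence by edge rewiring with
    ``10 * |E|`` attempted swaps each. When rewiring cannot move any edge
    (complete graph), every null equals the graph and sigma is exactly 1.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    _require_nodes(g, 2)
    if g.number_of_edges() == 0:
        return float("nan")
    cp, lp = clustering_coefficient(g), characteristic_path_length(g)
    rng = np.random.default_rng(rng_seed)
    attempts = 10 * g.number_of_edges()
    cps, lps = [], []
    for _ in range(n_null):
        h = _rewire(g, rng, attempts)
        cps.append(clustering_coefficient(h))
        lps.append(characteristic_path_length(h))
    cp_r, lp_r = float(np.mean(cps)), float(np.mean(lps))
    if cp_r == 0.0 or lp == 0.0 or not np.isfinite(lp_r):
        return float("nan")
    return float((cp / cp_r) / (lp / lp_r))


def _require_nodes(g: nx.Graph, n: int) -> None:
    if g.number_of_nodes() < n:
        raise ValueError(f"graph needs at least {n} nodes")


# ---------------------------------------------------------------------------
# curves and AUC
# ---------------------------------------------------------------------------

_METRIC_FUNCS = {
    "assortativity": assortativity,
    "hierarchy": hierarchy,
    "synchronization": synchronization,
    "Cp": clustering_coefficient,
    "Lp": characteristic_path_length,
    "Eglobal": global_efficiency,
    "Elocal": local_efficiency,
}


def metric_curves(
    fc,
    grid: Sequence[float] | None = None,
    n_null: int = 100,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """All eight global properties of one subject's FC matrix over the grid.

    Returns a DataFrame indexed by sparsity with one column per metric;
    undefined values are NaN. Sigma's null seed is derived from
    ``rng_seed`` and the grid position so each level is independently
    reproducible.
    """
    grid = sparsity_grid() if grid is None else np.asarray(grid, float)
    rows = {}
    for pos, s in enumerate(grid):
        g = binarize_at_sparsity(fc, float(s))
        row = {name: fn(g) for name, fn in _METRIC_FUNCS.items()}
        row["sigma"] = sigma(g, n_null=n_null, rng_seed=(rng_seed * 1009 + pos) % (2**31))
        rows[float(s)] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sparsity"
    return out[list(GLOBAL_METRICS)]


def auc_over_sparsity(values, grid: Sequence[float] | None = None) -> float:
    """Trapezoidal AUC of one metric curve over the sparsity grid.

    NaN gaps are excluded pairwise (integration runs over the finite
    points on the actual grid spacing); with more than half the grid
    undefined the AUC itself is the NaN sentinel.
    """
    values = np.asarray(values, float)
    grid = sparsity_grid() if grid is None else np.asarray(grid, float)
    if values.shape != grid.shape:
        raise ValueError("curve and grid lengths differ")
    finite = np.isfinite(values)
    if finite.sum() <= len(grid) // 2:
        return float("nan")
    return float(np.trapezoid(values[finite], grid[finite]))


def auc_table(curves: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-subject AUC summary (subjects x metrics) with grid coverage.

    ``curves`` maps subject id -> :func:`metric_curves` output. The
    ``<metric>__coverage`` columns record the fraction of grid points
    that were defined, making any gap renormalization auditable.
    """
    rows = {}
    for subject, df in curves.items():
        grid = df.index.to_numpy(float)
        row = {}
        for metric in df.columns:
            vals = df[metric].to_numpy(float)
            row[metric] = auc_over_sparsity(vals, grid)
            row[f"{metric}__coverage"] = float(np.isfinite(vals).mean())
        rows[subject] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "subject_id"
    return out
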