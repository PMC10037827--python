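"""Independent brute-force oracles used only by the tests.

Deliberately naive: Floyd-Warshall distances, explicit triangle
enumeration, direct-summation correlation, dense eigensolver, and
closed-form simple regression — no shared code with the implementation.
"""

import numpy as np


def adjacency(g):
    nodes = sorted(g.nodes())
    pos = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    A = np.zeros((n, n))
    for u, v in g.edges():
        A[pos[u], pos[v]] = A[pos[v], pos[u]] = 1.0
    return A


def floyd_warshall(A):
    n = len(A)
    D = np.where(A > 0, 1.0, np.inf)
    np.fill_diagonal(D, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if D[i, k] + D[k, j] < D[i, j]:
                    D[i, j] = D[i, k] + D[k, j]
    return D


def oracle_lp(A):
    """Mean shortest-path length over connected ordered pairs."""
    D = floyd_warshall(A)
    n = len(A)
    vals = [D[i, j] for i in range(n) for j in range(n)
            if i != j and np.isfinite(D[i, j])]
    return float(np.mean(vals)) if vals else float("nan")


def oracle_eglobal(A):
    D = floyd_warshall(A)
    n = len(A)
    inv = [1.0 / D[i, j] if np.isfinite(D[i, j]) and D[i, j] > 0 else 0.0
           for i in range(n) for j in range(n) if i != j]
    return float(np.mean(inv))


def oracle_clustering_per_node(A):
    n = len(A)
    out = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(A[i])
        k = len(nbrs)
        if k < 2:
            continue
        tri = sum(A[u, v] for a, u in enumerate(nbrs) for v in nbrs[a + 1:])
        out[i] = 2.0 * tri / (k * (k - 1))
    return out


def oracle_cp(A):
    return float(np.mean(oracle_clustering_per_node(A)))


def oracle_elocal(A):
    n = len(A)
    effs = []
    for i in range(n):
        nbrs = np.flatnonzero(A[i])
        if len(nbrs) < 2:
            effs.append(0.0)
            continue
        sub = A[np.ix_(nbrs, nbrs)]
        effs.append(oracle_eglobal(sub))
    return float(np.mean(effs))


def oracle_assortativity(A):
    deg = A.sum(axis=1)
    xs, ys = [], []
    n = len(A)
    for i in range(n):
        for j in range(i + 1, n):
            if A[i, j]:
                xs.extend((deg[i], deg[j]))
                ys.extend((deg[j], deg[i]))
    xs, ys = np.array(xs), np.array(ys)
    if len(xs) < 4 or xs.std() == 0 or ys.std() == 0:
        return float("nan")
    mx, my = xs.mean(), ys.mean()
    num = np.sum((xs - mx) * (ys - my))
    den = np.sqrt(np.sum((xs - mx) ** 2) * np.sum((ys - my) ** 2))
    return float(num / den)


def oracle_synchronization(A):
    # largest connected component via repeated BFS
    n = len(A)
    seen, comps = set(), []
    for s in range(n):
        if s in seen:
            continue
        comp, stack = {s}, [s]
        while stack:
            u = stack.pop()
            for v in np.flatnonzero(A[u]):
                if v not in comp:
                    comp.add(int(v))
                    stack.append(int(v))
        seen |= comp
        comps.append(sorted(comp))
    comp = max(comps, key=len)
    if len(comp) < 3:
        return float("nan")
    sub = A[np.ix_(comp, comp)]
    L = np.diag(sub.sum(axis=1)) - sub
    ev = np.sort(np.linalg.eigvalsh(L))
    return float(ev[1] / ev[-1])


def oracle_hierarchy(A):
    deg = A.sum(axis=1)
    clu = oracle_clustering_per_node(A)
    keep = (deg >= 2) & (clu > 0)
    if keep.sum() < 3:
        return float("nan")
    x, y = np.log(deg[keep]), np.log(clu[keep])
    if x.max() == x.min():
        return float("nan")
    slope = (np.mean(x * y) - x.mean() * y.mean()) / (np.mean(x * x) - x.mean() ** 2)
    return float(-slope)


def oracle_pearson(x, y):
    """Textbook covariance over product-of-SDs by direct summation."""
    n = len(x)
    sx = sum(x) / n
    sy = sum(y) / n
    cov = sum((a - sx) * (b - sy) for a, b in zip(x, y)) / n
    vx = sum((a - sx) ** 2 for a in x) / n
    vy = sum((b - sy) ** 2 for b in y) / n
    return cov / (vx ** 0.5 * vy ** 0.5)


def oracle_trapezoid(values, grid):
    total = 0.0
    for i in range(len(grid) - 1):
        total += 0.5 * (values[i] + values[i + 1]) * (grid[i + 1] - grid[i])
    return total


def oracle_topk_edges(W, k):
    """Edge set of the k strongest upper-triangle weights, brute scan."""
    n = len(W)
    items = [(W[i, j], i, j) for i in range(n) for j in range(i + 1, n)]
    items.sort(key=lambda t: (-t[0], t[1], t[2]))
    return {(i, j) for _, i, j in items[:k]}
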