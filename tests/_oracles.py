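"""Brute-force reference implementations used only to verify the package.

Everything here is written the slow, obvious way — explicit loops, explicit
formulas — and stays independent of the code paths it checks.
"""

from __future__ import annotations

import numpy as np


def floyd_warshall(lengths: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths by the classic triple loop.

    ``lengths`` has np.inf where there is no edge; diagonal 0.
    """
    d = lengths.copy().astype(float)
    n = d.shape[0]
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def length_matrix(W: np.ndarray) -> np.ndarray:
    What = W / W.max()
    with np.errstate(divide="ignore"):
        L = np.where(What > 0, 1.0 / What, np.inf)
    return L


def onnela_clustering(W: np.ndarray) -> np.ndarray:
    """Per-node weighted clustering by explicit triangle enumeration."""
    What = W / W.max()
    n = W.shape[0]
    c = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if What[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        total = 0.0
        for j in nbrs:
            for h in nbrs:
                if j != h and What[j, h] > 0:
                    total += (What[i, j] * What[i, h] * What[j, h]) ** (1 / 3)
        c[i] = total / (k * (k - 1))
    return c


def global_metrics(W: np.ndarray) -> dict[str, float]:
    """Cp, Lp, Eglob, Eloc via Floyd-Warshall and triangle enumeration."""
    n = W.shape[0]
    d = floyd_warshall(length_matrix(W))
    cp = onnela_clustering(W).mean()
    finite = []
    inv_sum = 0.0
    for i in range(n):
        for j in range(n):
            if i != j:
                if np.isfinite(d[i, j]):
                    finite.append(d[i, j])
                    inv_sum += 1.0 / d[i, j]
    lp = float(np.mean(finite)) if finite else 0.0
    eglob = inv_sum / (n * (n - 1))

    What = W / W.max()
    eloc_terms = []
    for i in range(n):
        nbrs = [j for j in range(n) if What[i, j] > 0]
        if len(nbrs) < 2:
            eloc_terms.append(0.0)
            continue
        # neighbor subgraph keeps the globally normalized weights
        sub = What[np.ix_(nbrs, nbrs)]
        with np.errstate(divide="ignore"):
            L = np.where(sub > 0, 1.0 / sub, np.inf)
        ds = floyd_warshall(L)
        m = len(nbrs)
        s = sum(1.0 / ds[a, b] for a in range(m) for b in range(m)
                if a != b and np.isfinite(ds[a, b]))
        eloc_terms.append(s / (m * (m - 1)))
    return {"Cp": float(cp), "Lp": lp, "Eglob": float(eglob),
            "Eloc": float(np.mean(eloc_terms))}


def nodal_efficiency(W: np.ndarray) -> np.ndarray:
    n = W.shape[0]
    d = floyd_warshall(length_matrix(W))
    out = np.zeros(n)
    for i in range(n):
        s = 0.0
        for j in range(n):
            if j != i and np.isfinite(d[i, j]) and d[i, j] > 0:
                s += 1.0 / d[i, j]
        out[i] = s / (n - 1)
    return out


def components_dfs(edges: list[tuple[int, int]]) -> list[set[tuple[int, int]]]:
    """Connected components of an edge set via depth-first search over nodes."""
    adj: dict[int, set[int]] = {}
    for a, b in edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    seen: set[int] = set()
    comps = []
    for start in sorted(adj):
        if start in seen:
            continue
        stack = [start]
        nodes = set()
        while stack:
            x = stack.pop()
            if x in nodes:
                continue
            nodes.add(x)
            stack.extend(adj[x] - nodes)
        seen |= nodes
        comps.append({(min(a, b), max(a, b)) for a, b in edges
                      if a in nodes and b in nodes})
    return comps


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up by the textbook definition."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running = min(running, p[idx] * m / rank_from_top)
        adj[idx] = running
    return adj


def partial_corr_formula(x, y, z) -> float:
    """First-order partial correlation from the three pairwise correlations."""
    r_xy = np.corrcoef(x, y)[0, 1]
    r_xz = np.corrcoef(x, z)[0, 1]
    r_yz = np.corrcoef(y, z)[0, 1]
    return (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz ** 2) * (1 - r_yz ** 2))


def dense_traversal(points: np.ndarray, step: float = 0.01) -> np.ndarray:
    """Voxel sequence by dense resampling of a polyline at ``step`` spacing."""
    samples = []
    for a, b in zip(points[:-1], points[1:]):
        seg = b - a
        n = max(int(np.ceil(np.linalg.norm(seg) / step)), 1)
        t = np.linspace(0, 1, n, endpoint=False)
        samples.append(a + t[:, None] * seg)
    samples.append(points[-1:])
    pts = np.vstack(samples)
    vox = np.floor(pts).astype(int)
    keep = np.r_[True, np.any(np.diff(vox, axis=0) != 0, axis=1)]
    return vox[keep]
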