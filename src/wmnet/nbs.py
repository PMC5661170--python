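"""Network-based statistic: edge-wise two-sample t-maps, suprathreshold
connected components, and permutation family-wise-error corrected p-values.

For each region pair the edge weight is compared between the two groups with a
pooled-variance two-sample t-statistic (zeros count as values; edges with zero
pooled variance are undefined and excluded). Edges exceeding the primary
threshold (default t = 2.1) in the tested direction form a graph whose
connected components are the candidate subnetworks; each component's extent
(edge count) is compared against the null distribution of the *maximal*
component extent over random relabelings of subjects into groups of the
original sizes (default 5000 permutations), giving the FWE-corrected

    p = (1 + #{permutations with max extent >= observed extent}) / (P + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .syndata import Cohort

__all__ = ["NBSConfig", "Component", "NBSResult", "edge_tstats",
           "suprathreshold_components", "nbs_fwe"]

_DIRECTIONS = ("decrease", "increase", "both")


@dataclass
class NBSConfig:
    t_threshold: float = 2.1
    n_permutations: int = 5000
    direction: str = "decrease"   # group1 < group2 | increase | both
    statistic: str = "extent"     # or "intensity" (sum of |t| - thr)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t_threshold <= 0:
            raise ValueError("t_threshold must be positive")
        if self.n_permutations < 1:
            raise ValueError("need at least one permutation")
        if self.direction not in _DIRECTIONS:
            raise ValueError(f"direction must be one of {_DIRECTIONS}")
        if self.statistic not in ("extent", "intensity"):
            raise ValueError("statistic must be 'extent' or 'intensity'")


@dataclass
class Component:
    """One suprathreshold connected subnetwork."""

    edges: list[tuple[int, int]]     # 0-based node pairs, i < j
    nodes: list[int]
    extent: int
    direction: str
    intensity: float = 0.0
    p_fwe: float | None = None

    def edge_codes(self, codes) -> list[tuple[str, str]]:
        return [(codes[i], codes[j]) for i, j in self.edges]


@dataclass
class NBSResult:
    components: list[Component]
    tmat: np.ndarray
    null_max: dict[str, np.ndarray]
    config: NBSConfig

    @property
    def significant(self) -> list[Component]:
        return [c for c in self.components if c.p_fwe is not None
                and c.p_fwe < 0.05]


def _tstats_1d(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t over axis 0; NaN where pooled var is 0."""
    n1, n2 = x1.shape[0], x2.shape[0]
    m1, m2 = x1.mean(axis=0), x2.mean(axis=0)
    ss1 = ((x1 - m1) ** 2).sum(axis=0)
    ss2 = ((x2 - m2) ** 2).sum(axis=0)
    sp2 = (ss1 + ss2) / (n1 + n2 - 2)
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / se
    t[se == 0] = np.nan
    return t


def edge_tstats(cohort: Cohort) -> np.ndarray:
    """Symmetric matrix of two-sample t-statistics (patients minus controls).

    The diagonal and edges with zero pooled variance are NaN.
    """
    pat, con = cohort.group_matrices()
    if len(pat) < 2 or len(con) < 2:
        raise ValueError("each group needs at least 2 subjects")
    n = cohort.n_nodes
    iu = np.triu_indices(n, k=1)
    t = _tstats_1d(pat[:, iu[0], iu[1]], con[:, iu[0], iu[1]])
    tmat = np.full((n, n), np.nan)
    tmat[iu] = t
    tmat[iu[1], iu[0]] = t
    return tmat


class _UnionFind:
    __slots__ = ("parent",)

    def __init__(self, n: int) -> None:
        self.parent = np.arange(n)

    def find(self, x: int) -> int:
        p = self.parent
        root = x
        while p[root] != root:
            root = p[root]
        while p[x] != root:
            p[x], x = root, p[x]
        return root

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _signed(tmat: np.ndarray, direction: str) -> np.ndarray:
    """Statistic oriented so 'suprathreshold' always means value > threshold."""
    return -tmat if direction == "decrease" else tmat


def suprathreshold_components(tmat: np.ndarray, cfg: NBSConfig,
                              direction: str | None = None
                              ) -> list[Component]:
    """Connected components of the suprathreshold edge graph, largest first.

    ``direction`` defaults to ``cfg.direction`` and must be one-sided here
    ('both' analyses call this once per side).
    """
    direction = direction or cfg.direction
    if direction == "both":
        raise ValueError("resolve 'both' into one direction per call")
    n = tmat.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    signed = _signed(tmat, direction)[iu, ju]
    hot = np.flatnonzero(np.nan_to_num(signed, nan=-np.inf) > cfg.t_threshold)
    if hot.size == 0:
        return []
    uf = _UnionFind(n)
    for e in hot:
        uf.union(int(iu[e]), int(ju[e]))
    groups: dict[int, list[int]] = {}
    for e in hot:
        groups.setdefault(uf.find(int(iu[e])), []).append(int(e))
    comps = []
    for members in groups.values():
        edges = [(int(iu[e]), int(ju[e])) for e in members]
        nodes = sorted({v for e in edges for v in e})
        intensity = float(sum(signed[e] - cfg.t_threshold for e in members))
        comps.append(Component(sorted(edges), nodes, len(edges),
                               direction, intensity))
    key = (lambda c: c.extent) if cfg.statistic == "extent" \
        else (lambda c: c.intensity)
    return sorted(comps, key=key, reverse=True)


def _perm_null_max(X: np.ndarray, n1: int, cfg: NBSConfig, direction: str,
                   iu: np.ndarray, ju: np.ndarray, n_nodes: int,
                   rng: np.random.Generator, batch: int = 500) -> np.ndarray:
    """Null distribution of the maximal component statistic.

    ``X`` is the (n_subjects, n_edges) upper-triangle weight stack. Group
    relabelings are drawn uniformly over splits of the original sizes;
    t-maps for a whole batch are computed with one pair of matrix products.
    """
    n_sub, n_edges = X.shape
    n2 = n_sub - n1
    X2 = X * X
    tot = X.sum(axis=0)
    tot2 = X2.sum(axis=0)
    sign = -1.0 if direction == "decrease" else 1.0
    out = np.empty(cfg.n_permutations)
    done = 0
    while done < cfg.n_permutations:
        b = min(batch, cfg.n_permutations - done)
        # b random splits: first n1 of a shuffled subject order form group 1
        L = (np.argsort(rng.random((b, n_sub)), axis=1) < n1).astype(float)
        s1 = L @ X
        q1 = L @ X2
        m1 = s1 / n1
        m2 = (tot - s1) / n2
        ss1 = q1 - n1 * m1 * m1
        ss2 = (tot2 - q1) - n2 * m2 * m2
        sp2 = (ss1 + ss2) / (n_sub - 2)
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = sign * (m1 - m2) / se
        t[se == 0] = -np.inf
        hot_mask = t > cfg.t_threshold
        for k in range(b):
            hot = np.flatnonzero(hot_mask[k])
            if hot.size == 0:
                out[done + k] = 0.0
                continue
            uf = _UnionFind(n_nodes)
            for e in hot:
                uf.union(int(iu[e]), int(ju[e]))
            sizes: dict[int, float] = {}
            for e in hot:
                r = uf.find(int(iu[e]))
                inc = 1.0 if cfg.statistic == "extent" \
                    else float(t[k, e] - cfg.t_threshold)
                sizes[r] = sizes.get(r, 0.0) + inc
            out[done + k] = max(sizes.values())
        done += b
    return out


def nbs_fwe(cohort: Cohort, cfg: NBSConfig | None = None) -> NBSResult:
    """Full NBS run: observed components + permutation FWE p-values.

    ``direction='both'`` runs two one-sided analyses (each with its own
    permutation null) and pools the components. Deterministic given
    ``cfg.seed``; independent of subject ordering in the manifest.
    """
    if cfg is None:
        cfg = NBSConfig()
    pat, con = cohort.group_matrices()
    n1 = len(pat)
    if n1 < 2 or len(con) < 2:
        raise ValueError("each group needs at least 2 subjects")
    from math import comb
    if comb(n1 + len(con), n1) <= 1:
        raise ValueError("group sizes admit no distinct permutation")

    tmat = edge_tstats(cohort)
    n = cohort.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    # canonical subject order (patients then controls, each sorted by id) so
    # results do not depend on manifest row order
    mask = cohort.patient_mask
    sid = cohort.manifest["subject_id"].to_numpy()
    p_rows = np.flatnonzero(mask)[np.argsort(sid[mask], kind="stable")]
    c_rows = np.flatnonzero(~mask)[np.argsort(sid[~mask], kind="stable")]
    ordered = cohort.matrices[np.concatenate([p_rows, c_rows])]
    X = ordered[:, iu, ju]

    directions = ("decrease", "increase") if cfg.direction == "both" \
        else (cfg.direction,)
    components: list[Component] = []
    null_max: dict[str, np.ndarray] = {}
    rng = np.random.default_rng(cfg.seed)
    for direction in directions:
        comps = suprathreshold_components(tmat, cfg, direction)
        null = _perm_null_max(X, n1, cfg, direction, iu, ju, n, rng)
        null_max[direction] = null
        for c in comps:
            stat = c.extent if cfg.statistic == "extent" else c.intensity
            c.p_fwe = float((1 + (null >= stat).sum())
                            / (cfg.n_permutations + 1))
        components.extend(comps)
    return NBSResult(components, tmat, null_max, cfg)


def result_tables(res: NBSResult, codes) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(component summary, per-edge rows for significant components)."""
    comp_rows = []
    edge_rows = []
    for k, c in enumerate(res.components):
        comp_rows.append((k, c.direction, c.extent, len(c.nodes),
                          round(c.intensity, 4), c.p_fwe))
        if c.p_fwe is not None and c.p_fwe < 0.05:
            for (i, j) in c.edges:
                edge_rows.append((k, codes[i], codes[j],
                                  res.tmat[i, j]))
    comps = pd.DataFrame(comp_rows, columns=[
        "component", "direction", "extent", "n_nodes", "intensity", "p_fwe"])
    edges = pd.DataFrame(edge_rows, columns=["component", "code_i", "code_j", "t"])
    return comps, edges
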