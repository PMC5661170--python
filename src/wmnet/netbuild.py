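"""Weighted structural connectome construction: w_ij = FN_ij x FA_ij.

Nodes are atlas regions from an integer label volume (0 = background); an edge
between regions i and j carries the number of streamlines whose two endpoints
fall in i and j (FN) times the mean FA pooled over every voxel those
streamlines traverse. Edges with FN below ``min_fn`` (default 3, i.e. FN < 3
zeroed) are removed as likely spurious connections.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .regions import AAL90_CODES
from .tracking import Streamline, streamline_voxels

__all__ = ["Parcellation", "ConnectomeMatrix", "ConnectomeResult",
           "assign_endpoints", "build_connectome"]

_EPS = 1e-6


@dataclass
class Parcellation:
    """Integer label volume (0 background, 1..n regions) plus region codes."""

    labels: np.ndarray
    codes: tuple[str, ...] = AAL90_CODES

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label volume must be integer")
        lmax = int(self.labels.max(initial=0))
        if self.labels.min(initial=0) < 0 or lmax > len(self.codes):
            raise ValueError(
                f"labels must lie in 0..{len(self.codes)}, got max {lmax}")

    @property
    def n_regions(self) -> int:
        return len(self.codes)


@dataclass
class ConnectomeMatrix:
    """Symmetric nonnegative weighted adjacency with zero diagonal."""

    weights: np.ndarray
    subject_id: str = ""
    codes: tuple[str, ...] = AAL90_CODES

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if not np.allclose(w, w.T):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        self.weights = w

    def save(self, path) -> None:
        pd.DataFrame(self.weights, index=self.codes, columns=self.codes
                     ).to_csv(path)

    @classmethod
    def load(cls, path, subject_id: str = "") -> "ConnectomeMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(dtype=float), subject_id=subject_id,
                   codes=tuple(df.columns))


def _terminal_voxel(points: np.ndarray, end: int) -> np.ndarray:
    """Voxel containing a terminal point, nudged inward along the last segment
    (terminal points typically sit exactly on a voxel face)."""
    if end == 0:
        p, d = points[0], points[1] - points[0]
    else:
        p, d = points[-1], points[-1] - points[-2]
        d = -d
    return np.floor(p + _EPS * np.sign(d)).astype(int)


def assign_endpoints(s: Streamline, parc: Parcellation
                     ) -> tuple[int, int] | None:
    """Region pair (i, j), i < j, 1-based labels, or None.

    None when either endpoint is background (label 0) or both endpoints lie in
    the same region (self-connections excluded).
    """
    shape = np.asarray(parc.labels.shape)
    va = _terminal_voxel(s.points, 0)
    vb = _terminal_voxel(s.points, -1)
    for v in (va, vb):
        if np.any(v < 0) or np.any(v >= shape):
            return None
    a = int(parc.labels[tuple(va)])
    b = int(parc.labels[tuple(vb)])
    if a == 0 or b == 0 or a == b:
        return None
    return (min(a, b), max(a, b))


@dataclass
class ConnectomeResult:
    matrix: ConnectomeMatrix
    edges: pd.DataFrame          # i, j, code_i, code_j, FN, meanFA, w
    n_streamlines: int
    n_unassigned: int            # background or intra-region streamlines


def build_connectome(streamlines: list[Streamline], parc: Parcellation,
                     fa_map: np.ndarray, min_fn: int = 3,
                     subject_id: str = "",
                     fa_pooling: str = "voxel") -> ConnectomeResult:
    """Aggregate streamlines into the weighted FN x FA network.

    Parameters
    ----------
    fa_map : array matching the label volume's shape
    min_fn : pairs with streamline count strictly below this are zeroed
    fa_pooling : 'voxel' pools per-voxel FA samples across all connecting
        streamlines (shared voxels counted once per streamline);
        'streamline' averages each streamline's mean FA.
    """
    fa_map = np.asarray(fa_map, dtype=float)
    if fa_map.shape != parc.labels.shape:
        raise ValueError("FA map and label volume shapes differ")
    if fa_pooling not in ("voxel", "streamline"):
        raise ValueError("fa_pooling must be 'voxel' or 'streamline'")

    n = parc.n_regions
    fn = {}
    fa_sum = {}
    fa_cnt = {}
    unassigned = 0
    for s in streamlines:
        pair = assign_endpoints(s, parc)
        if pair is None:
            unassigned += 1
            continue
        vox = streamline_voxels(s, shape=parc.labels.shape)
        samples = fa_map[vox[:, 0], vox[:, 1], vox[:, 2]]
        fn[pair] = fn.get(pair, 0) + 1
        if fa_pooling == "voxel":
            fa_sum[pair] = fa_sum.get(pair, 0.0) + samples.sum()
            fa_cnt[pair] = fa_cnt.get(pair, 0) + samples.size
        else:
            fa_sum[pair] = fa_sum.get(pair, 0.0) + samples.mean()
            fa_cnt[pair] = fa_cnt.get(pair, 0) + 1

    W = np.zeros((n, n), dtype=float)
    rows = []
    for (a, b), count in sorted(fn.items()):
        mean_fa = fa_sum[(a, b)] / fa_cnt[(a, b)]
        w = count * mean_fa if count >= min_fn else 0.0
        i, j = a - 1, b - 1
        W[i, j] = W[j, i] = w
        rows.append((a, b, parc.codes[i], parc.codes[j], count, mean_fa, w))
    edges = pd.DataFrame(rows, columns=["i", "j", "code_i", "code_j",
                                        "FN", "meanFA", "w"])
    return ConnectomeResult(
        ConnectomeMatrix(W, subject_id=subject_id, codes=parc.codes),
        edges, n_streamlines=len(streamlines), n_unassigned=unassigned)
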