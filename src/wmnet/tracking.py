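"""Deterministic FACT (fiber assignment by continuous tracking) tractography.

Streamlines are propagated in continuous 0-based voxel coordinates (voxel
center at integer + 0.5). Within a voxel the trajectory follows that voxel's
principal eigenvector until it crosses an axis-aligned face (exact ray-box
intersection); on entering a new voxel the track terminates if the voxel's FA
falls below ``fa_threshold`` or the turn between the previous and the new
(sign-aligned) direction exceeds ``angle_threshold``. The voxel that fails a
test is not appended — termination happens at its entry face. Seeds are the
centers of every voxel passing the FA gate; the two half-tracks launched along
+/- e1 are merged into one streamline.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .tensorfit import TensorVolume

__all__ = ["TrackingConfig", "Streamline", "fact_track", "streamline_voxels",
           "save_trk", "load_trk", "save_tsv", "load_tsv"]

_EPS = 1e-6  # voxel-boundary nudge for deterministic edge/corner handling
_MAX_STEPS = 100_000


@dataclass
class TrackingConfig:
    fa_threshold: float = 0.15
    angle_threshold: float = 45.0  # degrees
    min_points: int = 3

    def __post_init__(self) -> None:
        if not 0 <= self.fa_threshold <= 1:
            raise ValueError("fa_threshold must be in [0, 1]")
        if not 0 < self.angle_threshold < 90:
            raise ValueError("angle_threshold must be in (0, 90) degrees")
        if self.min_points < 2:
            raise ValueError("min_points must be >= 2")


@dataclass
class Streamline:
    """Ordered polyline in continuous voxel coordinates plus its seed voxel."""

    points: np.ndarray
    seed: tuple[int, int, int]

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if len(self.points) < 2:
            raise ValueError("a streamline needs at least 2 points")
        if np.any(np.all(np.diff(self.points, axis=0) == 0, axis=1)):
            raise ValueError("consecutive streamline points must be distinct")

    def __len__(self) -> int:
        return len(self.points)


def _voxel_exit(p: np.ndarray, d: np.ndarray, voxel: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray]:
    """Exit point of the ray p + t*d from the axis-aligned unit voxel, and the
    next voxel index (ties at edges/corners resolved by a small advance along d)."""
    with np.errstate(divide="ignore"):
        t_hi = np.where(d > 0, (voxel + 1.0 - p) / d, np.inf)
        t_lo = np.where(d < 0, (voxel - p) / d, np.inf)
    t = float(np.minimum(t_hi, t_lo).min())
    exit_p = p + t * d
    next_v = np.floor(exit_p + _EPS * d).astype(int)
    return exit_p, next_v


def _half_track(tv: TensorVolume, seed: np.ndarray, d0: np.ndarray,
                cos_thr: float, fa_thr: float) -> list[np.ndarray]:
    """Points visited from the seed center along d0 (seed center excluded)."""
    fa = tv.fa
    dirs = tv.principal_dirs
    shape = np.asarray(tv.shape)
    v = seed.copy()
    p = seed + 0.5
    d = d0
    pts: list[np.ndarray] = []
    for _ in range(_MAX_STEPS):
        exit_p, nv = _voxel_exit(p, d, v)
        pts.append(exit_p)
        if np.any(nv < 0) or np.any(nv >= shape):
            break
        if fa[tuple(nv)] < fa_thr:
            break
        nd = dirs[tuple(nv)]
        if float(nd @ d) < 0:
            nd = -nd
        if float(nd @ d) < cos_thr:
            break
        p, v, d = exit_p, nv, nd
    return pts


def fact_track(tv: TensorVolume, cfg: TrackingConfig | None = None
               ) -> list[Streamline]:
    """Whole-volume deterministic tracking, one seed at every passing voxel.

    Seeds are masked voxels with FA >= ``fa_threshold``, visited in fixed
    C order, so output is fully deterministic. Streamlines shorter than
    ``min_points`` are discarded.
    """
    if cfg is None:
        cfg = TrackingConfig()
    cos_thr = float(np.cos(np.deg2rad(cfg.angle_threshold)))
    seeds = np.argwhere((tv.fa >= cfg.fa_threshold) & tv.mask)
    out: list[Streamline] = []
    for seed in seeds:
        d0 = tv.principal_dirs[tuple(seed)]
        fwd = _half_track(tv, seed, d0, cos_thr, cfg.fa_threshold)
        bwd = _half_track(tv, seed, -d0, cos_thr, cfg.fa_threshold)
        center = seed + 0.5
        pts = bwd[::-1] + [center] + fwd
        arr = np.asarray(pts)
        keep = np.r_[True, np.any(np.diff(arr, axis=0) != 0, axis=1)]
        arr = arr[keep]
        if len(arr) >= cfg.min_points:
            out.append(Streamline(arr, tuple(int(x) for x in seed)))
    return out


def streamline_voxels(s: Streamline | np.ndarray,
                      shape: tuple[int, int, int] | None = None) -> np.ndarray:
    """Ordered voxel indices a polyline passes through, consecutive dups removed.

    Exact axis-aligned grid traversal of every segment (no resampling); a point
    lying exactly on a face is attributed to the voxel ahead of it along the
    direction of travel.
    """
    pts = s.points if isinstance(s, Streamline) else np.atleast_2d(np.asarray(s, float))
    d0 = pts[1] - pts[0] if len(pts) > 1 else np.ones(3)
    cur = np.floor(pts[0] + _EPS * np.sign(d0)).astype(int)
    visited = [cur.copy()]
    p = pts[0].astype(float)
    for target in pts[1:]:
        d = target - p
        if not np.any(d):
            continue
        while True:
            exit_p, nv = _voxel_exit(p, d, cur)
            # stop if the segment ends before the boundary crossing
            t = np.linalg.norm(exit_p - p) / np.linalg.norm(target - p) \
                if np.linalg.norm(target - p) > 0 else np.inf
            if t >= 1.0 - 1e-12:
                break
            p = exit_p
            cur = nv
            visited.append(cur.copy())
            d = target - p
            if not np.any(d):
                break
        p = target.astype(float)
    vox = np.asarray(visited)
    keep = np.r_[True, np.any(np.diff(vox, axis=0) != 0, axis=1)]
    vox = vox[keep]
    if shape is not None:
        inside = np.all((vox >= 0) & (vox < np.asarray(shape)), axis=1)
        vox = vox[inside]
    return vox


# ---------------------------------------------------------------------------
# IO: TrackVis TRK (voxel-mm convention) and plain TSV
# ---------------------------------------------------------------------------

def save_trk(streamlines: list[Streamline], path,
             shape: tuple[int, int, int],
             voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> None:
    """Write a TrackVis file; points stored via the voxel->mm scaling affine."""
    import nibabel as nib
    from nibabel.streamlines import Tractogram
    from nibabel.streamlines.trk import TrkFile

    affine = np.diag(list(voxel_size) + [1.0])
    tg = Tractogram([s.points for s in streamlines], affine_to_rasmm=affine)
    header = {
        "dimensions": np.asarray(shape, dtype=np.int16),
        "voxel_sizes": np.asarray(voxel_size, dtype=np.float32),
        "voxel_to_rasmm": affine.astype(np.float32),
        "voxel_order": "RAS",
    }
    TrkFile(tg, header=header).save(str(path))


def load_trk(path) -> list[Streamline]:
    from nibabel.streamlines import load as trk_load

    trk = trk_load(str(path))
    affine = trk.header["voxel_to_rasmm"].astype(float)
    inv = np.linalg.inv(affine)
    out = []
    for pts in trk.tractogram.streamlines:
        vox = pts @ inv[:3, :3].T + inv[:3, 3]
        out.append(Streamline(vox, seed=(0, 0, 0)))
    return out


def save_tsv(streamlines: list[Streamline], path) -> None:
    rows = []
    for sid, s in enumerate(streamlines):
        for k, (x, y, z) in enumerate(s.points):
            rows.append((sid, k, x, y, z))
    pd.DataFrame(rows, columns=["streamline_id", "point_index", "x", "y", "z"]
                 ).to_csv(path, sep="\t", index=False)


def load_tsv(path) -> list[Streamline]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, grp in df.groupby("streamline_id", sort=True):
        grp = grp.sort_values("point_index")
        out.append(Streamline(grp[["x", "y", "z"]].to_numpy(float),
                              seed=(0, 0, 0)))
    return out
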