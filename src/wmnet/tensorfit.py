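"""Diffusion tensor estimation and fractional anisotropy.

Per-voxel log-linear ordinary least squares on the single-tensor signal model

    S_i = S0 * exp(-b_i * g_i' D g_i)

followed by an eigendecomposition of the symmetric tensor D to obtain sorted
eigenvalues, the principal diffusion direction e1, and FA

    FA = sqrt(3/2) * sqrt(sum_i (lam_i - mean(lam))^2) / sqrt(sum_i lam_i^2).

OLS on log(S/S0) is the minimal estimator for this model; weighted or robust
variants are deliberately out of scope. Signals <= 0 are clamped to a small
positive floor before the log, and eigenvalues that come out slightly negative
under noise are clamped to zero for the FA computation only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

log = logging.getLogger(__name__)

#: fraction of S0 used as the positive signal floor before taking logs
SIGNAL_FLOOR_FRACTION = 1e-6
#: eigenvalue gap below which the principal direction is flagged degenerate
DEGENERACY_TOL = 1e-12


def compute_fa(evals: np.ndarray) -> np.ndarray:
    """Fractional anisotropy from eigenvalues, vectorised over leading axes.

    Parameters
    ----------
    evals : array, shape (..., 3)
        Tensor eigenvalues. Slightly negative values (noise) are clamped to 0.

    Returns
    -------
    array, shape (...)
        FA clipped to [0, 1]; 0 where all three eigenvalues vanish.
    """
    lam = np.clip(np.asarray(evals, dtype=float), 0.0, None)
    mean = lam.mean(axis=-1, keepdims=True)
    num = np.sqrt((np.square(lam - mean)).sum(axis=-1))
    den = np.sqrt(np.square(lam).sum(axis=-1))
    with np.errstate(divide="ignore", invalid="ignore"):
        fa = np.sqrt(1.5) * num / den
    fa = np.where(den > 0, fa, 0.0)
    return np.clip(fa, 0.0, 1.0)


@dataclass
class TensorVolume:
    """A 3D grid of symmetric 3x3 diffusion tensors.

    ``tensors`` has shape (X, Y, Z, 3, 3) in mm^2/s; ``voxel_size`` is in mm;
    ``mask`` marks voxels considered brain. Eigen-derived maps are computed
    lazily and cached.
    """

    tensors: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.tensors = np.asarray(self.tensors, dtype=float)
        if self.tensors.ndim != 5 or self.tensors.shape[-2:] != (3, 3):
            raise ValueError("tensors must have shape (X, Y, Z, 3, 3)")
        if self.mask is None:
            self.mask = np.ones(self.tensors.shape[:3], dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.shape:
            raise ValueError("mask shape does not match tensor grid")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.tensors.shape[:3]

    @cached_property
    def _eig(self) -> tuple[np.ndarray, np.ndarray]:
        # eigh returns ascending eigenvalues; flip to descending
        w, v = np.linalg.eigh(self.tensors)
        return w[..., ::-1], v[..., ::-1]

    @property
    def evals(self) -> np.ndarray:
        """Eigenvalues, descending, shape (X, Y, Z, 3)."""
        return self._eig[0]

    @property
    def evecs(self) -> np.ndarray:
        """Eigenvectors as columns matching ``evals``, shape (X, Y, Z, 3, 3)."""
        return self._eig[1]

    @cached_property
    def fa(self) -> np.ndarray:
        """FA map, zero outside the mask."""
        fa = compute_fa(self.evals)
        return np.where(self.mask, fa, 0.0)

    @cached_property
    def principal_dirs(self) -> np.ndarray:
        """Unit principal eigenvector per voxel, shape (X, Y, Z, 3).

        The sign is arbitrary; tracking aligns it against the incoming
        direction at every voxel entry.
        """
        return self.evecs[..., 0]


def principal_direction(D: np.ndarray) -> np.ndarray:
    """Principal eigenvector of one symmetric 3x3 tensor (sign-ambiguous).

    A near-degenerate leading eigenvalue pair (gap < 1e-12) is resolved by the
    fixed ordering of the eigensolver and logged.
    """
    w, v = np.linalg.eigh(np.asarray(D, dtype=float))
    if abs(w[2] - w[1]) < DEGENERACY_TOL:
        log.warning("degenerate principal direction: lam1 ~= lam2 (%g ~ %g)", w[2], w[1])
    return v[:, 2]


@dataclass
class GradientTable:
    """Diffusion gradient scheme: b-values (s/mm^2) and unit b-vectors.

    b0 entries have b = 0; every nonzero-b direction must be unit norm. At
    least 6 distinct nonzero-b directions and one b0 are required for the
    six-element tensor fit.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.shape != (self.bvals.size, 3):
            raise ValueError("bvecs must have shape (len(bvals), 3)")
        nz = self.bvals > 0
        norms = np.linalg.norm(self.bvecs[nz], axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("nonzero-b directions must be unit vectors")
        if nz.sum() < 6:
            raise ValueError("need at least 6 nonzero-b directions")
        if (~nz).sum() < 1:
            raise ValueError("need at least one b0 volume")

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    @classmethod
    def fibonacci_scheme(cls, n_dirs: int = 32, b: float = 1000.0,
                         n_b0: int = 1) -> "GradientTable":
        """Deterministic golden-angle spiral of ``n_dirs`` directions plus b0s.

        Emulates a clinical single-shell scheme (default b = 1000 s/mm^2,
        32 directions).
        """
        i = np.arange(n_dirs)
        phi = np.pi * (3.0 - np.sqrt(5.0)) * i
        z = 1.0 - (2.0 * i + 1.0) / n_dirs
        r = np.sqrt(1.0 - z * z)
        dirs = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
        bvals = np.concatenate([np.zeros(n_b0), np.full(n_dirs, float(b))])
        bvecs = np.vstack([np.zeros((n_b0, 3)), dirs])
        return cls(bvals, bvecs)

    def save(self, bval_path, bvec_path) -> None:
        """Write FSL-style .bval/.bvec text (one row; bvec as 3 rows)."""
        np.savetxt(bval_path, self.bvals[None, :], fmt="%g")
        np.savetxt(bvec_path, self.bvecs.T, fmt="%.10g")

    @classmethod
    def load(cls, bval_path, bvec_path) -> "GradientTable":
        bvals = np.loadtxt(bval_path).ravel()
        bvecs = np.loadtxt(bvec_path)
        if bvecs.shape[0] == 3:
            bvecs = bvecs.T
        return cls(bvals, bvecs)


def design_matrix(gt: GradientTable) -> np.ndarray:
    """OLS design for the six unique tensor elements, rows = nonzero-b volumes.

    Column order: Dxx, Dyy, Dzz, Dxy, Dxz, Dyz.
    """
    nz = ~gt.b0_mask
    g = gt.bvecs[nz]
    b = gt.bvals[nz]
    gx, gy, gz = g[:, 0], g[:, 1], g[:, 2]
    B = np.column_stack([gx * gx, gy * gy, gz * gz,
                         2 * gx * gy, 2 * gx * gz, 2 * gy * gz])
    return b[:, None] * B


def _six_to_tensor(d: np.ndarray) -> np.ndarray:
    """(..., 6) unique elements -> (..., 3, 3) symmetric tensors."""
    D = np.empty(d.shape[:-1] + (3, 3), dtype=float)
    D[..., 0, 0] = d[..., 0]
    D[..., 1, 1] = d[..., 1]
    D[..., 2, 2] = d[..., 2]
    D[..., 0, 1] = D[..., 1, 0] = d[..., 3]
    D[..., 0, 2] = D[..., 2, 0] = d[..., 4]
    D[..., 1, 2] = D[..., 2, 1] = d[..., 5]
    return D


def fit_tensor(dwi: np.ndarray, gt: GradientTable,
               mask: np.ndarray | None = None,
               voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
               ) -> TensorVolume:
    """Fit the diffusion tensor per voxel by log-linear OLS.

    Parameters
    ----------
    dwi : array, shape (X, Y, Z, N)
        Signal volumes in gradient-table order (b0s included).
    gt : GradientTable
    mask : bool array (X, Y, Z), optional
        Voxels to fit; others get zero tensors.

    Raises
    ------
    ValueError
        If the gradient directions are collinear (rank-deficient design).
    """
    dwi = np.asarray(dwi, dtype=float)
    if dwi.ndim != 4 or dwi.shape[3] != gt.bvals.size:
        raise ValueError("dwi must be (X, Y, Z, n_volumes) matching the gradient table")
    B = design_matrix(gt)
    rank = np.linalg.matrix_rank(B)
    if rank < 6:
        raise ValueError(
            f"rank-deficient gradient design (rank {rank} < 6): "
            "directions are collinear/coplanar; a full tensor cannot be estimated"
        )
    shape = dwi.shape[:3]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)

    s0 = dwi[..., gt.b0_mask].mean(axis=-1)  # average multiple b0s
    if np.any(s0[mask] <= 0):
        raise ValueError("nonpositive b0 signal inside the mask")

    sig = dwi[..., ~gt.b0_mask][mask]                     # (n_vox, n_dirs)
    floor = SIGNAL_FLOOR_FRACTION * s0[mask][:, None]
    sig = np.maximum(sig, floor)
    y = -np.log(sig / s0[mask][:, None])                  # (n_vox, n_dirs)
    coef = y @ np.linalg.pinv(B).T                        # (n_vox, 6)

    tensors = np.zeros(shape + (3, 3), dtype=float)
    tensors[mask] = _six_to_tensor(coef)
    return TensorVolume(tensors, voxel_size=voxel_size, mask=mask)
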