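"""Synthetic inputs for every pipeline stage.

Two generator families:

* **DWI phantoms** — voxel grids of single diffusion tensors laid out along
  analytic fiber bundles, plus the forward single-tensor signal model with
  Rician noise. These exercise tensor fitting, FACT tracking and connectome
  construction with known ground truth.
* **Connectome cohorts** — groups of sparse symmetric nonnegative 90-node
  matrices sharing one modular small-world template, with subject-level
  multiplicative lognormal noise, optional edge dropout, and an optional
  planted group-difference on a connected edge set. Defaults emulate a
  two-group clinical study: 21 patients vs 25 controls, patient ages
  ~37.5+/-11.6 vs ~31.4+/-11.0 years, patient depression-severity (HDRS)
  scores in 18-34, illness duration 1-10 months, and a 7-edge/8-node
  fronto-subcortical-limbic decreased subnetwork.

All randomness flows from one explicit seed per spec; same seed, same bits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .regions import AAL90_CODES, PLANTED_EDGES
from .tensorfit import GradientTable, TensorVolume

__all__ = [
    "Bundle", "PhantomSpec", "gen_tensor_phantom", "gen_dwi_from_tensors",
    "CohortSpec", "Cohort", "gen_template", "gen_cohort",
]


# ---------------------------------------------------------------------------
# DWI phantoms
# ---------------------------------------------------------------------------

@dataclass
class Bundle:
    """One fiber bundle: a tube of given radius around a centerline polyline.

    ``centerline`` is (M, 3) in continuous voxel coordinates; ``eigvals`` are
    the tensor eigenvalues (lam1 > lam2 = lam3, mm^2/s) assigned inside the
    tube, with the principal axis along the local centerline tangent.
    """

    centerline: np.ndarray
    radius: float = 2.0
    eigvals: tuple[float, float, float] = (1.7e-3, 3.0e-4, 3.0e-4)

    def __post_init__(self) -> None:
        self.centerline = np.atleast_2d(np.asarray(self.centerline, dtype=float))
        if self.centerline.shape[0] < 2 or self.centerline.shape[1] != 3:
            raise ValueError("centerline must be an (M>=2, 3) polyline")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        l1, l2, l3 = self.eigvals
        if not (l1 >= l2 == l3 > 0):
            raise ValueError("eigvals must satisfy lam1 >= lam2 == lam3 > 0")


@dataclass
class PhantomSpec:
    """Geometry and signal parameters of a tensor phantom."""

    shape: tuple[int, int, int]
    bundles: list[Bundle] = field(default_factory=list)
    background_adc: float = 7.0e-4
    s0: float = 1000.0
    noise_sigma: float = 0.0
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ValueError("shape must be three positive ints")
        if self.background_adc <= 0:
            raise ValueError("background_adc must be positive")
        if self.s0 <= 0:
            raise ValueError("S0 must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")


def _polyline_closest(points: np.ndarray, line: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Distance from each point to a polyline and the tangent at the closest spot."""
    a, b = line[:-1], line[1:]                       # (S, 3) segment ends
    ab = b - a
    ab2 = (ab * ab).sum(axis=1)                      # (S,)
    # t of the projection of each point on each segment, clipped to [0, 1]
    ap = points[:, None, :] - a[None, :, :]          # (P, S, 3)
    t = np.clip((ap * ab[None]).sum(axis=2) / ab2[None], 0.0, 1.0)
    proj = a[None] + t[..., None] * ab[None]         # (P, S, 3)
    d = np.linalg.norm(points[:, None, :] - proj, axis=2)
    idx = d.argmin(axis=1)
    tangents = ab[idx] / np.linalg.norm(ab[idx], axis=1, keepdims=True)
    return d[np.arange(len(points)), idx], tangents


def gen_tensor_phantom(spec: PhantomSpec) -> tuple[TensorVolume, np.ndarray]:
    """Build a tensor volume with anisotropic tubes on an isotropic background.

    Voxels within ``radius`` of a bundle centerline get the tensor
    ``lam2*I + (lam1-lam2) * t t'`` with t the local tangent; all other voxels
    get ``background_adc * I``. Where bundles overlap, the first-listed bundle
    wins.

    Returns the TensorVolume and a boolean mask of bundle voxels.
    """
    nx, ny, nz = spec.shape
    centers = np.stack(np.meshgrid(
        np.arange(nx) + 0.5, np.arange(ny) + 0.5, np.arange(nz) + 0.5,
        indexing="ij"), axis=-1).reshape(-1, 3)

    tensors = np.broadcast_to(
        spec.background_adc * np.eye(3), (centers.shape[0], 3, 3)).copy()
    assigned = np.zeros(centers.shape[0], dtype=bool)

    for bundle in spec.bundles:
        dist, tang = _polyline_closest(centers, bundle.centerline)
        inside = (dist <= bundle.radius) & ~assigned
        l1, l2, _ = bundle.eigvals
        outer = tang[inside, :, None] * tang[inside, None, :]
        tensors[inside] = l2 * np.eye(3) + (l1 - l2) * outer
        assigned |= inside

    vol = TensorVolume(tensors.reshape(nx, ny, nz, 3, 3),
                       voxel_size=spec.voxel_size)
    return vol, assigned.reshape(nx, ny, nz)


def gen_dwi_from_tensors(tensors: TensorVolume, gt: GradientTable,
                         s0: float = 1000.0, noise_sigma: float = 0.0,
                         seed: int | None = 0) -> np.ndarray:
    """Forward single-tensor signal S_i = S0 exp(-b_i g_i' D g_i), + Rician noise.

    Rician noise is the magnitude of a complex Gaussian perturbation (sigma per
    channel), the standard MR magnitude-noise model. With ``noise_sigma=0`` the
    output is deterministic.
    """
    if s0 <= 0:
        raise ValueError("S0 must be positive")
    D = tensors.tensors
    g = gt.bvecs
    # quadratic form g' D g per voxel per direction
    q = np.einsum("...ij,ni,nj->...n", D, g, g)
    signal = s0 * np.exp(-gt.bvals * q)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        re = signal + rng.normal(0.0, noise_sigma, signal.shape)
        im = rng.normal(0.0, noise_sigma, signal.shape)
        signal = np.hypot(re, im)
    return signal


# ---------------------------------------------------------------------------
# Connectome cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Parameters of a two-group synthetic connectome cohort.

    The template is a modular small-world weighted graph: ``n_modules``
    node blocks with ``intra_frac`` of edges inside modules (dense, cliquish)
    and the rest as inter-module shortcuts. Weights are lognormal, clipped to
    the FN x FA plausible range [1, 300], with intra-module edges boosted so
    sparsity thresholding preferentially retains the modular core.

    ``effect_edges`` (undirected node pairs, 0-based) are multiplied by
    ``1 - effect_size`` in the patient group; they are forced into the
    template support.
    """

    n_patients: int = 21
    n_controls: int = 25
    n_nodes: int = 90
    density: float = 0.15
    effect_edges: tuple[tuple[int, int], ...] = PLANTED_EDGES
    effect_size: float = 0.4
    subject_noise_sd: float = 0.2
    dropout: float = 0.02
    n_modules: int = 6
    intra_frac: float = 0.85
    weight_mu: float = 3.0
    weight_sigma: float = 1.0
    intra_boost: float = 3.0
    patient_age: tuple[float, float] = (37.5, 11.6)
    control_age: tuple[float, float] = (31.4, 11.0)
    hdrs_mean_sd: tuple[float, float] = (24.4, 4.1)
    hdrs_range: tuple[int, int] = (18, 34)
    duration_range: tuple[int, int] = (1, 10)
    n_female: tuple[int, int] = (8, 8)   # per group, Table-1-style counts
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.n_controls < 1:
            raise ValueError("group sizes must be positive")
        if not 0 < self.density <= 1:
            raise ValueError("density must be in (0, 1]")
        if not 0 <= self.effect_size < 1:
            raise ValueError("effect_size must be in [0, 1)")
        if self.subject_noise_sd < 0 or self.dropout < 0:
            raise ValueError("noise/dropout must be nonnegative")
        seen = set()
        for i, j in self.effect_edges:
            if i == j:
                raise ValueError("effect edges must be off-diagonal")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError("effect edges must be distinct")
            if not (0 <= i < self.n_nodes and 0 <= j < self.n_nodes):
                raise ValueError("effect edge node out of range")
            seen.add(key)


def _module_assignment(n_nodes: int, n_modules: int) -> list[np.ndarray]:
    return list(map(np.asarray, np.array_split(np.arange(n_nodes), n_modules)))


def gen_template(spec: CohortSpec, rng: np.random.Generator | None = None
                 ) -> np.ndarray:
    """Modular small-world weighted template matrix (symmetric, zero diagonal).

    Edge count is exactly ``round(density * n(n-1)/2)``; ``effect_edges`` are
    always part of the support.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = spec.n_nodes
    n_edges = int(round(spec.density * n * (n - 1) / 2))
    modules = _module_assignment(n, spec.n_modules)
    member = np.empty(n, dtype=int)
    for m, nodes in enumerate(modules):
        member[nodes] = m

    chosen: set[tuple[int, int]] = set()
    for i, j in spec.effect_edges:
        chosen.add((min(i, j), max(i, j)))

    # intra-module edges, spread proportionally to module capacity
    n_intra = min(int(round(spec.intra_frac * n_edges)),
                  sum(len(m) * (len(m) - 1) // 2 for m in modules))
    caps = np.array([len(m) * (len(m) - 1) // 2 for m in modules], dtype=float)
    quota = np.floor(n_intra * caps / caps.sum()).astype(int)
    for m, nodes in enumerate(modules):
        pairs = [(int(a), int(b)) for ai, a in enumerate(nodes)
                 for b in nodes[ai + 1:]]
        pool = [p for p in pairs if p not in chosen]
        take = min(quota[m], len(pool))
        idx = rng.choice(len(pool), size=take, replace=False)
        chosen.update(pool[k] for k in idx)

    # inter-module shortcuts until the target count is met
    while len(chosen) < n_edges:
        i, j = rng.integers(0, n, size=2)
        if i == j or member[i] == member[j]:
            continue
        chosen.add((min(i, j), max(i, j)))

    W = np.zeros((n, n), dtype=float)
    edges = sorted(chosen)
    w = np.clip(rng.lognormal(spec.weight_mu, spec.weight_sigma, len(edges)),
                1.0, 300.0)
    for (i, j), wij in zip(edges, w):
        if member[i] == member[j]:
            wij = min(wij * spec.intra_boost, 300.0)
        W[i, j] = W[j, i] = wij
    return W


@dataclass
class Cohort:
    """Subject connectomes plus manifest and planted ground truth.

    ``matrices`` has shape (n_subjects, n, n); ``manifest`` carries columns
    subject_id, group ('patient'/'control'), age, sex, HDRS, duration_months.
    """

    matrices: np.ndarray
    manifest: pd.DataFrame
    codes: tuple[str, ...] = AAL90_CODES
    ground_truth: dict | None = None

    @property
    def n_nodes(self) -> int:
        return self.matrices.shape[1]

    @property
    def patient_mask(self) -> np.ndarray:
        return (self.manifest["group"] == "patient").to_numpy()

    def group_matrices(self) -> tuple[np.ndarray, np.ndarray]:
        """(patients, controls) matrix stacks."""
        m = self.patient_mask
        return self.matrices[m], self.matrices[~m]

    # -- IO ------------------------------------------------------------
    def save(self, outdir) -> None:
        """One CSV per subject (region codes as header), manifest CSV, and a
        JSON ground-truth sidecar."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for sid, mat in zip(self.manifest["subject_id"], self.matrices):
            pd.DataFrame(mat, index=self.codes, columns=self.codes).to_csv(
                outdir / f"{sid}.csv")
        self.manifest.to_csv(outdir / "manifest.csv", index=False)
        if self.ground_truth is not None:
            gt = dict(self.ground_truth)
            gt["effect_edges"] = [list(map(int, e)) for e in gt["effect_edges"]]
            (outdir / "ground_truth.json").write_text(json.dumps(gt, indent=2))

    @classmethod
    def load(cls, indir) -> "Cohort":
        indir = Path(indir)
        manifest = pd.read_csv(indir / "manifest.csv")
        mats, codes = [], None
        for sid in manifest["subject_id"]:
            df = pd.read_csv(indir / f"{sid}.csv", index_col=0)
            codes = tuple(df.columns)
            mats.append(df.to_numpy(dtype=float))
        gt_path = indir / "ground_truth.json"
        gt = json.loads(gt_path.read_text()) if gt_path.exists() else None
        if gt is not None:
            gt["effect_edges"] = [tuple(e) for e in gt["effect_edges"]]
        return cls(np.stack(mats), manifest, codes=codes, ground_truth=gt)


def _covariates(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for group, n_sub, (mu, sd), n_f in (
            ("patient", spec.n_patients, spec.patient_age, spec.n_female[0]),
            ("control", spec.n_controls, spec.control_age, spec.n_female[1])):
        age = np.clip(rng.normal(mu, sd, n_sub), 18, 60)
        sex = np.array(["F"] * min(n_f, n_sub) + ["M"] * max(n_sub - n_f, 0))
        rng.shuffle(sex)
        if group == "patient":
            lo, hi = spec.hdrs_range
            hdrs = np.clip(np.rint(rng.normal(*spec.hdrs_mean_sd, n_sub)),
                           lo, hi).astype(int)
            dlo, dhi = spec.duration_range
            dur = np.clip(np.rint(rng.lognormal(np.log(3.0), 0.6, n_sub)),
                          dlo, dhi).astype(int)
        else:
            hdrs = np.full(n_sub, np.nan)
            dur = np.full(n_sub, np.nan)
        for k in range(n_sub):
            rows.append((group, round(float(age[k]), 1), sex[k],
                         hdrs[k], dur[k]))
    df = pd.DataFrame(rows, columns=["group", "age", "sex", "HDRS",
                                     "duration_months"])
    df.insert(0, "subject_id", [f"sub-{i + 1:03d}" for i in range(len(df))])
    return df


def gen_cohort(spec: CohortSpec,
               template: np.ndarray | None = None) -> Cohort:
    """Generate a two-group cohort of noisy copies of one template connectome.

    Each subject's nonzero weights are the template's multiplied by iid
    lognormal factors with unit mean (sigma = ``subject_noise_sd``); each edge
    independently drops out with probability ``dropout``. Patient weights on
    ``effect_edges`` are further multiplied by ``1 - effect_size``, so the
    planted group-mean difference is ``effect_size x template weight``.

    A caller-supplied ``template`` must contain every effect edge in its
    support, else a ValueError is raised.
    """
    rng = np.random.default_rng(spec.seed)
    if template is None:
        template = gen_template(spec, rng)
    else:
        template = np.asarray(template, dtype=float)
        for i, j in spec.effect_edges:
            if template[i, j] == 0:
                raise ValueError(
                    f"effect edge ({i}, {j}) absent from template support")

    n_sub = spec.n_patients + spec.n_controls
    n = spec.n_nodes
    iu = np.triu_indices(n, k=1)
    base = template[iu]
    support = base > 0

    sd = spec.subject_noise_sd
    mu = -0.5 * sd * sd  # unit-mean lognormal
    factors = (rng.lognormal(mu, sd, size=(n_sub, base.size))
               if sd > 0 else np.ones((n_sub, base.size)))
    if spec.dropout > 0:
        keep = rng.random((n_sub, base.size)) >= spec.dropout
        factors = factors * keep
    weights = base[None, :] * factors * support[None, :]

    if spec.effect_size > 0 and spec.effect_edges:
        eff_cols = []
        col_of = {}
        for k, (i, j) in enumerate(zip(*iu)):
            col_of[(int(i), int(j))] = k
        for i, j in spec.effect_edges:
            eff_cols.append(col_of[(min(i, j), max(i, j))])
        weights[:spec.n_patients, eff_cols] *= (1.0 - spec.effect_size)

    matrices = np.zeros((n_sub, n, n), dtype=float)
    matrices[:, iu[0], iu[1]] = weights
    matrices += matrices.transpose(0, 2, 1)

    manifest = _covariates(spec, rng)
    codes = AAL90_CODES if n == 90 else tuple(f"R{i + 1:02d}" for i in range(n))
    gt = {
        "effect_edges": [tuple(map(int, e)) for e in spec.effect_edges],
        "effect_size": spec.effect_size,
        "seed": spec.seed,
        "template_density": float(support.mean()),
    }
    return Cohort(matrices, manifest, codes=codes, ground_truth=gt)
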