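# Methods

`wmnet` implements a whole-brain white-matter structural-network analysis
pipeline of the kind used in clinical diffusion-MRI group studies: diffusion
tensor estimation, deterministic tractography, weighted connectome
construction, sparsity-swept graph-theory metrics with small-world
normalization, network-based statistic (NBS) inference, and the surrounding
clinical statistics. Because no patient data ship with the package, a
synthetic-data module generates DWI phantoms with known fiber geometry and
two-group connectome cohorts with a planted group difference; every empirical
statement below is one the test suite or `scripts/acceptance.py` computes at
run time.

## Diffusion model and tensor fitting

The signal model is the single diffusion tensor, S_i = S0 exp(−b_i g_iᵀ D g_i),
with b in s/mm² and D in mm²/s. Fitting is per-voxel ordinary least squares on
log(S/S0) for the six unique tensor elements. OLS is the minimal estimator for
this model; weighted least squares and robust variants change little on the
synthetic data used here and are out of scope. Numerical choices:

- multiple b0 volumes are averaged before forming the ratio;
- signals ≤ 0 (possible under Rician noise) are clamped to 1e−6·S0 before the
  logarithm;
- eigenvalues that come out slightly negative are clamped to zero for the FA
  computation only, and FA is clipped to [0, 1];
- a gradient scheme whose design matrix has rank < 6 is rejected with an error
  naming the deficiency;
- a near-degenerate leading eigenvalue pair (gap < 1e−12) makes the principal
  direction ill-defined; the eigensolver's fixed ordering breaks the tie and a
  warning is logged.

The default synthetic gradient scheme is a deterministic golden-angle spiral
of 32 unit directions at b = 1000 s/mm² plus one b0, emulating a clinical
single-shell acquisition. Rician noise is implemented as the magnitude of a
complex Gaussian perturbation of the noiseless signal.

## FACT tractography

Tracking is deterministic fiber assignment by continuous tracking: inside a
voxel the trajectory follows that voxel's principal eigenvector; voxel transit
is an exact ray/axis-aligned-box intersection. Coordinates are 0-based
continuous voxel space with voxel centers at integer + 0.5. Termination and
seeding rules:

- stop on entering a voxel with FA < 0.15 (default) or when the sign-aligned
  turn from the previous direction exceeds 45° (default);
- the voxel that fails a test is **not** appended — termination happens at its
  entry face. This boundary convention is ours; alternatives shift endpoints
  by at most one voxel;
- one seed per voxel center, at every voxel passing the FA gate; the two
  half-tracks along ±e1 are merged. The FA gate itself restricts seeding to
  coherent (high-anisotropy) tissue, which is how we reconcile "seed
  everywhere" with tracking that effectively starts in deep white matter;
- streamlines shorter than `min_points = 3` (≈ two voxel transits) are
  discarded as single-voxel debris;
- ties at voxel edges/corners are resolved by advancing 1e−6 voxels along the
  travel direction, making the whole procedure deterministic; identical inputs
  give bit-identical streamline sets.

`streamline_voxels` enumerates traversed voxels by exact grid traversal of the
polyline (verified in tests against dense 0.005-voxel resampling).

## Connectome construction

Nodes are the 90 cerebral regions of the AAL atlas (45 per hemisphere),
supplied as an integer label volume. An edge's weight is
w_ij = FN_ij × FA_ij: the streamline count between regions i and j times the
mean FA along the connecting bundles. Conventions:

- a streamline's endpoint region is the label of the voxel containing its
  terminal point, nudged 1e−6 voxels inward along the final segment because
  terminal points sit exactly on voxel faces; no dilation or search radius;
- streamlines with a background endpoint or both endpoints in one region are
  discarded (counted, so FN accounting is conserved);
- FA_ij pools per-voxel FA samples across all connecting streamlines (each
  streamline contributes its traversed-voxel FA values; shared voxels count
  once per streamline). A per-streamline-mean alternative is available via
  `fa_pooling="streamline"`; the two coincide for equal-length paths;
- pairs with FN < 3 are zeroed (strictly below 3; FN = 3 is kept), removing
  likely spurious connections.

## Graph metrics

All metrics follow the Rubinov–Sporns weighted conventions. Weights are first
normalized by the matrix maximum, so ŵ ∈ [0, 1] and Cp, Eglob, Eloc, Enodal
are all bounded by 1:

- Cp: mean over nodes of Onnela's clustering, C_i = Σ_{jh}(ŵ_ij ŵ_ih ŵ_jh)^{1/3}
  / (k_i(k_i−1)); nodes with degree < 2 contribute 0;
- distances: shortest paths with edge length 1/ŵ (Dijkstra);
- Lp: mean distance over *reachable* off-diagonal pairs — excluding
  unreachable pairs keeps Lp finite on the sparse end of the sweep, and this
  choice propagates into λ;
- Eglob and Enodal: mean inverse distance with unreachable pairs contributing
  0; Eloc: mean over nodes of the efficiency of each node's neighbor-induced
  subgraph, keeping the globally normalized weights (no per-subgraph
  renormalization);
- the all-zero matrix yields all-zero metrics (logged) rather than an error.

Sparsity thresholding keeps the ⌊S·N(N−1)/2⌋ largest-weight edges (weights
retained, not binarized; a `binarize` flag exists because toolboxes differ
here), with ties broken lexicographically so runs are reproducible. The sweep
is S = 0.05 to 0.40 in 0.01 steps — 36 points, interpreted as the closed
interval — and each metric curve is summarized by its trapezoidal AUC.

Small-world normalization uses M = 100 degree-preserving Maslov–Sneppen
rewired nulls per graph (10 successful double-edge swaps per edge), with the
original weight multiset randomly reassigned to the rewired topology. Then
γ = Cp/⟨Cp_rand⟩, λ = Lp/⟨Lp_rand⟩, σ = γ/λ. M and the rewiring depth are
configuration, not science: 100 nulls puts the Monte-Carlo error of ⟨Cp_rand⟩
well below the effect sizes of interest at this graph size. A graph too
sparse to swap raises an error suggesting a higher S.

## Network-based statistic

Edge-wise pooled-variance two-sample t-statistics (zeros are data; edges with
zero pooled variance are undefined and excluded) are thresholded at t = 2.1,
one-sided per direction; the connected components of the suprathreshold graph
are the candidate subnetworks. Significance uses the permutation distribution
of the *maximal* component extent (edge count) over 5000 random relabelings
of subjects into groups of the original sizes, with the add-one correction
p = (1 + #{max extent ≥ k}) / (P + 1), which guarantees p ∈ (0, 1]. Choices:

- component statistic is extent; intensity (sum of t − threshold) is a config
  option;
- `direction="both"` runs two one-sided analyses, each against its own null;
- no covariate adjustment inside the permutation scheme and no
  minimum-prevalence edge mask by default;
- subjects are canonically ordered (patients then controls, each sorted by
  subject id) before permutation, so results are independent of manifest row
  order at a fixed seed.

The permutation engine computes whole batches of t-maps via two matrix
products per batch, which keeps a 5000-permutation run on a 90-node,
46-subject cohort at a few seconds on one core.

## Clinical statistics

- Group tests on metric AUCs: OLS of value ~ intercept + group + age, with the
  group coefficient's t (df = n−3). With one covariate this equals the
  classical one-way ANCOVA F test (F = t²). A constant age column is dropped,
  which reduces the model exactly to the unpaired t-test.
- FDR: Benjamini–Hochberg step-up; the family is whatever metric set is
  passed — the seven global-metric AUCs, or the 90 nodal-efficiency AUCs.
- Partial correlation: residualize both variables on (intercept, covariate);
  Pearson r of residuals; p from t = r√((n−3)/(1−r²)), df = n−3.
- Power: noncentral-t power of the pooled two-sample test,
  ncp = (Δ/SD)√(n1·n2/(n1+n2)). The default scenario (Δ = 0.32, SD = 0.37,
  21 vs 25, α = 0.05 two-sided) computes to ≈ 0.81. For very large ncp where
  scipy's noncentral t loses accuracy, power is returned as 1 (the miss
  probability is below double precision there).
- Demographics: Pearson chi-square without continuity correction for 2×2
  tables (the Yates-corrected variant does not reproduce standard
  clinical-table p-values such as 0.665 for an 8/13 vs 8/17 split), and the
  pooled-variance unpaired t from (mean, SD, n) summaries.

## Synthetic data: what it emulates and what it does not

**Phantoms.** Tubes of prolate tensors (default eigenvalues
1.7/0.3/0.3 × 10⁻³ mm²/s, FA ≈ 0.80) around analytic centerlines on an
isotropic background (ADC 0.7 × 10⁻³ mm²/s, FA = 0). Where bundles overlap,
the first-listed bundle wins. Phantoms validate geometry — tensor recovery,
termination rules, endpoint assignment — not biology: there is no partial
voluming, no crossing-fiber signal, no susceptibility or motion artifact.

**Cohorts.** A single weighted template graph per cohort: 90 nodes in 6
modules, 15% density, 85% of edges intra-module, lognormal weights clipped to
[1, 300] (the plausible FN × FA range) with intra-module edges boosted 3×, so
sparsity thresholding preferentially retains the modular core — this is what
makes the template robustly small-world (σ ≈ 3–4 across the sweep). Each
subject multiplies every template weight by an iid unit-mean lognormal factor
(σ = 0.2) and drops each edge with probability 0.02; patients additionally
scale the planted edges by 1 − effect_size (default 0.4), so the planted
group-mean difference converges to effect_size × template weight as the noise
vanishes. Covariates emulate a first-episode depression study: 21 patients
(ages ≈ 37.5 ± 11.6, HDRS 18–34, duration 1–10 months, 8 F / 13 M) and 25
controls (ages ≈ 31.4 ± 11.0, 8 F / 17 M).

The planted subnetwork is a 7-edge spanning tree over 8 fronto-subcortical
and limbic nodes (ORBmid.L, ORBsup.L, ORBsupmed.L, THA.L, HIP.L, PoCG.L,
REC.R, ORBinf.R) with THA.L as the local hub, including the THA.L–PoCG.L and
ORBmid.L–ORBsup.L edges. This is a *fixture*: a connected, clinically
plausible edge set for testing recovery, not a claim about any real cohort's
edge list.

Because real structural connectomes have heavier-tailed weights, distance-
dependent topology and spatially correlated noise that this generator does
not model, passing tests demonstrate the *correctness of the machinery*
(metric formulas, permutation validity, recovery of effects of known
location and size) — not that the pipeline's clinical findings on real data
would be reproduced.

All generators draw from one explicit `numpy` seed; no hidden global state.
Identical seeds give bit-identical phantoms and cohorts.

## Problem sizes

Simulation sizes used by the tests and the acceptance script are chosen so a
full run completes in minutes on one core: the NBS recovery run uses the full
46-subject cohort with 5000 permutations; the type-I-error study uses 200
null cohorts at 1000 permutations; the small-world sweep evaluates 36
thresholds at 100 nulls each; phantoms are tens of voxels per side. Larger
sizes change none of the logic.

## Known limitations

- Single-tensor model and deterministic tracking cannot represent crossing
  fibers; junction regions terminate rather than branch.
- The every-voxel seeding rule overcounts long bundles relative to
  seed-per-bundle schemes; FN is therefore comparable within, not across,
  tracking configurations.
- Lp on disconnected graphs averages only reachable pairs, so λ (and hence σ)
  at very sparse thresholds compares graphs whose reachable-pair sets differ
  from their nulls'.
- The ANCOVA is a single-covariate linear model; no interaction or
  higher-order nuisance terms.
- Registration, atlas warping, eddy/motion correction and skull stripping are
  upstream of this package and assumed done.
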