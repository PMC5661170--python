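# wmnet

Whole-brain **white-matter structural connectome** analysis for diffusion
MRI group studies, with synthetic phantoms and cohorts so the entire pipeline
is testable without patient data.

The package is aimed at neuroimaging researchers who want a transparent,
scriptable implementation of the classic structural-network workflow:

1. **Tensor fitting** — per-voxel log-linear least squares on the
   single-tensor model S = S0·exp(−b·gᵀDg), with FA and principal diffusion
   directions.
2. **FACT tractography** — deterministic fiber assignment by continuous
   tracking, seeded at every voxel, terminating at FA < 0.15 or turns > 45°.
3. **Connectome construction** — 90-region (AAL) weighted networks with edge
   weight w_ij = FN_ij × FA_ij (streamline count × mean FA along the bundle),
   zeroing edges with FN < 3.
4. **Graph metrics** — clustering coefficient C_p, characteristic path length
   L_p, global/local/nodal efficiency, and small-world parameters
   γ = C_p/⟨C_p^rand⟩, λ = L_p/⟨L_p^rand⟩, σ = γ/λ against degree-preserving
   rewired nulls, swept over sparsity thresholds 5–40% (1% steps) and
   summarized by area under the curve.
5. **NBS** — network-based statistic: edge-wise two-sample t-maps thresholded
   at t = 2.1, connected components, and family-wise-error corrected p-values
   from 5000 permutations of the group labels.
6. **Clinical statistics** — age-adjusted ANCOVA group tests with
   Benjamini–Hochberg FDR, Pearson partial correlations, noncentral-t power
   analysis, and demographics-table tests.

The synthetic-data module generates DWI phantoms with known bundle geometry
and two-group connectome cohorts (default: 21 patients vs 25 controls on a
modular small-world 90-node template) with an optional planted group
difference on a 7-edge fronto-subcortical–limbic subnetwork, so effect
recovery can be validated against ground truth. See `docs/methods.md` for
the model conventions and generator details.

## Worked example

```python
import numpy as np
from wmnet import (CohortSpec, NBSConfig, NullModelConfig, ThresholdSpec,
                   gen_cohort, gen_template, nbs_fwe, normalized_smallworld,
                   power_two_sample_t, PowerSpec, threshold_sparsity)

# a 21 vs 25 cohort with a planted 40% decrease on 7 edges
cohort = gen_cohort(CohortSpec(seed=11))

# NBS at t = 2.1, 1000 permutations
res = nbs_fwe(cohort, NBSConfig(n_permutations=1000, seed=3))
best = res.significant[0]
print(f"component: {best.extent} edges, {len(best.nodes)} nodes, "
      f"p_FWE = {best.p_fwe:.4f}")
print("edges:", best.edge_codes(cohort.codes)[:3], "...")

# small-worldness of the group template at 10% sparsity
W = threshold_sparsity(gen_template(CohortSpec(seed=11)), 0.10)
sw = normalized_smallworld(W, NullModelConfig(n_nulls=100, seed=1))
print(f"gamma = {sw['gamma']:.2f}, lambda = {sw['lambda']:.2f}, "
      f"sigma = {sw['sigma']:.2f}")

# power of the two-sample design (difference 0.32, SD 0.37, alpha 0.05)
print(f"power = {power_two_sample_t(PowerSpec()):.3f}")
```

Output:

```
component: 11 edges, 12 nodes, p_FWE = 0.0010
edges: [('ORBsup.L', 'ORBmid.L'), ('ORBsup.L', 'ORBsupmed.L'), ('ORBmid.L', 'THA.L')] ...
gamma = 5.72, lambda = 1.72, sigma = 3.32
power = 0.815
```

The significant component contains all seven planted edges (plus noise edges
picked up at the threshold); σ ≈ 3.3 > 1 says the template is in the
small-world regime; the design has ~82% power to detect a between-group
clustering-coefficient difference of 0.32 at SD 0.37.

The same steps are available from the shell:

```bash
wmnet simulate cohort --seed 11 --out cohort/
wmnet nbs --cohort cohort/ --thr 2.1 --perms 5000 --direction decrease --seed 3 --out nbs/
wmnet metrics --cohort cohort/ --nulls 100 --seed 7 --out metrics/
wmnet stats ancova --auc metrics/auc.csv --manifest cohort/manifest.csv --out ancova.csv
wmnet stats power --diff 0.32 --sd 0.37 --n1 21 --n2 25
```

plus `wmnet simulate phantom`, `wmnet fit-tensor`, `wmnet track` and
`wmnet build-network` for the voxel-level half of the pipeline.

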