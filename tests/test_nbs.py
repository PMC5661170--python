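"""Network-based statistic: t-maps, components, permutation FWE behavior."""

import numpy as np
import pandas as pd
import pytest

import _oracles as oracle
from wmnet import (Cohort, CohortSpec, NBSConfig, edge_tstats, gen_cohort,
                   nbs_fwe, suprathreshold_components)


def _cohort_from_stacks(pat, con, codes=None):
    n = pat.shape[1]
    codes = codes or tuple(f"R{i:02d}" for i in range(n))
    mats = np.concatenate([pat, con])
    manifest = pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(len(mats))],
        "group": ["patient"] * len(pat) + ["control"] * len(con),
        "age": np.linspace(20, 50, len(mats)),
    })
    return Cohort(mats, manifest, codes=codes)


def _sym(n, vals):
    m = np.zeros((len(vals), n, n))
    m[:, 0, 1] = m[:, 1, 0] = vals
    return m


class TestEdgeTstats:
    def test_identical_groups_give_zero_t(self):
        mats = np.random.default_rng(0).uniform(1, 5, (4, 6, 6))
        mats = np.triu(mats, 1) + np.triu(mats, 1).transpose(0, 2, 1)
        c = _cohort_from_stacks(mats, mats.copy())
        t = edge_tstats(c)
        defined = np.isfinite(t)
        assert np.all(t[defined] == 0)

    def test_hand_computed_pooled_t(self):
        # patients {1,2,3}, controls {4,5,6}: t = -3/sqrt(2/3) = -3.6742
        c = _cohort_from_stacks(_sym(3, [1, 2, 3]), _sym(3, [4, 5, 6]))
        t = edge_tstats(c)
        assert t[0, 1] == pytest.approx(-3.0 / np.sqrt(2 / 3), abs=1e-9)
        assert t[0, 1] == pytest.approx(-3.6742, abs=1e-4)

    def test_matrix_symmetric_with_nan_diagonal(self, default_cohort):
        t = edge_tstats(default_cohort)
        assert np.array_equal(np.isnan(t), np.isnan(t.T))
        finite = np.isfinite(t)
        assert np.allclose(t[finite], t.T[finite])
        assert np.all(np.isnan(np.diag(t)))

    def test_zero_variance_edges_undefined(self):
        pat = _sym(3, [2.0, 2.0, 2.0])
        con = _sym(3, [2.0, 2.0, 2.0])
        t = edge_tstats(_cohort_from_stacks(pat, con))
        assert np.isnan(t[0, 1])

    def test_label_exchange_negates_t(self, default_cohort):
        t = edge_tstats(default_cohort)
        flipped = default_cohort.manifest.copy()
        flipped["group"] = np.where(flipped["group"] == "patient",
                                    "control", "patient")
        t2 = edge_tstats(Cohort(default_cohort.matrices, flipped,
                                codes=default_cohort.codes))
        finite = np.isfinite(t)
        assert np.allclose(t[finite], -t2[finite])

    def test_single_group_rejected(self):
        mats = _sym(3, [1, 2, 3])
        manifest = pd.DataFrame({"subject_id": ["a", "b", "c"],
                                 "group": ["patient"] * 3,
                                 "age": [30, 40, 50]})
        with pytest.raises(ValueError):
            edge_tstats(Cohort(mats, manifest, codes=("A", "B", "C")))


class TestComponents:
    def _tmat(self, n, hot_edges, value=5.0):
        t = np.zeros((n, n))
        for i, j in hot_edges:
            t[i, j] = t[j, i] = value
        np.fill_diagonal(t, np.nan)
        return t

    def test_two_components_by_shared_nodes(self):
        cfg = NBSConfig(direction="increase")
        comps = suprathreshold_components(
            self._tmat(10, [(1, 2), (2, 3), (7, 8)]), cfg)
        assert [c.extent for c in comps] == [2, 1]
        assert comps[0].nodes == [1, 2, 3]

    def test_no_suprathreshold_edges_empty(self):
        cfg = NBSConfig(direction="increase")
        assert suprathreshold_components(self._tmat(5, [], 0.0), cfg) == []

    def test_threshold_is_strict_in_configured_direction(self):
        cfg = NBSConfig(t_threshold=2.1, direction="decrease")
        t = self._tmat(4, [(0, 1)], value=-2.1)  # exactly at threshold
        assert suprathreshold_components(t, cfg) == []
        t = self._tmat(4, [(0, 1)], value=-2.2)
        assert len(suprathreshold_components(t, cfg)) == 1

    def test_matches_dfs_oracle_on_random_matrix(self):
        rng = np.random.default_rng(4)
        t = rng.normal(0, 1.5, (90, 90))
        t = np.triu(t, 1) + np.triu(t, 1).T
        np.fill_diagonal(t, np.nan)
        cfg = NBSConfig(t_threshold=2.1, direction="increase")
        got = suprathreshold_components(t, cfg)
        iu, ju = np.triu_indices(90, 1)
        hot = [(int(i), int(j)) for i, j in zip(iu, ju) if t[i, j] > 2.1]
        ref = oracle.components_dfs(hot)
        assert sorted(len(c) for c in ref) == \
            sorted(c.extent for c in got)
        assert {frozenset(c.edges) for c in got} == \
            {frozenset(c) for c in ref}


class TestNbsFwe:
    def test_planted_effect_recovered(self, default_cohort):
        cfg = NBSConfig(n_permutations=1000, seed=3)
        res = nbs_fwe(default_cohort, cfg)
        planted = {tuple(e) for e in
                   default_cohort.ground_truth["effect_edges"]}
        sig = res.significant
        assert sig, "no significant component on a strongly planted effect"
        best = max(sig, key=lambda c: len(planted & set(c.edges)))
        assert planted <= set(best.edges)
        assert best.p_fwe < 0.05

    def test_p_values_bounded_and_monotone_in_extent(self, default_cohort):
        cfg = NBSConfig(n_permutations=200, seed=4)
        res = nbs_fwe(default_cohort, cfg)
        lo = 1.0 / (cfg.n_permutations + 1)
        ranked = sorted(res.components, key=lambda c: c.extent, reverse=True)
        prev_p = 0.0
        for c in ranked:
            assert lo <= c.p_fwe <= 1.0
            assert c.p_fwe >= prev_p - 1e-12
            prev_p = c.p_fwe

    def test_identity_relabeling_reproduces_observed_extent(self,
                                                            default_cohort):
        # the observed grouping is one of the possible relabelings, so its
        # max extent must equal what the permutation engine computes for it
        from wmnet.nbs import _perm_null_max, _UnionFind
        cfg = NBSConfig(n_permutations=1, seed=0)
        pat, con = default_cohort.group_matrices()
        iu, ju = np.triu_indices(90, 1)
        X = np.vstack([pat[:, iu, ju], con[:, iu, ju]])

        class _IdentityRng:
            def random(self, shape):
                # ascending noise keeps the first n1 subjects in group 1
                return np.arange(np.prod(shape)).reshape(shape) / np.prod(shape)

        null = _perm_null_max(X, len(pat), cfg, "decrease", iu, ju, 90,
                              _IdentityRng())
        comps = suprathreshold_components(edge_tstats(default_cohort), cfg,
                                          "decrease")
        assert null[0] == max(c.extent for c in comps)

    def test_independent_of_subject_ordering(self, default_cohort):
        cfg = NBSConfig(n_permutations=300, seed=5)
        res_a = nbs_fwe(default_cohort, cfg)
        perm = np.random.default_rng(1).permutation(len(default_cohort.matrices))
        shuffled = Cohort(default_cohort.matrices[perm],
                          default_cohort.manifest.iloc[perm].reset_index(drop=True),
                          codes=default_cohort.codes)
        res_b = nbs_fwe(shuffled, cfg)
        assert [(c.extent, c.p_fwe) for c in res_a.components] == \
            [(c.extent, c.p_fwe) for c in res_b.components]

    def test_increased_effect_found_only_in_increase_direction(self):
        spec = CohortSpec(effect_size=0.5, seed=21)
        c = gen_cohort(spec)
        # flip groups so the planted decrease becomes an increase in 'patients'
        flipped = c.manifest.copy()
        flipped["group"] = np.where(flipped["group"] == "patient",
                                    "control", "patient")
        c_inc = Cohort(c.matrices, flipped, codes=c.codes,
                       ground_truth=c.ground_truth)
        res = nbs_fwe(c_inc, NBSConfig(n_permutations=500, direction="both",
                                       seed=6))
        sig = res.significant
        assert sig
        assert {comp.direction for comp in sig} == {"increase"}

    def test_deterministic_given_seed(self, default_cohort):
        cfg = NBSConfig(n_permutations=100, seed=7)
        a = nbs_fwe(default_cohort, cfg)
        b = nbs_fwe(default_cohort, cfg)
        assert [(c.edges, c.p_fwe) for c in a.components] == \
            [(c.edges, c.p_fwe) for c in b.components]

    def test_config_validation(self):
        with pytest.raises(ValueError):
            NBSConfig(t_threshold=0.0)
        with pytest.raises(ValueError):
            NBSConfig(direction="sideways")
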