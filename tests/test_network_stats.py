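"""Edge t-statistics, NBS permutation inference, and effect sizes,
checked against hand computations and brute-force oracles."""
import itertools
import math

import numpy as np
import pytest

from neonet import Design, cohens_d, edge_statistics, nbs_extent_test
from neonet.network_stats import (_components, _permutation_assignments,
                                  empirical_fwe)


def edge_matrix(values_per_subject, P):
    """Stack subject-level symmetric matrices from upper-tri vectors."""
    iu = np.triu_indices(P, 1)
    out = np.zeros((len(values_per_subject), P, P))
    for s, vec in enumerate(values_per_subject):
        out[s][iu] = vec
        out[s] += out[s].T
    return out


def brute_force_components(edges, n_nodes):
    """Connected components of an edge list by exhaustive BFS."""
    comps = []
    remaining = set(map(tuple, edges))
    while remaining:
        stack = [next(iter(remaining))]
        comp = set()
        while stack:
            e = stack.pop()
            if e in comp:
                continue
            comp.add(e)
            for f in list(remaining):
                if set(e) & set(f) and f not in comp:
                    stack.append(f)
        remaining -= comp
        comps.append(comp)
    return sorted((len(c) for c in comps), reverse=True)


class TestEdgeStatistics:
    def test_hand_computed_unpaired_t(self):
        """Group A {1,2,3} vs group B {4,5,6}: pooled-variance t = -3.674."""
        vals = edge_matrix([[1.0], [2.0], [3.0], [4.0], [5.0], [6.0]], 2)
        design = Design(subjects=[f"s{i}" for i in range(6)],
                        group=np.array([1, 1, 1, 0, 0, 0]),
                        contrast="group_main")
        t = edge_statistics(vals, design)
        assert t[0, 1] == pytest.approx(-3.6742346, abs=1e-4)

    def test_identical_groups_give_zero_t(self, rng):
        base = rng.random((5, 3, 3))
        base = (base + base.transpose(0, 2, 1)) / 2
        for s in range(5):
            np.fill_diagonal(base[s], 0)
        vals = np.concatenate([base, base])
        design = Design(subjects=[f"s{i}" for i in range(10)],
                        group=np.array([1] * 5 + [0] * 5),
                        contrast="group_main")
        t = edge_statistics(vals, design)
        iu = np.triu_indices(3, 1)
        assert np.allclose(t[iu], 0.0)

    def test_interaction_invariant_to_state_offsets(self, rng):
        vals = rng.random((8, 2, 4, 4))
        vals = (vals + vals.transpose(0, 1, 3, 2)) / 2
        design = Design(subjects=[f"s{i}" for i in range(8)],
                        group=np.array([1] * 4 + [0] * 4),
                        contrast="interaction")
        t1 = edge_statistics(vals, design)
        shifted = vals + rng.random((8, 1, 1, 1))  # same offset both states
        t2 = edge_statistics(shifted, design)
        iu = np.triu_indices(4, 1)
        assert np.allclose(t1[iu], t2[iu], atol=1e-10)

    def test_paired_t_matches_scipy(self, rng):
        from scipy import stats as sps
        vals = rng.random((9, 2, 3, 3))
        vals = (vals + vals.transpose(0, 1, 3, 2)) / 2
        design = Design(subjects=[f"s{i}" for i in range(9)],
                        group=np.ones(9, dtype=int), contrast="sleep_main")
        t = edge_statistics(vals, design)
        ref = sps.ttest_rel(vals[:, 0, 0, 1], vals[:, 1, 0, 1]).statistic
        assert t[0, 1] == pytest.approx(ref, abs=1e-10)

    def test_degenerate_variance_gives_zero(self):
        vals = edge_matrix([[1.0]] * 6, 2)  # identical values everywhere
        design = Design(subjects=[f"s{i}" for i in range(6)],
                        group=np.array([1, 1, 1, 0, 0, 0]),
                        contrast="group_main")
        t = edge_statistics(vals, design)
        assert t[0, 1] == 0.0


class TestComponents:
    def test_spec_example_extents(self):
        """Edges {(1,2),(2,3),(4,5)} on 5 nodes: components 2 and 1."""
        P = 6
        iu = np.triu_indices(P, 1)
        sel = np.zeros(iu[0].size, dtype=bool)
        for e in [(1, 2), (2, 3), (4, 5)]:
            idx = np.flatnonzero((iu[0] == e[0]) & (iu[1] == e[1]))[0]
            sel[idx] = True
        comps = _components(sel, iu, P)
        assert sorted((ext for _, ext in comps), reverse=True) == [2, 1]

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        P = 6
        iu = np.triu_indices(P, 1)
        sel = rng.random(iu[0].size) < 0.3
        comps = _components(sel, iu, P)
        got = sorted((ext for _, ext in comps), reverse=True)
        edges = [(int(iu[0][k]), int(iu[1][k]))
                 for k in np.flatnonzero(sel)]
        assert got == brute_force_components(edges, P)


class TestNBS:
    def planted_cohort(self, seed, d=1.0, n1=20, n2=20, P=10, n_edges=10):
        """Null cohort plus a connected planted component with effect d."""
        rng = np.random.default_rng(seed)
        iu = np.triu_indices(P, 1)
        n_e = iu[0].size
        Y = rng.standard_normal((n1 + n2, n_e))
        nodes = list(range(5))
        edges = [e for e in itertools.combinations(nodes, 2)][:n_edges]
        idx = [np.flatnonzero((iu[0] == a) & (iu[1] == b))[0]
               for a, b in edges]
        Y[:n1, idx] += d
        vals = edge_matrix(Y, P)
        design = Design(subjects=[f"s{i}" for i in range(n1 + n2)],
                        group=np.array([1] * n1 + [0] * n2),
                        contrast="group_main")
        return vals, design, set(edges)

    def test_planted_component_detected_with_power(self):
        hits = 0
        for seed in range(10):
            vals, design, edges = self.planted_cohort(seed)
            res = nbs_extent_test(vals, design, threshold=2.5, n_perm=200,
                                  seed=seed)
            if any(r.p_fwe < 0.05 and r.direction == "positive" for r in res):
                hits += 1
        assert hits >= 9

    def test_p_value_floor(self):
        vals, design, _ = self.planted_cohort(0, d=2.0)
        res = nbs_extent_test(vals, design, n_perm=199, seed=0)
        assert all(r.p_fwe >= 1.0 / 200 for r in res)

    def test_parcel_relabeling_leaves_inference_unchanged(self):
        vals, design, _ = self.planted_cohort(3)
        res = nbs_extent_test(vals, design, n_perm=200, seed=5)
        perm = np.random.default_rng(1).permutation(10)
        vals_p = vals[:, perm][:, :, perm]
        res_p = nbs_extent_test(vals_p, design, n_perm=200, seed=5)
        assert [(r.extent, r.p_fwe, round(r.cohens_d, 12), r.direction)
                for r in res] == \
               [(r.extent, r.p_fwe, round(r.cohens_d, 12), r.direction)
                for r in res_p]
        # index a of the permuted matrix is parcel perm[a] of the original
        mapped = {tuple(sorted((int(perm[i]), int(perm[j]))))
                  for i, j in res_p[0].component_edges}
        assert mapped == {tuple(e) for e in res[0].component_edges}

    def test_exhaustive_enumeration_for_small_groups(self):
        vals, design, _ = self.planted_cohort(0, d=3.0, n1=4, n2=4, P=5,
                                              n_edges=3)
        res = nbs_extent_test(vals, design, n_perm=5000, seed=0)
        assert res and all(r.n_permutations == math.comb(8, 4) for r in res)

    def test_permutation_scheme_shapes(self):
        design = Design(subjects=[f"s{i}" for i in range(6)],
                        group=np.array([1, 1, 1, 0, 0, 0]),
                        contrast="group_main")
        rng = np.random.default_rng(0)
        perms, exhaustive = _permutation_assignments(design, 6, 5000, rng)
        assert exhaustive and perms.shape == (20, 6)
        assert np.all(perms.sum(axis=1) == 3)

    def test_null_calibration_quick(self):
        """FWE on a small null batch stays near or below nominal."""
        fwe = empirical_fwe(n_cohorts=40, n_parcels=10, n_perm=200, seed=3)
        assert fwe <= 0.125  # binomial 95% upper bound for p=0.05, n=40


class TestCohensD:
    def test_single_edge_formula(self):
        t = np.zeros((3, 3))
        t[0, 1] = t[1, 0] = 2.5
        assert cohens_d(t, [(0, 1)], 100) == pytest.approx(0.25)

    def test_reported_magnitude_scale(self):
        """Mean t 2.97 over df 105 gives d ~ 0.29."""
        t = np.zeros((2, 2))
        t[0, 1] = t[1, 0] = 2.97
        assert cohens_d(t, [(0, 1)], 105) == pytest.approx(0.2899, abs=1e-3)

    def test_linear_in_t(self, rng):
        t = rng.random((4, 4))
        t = (t + t.T) / 2
        comp = [(0, 1), (1, 2)]
        assert cohens_d(3 * t, comp, 50) == pytest.approx(
            3 * cohens_d(t, comp, 50))

    def test_empty_component_rejected(self):
        with pytest.raises(ValueError):
            cohens_d(np.zeros((2, 2)), [], 10)
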