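"""Composite scores, Delta connectivity, Spearman + BH-FDR contracts."""
import numpy as np
import pandas as pd
import pytest

from neonet import (ConnectivityMatrix, bh_adjust, correlate_outcomes,
                    delta_connectivity, pca_composites, spearman_test)


def sym(v):
    v = np.asarray(v, float)
    out = (v + v.T) / 2
    np.fill_diagonal(out, 0)
    return out


class TestPcaComposites:
    def test_single_factor_items_load_on_first_component(self, rng):
        x = rng.standard_normal(40)
        items = pd.DataFrame({f"i{k}": x + 0.01 * rng.standard_normal(40)
                              for k in range(4)})
        scores, loadings = pca_composites(items)
        c1_var = scores["C1"].var()
        c2_var = scores["C2"].var()
        assert c1_var / (c1_var + c2_var) > 0.99

    def test_two_factor_recovery(self, rng):
        """Loadings of planted orthogonal factors are recovered up to
        sign (|cos| > 0.95)."""
        n = 300
        # unequal block sizes with no cross-loadings keep the principal
        # axes identifiable after per-item standardization
        f1 = rng.standard_normal(n)
        f2 = rng.standard_normal(n)
        l1 = np.array([1.0, 0.9, 0.8, 0.9, 0.0, 0.0])
        l2 = np.array([0.0, 0.0, 0.0, 0.0, 1.0, 0.9])
        X = (np.outer(f1, l1) + np.outer(f2, l2)
             + 0.05 * rng.standard_normal((n, 6)))
        scores, loadings = pca_composites(pd.DataFrame(X))
        for comp, planted in (("C1", l1), ("C2", l2)):
            cos = abs(np.dot(loadings.loc[comp], planted)
                      / np.linalg.norm(loadings.loc[comp])
                      / np.linalg.norm(planted))
            assert cos > 0.95

    def test_duplicated_subjects_get_identical_scores(self, rng):
        items = pd.DataFrame(rng.standard_normal((10, 4)))
        doubled = pd.concat([items, items], ignore_index=True)
        scores, _ = pca_composites(doubled)
        assert np.allclose(scores.iloc[:10].to_numpy(),
                           scores.iloc[10:].to_numpy())

    def test_constant_item_dropped_with_warning(self, rng):
        items = pd.DataFrame(rng.standard_normal((20, 4)))
        items["flat"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            scores, loadings = pca_composites(items)
        assert "flat" not in loadings.columns

    def test_sign_convention_largest_loading_positive(self, rng):
        items = pd.DataFrame(rng.standard_normal((50, 5)))
        _, loadings = pca_composites(items)
        for c in loadings.index:
            row = loadings.loc[c].to_numpy()
            assert row[np.argmax(np.abs(row))] > 0


class TestDeltaConnectivity:
    def make_pair(self, a_vals, q_vals):
        return (ConnectivityMatrix(values=sym(a_vals), state="AS"),
                ConnectivityMatrix(values=sym(q_vals), state="QS"))

    def test_equal_states_give_zero(self, rng):
        v = rng.random((4, 4))
        a, q = self.make_pair(v, v)
        assert delta_connectivity(a, q, [(0, 1), (2, 3)]) == 0.0

    def test_constant_offset_recovered(self, rng):
        v = rng.random((4, 4))
        a, q = self.make_pair(v + 0.1, v)
        assert delta_connectivity(a, q, [(0, 1), (1, 2)]) == pytest.approx(0.1)

    def test_antisymmetric_under_state_swap(self, rng):
        a, q = self.make_pair(rng.random((4, 4)), rng.random((4, 4)))
        net = [(0, 2), (1, 3)]
        assert delta_connectivity(a, q, net) == pytest.approx(
            -delta_connectivity(q, a, net))

    def test_masked_edge_rejected(self, rng):
        v = sym(rng.random((4, 4)))
        v[0, 1] = v[1, 0] = np.nan
        a = ConnectivityMatrix(values=v)
        q = ConnectivityMatrix(values=sym(rng.random((4, 4))))
        with pytest.raises(ValueError):
            delta_connectivity(a, q, [(0, 1)])

    def test_empty_network_rejected(self, rng):
        a, q = self.make_pair(rng.random((3, 3)), rng.random((3, 3)))
        with pytest.raises(ValueError):
            delta_connectivity(a, q, [])


class TestSpearman:
    def test_hand_computed_rho(self):
        rho, p, n = spearman_test([1, 2, 3], [3, 1, 2])
        assert rho == pytest.approx(-0.5)
        assert n == 3

    def test_perfect_monotone(self):
        rho, p, _ = spearman_test([1, 2, 3, 4, 5, 6],
                                  [10, 20, 25, 40, 55, 100])
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(2 / 720)  # both extreme orderings

    def test_exact_p_matches_enumeration_at_small_n(self):
        """Exact permutation p agrees with the t-approximation in rank."""
        x = [1, 2, 3, 4, 5, 6, 7]
        y = [2, 1, 4, 3, 7, 5, 6]
        rho, p, _ = spearman_test(x, y)
        from scipy.stats import spearmanr
        assert 0 < p < 1
        assert rho == pytest.approx(spearmanr(x, y).statistic)

    def test_all_tied_reports_nan(self):
        rho, p, _ = spearman_test([1, 1, 1, 1, 1], [1, 2, 3, 4, 5])
        assert np.isnan(rho) and np.isnan(p)

    def test_monotone_transform_invariance(self, rng):
        x = rng.standard_normal(30)
        y = rng.standard_normal(30)
        r1, p1, _ = spearman_test(x, y)
        r2, p2, _ = spearman_test(np.exp(x), y ** 3)
        assert r1 == pytest.approx(r2)
        assert p1 == pytest.approx(p2)


class TestBH:
    def test_hand_computed_step_up(self):
        adj = bh_adjust([0.01, 0.04, 0.03, 0.002])
        assert np.allclose(adj, [0.02, 0.04, 0.04, 0.008])

    def test_adjusted_at_least_raw_and_order_invariant(self, rng):
        p = rng.random(20)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-15)
        perm = rng.permutation(20)
        assert np.allclose(bh_adjust(p[perm]), adj[perm])

    def test_monotone_in_raw_order(self, rng):
        p = np.sort(rng.random(15))
        adj = bh_adjust(p)
        assert np.all(np.diff(adj) >= -1e-15)


class TestCorrelateOutcomes:
    def make_tables(self, rng, n=30, rho_target=0.8):
        subjects = [f"S{i:03d}" for i in range(n)]
        delta = rng.standard_normal(n)
        deltas = pd.DataFrame({"net_a": delta},
                              index=pd.Index(subjects, name="subject"))
        noise = rng.standard_normal(n)
        outcomes = pd.DataFrame({
            "C1": rng.standard_normal(n),
            "C2": rho_target * delta + (1 - rho_target) * noise,
            "cognitive": rng.standard_normal(n),
            "receptive_language": rng.standard_normal(n),
            "expressive_language": rng.standard_normal(n),
            "fine_motor": delta + 0.2 * rng.standard_normal(n),
        }, index=deltas.index)
        return deltas, outcomes

    def test_families_and_columns(self, rng):
        deltas, outcomes = self.make_tables(rng)
        rep = correlate_outcomes(deltas, outcomes)
        assert set(rep["family"]) == {"neurological", "neurocognitive"}
        assert len(rep) == 6
        strong = rep[rep["score"] == "fine_motor"].iloc[0]
        assert strong["rho"] > 0.8 and strong["p_fdr"] < 0.01

    def test_missing_scores_deleted_pairwise(self, rng):
        deltas, outcomes = self.make_tables(rng)
        outcomes.loc[outcomes.index[:4], "C2"] = np.nan
        rep = correlate_outcomes(deltas, outcomes)
        assert rep[rep["score"] == "C2"].iloc[0]["n"] == 26
        assert rep[rep["score"] == "C1"].iloc[0]["n"] == 30

    def test_fdr_applied_within_family(self, rng):
        deltas, outcomes = self.make_tables(rng)
        rep = correlate_outcomes(deltas, outcomes)
        for fam, sub in rep.groupby("family"):
            assert np.allclose(sub["p_fdr"].to_numpy(),
                               bh_adjust(sub["p"].to_numpy()), equal_nan=True)

    def test_monotone_transform_of_scores_invariant(self, rng):
        deltas, outcomes = self.make_tables(rng)
        rep1 = correlate_outcomes(deltas, outcomes)
        outcomes2 = outcomes.copy()
        outcomes2["fine_motor"] = np.exp(outcomes2["fine_motor"] / 50.0)
        rep2 = correlate_outcomes(deltas, outcomes2)
        a = rep1[rep1.score == "fine_motor"].iloc[0]
        b = rep2[rep2.score == "fine_motor"].iloc[0]
        assert a["rho"] == pytest.approx(b["rho"])

    def test_planted_outcome_effect_recovered(self):
        """Generator's copula hits the requested Spearman rho on average
        (outcome_effect 0.4, n=44, 100 seeds, +-0.15)."""
        from neonet import StudyConfig
        from neonet.synthetic import _copula_scores
        from scipy.stats import spearmanr
        rhos = []
        for s in range(100):
            rng = np.random.default_rng(s)
            delta = rng.standard_normal(44)
            score = _copula_scores(delta, 0.4, 100.0, 15.0, rng)
            rhos.append(spearmanr(delta, score).statistic)
        assert abs(np.mean(rhos) - 0.4) < 0.15
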