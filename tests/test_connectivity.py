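"""Debiased-wPLI estimator and edge-fidelity mask contracts."""
import numpy as np
import pytest

from neonet import (ConnectivityMatrix, EdgeMask, LeadField, Parcellation,
                    StudyConfig, apply_mask, connectivity_matrix,
                    debiased_wpli, fidelity_mask, generate_coupled_pair,
                    generate_head_model, make_inverse)
from neonet.connectivity import UndefinedSignalError
from neonet.signals import band_limited_noise


class TestDebiasedWpli:
    def test_quarter_cycle_lag_reaches_one(self, band_hd):
        x, y = generate_coupled_pair(6000, 100.0, band_hd, np.pi / 2, 1.0,
                                     seed=0)
        assert debiased_wpli(x, y) >= 0.95

    def test_zero_lag_identical_signal_is_exactly_zero(self, band_hd, rng):
        x = band_limited_noise(2000, 100.0, band_hd, rng)
        assert debiased_wpli(x, x) == 0.0
        assert debiased_wpli(x, 2.5 * x) == 0.0

    def test_independent_signals_unbiased(self, band_hd):
        """Mean estimate over 200 independent pairs at epoch length
        (30 s) is within +-0.05 of zero."""
        vals = [debiased_wpli(*generate_coupled_pair(
            3000, 100.0, band_hd, np.pi / 2, 0.0, seed=s))
            for s in range(200)]
        assert abs(np.mean(vals)) < 0.05

    def test_estimates_stay_in_range(self, band_hd):
        for s in range(20):
            x, y = generate_coupled_pair(800, 100.0, band_hd, np.pi / 3,
                                         s / 19.0, seed=s)
            assert -1.0 <= debiased_wpli(x, y) <= 1.0

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedSignalError):
            debiased_wpli(np.zeros(500), np.ones(500))

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            debiased_wpli(np.arange(50.0), np.arange(50.0))


class TestConnectivityMatrix:
    def test_identical_signal_on_all_parcels_gives_zero(self, band_hd, rng):
        x = band_limited_noise(2000, 100.0, band_hd, rng)
        w = np.tile(x, (4, 1))
        cm = connectivity_matrix([w], 100.0, band=band_hd, trim_seconds=0.5)
        assert np.allclose(cm.values, 0.0)

    def test_planted_pair_is_largest_entry(self, band_hd, rng):
        x, y = generate_coupled_pair(4000, 100.0, band_hd, np.pi / 2, 1.0,
                                     seed=1)
        others = [band_limited_noise(4000, 100.0, band_hd, rng)
                  for _ in range(3)]
        w = np.vstack([x, others[0], y, others[1], others[2]])
        cm = connectivity_matrix([w], 100.0, band=band_hd)
        iu = np.triu_indices(5, 1)
        assert (cm.values[0, 2] == cm.values[iu].max()) and cm.values[0, 2] > 0.9

    def test_parcel_relabeling_equivariance(self, band_hd, rng):
        w = np.vstack([band_limited_noise(1500, 100.0, band_hd, rng)
                       for _ in range(4)])
        cm = connectivity_matrix([w], 100.0, trim_seconds=0.5)
        perm = np.array([2, 0, 3, 1])
        cm_p = connectivity_matrix([w[perm]], 100.0, trim_seconds=0.5)
        assert np.allclose(cm_p.values, cm.values[np.ix_(perm, perm)],
                           atol=1e-12)

    def test_pooling_windows_matches_concatenated_terms(self, band_hd, rng):
        """Pooling cross-spectral terms across windows equals computing
        on the union of the trimmed windows' terms."""
        w1 = np.vstack([band_limited_noise(1000, 100.0, band_hd, rng)
                        for _ in range(2)])
        w2 = np.vstack([band_limited_noise(1000, 100.0, band_hd, rng)
                        for _ in range(2)])
        pooled = connectivity_matrix([w1, w2], 100.0, trim_seconds=0.0)
        single1 = connectivity_matrix([w1], 100.0, trim_seconds=0.0)
        single2 = connectivity_matrix([w2], 100.0, trim_seconds=0.0)
        # pooled is not the mean of per-window estimates in general, but
        # must lie between them (shared denominator pooling)
        lo = min(single1.values[0, 1], single2.values[0, 1])
        hi = max(single1.values[0, 1], single2.values[0, 1])
        assert lo - 1e-9 <= pooled.values[0, 1] <= hi + 1e-9

    def test_symmetry_enforced(self):
        with pytest.raises(ValueError):
            ConnectivityMatrix(values=np.array([[0.0, 1.0], [0.5, 0.0]]))


def small_model(n=6, identity=True, duplicate=None, seed=0):
    if identity:
        G = np.eye(n)
    else:
        cfg = StudyConfig(n_sensors=max(8, n), n_sources=n, n_parcels=n,
                          seed=seed)
        G, _ = generate_head_model(cfg)
        G = G.matrix
    if duplicate is not None:
        i, j = duplicate
        G[:, j] = G[:, i]
    lf = LeadField(matrix=G)
    parc = Parcellation(assignment=np.arange(n), n_parcels=n)
    inv = make_inverse(lf, None, lam=1e-6 if identity else 1.0 / 9.0)
    return lf, inv, parc


class TestFidelityMask:
    def test_identity_model_excludes_nothing(self, band_hd):
        lf, inv, parc = small_model(6)
        mask = fidelity_mask(lf, inv, parc, band_hd, 100.0, n_iter=10,
                             seed=0, signal_seconds=4.0)
        assert mask.n_excluded == 0

    def test_duplicated_gain_columns_exclude_their_edge(self, band_hd):
        lf, inv, parc = small_model(6, duplicate=(1, 2))
        mask = fidelity_mask(lf, inv, parc, band_hd, 100.0, n_iter=10,
                             seed=0, signal_seconds=4.0)
        assert not mask.mask[1, 2]
        assert mask.n_excluded >= 1

    def test_mask_symmetric(self, band_hd):
        lf, inv, parc = small_model(5)
        mask = fidelity_mask(lf, inv, parc, band_hd, 100.0, n_iter=5,
                             seed=1, signal_seconds=4.0)
        assert np.array_equal(mask.mask, mask.mask.T)

    def test_n_iter_below_two_rejected(self, band_hd):
        lf, inv, parc = small_model(4)
        with pytest.raises(ValueError):
            fidelity_mask(lf, inv, parc, band_hd, 100.0, n_iter=1)

    def test_edges_tested_bookkeeping(self, band_hd):
        """Edges entering downstream analysis = P(P-1)/2 - n_excluded."""
        lf, inv, parc = small_model(6, duplicate=(0, 3))
        mask = fidelity_mask(lf, inv, parc, band_hd, 100.0, n_iter=8,
                             seed=2, signal_seconds=4.0)
        iu = np.triu_indices(6, 1)
        assert mask.mask[iu].sum() == 15 - mask.n_excluded

    def test_mask_stable_under_iteration_count(self, band_hd):
        """Halving the iteration count changes few mask entries."""
        cfg = StudyConfig(n_sensors=12, n_sources=24, n_parcels=8, seed=3)
        lf, parc = generate_head_model(cfg)
        inv = make_inverse(lf, None, lam=1.0 / 9.0)
        m1 = fidelity_mask(lf, inv, parc, band_hd, 100.0, n_iter=50,
                           seed=0, signal_seconds=3.0)
        m2 = fidelity_mask(lf, inv, parc, band_hd, 100.0, n_iter=25,
                           seed=1, signal_seconds=3.0)
        iu = np.triu_indices(8, 1)
        agree = np.mean(m1.mask[iu] == m2.mask[iu])
        assert agree >= 0.95


class TestApplyMask:
    def make_cm(self, n=4):
        rng = np.random.default_rng(0)
        v = rng.random((n, n))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        return ConnectivityMatrix(values=v)

    def test_all_pass_mask_is_identity(self):
        cm = self.make_cm()
        mask = EdgeMask(mask=~np.eye(4, dtype=bool))
        out = apply_mask(cm, mask)
        assert np.array_equal(out.values, cm.values)

    def test_all_exclude_mask_leaves_no_edges(self):
        cm = self.make_cm()
        mask = EdgeMask(mask=np.zeros((4, 4), dtype=bool))
        out = apply_mask(cm, mask)
        iu = np.triu_indices(4, 1)
        assert np.all(np.isnan(out.values[iu]))

    def test_idempotent(self):
        cm = self.make_cm()
        m = ~np.eye(4, dtype=bool)
        m[0, 1] = m[1, 0] = False
        mask = EdgeMask(mask=m)
        once = apply_mask(cm, mask)
        twice = apply_mask(once, mask)
        assert np.array_equal(np.isnan(once.values), np.isnan(twice.values))

    def test_shape_mismatch_rejected(self):
        cm = self.make_cm(4)
        with pytest.raises(ValueError):
            apply_mask(cm, EdgeMask(mask=np.zeros((5, 5), dtype=bool)))
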