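import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from beem.glv import GLVParameters, integrate_glv
from beem.postprocess import (
    confidence_scores,
    consensus_edges,
    export_network,
    fit_glv_direct,
    recover_beta,
    recover_growth_rates,
)
from beem.preprocess import preprocess


class TestRecoverBeta:
    def test_sparse_column_unchanged(self):
        b = np.zeros((4, 5))
        b[3, 2] = 5.0
        beta = recover_beta(b, r=0)
        assert beta[0, 2] == 0.0  # median of [0,0,0,5] is 0
        assert beta[4, 2] == 5.0  # row order: non-reference rows shifted past r

    def test_constant_column_attributed_to_reference(self):
        # all true beta_ij = 0 with beta_rj = 2 makes every b_ij = -2
        b = np.full((3, 4), 0.0)
        b[:, 1] = -2.0
        beta = recover_beta(b, r=0)
        assert beta[0, 1] == pytest.approx(2.0)
        np.testing.assert_allclose(beta[1:, 1], 0.0)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 6), st.integers(0, 2**31 - 1))
    def test_round_trip_under_majority_zero_columns(self, r, seed):
        """recover_beta inverts b_ij = beta_ij - beta_rj exactly whenever each
        column of beta has a strict majority of zeros among non-reference
        rows."""
        rng = np.random.default_rng(seed)
        p = 7
        beta = np.zeros((p, p))
        for j in range(p):
            nonref = [i for i in range(p) if i != r]
            k = rng.integers(0, (p - 1) // 2)  # strictly fewer than half
            rows = rng.choice(nonref, size=k, replace=False)
            beta[rows, j] = rng.normal(0, 1, k)
            if rng.random() < 0.5:
                beta[r, j] = rng.normal()
        rows = [i for i in range(p) if i != r]
        b = beta[rows] - beta[r][None, :]
        np.testing.assert_allclose(recover_beta(b, r), beta, atol=1e-12)


class TestConfidenceScores:
    def test_hand_computed(self):
        beta = np.array([[-2.0, 1.0, 0.0], [0.5, -3.0, 0.0], [0.5, 2.0, -1.0]])
        s = confidence_scores(beta)
        sd0 = np.std([0.5, 0.5], ddof=1)  # column 0 off-diagonal
        assert sd0 == 0.0  # equal entries: zero spread, scores zeroed
        np.testing.assert_allclose(s[:, 0], 0.0)
        sd1 = np.std([1.0, 2.0], ddof=1)
        assert s[0, 1] == pytest.approx(1.0 / sd1)
        assert s[1, 1] == pytest.approx(3.0 / sd1)

    def test_monotone_in_magnitude(self):
        beta = np.array([[-1.0, 0.0, 10.0], [0.0, -1.0, 1.0], [0.1, 0.0, -1.0]])
        s = confidence_scores(beta)
        assert s[0, 2] > s[1, 2]

    def test_all_zero_column_scores_zero(self):
        beta = np.diag([-1.0, -1.0, -1.0])
        s = confidence_scores(beta)
        assert np.all(s[np.eye(3, dtype=bool) == 0] == 0)

    def test_small_matrix_rejected(self):
        with pytest.raises(ValueError, match="3 species"):
            confidence_scores(np.array([[-1.0, 0.0], [0.0, -1.0]]))


class TestGrowthRateRecovery:
    def test_independent_logistics_with_known_biomass(self):
        """Two non-interacting logistic species: with the true biomass and
        interaction matrix, the gLV-solving recovery finds both growth
        rates."""
        mu = np.array([0.8, 0.5])
        beta = np.diag([-2.0, -1.0])
        params = GLVParameters(mu=mu, beta=beta)
        times = np.linspace(0, 14, 30)
        trajs = [
            integrate_glv(params, params.equilibrium() * f, times)
            for f in ([0.15, 0.3], [0.4, 0.1])
        ]
        abund = [t / t.sum(axis=0, keepdims=True) for t in trajs]
        pre = preprocess(None, [times, times], abundances=abund)
        m = np.concatenate([t.sum(axis=0) for t in trajs])
        mu_hat = recover_growth_rates(pre, m, beta)
        np.testing.assert_allclose(mu_hat, mu, rtol=0.02)

    def test_no_interactions_constant_biomass_reduces_to_alr_gradients(self):
        """With beta = 0 and m constant, mu_i is the median positive
        d ln x~_i/dt."""
        rng = np.random.default_rng(0)
        times = np.linspace(0, 9, 12)
        # compositions drifting exponentially toward species 0
        w = np.exp(np.outer([0.3, 0.1, -0.2], times))
        X = w / w.sum(axis=0, keepdims=True)
        pre = preprocess(None, [times], abundances=[X])
        mu_hat = recover_growth_rates(pre, np.ones(12), np.zeros((3, 3)))
        # d ln x~_i/dt = r_i - sum_j r_j x~_j; positive medians only for the
        # fastest-growing species
        assert mu_hat[0] > 0
        assert np.isnan(mu_hat[2]) or mu_hat[2] < mu_hat[0]


class TestNetworkExport:
    def test_infinite_threshold_empty(self):
        beta = np.array([[-1.0, 2.0, 0.0], [0.0, -1.0, 3.0], [0.5, 0.0, -1.0]])
        s = confidence_scores(beta)
        edges, nodes = export_network(beta, s, np.full(3, 1 / 3), ["a", "b", "c"],
                                      threshold=np.inf)
        assert edges.empty
        assert len(nodes) == 3

    def test_true_edges_pass_with_separated_magnitudes(self):
        p = 5
        beta = -np.eye(p)
        beta[0, 3] = 4.0
        beta[2, 1] = -5.0
        s = confidence_scores(beta)
        edges, _ = export_network(beta, s, np.full(p, 0.2),
                                  [f"s{i}" for i in range(p)], threshold=1.0)
        got = {(e.source, e.target, e.sign) for e in edges.itertuples()}
        assert ("s3", "s0", 1) in got
        assert ("s1", "s2", -1) in got

    def test_candidate_edge_budget(self):
        """A 7-species community has at most 42 candidate off-diagonal
        interaction terms."""
        rng = np.random.default_rng(1)
        beta = rng.normal(size=(7, 7))
        np.fill_diagonal(beta, -1.0)
        s = confidence_scores(beta)
        edges, _ = export_network(beta, s, np.full(7, 1 / 7),
                                  [f"s{i}" for i in range(7)], threshold=0.0)
        assert len(edges) <= 42


class TestConsensus:
    def test_majority_rule(self):
        s_hi = np.full((3, 3), 2.0)
        s_lo = np.full((3, 3), 0.1)
        keep = consensus_edges([s_hi, s_hi, s_lo], threshold=1.0, min_fraction=0.5)
        assert keep.all()
        keep = consensus_edges([s_hi, s_lo, s_lo], threshold=1.0, min_fraction=0.5)
        assert not keep.any()

    def test_literal_inverted_reading_available(self):
        s_lo = np.full((2, 2), 0.5)
        keep = consensus_edges([s_lo, s_lo], keep_if_large=False)
        assert keep.all()


class TestDirectFit:
    def test_noise_free_recovery(self, small_dataset):
        ds = small_dataset
        X_true = ds.relative_abundances_true()
        pre = preprocess(None, ds.times, abundances=X_true,
                         species_ids=ds.params_true.species_ids)
        mu, beta = fit_glv_direct(pre, [m.copy() for m in ds.biomass_true])
        err_mu = np.median(np.abs((mu - ds.params_true.mu) / ds.params_true.mu))
        assert err_mu < 0.25  # 6 replicates: below benchmark scale
        nz = ds.params_true.beta != 0
        err_b = np.median(np.abs((beta[nz] - ds.params_true.beta[nz]) / ds.params_true.beta[nz]))
        assert err_b < 0.35
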