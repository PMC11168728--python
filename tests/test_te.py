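"""Kernel-entropy estimator, nonuniform embedding and multivariate TE."""

import numpy as np
import pytest
from scipy.linalg import solve_discrete_lyapunov

from mesoflow._engine import TrialEngine
from mesoflow.config import EmbeddingCandidates, KernelConfig
from mesoflow.te import (EmbeddingSpec, TEMatrix, conditional_entropy_terms,
                         kernel_entropy, select_nonuniform_embedding,
                         standardize, te_matrix_single_trial,
                         transfer_entropy_mv, trial_average_te)

from conftest import ar_coupled_pair


def brute_force_entropy(points: np.ndarray, r: float) -> float:
    """Independent O(n^2) double-loop evaluation of the same formula."""
    pts = np.atleast_2d(points.T).T if points.ndim == 1 else points
    if pts.ndim == 1:
        pts = pts[:, None]
    n = len(pts)
    h = 0.0
    for i in range(n):
        cnt = 0
        for j in range(n):
            if np.max(np.abs(pts[i] - pts[j])) <= r:
                cnt += 1
        h -= np.log(cnt / n)
    return h / n


class TestKernelEntropy:
    def test_identical_points_have_zero_entropy(self):
        pts = np.zeros((50, 3))
        assert kernel_entropy(pts, r=0.2) == 0.0

    def test_isolated_points_reach_log_n(self):
        pts = np.arange(40, dtype=float)[:, None]  # pairwise distance >= 1
        assert kernel_entropy(pts, r=0.2) == pytest.approx(np.log(40), abs=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            d = rng.integers(1, 4)
            pts = rng.standard_normal((120, d))
            assert kernel_entropy(pts, r=0.3) == pytest.approx(
                brute_force_entropy(pts, 0.3), abs=1e-9)

    def test_gaussian_sample_close_to_oracle_at_n2000(self):
        rng = np.random.default_rng(0)
        x = standardize(rng.standard_normal(2000))
        est = kernel_entropy(x, r=0.2)
        # subsampled oracle cross-check at identical formula, full n
        assert est == pytest.approx(brute_force_entropy(x[:400], 0.2), abs=0.1)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            kernel_entropy(np.zeros((5, 2)), r=0.2)
        with pytest.raises(ValueError):
            kernel_entropy(np.zeros((50, 2)), r=0.0)


class TestConditionalEntropy:
    def test_empty_conditioning_returns_plain_entropy(self):
        rng = np.random.default_rng(1)
        y = standardize(rng.standard_normal(500))
        assert conditional_entropy_terms(y, None) == kernel_entropy(y)

    def test_conditioning_on_exact_copy_is_zero(self):
        rng = np.random.default_rng(2)
        y = standardize(rng.standard_normal(2000))
        cfg = KernelConfig(r_fraction=0.5)
        assert abs(conditional_entropy_terms(y, y, cfg)) < 0.05

    def test_independent_conditioner_changes_nothing(self):
        cfg = KernelConfig(r_fraction=0.5)
        for sd in range(3):
            rng = np.random.default_rng(sd)
            y = standardize(rng.standard_normal(2000))
            v = standardize(rng.permutation(rng.standard_normal(2000)))
            assert conditional_entropy_terms(y, v, cfg) == pytest.approx(
                kernel_entropy(y, cfg), abs=0.05)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            conditional_entropy_terms(np.zeros(100), np.zeros((99, 1)))


class TestPackedEngine:
    """The bit-packed fast path must agree exactly with the reference
    estimator evaluated on the explicitly built lag matrices."""

    def test_joint_entropies_match_reference(self):
        rng = np.random.default_rng(3)
        x = standardize(rng.standard_normal((4, 300)))
        l, r = 30, 0.3
        eng = TrialEngine(x, r, l)
        t = np.arange(l, 300)
        jp = eng.joint_packed([(0, 0), (0, 4), (2, 11)])
        ref_pts = np.column_stack([x[0, t], x[0, t - 4], x[2, t - 11]])
        assert eng.entropy(jp) == pytest.approx(
            kernel_entropy(ref_pts, r=r), abs=1e-9)

    def test_shifted_window_equals_rolled_series(self):
        rng = np.random.default_rng(4)
        x = standardize(rng.standard_normal((2, 200)))
        l, r, sig = 20, 0.3, 57
        eng = TrialEngine(x, r, l)
        t = np.arange(l, 200)
        rolled = np.roll(x[1], sig)
        jp = eng.joint_packed([(0, 0)]) & eng.window(1, 5, shift=sig)
        ref = np.column_stack([x[0, t], rolled[t - 5]])
        assert eng.entropy(jp) == pytest.approx(kernel_entropy(ref, r=r), abs=1e-9)


class TestEmbeddingSelection:
    def test_iid_target_yields_empty_selection(self):
        """Per-step familywise false-acceptance stays near alpha: at most a
        small fraction of null targets select any term."""
        cfg = KernelConfig(surrogates=100)
        cand = EmbeddingCandidates(max_lag=50)
        nonempty = 0
        for sd in range(100):
            rng = np.random.default_rng(10_000 + sd)
            x = rng.standard_normal((5, 400))
            spec = select_nonuniform_embedding(x, 0, cand, cfg, seed=sd)
            nonempty += bool(spec.terms)
        assert nonempty <= 5

    def test_ar1_self_memory_selected(self):
        cfg = KernelConfig(r_fraction=0.5, surrogates=100)
        cand = EmbeddingCandidates(max_lag=20)
        hits = 0
        for sd in range(10):
            rng = np.random.default_rng(sd)
            n = 1000
            y = np.zeros(n + 100)
            e = rng.standard_normal(n + 100)
            for t in range(1, n + 100):
                y[t] = 0.9 * y[t - 1] + e[t]
            x = np.vstack([y[100:], rng.standard_normal(n)])
            spec = select_nonuniform_embedding(x, 0, cand, cfg, seed=sd)
            hits += (0, 1) in spec.terms
        assert hits >= 9

    def test_lagged_coupling_selected(self):
        """X -> Y at lag 3, strength 0.6: the source past is admitted in at
        least 90% of seeded realizations."""
        cfg = KernelConfig(surrogates=100)
        cand = EmbeddingCandidates(max_lag=50)
        hits = 0
        for sd in range(20):
            rng = np.random.default_rng(sd)
            n = 2000
            x = np.zeros((3, n + 100))
            e = rng.standard_normal((3, n + 100))
            for t in range(3, n + 100):
                x[0, t] = 0.5 * x[0, t - 1] + e[0, t]
                x[1, t] = 0.5 * x[1, t - 1] + np.tanh(0.6 * x[0, t - 3]) + e[1, t]
                x[2, t] = 0.5 * x[2, t - 1] + e[2, t]
            spec = select_nonuniform_embedding(x[:, 100:], 1, cand, cfg, seed=sd)
            hits += (0, 3) in spec.terms
        assert hits >= 18

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            select_nonuniform_embedding(np.random.default_rng(0).standard_normal((2, 40)),
                                        0, EmbeddingCandidates(max_lag=50))


class TestTransferEntropy:
    def test_no_source_term_gives_exact_zero(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal((3, 400))
        spec = EmbeddingSpec(target=1, terms=[(1, 1)])
        assert transfer_entropy_mv(x, 0, 1, spec) == 0.0

    def test_spec_target_mismatch_rejected(self):
        x = np.random.default_rng(0).standard_normal((3, 400))
        with pytest.raises(ValueError):
            transfer_entropy_mv(x, 0, 1, EmbeddingSpec(target=2))

    def test_gaussian_ar_closed_form(self):
        """Linear-Gaussian VAR(1) benchmark: kernel TE with the known-lag
        embedding matches 1/2 ln(var_reduced / var_full) within 30%."""
        a = b = c = 0.5
        A = np.array([[b, 0.0], [c, a]])
        S = solve_discrete_lyapunov(A, np.eye(2))
        cov_lag = A @ S
        var_red = S[1, 1] - cov_lag[1, 1] ** 2 / S[1, 1]
        te_true = 0.5 * np.log(var_red / 1.0)
        cfg = KernelConfig(r_fraction=0.5, surrogates=100)
        spec = EmbeddingSpec(target=1, terms=[(1, 1), (0, 1)])
        ests = [transfer_entropy_mv(ar_coupled_pair(sd, 2000), 0, 1, spec, cfg)
                for sd in range(20)]
        assert abs(np.mean(ests) - te_true) / te_true < 0.30

    def test_direction_asymmetry(self):
        """Unidirectional coupling: TE(true direction) > TE(reverse)."""
        cfg = KernelConfig(r_fraction=0.5, surrogates=100)
        spec_fwd = EmbeddingSpec(target=1, terms=[(1, 1), (0, 1)])
        spec_rev = EmbeddingSpec(target=0, terms=[(0, 1), (1, 1)])
        wins = 0
        for sd in range(10):
            z = ar_coupled_pair(sd, 1500)
            fwd = transfer_entropy_mv(z, 0, 1, spec_fwd, cfg)
            rev = transfer_entropy_mv(z, 1, 0, spec_rev, cfg)
            wins += fwd > rev
        assert wins >= 9

    def test_amplitude_invariance(self):
        """Per-channel affine rescaling cancels in the standardization."""
        cfg = KernelConfig(r_fraction=0.5, surrogates=100)
        cand = EmbeddingCandidates(max_lag=10)
        rng = np.random.default_rng(7)
        x = rng.standard_normal((3, 400))
        scaled = x * np.array([[13.0], [0.07], [3e3]]) + np.array([[5.], [-2.], [0.]])
        m1 = te_matrix_single_trial(x, cand, cfg, seed=9)
        m2 = te_matrix_single_trial(scaled, cand, cfg, seed=9)
        np.testing.assert_allclose(m1.values, m2.values, atol=1e-9)


class TestTEMatrix:
    def test_independent_channels_give_zero_matrix(self):
        cfg = KernelConfig(surrogates=100)
        cand = EmbeddingCandidates(max_lag=50)
        zero_runs = 0
        for sd in range(10):
            rng = np.random.default_rng(100 + sd)
            m = te_matrix_single_trial(rng.standard_normal((3, 400)), cand, cfg,
                                       seed=sd)
            zero_runs += not np.any(m.values)
        assert zero_runs >= 9

    def test_nonnegative_with_zero_diagonal(self, go_epoch_tensor, recovery_config):
        m = te_matrix_single_trial(go_epoch_tensor[:, :, 0],
                                   recovery_config.embedding,
                                   recovery_config.kernel, seed=0)
        assert np.all(m.values >= 0)
        assert np.all(np.diag(m.values) == 0)

    def test_channel_relabeling_equivariance(self):
        """Permuting the channels permutes the TE matrix consistently."""
        cfg = KernelConfig(r_fraction=0.5, surrogates=100)
        cand = EmbeddingCandidates(max_lag=10)
        z = ar_coupled_pair(11, 800, c=0.9)
        x = np.vstack([z, np.random.default_rng(12).standard_normal(800)])
        perm = np.array([2, 0, 1])
        m1 = te_matrix_single_trial(x, cand, cfg, seed=5)
        m2 = te_matrix_single_trial(x[perm], cand, cfg, seed=5)
        # binarized detection pattern must be exactly equivariant
        det1 = m1.values > 0
        det2 = m2.values > 0
        np.testing.assert_array_equal(det1[np.ix_(perm, perm)], det2)

    def test_emergent_lags_are_recent(self, go_epoch_tensor, recovery_config):
        """With true couplings at lags <= 5 ms, at least 95% of accepted
        source terms sit at lags <= 10 ms."""
        lags = []
        for tr in range(5):
            x = go_epoch_tensor[:, :, tr]
            for tgt in range(10):
                spec = select_nonuniform_embedding(
                    x, tgt, recovery_config.embedding, recovery_config.kernel,
                    seed=1000 + 10 * tr + tgt)
                lags += [lag for s, lag in spec.terms if s != tgt]
        assert len(lags) >= 20
        assert np.mean(np.asarray(lags) <= 10) >= 0.95

    def test_validation(self):
        with pytest.raises(ValueError):
            TEMatrix(values=np.array([[0.0, -0.1], [0.2, 0.0]]))
        with pytest.raises(ValueError):
            TEMatrix(values=np.array([[0.5, 0.1], [0.2, 0.0]]))
        with pytest.raises(ValueError):
            te_matrix_single_trial(np.full((3, 400), np.nan))


class TestTrialAverage:
    def test_mean_of_two_matrices(self):
        a = TEMatrix(values=np.array([[0, 2.0, 0], [1.0, 0, 0], [0, 4.0, 0]]),
                     condition="go")
        b = TEMatrix(values=np.array([[0, 0.0, 6.0], [3.0, 0, 0], [0, 0.0, 0]]),
                     condition="go")
        avg = trial_average_te([a, b])
        expected = np.array([[0, 1.0, 3.0], [2.0, 0, 0], [0, 2.0, 0]])
        np.testing.assert_array_equal(avg.values, expected)
        assert avg.trial_averaged

    def test_identical_and_zero_matrices(self):
        z = TEMatrix(values=np.zeros((3, 3)), condition="go")
        np.testing.assert_array_equal(trial_average_te([z, z]).values, np.zeros((3, 3)))

    def test_condition_mismatch_rejected(self):
        a = TEMatrix(values=np.zeros((3, 3)), condition="go")
        b = TEMatrix(values=np.zeros((3, 3)), condition="correct_stop")
        with pytest.raises(ValueError):
            trial_average_te([a, b])
        with pytest.raises(ValueError):
            trial_average_te([a])
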