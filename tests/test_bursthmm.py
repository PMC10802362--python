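"""Time-delay embedding, Gaussian HMM inference, burst statistics, PSDs."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from opmbeta.bursthmm import (EmbeddingError, HMMParams, StatePosterior,
                              TDEHMM, binarize_and_select, forward_backward,
                              state_psd, spectral_peak, time_delay_embed)


# ---------------------------------------------------------------------------
# independent oracle: exact HMM likelihood/posterior by path enumeration
# ---------------------------------------------------------------------------

def enumerate_posteriors(params: HMMParams, x: np.ndarray):
    """Sum over all K^T state paths (tiny T only)."""
    t_len = x.shape[0]
    k = params.n_states
    logb = np.empty((t_len, k))
    for j in range(k):
        logb[:, j] = stats.multivariate_normal.logpdf(
            x, params.means[j], params.covs[j])
    total = 0.0
    marg = np.zeros((t_len, k))
    for path in itertools.product(range(k), repeat=t_len):
        lp = np.log(params.startprob[path[0]]) + logb[0, path[0]]
        for t in range(1, t_len):
            lp += np.log(params.transmat[path[t - 1], path[t]]) \
                + logb[t, path[t]]
        p = np.exp(lp)
        total += p
        for t, s in enumerate(path):
            marg[t, s] += p
    return marg / total, np.log(total)


def _random_params(rng, k=3, d=2):
    means = rng.standard_normal((k, d))
    covs = np.stack([np.eye(d) * (0.5 + rng.random()) for _ in range(k)])
    trans = rng.random((k, k)) + 0.2
    trans /= trans.sum(axis=1, keepdims=True)
    start = rng.random(k) + 0.2
    start /= start.sum()
    return HMMParams(means, covs, trans, start)


class TestEmbedding:
    def test_definition_on_small_signal(self):
        emb = time_delay_embed([1, 2, 3, 4, 5], lags=(-1, 0, 1),
                               standardize=False)
        assert np.array_equal(emb.matrix, [[1, 2, 3], [2, 3, 4], [3, 4, 5]])
        assert emb.offset == 1

    def test_constant_signal_rejected(self):
        with pytest.raises(EmbeddingError):
            time_delay_embed(np.ones(500))

    def test_lag_span_exceeding_signal_rejected(self):
        with pytest.raises(EmbeddingError):
            time_delay_embed([1.0, 2.0], lags=(-3, 0, 3))

    def test_sinusoid_column_correlations_follow_autocorrelation(self):
        """Embedded-column correlations of a sinusoid = cos(2 pi f lag/fs)."""
        fs, f = 100.0, 7.0
        t = np.arange(20000) / fs
        emb = time_delay_embed(np.sin(2 * np.pi * f * t),
                               lags=tuple(range(-4, 5)), fs=fs)
        c = np.corrcoef(emb.matrix.T)
        for i, li in enumerate(emb.lags):
            for j, lj in enumerate(emb.lags):
                want = np.cos(2 * np.pi * f * (li - lj) / fs)
                assert abs(c[i, j] - want) < 0.01


class TestForwardBackward:
    def test_matches_path_enumeration(self, rng):
        """Exact smoothed posteriors and log-likelihood vs brute force."""
        params = _random_params(rng)
        x = rng.standard_normal((6, 2))
        emb_like = time_delay_embed(np.arange(100.0), lags=(0,))
        emb = type(emb_like)(x, (0,), 100.0, 0, 6)
        post, ll = forward_backward(params, emb)
        want_post, want_ll = enumerate_posteriors(params, x)
        assert abs(ll - want_ll) < 1e-8
        assert np.abs(post.probs - want_post).max() < 1e-8

    def test_symmetric_states_uniform_posterior(self):
        k = 3
        params = HMMParams(np.zeros((k, 2)), np.stack([np.eye(2)] * k),
                           np.full((k, k), 1 / k), np.full(k, 1 / k))
        x = np.random.default_rng(0).standard_normal((50, 2))
        emb = type(time_delay_embed(np.arange(100.0), lags=(0,)))(
            x, (0,), 100.0, 0, 50)
        post, _ = forward_backward(params, emb)
        assert np.allclose(post.probs, 1 / 3, atol=1e-12)

    def test_posterior_rows_sum_to_one(self, rng):
        params = _random_params(rng)
        x = rng.standard_normal((500, 2))
        emb = type(time_delay_embed(np.arange(100.0), lags=(0,)))(
            x, (0,), 100.0, 0, 500)
        post, _ = forward_backward(params, emb)
        assert np.allclose(post.probs.sum(axis=1), 1.0, atol=1e-10)


def _three_state_data(rng, t_len=6000):
    """Ground-truth 3-state sequence with well-separated spectra.

    Each state emits narrowband Gaussian noise in its own band with its own
    amplitude, so the embedded covariances are cleanly distinct.
    """
    from scipy import signal as sps
    fs = 100.0
    trans = np.array([[0.98, 0.01, 0.01],
                      [0.01, 0.98, 0.01],
                      [0.01, 0.01, 0.98]])
    states = np.zeros(t_len, dtype=int)
    s = 0
    for t in range(1, t_len):
        s = rng.choice(3, p=trans[s])
        states[t] = s
    bands = [(2.0, 6.0), (12.0, 18.0), (30.0, 40.0)]
    amps = [1.0, 1.0, 1.0]
    x = np.zeros(t_len)
    for j, (band, amp) in enumerate(zip(bands, amps)):
        b, a = sps.butter(4, (band[0] / (fs / 2), band[1] / (fs / 2)),
                          btype="band")
        comp = sps.filtfilt(b, a, rng.standard_normal(t_len))
        x[states == j] = amp * (comp / comp.std())[states == j]
    x += 0.1 * rng.standard_normal(t_len)
    return x, states, fs


class TestEMFitting:
    def test_loglik_monotone_nondecreasing(self, rng):
        x, _, fs = _three_state_data(rng)
        model = TDEHMM(time_delay_embed(x, lags=tuple(range(-3, 4)), fs=fs))
        res = model.fit(n_restarts=1, seed=0, max_iter=60, tol=1e-8)
        trace = res.params.loglik_trace
        assert np.all(np.diff(trace) >= -1e-8 * np.abs(trace[:-1]))

    def test_recovers_planted_states_after_permutation(self, rng):
        x, states, fs = _three_state_data(rng, t_len=8000)
        emb = time_delay_embed(x, lags=tuple(range(-3, 4)), fs=fs)
        res = TDEHMM(emb).fit(n_restarts=3, seed=0, max_iter=100, tol=1e-6)
        decoded = np.argmax(res.posterior.probs, axis=1)
        truth = states[emb.offset:emb.offset + decoded.size]
        best = 0.0
        for perm in itertools.permutations(range(3)):
            overlap = (np.array(perm)[decoded] == truth).mean()
            best = max(best, overlap)
        assert best > 0.9

    def test_single_state_posterior_all_one(self, rng):
        x = rng.standard_normal(2000)
        res = TDEHMM(time_delay_embed(x), n_states=1).fit(
            n_restarts=1, seed=0, max_iter=10)
        assert np.allclose(res.posterior.probs, 1.0)

    def test_deterministic_under_seed(self, rng):
        x, _, fs = _three_state_data(rng)
        emb = time_delay_embed(x, lags=tuple(range(-3, 4)), fs=fs)
        r1 = TDEHMM(emb).fit(n_restarts=2, seed=3, max_iter=40)
        r2 = TDEHMM(emb).fit(n_restarts=2, seed=3, max_iter=40)
        assert np.array_equal(r1.params.means, r2.params.means)
        assert np.array_equal(r1.params.transmat, r2.params.transmat)

    def test_posteriors_agree_with_hmmlearn_given_same_params(self, rng):
        """Independent cross-check: smoothing vs hmmlearn's implementation."""
        from hmmlearn.hmm import GaussianHMM
        params = _random_params(rng, k=3, d=2)
        x = rng.standard_normal((400, 2))
        emb = type(time_delay_embed(np.arange(100.0), lags=(0,)))(
            x, (0,), 100.0, 0, 400)
        post, ll = forward_backward(params, emb)

        ref = GaussianHMM(n_components=3, covariance_type="full",
                          init_params="")
        ref.startprob_ = params.startprob
        ref.transmat_ = params.transmat
        ref.means_ = params.means
        ref.covars_ = params.covs
        ll_ref, post_ref = ref.score_samples(x)
        assert abs(ll - ll_ref) < 1e-6 * abs(ll_ref)
        assert np.abs(post.probs - post_ref).max() < 1e-6

    def test_summary_reports_states_and_occupancy(self, rng):
        x, _, fs = _three_state_data(rng)
        res = TDEHMM(time_delay_embed(x, lags=tuple(range(-3, 4)), fs=fs)
                     ).fit(n_restarts=1, seed=0, max_iter=30)
        text = res.summary()
        assert "states: 3" in text
        assert "log-likelihood" in text


class TestBinarize:
    def _posterior(self, probs, fs=100.0):
        probs = np.asarray(probs, dtype=float)
        return StatePosterior(probs, fs, 0, probs.shape[0])

    def test_threshold_boundary_two_thirds_counts_as_active(self):
        post = self._posterior([[0.70, 0.20, 0.10],
                                [0.50, 0.30, 0.20],
                                [2 / 3, 1 / 6, 1 / 6]])
        b = post.binary()
        assert b[0, 0] == 1
        assert b[1].sum() == 0
        assert b[2, 0] == 1  # exactly at threshold -> active

    def test_at_most_one_active_state_per_row(self, rng):
        p = rng.dirichlet(np.ones(3), size=200)
        b = self._posterior(p).binary()
        assert set(np.unique(b)) <= {0, 1}
        assert b.sum(axis=1).max() <= 1

    def test_state_relabelling_leaves_burst_statistics_invariant(self, rng):
        probs = rng.dirichlet(np.ones(3) * 0.3, size=3500 * 4)
        table = pd.DataFrame({"onset_sample": np.arange(4) * 350,
                              "condition": ["index", "little"] * 2})
        post = self._posterior(probs)
        stats_a = binarize_and_select(post, table, 100.0)
        perm = [2, 0, 1]
        stats_b = binarize_and_select(self._posterior(probs[:, perm]),
                                      table, 100.0)
        assert np.isclose(stats_a.modulation, stats_b.modulation)
        assert perm[stats_b.burst_state] == stats_a.burst_state


class TestStatePSD:
    def test_planted_carrier_peak_recovered(self, rng):
        fs = 100.0
        n = 60000
        on = np.zeros(n, dtype=bool)
        # periodic long visits
        for start in range(0, n - 300, 600):
            on[start:start + 300] = True
        x = np.where(on, np.sin(2 * np.pi * 21.0 * np.arange(n) / fs), 0.0)
        x += 0.05 * rng.standard_normal(n)
        probs = np.zeros((n, 2))
        probs[:, 0] = np.where(on, 0.9, 0.05)
        probs[:, 1] = 1 - probs[:, 0]
        post = StatePosterior(probs, fs, 0, n)
        freqs, psd = state_psd(x, post, 0)
        df = freqs[1] - freqs[0]
        assert abs(spectral_peak(freqs, psd, near=21.0) - 21.0) \
            <= df + 1e-9

    def test_white_noise_state_flat_spectrum(self, rng):
        fs = 100.0
        n = 100000
        x = rng.standard_normal(n)
        probs = np.column_stack([np.full(n, 0.9), np.full(n, 0.1)])
        post = StatePosterior(probs, fs, 0, n)
        freqs, psd = state_psd(x, post, 0)
        sel = (freqs >= 5) & (freqs <= 45)
        assert psd[sel].max() / psd[sel].min() < 2.0

    def test_psd_nonnegative(self, rng):
        fs = 100.0
        n = 30000
        x = rng.standard_normal(n)
        probs = np.column_stack([np.full(n, 0.8), np.full(n, 0.2)])
        freqs, psd = state_psd(x, StatePosterior(probs, fs, 0, n), 0)
        assert np.all(psd >= 0)
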