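"""Time-delay-embedded Gaussian HMM for pan-spectral burst detection.

A univariate source time course (1-48 Hz, decimated to ~100 Hz) is lifted
into a lag-embedding — row t holds the signal at t+lag for a symmetric set
of lags — so that a Gaussian hidden Markov model over the embedded space
captures states with distinct spectral signatures.  A three-state model is
fitted by maximum-likelihood EM (Baum-Welch, k-means++ initialisation,
multiple restarts); smoothed posteriors are binarized at 2/3 and the state
whose occupancy is most task-modulated is the "burst state".

The model/fit split follows the statsmodels convention: :class:`TDEHMM` is
built from data, ``fit()`` returns a :class:`TDEHMMResults` with the
parameters, posteriors and a ``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy import signal as sps

__all__ = ["EmbeddedSeries", "HMMParams", "StatePosterior",
           "BurstStatistics", "time_delay_embed", "TDEHMM", "TDEHMMResults",
           "fit_hmm", "forward_backward", "binarize_and_select", "state_psd",
           "spectral_peak"]

BINARIZE_THRESHOLD = 2.0 / 3.0
DEFAULT_LAGS = tuple(range(-7, 8))


class EmbeddingError(ValueError):
    """Degenerate input to the lag embedding."""


# ---------------------------------------------------------------------------
# embedding
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EmbeddedSeries:
    """Lag-embedded, per-column standardized signal matrix.

    ``matrix[t, j] = (x[t + offset + lags[j]] - mean_j) / sd_j`` where
    ``offset = -min(lags)``; rows needing out-of-range samples are dropped.
    """

    matrix: np.ndarray          # (n_rows, n_lags)
    lags: tuple                 # sample offsets
    fs: float                   # rate of the embedded signal
    offset: int                 # index of first embedded row in the signal
    n_signal: int               # length of the source signal

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_dims(self) -> int:
        return self.matrix.shape[1]

    def row_sample_indices(self) -> np.ndarray:
        """Signal sample index that each embedded row is centred on."""
        return np.arange(self.n_rows) + self.offset


def time_delay_embed(signal: np.ndarray, lags=DEFAULT_LAGS,
                     fs: float = 100.0, standardize: bool = True
                     ) -> EmbeddedSeries:
    """Build the lag-embedding matrix of a 1-D signal."""
    x = np.asarray(signal, dtype=float).ravel()
    lags = tuple(int(l) for l in lags)
    lo, hi = min(lags), max(lags)
    n_rows = x.size - (hi - lo)
    if n_rows < 1:
        raise EmbeddingError("lag span exceeds signal length")
    offset = -lo
    mat = np.empty((n_rows, len(lags)))
    for j, lag in enumerate(lags):
        mat[:, j] = x[offset + lag:offset + lag + n_rows]
    if standardize:
        mu = mat.mean(axis=0)
        sd = mat.std(axis=0)
        if np.any(sd <= 0):
            raise EmbeddingError("zero-variance embedding column "
                                 "(constant signal?)")
        mat = (mat - mu) / sd
    return EmbeddedSeries(mat, lags, fs, offset, x.size)


# ---------------------------------------------------------------------------
# model parameters and posteriors
# ---------------------------------------------------------------------------

@dataclass
class HMMParams:
    means: np.ndarray           # (K, D)
    covs: np.ndarray            # (K, D, D)
    transmat: np.ndarray        # (K, K), rows sum to 1
    startprob: np.ndarray       # (K,)
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_states(self) -> int:
        return self.means.shape[0]

    def validate(self) -> None:
        k = self.n_states
        if not np.allclose(self.transmat.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition rows must sum to 1")
        if self.transmat.shape != (k, k) or self.startprob.shape != (k,):
            raise ValueError("inconsistent parameter shapes")
        for c in self.covs:
            np.linalg.cholesky(c)  # raises if not positive definite


@dataclass
class StatePosterior:
    """Smoothed state probabilities over the embedded rows."""

    probs: np.ndarray           # (T, K), rows sum to 1
    fs: float
    offset: int                 # first covered sample of the source signal
    n_signal: int

    def binary(self, threshold: float = BINARIZE_THRESHOLD) -> np.ndarray:
        """Thresholded occupancy; probability exactly at threshold counts."""
        return (self.probs >= threshold).astype(np.int8)

    def full_length(self, values: np.ndarray) -> np.ndarray:
        """Pad per-row values to the full signal length with NaN."""
        out = np.full((self.n_signal,) + values.shape[1:], np.nan)
        out[self.offset:self.offset + values.shape[0]] = values
        return out


@dataclass
class BurstStatistics:
    burst_state: int
    occupancy: np.ndarray       # (n_trial_samples, K) trial-averaged binary
    times: np.ndarray           # s relative to onset
    burst_probability: np.ndarray   # occupancy[:, burst_state]
    modulation: float           # post-window minus stimulus-window occupancy
    per_state_modulation: np.ndarray
    amplitude: float | None = None  # mean broadband envelope during bursts


# ---------------------------------------------------------------------------
# numba inference kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _fb_kernel(bmat, logscale, transmat, startprob):
    """Scaled forward-backward.

    ``bmat`` holds emission likelihoods scaled per row (exp(logb - rowmax)),
    ``logscale`` the per-row max log-density.  Returns (gamma, xi_sum,
    loglik).
    """
    t_len, k = bmat.shape
    alpha = np.empty((t_len, k))
    c = np.empty(t_len)

    s = 0.0
    for j in range(k):
        alpha[0, j] = startprob[j] * bmat[0, j]
        s += alpha[0, j]
    c[0] = s
    for j in range(k):
        alpha[0, j] /= s
    for t in range(1, t_len):
        s = 0.0
        for j in range(k):
            acc = 0.0
            for i in range(k):
                acc += alpha[t - 1, i] * transmat[i, j]
            alpha[t, j] = acc * bmat[t, j]
            s += alpha[t, j]
        c[t] = s
        for j in range(k):
            alpha[t, j] /= s

    beta = np.empty((t_len, k))
    for j in range(k):
        beta[t_len - 1, j] = 1.0
    xi_sum = np.zeros((k, k))
    for t in range(t_len - 2, -1, -1):
        for i in range(k):
            acc = 0.0
            for j in range(k):
                acc += transmat[i, j] * bmat[t + 1, j] * beta[t + 1, j]
            beta[t, i] = acc / c[t + 1]
        denom = 0.0
        for i in range(k):
            for j in range(k):
                denom += (alpha[t, i] * transmat[i, j]
                          * bmat[t + 1, j] * beta[t + 1, j])
        if denom > 0.0:
            for i in range(k):
                for j in range(k):
                    xi_sum[i, j] += (alpha[t, i] * transmat[i, j]
                                     * bmat[t + 1, j] * beta[t + 1, j]) / denom

    gamma = np.empty((t_len, k))
    for t in range(t_len):
        s = 0.0
        for j in range(k):
            gamma[t, j] = alpha[t, j] * beta[t, j]
            s += gamma[t, j]
        for j in range(k):
            gamma[t, j] /= s

    loglik = 0.0
    for t in range(t_len):
        loglik += np.log(c[t]) + logscale[t]
    return gamma, xi_sum, loglik


def _log_emission(x: np.ndarray, params: HMMParams) -> np.ndarray:
    """Gaussian log-densities, (T, K)."""
    from scipy.linalg import solve_triangular
    t_len, d = x.shape
    out = np.empty((t_len, params.n_states))
    for k in range(params.n_states):
        chol = np.linalg.cholesky(params.covs[k])
        # x @ chol^-T via a single GEMM (chol is small, x is long)
        inv_chol = solve_triangular(chol, np.eye(d), lower=True,
                                    check_finite=False)
        sol = (x - params.means[k]) @ inv_chol.T
        maha = np.einsum("td,td->t", sol, sol)
        logdet = 2.0 * np.log(np.diag(chol)).sum()
        out[:, k] = -0.5 * (maha + logdet + d * np.log(2.0 * np.pi))
    return out


def forward_backward(params: HMMParams, embedded: EmbeddedSeries
                     ) -> tuple[StatePosterior, float]:
    """Exact smoothed posteriors and total log-likelihood (scaled)."""
    params.validate()
    logb = _log_emission(embedded.matrix, params)
    if not np.all(np.isfinite(logb)):
        bad = int(np.flatnonzero(~np.isfinite(logb).all(axis=1))[0])
        raise FloatingPointError(
            f"non-finite emission density at embedded row {bad}")
    scale = logb.max(axis=1)
    bmat = np.exp(logb - scale[:, None])
    gamma, _, loglik = _fb_kernel(bmat, scale,
                                  np.ascontiguousarray(params.transmat),
                                  np.ascontiguousarray(params.startprob))
    post = StatePosterior(gamma, embedded.fs, embedded.offset,
                          embedded.n_signal)
    return post, float(loglik)


# ---------------------------------------------------------------------------
# EM fitting
# ---------------------------------------------------------------------------

_COV_FLOOR = 1e-6  # fraction of (unit) column variance


def _m_step(x: np.ndarray, gamma: np.ndarray, xi_sum: np.ndarray
            ) -> HMMParams:
    k = gamma.shape[1]
    d = x.shape[1]
    nk = gamma.sum(axis=0)
    means = (gamma.T @ x) / nk[:, None]
    covs = np.empty((k, d, d))
    floored = False
    for j in range(k):
        diff = x - means[j]
        cov = (diff.T * gamma[:, j]) @ diff / nk[j]
        cov = 0.5 * (cov + cov.T)
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            floored = True
            cov = cov + _COV_FLOOR * np.eye(d)
        if np.any(np.diag(cov) < _COV_FLOOR):
            floored = True
            cov = cov + _COV_FLOOR * np.eye(d)
        covs[j] = cov
    if floored:
        warnings.warn("covariance collapse: variance floor applied")
    trans = xi_sum / np.maximum(xi_sum.sum(axis=1, keepdims=True), 1e-300)
    start = gamma[0] / gamma[0].sum()
    return HMMParams(means, covs, trans, start)


def _init_params(x: np.ndarray, k: int, seed: int) -> HMMParams:
    from sklearn.cluster import KMeans
    labels = KMeans(n_clusters=k, n_init=1, random_state=seed
                    ).fit_predict(x)
    d = x.shape[1]
    means = np.empty((k, d))
    covs = np.empty((k, d, d))
    global_cov = np.cov(x.T) + _COV_FLOOR * np.eye(d)
    for j in range(k):
        sel = labels == j
        if sel.sum() > d:
            means[j] = x[sel].mean(axis=0)
            covs[j] = np.cov(x[sel].T) + _COV_FLOOR * np.eye(d)
        else:
            means[j] = x.mean(axis=0)
            covs[j] = global_cov
    trans = np.full((k, k), 0.05 / max(1, k - 1))
    np.fill_diagonal(trans, 0.95)
    if k == 1:
        trans = np.ones((1, 1))
    start = np.full(k, 1.0 / k)
    return HMMParams(means, covs, trans, start)


def _em(x: np.ndarray, embedded: EmbeddedSeries, k: int, seed: int,
        max_iter: int, tol: float) -> tuple[HMMParams, float]:
    params = _init_params(x, k, seed)
    trace = []
    prev = -np.inf
    for _ in range(max_iter):
        logb = _log_emission(x, params)
        scale = logb.max(axis=1)
        bmat = np.exp(logb - scale[:, None])
        gamma, xi_sum, loglik = _fb_kernel(
            bmat, scale, np.ascontiguousarray(params.transmat),
            np.ascontiguousarray(params.startprob))
        trace.append(loglik)
        new = _m_step(x, gamma, xi_sum)
        if k == 1:
            new.transmat = np.ones((1, 1))
        new.loglik_trace = np.asarray(trace)
        params = new
        if np.isfinite(prev) and abs(loglik - prev) < tol * abs(prev):
            break
        prev = loglik
    params.loglik_trace = np.asarray(trace)
    return params, trace[-1]


class TDEHMM:
    """Gaussian HMM over a time-delay embedding of one source signal.

    Parameters
    ----------
    embedded : EmbeddedSeries or array-like
        Lag-embedded data (see :func:`time_delay_embed`); a raw 1-D signal
        is embedded with the default lags.
    n_states : int
        Number of hidden states (three in the burst analysis).
    """

    def __init__(self, embedded, n_states: int = 3):
        if not isinstance(embedded, EmbeddedSeries):
            embedded = time_delay_embed(np.asarray(embedded, dtype=float))
        if embedded.n_rows < 100 * n_states:
            raise ValueError("need at least 100 rows per state")
        self.embedded = embedded
        self.n_states = int(n_states)

    @classmethod
    def from_virtual_electrode(cls, ve, band: tuple = (1.0, 48.0),
                               fs_target: float = 100.0,
                               lags=DEFAULT_LAGS, n_states: int = 3
                               ) -> "TDEHMM":
        """Filter a virtual electrode to ``band``, decimate, and embed."""
        factor = int(round(ve.fs / fs_target))
        if factor < 1 or abs(ve.fs / factor - fs_target) > 1e-9:
            raise ValueError(f"fs {ve.fs} not an integer multiple of "
                             f"{fs_target}")
        hi = min(band[1], 0.95 * fs_target / 2.0)
        sos = sps.butter(4, [band[0] / (ve.fs / 2), hi / (ve.fs / 2)],
                         btype="band", output="sos")
        x = sps.sosfiltfilt(sos, ve.timecourse)[::factor]
        emb = time_delay_embed(x, lags=lags, fs=fs_target)
        return cls(emb, n_states=n_states)

    def fit(self, n_restarts: int = 5, seed: int = 0, max_iter: int = 500,
            tol: float = 1e-6) -> "TDEHMMResults":
        """Run EM from ``n_restarts`` k-means++ initialisations, keep best."""
        best: tuple[HMMParams, float] | None = None
        for r in range(n_restarts):
            params, ll = _em(self.embedded.matrix, self.embedded,
                             self.n_states, seed + r, max_iter, tol)
            if best is None or ll > best[1]:
                best = (params, ll)
        params, ll = best
        post, _ = forward_backward(params, self.embedded)
        return TDEHMMResults(self, params, post, ll)


@dataclass
class TDEHMMResults:
    """Fitted TDE-HMM: parameters, smoothed posteriors, log-likelihood."""

    model: TDEHMM
    params: HMMParams
    posterior: StatePosterior
    loglik: float

    def fractional_occupancy(self) -> np.ndarray:
        return self.posterior.binary().mean(axis=0)

    def burst_statistics(self, trial_table: pd.DataFrame, rec_fs: float,
                         **kwargs) -> BurstStatistics:
        return binarize_and_select(self.posterior, trial_table, rec_fs,
                                   **kwargs)

    def state_psd(self, signal: np.ndarray, state: int, **kwargs):
        return state_psd(signal, self.posterior, state,
                         fs=self.posterior.fs, **kwargs)

    def summary(self) -> str:
        k = self.params.n_states
        occ = self.fractional_occupancy()
        dwell = 1.0 / np.maximum(1.0 - np.diag(self.params.transmat), 1e-12)
        lines = [
            "Time-delay-embedded Gaussian HMM",
            "=" * 48,
            f"states: {k}   embedding dim: {self.model.embedded.n_dims}"
            f"   rows: {self.model.embedded.n_rows}",
            f"log-likelihood: {self.loglik:.2f}"
            f"   EM iterations: {self.params.loglik_trace.size}",
            "",
            "state  frac.occupancy  mean dwell (samples)",
        ]
        for j in range(k):
            lines.append(f"{j:5d}  {occ[j]:14.3f}  {dwell[j]:18.1f}")
        return "\n".join(lines)


def fit_hmm(embedded: EmbeddedSeries, k: int = 3, n_restarts: int = 5,
            seed: int = 0, max_iter: int = 500, tol: float = 1e-6
            ) -> HMMParams:
    """Functional wrapper around :class:`TDEHMM` returning the parameters."""
    res = TDEHMM(embedded, n_states=k).fit(n_restarts=n_restarts, seed=seed,
                                           max_iter=max_iter, tol=tol)
    return res.params


# ---------------------------------------------------------------------------
# burst statistics
# ---------------------------------------------------------------------------

def binarize_and_select(post: StatePosterior, trial_table: pd.DataFrame,
                        rec_fs: float,
                        threshold: float = BINARIZE_THRESHOLD,
                        stim_window: tuple = (0.3, 0.8),
                        post_window: tuple = (1.0, 1.5),
                        good_trials: np.ndarray | None = None,
                        signal: np.ndarray | None = None,
                        direction: str = "suppressed"
                        ) -> BurstStatistics:
    """Binarize posteriors, pick the most task-modulated state.

    Occupancy is folded into trials (at the posterior's sampling rate) and
    trial-averaged.  With ``direction="suppressed"`` (default) the burst
    state maximises the signed post-minus-stimulus occupancy difference —
    the state most suppressed during stimulation, which is the defining
    signature of sensorimotor bursts in this task.  ``"absolute"`` selects
    by magnitude instead, but is degenerate whenever a single quiescent
    state carries the whole complement of the burst occupancy: that
    complement always modulates at least as strongly as the burst state
    itself.  ``signal`` (optional, at the posterior rate) yields the mean
    broadband Hilbert envelope over burst-on samples as the burst
    amplitude.
    """
    binary = post.binary(threshold)
    if not binary.any():
        warnings.warn("no state posterior ever exceeds the threshold")
    full = post.full_length(binary.astype(float))    # (n_signal, K), NaN pad

    onsets = trial_table["onset_sample"].to_numpy()
    if good_trials is not None:
        onsets = onsets[np.asarray(good_trials, dtype=int)]
    ratio = post.fs / rec_fs
    tl = int(np.floor(np.min(np.diff(np.sort(
        trial_table["onset_sample"].to_numpy()))) * ratio))
    rows = []
    for o in onsets:
        lo = int(round(o * ratio))
        if lo + tl <= full.shape[0]:
            rows.append(full[lo:lo + tl])
    folded = np.asarray(rows)                        # (n_trials, tl, K)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        occupancy = np.nanmean(folded, axis=0)
    occupancy = np.nan_to_num(occupancy)
    times = np.arange(tl) / post.fs

    def wmean(w):
        sel = (times >= w[0]) & (times < w[1])
        return occupancy[sel].mean(axis=0)
    diff = wmean(post_window) - wmean(stim_window)   # (K,)
    if direction == "suppressed":
        burst_state = int(np.argmax(diff))
    elif direction == "absolute":
        burst_state = int(np.argmax(np.abs(diff)))
    else:
        raise ValueError(f"unknown selection direction {direction!r}")

    amplitude = None
    if signal is not None:
        sig = np.asarray(signal, dtype=float)
        env = np.abs(sps.hilbert(sig))
        on = post.full_length(binary[:, burst_state].astype(float))
        mask = on[:sig.size] == 1.0
        if mask.any():
            amplitude = float(env[mask].mean())

    return BurstStatistics(
        burst_state=burst_state, occupancy=occupancy, times=times,
        burst_probability=occupancy[:, burst_state],
        modulation=float(diff[burst_state]),
        per_state_modulation=diff, amplitude=amplitude)


# ---------------------------------------------------------------------------
# state-resolved spectra
# ---------------------------------------------------------------------------

def state_psd(signal: np.ndarray, post: StatePosterior, state: int,
              fs: float | None = None, nperseg: int = 256,
              time_bandwidth: float = 4.0,
              fband: tuple = (1.0, 48.0),
              min_duration: float = 0.1, min_visits: int = 20
              ) -> tuple[np.ndarray, np.ndarray]:
    """Multitaper PSD of the signal during visits to one state.

    Samples where the binarized state indicator is on are concatenated,
    split into ``nperseg`` segments and averaged over DPSS tapers
    (time-bandwidth product ``time_bandwidth``).  Returns ``(freqs, psd)``
    restricted to ``fband``.
    """
    fs = fs or post.fs
    sig = np.asarray(signal, dtype=float)
    binary = post.binary()[:, state].astype(bool)
    on = np.zeros(sig.size, dtype=bool)
    n = min(binary.size, sig.size - post.offset)
    on[post.offset:post.offset + n] = binary[:n]

    edges = np.flatnonzero(np.diff(np.concatenate(
        [[0], on.view(np.int8), [0]])))
    seg_lens = edges[1::2] - edges[::2]
    n_visits = int((seg_lens >= min_duration * fs).sum())
    if n_visits < min_visits:
        warnings.warn(f"only {n_visits} visits of >= {min_duration}s; "
                      "state PSD unreliable")
        if n_visits == 0:
            return np.empty(0), np.empty(0)

    concat = sig[on]
    n_seg = concat.size // nperseg
    if n_seg == 0:
        warnings.warn("not enough burst samples for one PSD segment")
        return np.empty(0), np.empty(0)
    segs = concat[:n_seg * nperseg].reshape(n_seg, nperseg)
    segs = segs - segs.mean(axis=1, keepdims=True)

    k_tapers = int(2 * time_bandwidth - 1)
    tapers = sps.windows.dpss(nperseg, time_bandwidth, Kmax=k_tapers)
    freqs = np.fft.rfftfreq(nperseg, d=1.0 / fs)
    psd = np.zeros(freqs.size)
    for w in tapers:
        spec = np.fft.rfft(segs * w[None, :], axis=1)
        psd += (np.abs(spec) ** 2).mean(axis=0)
    psd /= k_tapers * fs
    sel = (freqs >= fband[0]) & (freqs <= fband[1])
    return freqs[sel], psd[sel]


def spectral_peak(freqs: np.ndarray, psd: np.ndarray,
                  near: float | None = None, search: float = 3.0) -> float:
    """Frequency of a spectral peak, robust to multitaper flat-tops.

    Multitaper smoothing turns a narrowband peak into a plateau ~2W wide
    whose raw argmax wanders within the plateau; the power-weighted centroid
    of the region within 3 dB of the local maximum recovers the centre.
    ``near`` restricts the search to +- ``search`` Hz around a candidate.
    """
    freqs = np.asarray(freqs, dtype=float)
    psd = np.asarray(psd, dtype=float)
    if near is not None:
        sel = np.abs(freqs - near) <= search
        freqs, psd = freqs[sel], psd[sel]
    if freqs.size == 0:
        raise ValueError("empty frequency range")
    k = int(np.argmax(psd))
    top = psd >= 0.5 * psd[k]
    # contiguous 3 dB region around the maximum
    lo = k
    while lo > 0 and top[lo - 1]:
        lo -= 1
    hi = k
    while hi < psd.size - 1 and top[hi + 1]:
        hi += 1
    w = psd[lo:hi + 1]
    return float((freqs[lo:hi + 1] * w).sum() / w.sum())
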