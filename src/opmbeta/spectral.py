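"""Hilbert-envelope spectral analysis of virtual-electrode time courses.

Implements the induced/evoked split used in sensorimotor task MEG: a
time-frequency spectrogram of fractional envelope change from baseline, a
beta modulation index contrasting stimulus (0.3-0.8 s), post-stimulus
(1-1.5 s) and baseline (2.5-3 s) windows, and the phase-locked evoked
response with its ~50 ms (M50) component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.fft import next_fast_len

__all__ = ["TimeFreqSpectrogram", "BetaModulation", "EvokedResponse",
           "hilbert_envelope", "fold_trials", "time_frequency_spectrogram",
           "beta_modulation_index", "evoked_response", "default_tfs_bands"]

STIM_WINDOW = (0.3, 0.8)
POST_WINDOW = (1.0, 1.5)
BASELINE_WINDOW = (2.5, 3.0)


@dataclass(frozen=True)
class TimeFreqSpectrogram:
    """Fractional envelope change from baseline, time x frequency."""

    values: np.ndarray          # (n_times, n_bands)
    times: np.ndarray           # s, relative to stimulus onset
    band_centres: np.ndarray    # Hz
    bands: tuple                # ((lo, hi), ...)
    baseline_window: tuple      # s


@dataclass(frozen=True)
class BetaModulation:
    beta_stim: float
    beta_post: float
    beta_baseline: float

    @property
    def betamod(self) -> float:
        """(post - stim) / baseline envelope amplitude."""
        if self.beta_baseline <= 0:
            raise ZeroDivisionError("baseline beta amplitude is zero")
        return (self.beta_post - self.beta_stim) / self.beta_baseline


@dataclass(frozen=True)
class EvokedResponse:
    average: np.ndarray         # trial-averaged 4-40 Hz time course
    times: np.ndarray           # s relative to onset
    m50_amplitude: float
    m50_latency: float


# ---------------------------------------------------------------------------

def hilbert_envelope(signal: np.ndarray, band: tuple, fs: float,
                     order: int = 4) -> np.ndarray:
    """Amplitude envelope of the band-filtered signal (analytic magnitude)."""
    if not 0 < band[0] < band[1] < fs / 2:
        raise ValueError(f"band {band} invalid for fs={fs}")
    sos = sps.butter(order, [band[0] / (fs / 2), band[1] / (fs / 2)],
                     btype="band", output="sos")
    x = sps.sosfiltfilt(sos, np.asarray(signal, dtype=float), axis=-1)
    n = x.shape[-1]
    nfft = next_fast_len(n)  # pad for FFT speed, then trim
    analytic = sps.hilbert(x, N=nfft, axis=-1)[..., :n]
    return np.abs(analytic)


def fold_trials(x: np.ndarray, trial_table: pd.DataFrame, fs: float,
                good_trials: np.ndarray | None = None,
                trial_length: float | None = None,
                pre: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Cut a 1-D time course into (n_trials, n_samples) epochs.

    Epochs run from ``-pre`` to ``trial_length`` s around each onset; trials
    whose window falls outside the data are dropped.
    """
    onsets = trial_table["onset_sample"].to_numpy()
    if good_trials is not None:
        onsets = onsets[np.asarray(good_trials, dtype=int)]
    if trial_length is None:
        tl = int(np.min(np.diff(np.sort(
            trial_table["onset_sample"].to_numpy()))))
    else:
        tl = int(round(trial_length * fs))
    npre = int(round(pre * fs))
    rows = [x[o - npre:o + tl] for o in onsets
            if o - npre >= 0 and o + tl <= x.size]
    times = (np.arange(-npre, tl)) / fs
    return np.asarray(rows), times


def default_tfs_bands(fmin: float = 1.0, fmax: float = 48.0,
                      width: float = 4.0, step: float = 2.0) -> tuple:
    """Overlapping analysis bands: ``width`` Hz wide, stepped by ``step``."""
    lows = np.arange(fmin, fmax - width + step / 2, step)
    return tuple((float(lo), float(lo + width)) for lo in lows)


def time_frequency_spectrogram(ve, trial_table: pd.DataFrame,
                               bands: tuple | None = None,
                               baseline: tuple = BASELINE_WINDOW,
                               good_trials: np.ndarray | None = None
                               ) -> TimeFreqSpectrogram:
    """Trial-averaged Hilbert-envelope spectrogram, baseline-normalised.

    Per band: envelope -> trial average -> (x - mean_baseline)/mean_baseline.
    ``ve`` is a :class:`~opmbeta.beamform.VirtualElectrode` or any object
    with ``timecourse``/``fs`` attributes.
    """
    bands = bands or default_tfs_bands()
    x, fs = ve.timecourse, ve.fs
    folded0, times = fold_trials(np.zeros_like(x), trial_table, fs,
                                 good_trials)
    if folded0.shape[0] < 5:
        raise ValueError("need at least 5 good trials for a spectrogram")
    bsel = (times >= baseline[0]) & (times < baseline[1])
    if not bsel.any():
        raise ValueError("baseline window outside trial")

    out = np.empty((times.size, len(bands)))
    for j, band in enumerate(bands):
        env = hilbert_envelope(x, band, fs)
        folded, _ = fold_trials(env, trial_table, fs, good_trials)
        avg = folded.mean(axis=0)
        base = avg[bsel].mean()
        out[:, j] = (avg - base) / base
    centres = np.array([(lo + hi) / 2 for lo, hi in bands])
    return TimeFreqSpectrogram(out, times, centres, tuple(bands), baseline)


def _window_mean(avg: np.ndarray, times: np.ndarray, window: tuple) -> float:
    sel = (times >= window[0]) & (times < window[1])
    if not sel.any():
        raise ValueError(f"window {window} outside trial")
    return float(avg[sel].mean())


def beta_modulation_index(ve, trial_table: pd.DataFrame,
                          band: tuple = (13.0, 30.0),
                          good_trials: np.ndarray | None = None,
                          stim_window: tuple = STIM_WINDOW,
                          post_window: tuple = POST_WINDOW,
                          baseline_window: tuple = BASELINE_WINDOW
                          ) -> BetaModulation:
    """Beta modulation index from the trial-averaged beta envelope."""
    env = hilbert_envelope(ve.timecourse, band, ve.fs)
    folded, times = fold_trials(env, trial_table, ve.fs, good_trials)
    avg = folded.mean(axis=0)
    return BetaModulation(
        beta_stim=_window_mean(avg, times, stim_window),
        beta_post=_window_mean(avg, times, post_window),
        beta_baseline=_window_mean(avg, times, baseline_window))


def evoked_response(ve, trial_table: pd.DataFrame,
                    band: tuple = (4.0, 40.0),
                    good_trials: np.ndarray | None = None,
                    search_window: tuple = (0.04, 0.07),
                    baseline_window: tuple = (-0.1, 0.0),
                    pre: float = 0.1) -> EvokedResponse:
    """Phase-locked trial average and its M50 component.

    The M50 amplitude is the signed extremum in ``search_window`` after
    subtracting the pre-stimulus baseline mean.  Trials without a full
    pre-stimulus margin (e.g. the first) are dropped from the average.
    """
    x = ve.timecourse
    if band is not None:
        sos = sps.butter(4, [band[0] / (ve.fs / 2), band[1] / (ve.fs / 2)],
                         btype="band", output="sos")
        x = sps.sosfiltfilt(sos, x)
    folded, times = fold_trials(x, trial_table, ve.fs, good_trials, pre=pre)
    avg = folded.mean(axis=0) if folded.size else np.zeros(times.size)

    bsel = (times >= baseline_window[0]) & (times < baseline_window[1])
    corrected = avg - (avg[bsel].mean() if bsel.any() else 0.0)
    ssel = (times >= search_window[0]) & (times <= search_window[1])
    seg = corrected[ssel]
    k = int(np.argmax(np.abs(seg)))
    return EvokedResponse(average=avg, times=times,
                          m50_amplitude=float(seg[k]),
                          m50_latency=float(times[ssel][k]))
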