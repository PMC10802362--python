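"""Filtering, channel/trial quality control and homogeneous field correction.

The chain mirrors standard OPM-MEG practice: flag bad channels from their
broadband power, zero-phase band-pass + powerline notch filtering, variance
based trial rejection, then homogeneous field correction (HFC) — projection
of the data onto the complement of the rank-3 subspace spanned by the
channel orientation vectors, which removes any spatially uniform field.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .geometry import SensorArray
from .synthcohort import Recording

__all__ = ["PreprocConfig", "QCReport", "apply_filters",
           "detect_bad_channels", "reject_trials", "variance_threshold",
           "homogeneous_field_correction", "hfc_projector", "run_preprocessing"]


class ConfigError(ValueError):
    """Invalid preprocessing configuration."""


class PipelineAbort(RuntimeError):
    """Unrecoverable data-quality failure."""


@dataclass(frozen=True)
class PreprocConfig:
    """Preprocessing parameters (defaults follow common 50 Hz-mains setups)."""

    notch_freq: float = 50.0
    n_harmonics: int = 2
    band: tuple = (1.0, 150.0)
    trial_var_sd: float = 3.0
    hfc: bool = True
    notch_q: float = 30.0
    filter_order: int = 4

    def __post_init__(self) -> None:
        lo, hi = self.band
        if not 0 < lo < hi:
            raise ConfigError("band must satisfy 0 < low < high")
        if self.trial_var_sd <= 0:
            raise ConfigError("trial_var_sd must be positive")

    def validate_against(self, fs: float) -> None:
        if self.band[1] >= fs / 2.0:
            raise ConfigError(
                f"band-pass upper edge {self.band[1]} Hz >= Nyquist {fs/2}")


@dataclass
class QCReport:
    """Outcome of automated quality control."""

    bad_channels: dict = field(default_factory=dict)   # index -> reason
    bad_trials: dict = field(default_factory=dict)     # index -> variance
    trial_variances: np.ndarray | None = None
    fraction_trials_removed: float = 0.0

    def to_dict(self) -> dict:
        return {
            "bad_channels": {int(k): v for k, v in self.bad_channels.items()},
            "bad_trials": {int(k): float(v)
                           for k, v in self.bad_trials.items()},
            "fraction_trials_removed": float(self.fraction_trials_removed),
        }


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def _notch_sos(freq: float, fs: float, q: float) -> np.ndarray:
    b, a = sps.iirnotch(freq, q, fs=fs)
    return sps.tf2sos(b, a)


def apply_filters(rec: Recording, cfg: PreprocConfig = PreprocConfig()
                  ) -> Recording:
    """Zero-phase band-pass plus powerline notches.

    Butterworth band-pass (order ``cfg.filter_order``) and IIR notches at
    the powerline frequency and its harmonics, all applied forward-backward
    (``sosfiltfilt``) so the net phase response is zero.  Harmonics at or
    above Nyquist are skipped.
    """
    cfg.validate_against(rec.fs)
    sos = sps.butter(cfg.filter_order,
                     [cfg.band[0] / (rec.fs / 2), cfg.band[1] / (rec.fs / 2)],
                     btype="band", output="sos")
    out = rec.copy()
    out.data = sps.sosfiltfilt(sos, out.data, axis=1)
    for k in range(1, cfg.n_harmonics + 2):
        f = cfg.notch_freq * k
        if f >= rec.fs / 2.0:
            break
        out.data = sps.sosfiltfilt(_notch_sos(f, rec.fs, cfg.notch_q),
                                   out.data, axis=1)
    return out


# ---------------------------------------------------------------------------
# channel QC
# ---------------------------------------------------------------------------

def detect_bad_channels(rec: Recording, power_band: tuple = (1.0, 98.0),
                        n_mad: float = 3.0, min_dex: float = 0.5) -> dict:
    """Flag dead or outlier channels from broadband log-power.

    A deterministic surrogate for manual spectrum inspection: channels with
    zero variance, or whose log10 broadband power lies more than ``n_mad``
    scaled MADs *and* ``min_dex`` decades from the cross-channel median, are
    flagged.  The absolute floor keeps homogeneous arrays (where the MAD is
    driven by estimator noise alone) from flagging healthy channels.
    """
    if rec.n_channels < 8:
        raise PipelineAbort("need at least 8 channels for channel QC")
    hi = min(power_band[1], 0.99 * rec.fs / 2.0)
    f, pxx = sps.welch(rec.data, fs=rec.fs,
                       nperseg=min(2048, rec.n_samples), axis=1)
    sel = (f >= power_band[0]) & (f <= hi)
    power = pxx[:, sel].sum(axis=1)

    reasons: dict[int, str] = {}
    dead = power <= 0
    for idx in np.flatnonzero(dead):
        reasons[int(idx)] = "zero variance"
    logp = np.full(power.shape, np.nan)
    logp[~dead] = np.log10(power[~dead])
    med = np.nanmedian(logp)
    mad = 1.4826 * np.nanmedian(np.abs(logp - med))
    if mad > 0:
        dev = np.abs(logp - med)
        for idx in np.flatnonzero((dev > n_mad * mad) & (dev > min_dex)):
            reasons.setdefault(int(idx), "log-power outlier")
    if len(reasons) == rec.n_channels:
        raise PipelineAbort("all channels flagged bad; aborting")
    return reasons


# ---------------------------------------------------------------------------
# trial QC
# ---------------------------------------------------------------------------

def _trial_variances(rec: Recording) -> np.ndarray:
    good = rec.good_channel_indices()
    tl = rec.trial_length_samples or rec.n_samples
    var = np.empty(len(rec.trial_table))
    for i, onset in enumerate(rec.trial_table["onset_sample"].to_numpy()):
        seg = rec.data[np.ix_(good, np.arange(onset, min(onset + tl,
                                                         rec.n_samples)))]
        var[i] = seg.var()
    return var


def variance_threshold(variances: np.ndarray, n_sd: float = 3.0) -> float:
    """Rejection threshold: mean + ``n_sd`` sample SDs of the variances."""
    v = np.asarray(variances, dtype=float)
    return float(v.mean() + n_sd * v.std(ddof=1))


def reject_trials(rec: Recording, n_sd: float = 3.0) -> QCReport:
    """Flag trials whose pooled variance exceeds mean + ``n_sd`` SDs.

    Variance is pooled over good channels per trial.  After removing the
    flagged trials the rule is re-applied once to the survivors (a single
    re-iteration), since extreme trials inflate the first-pass threshold.
    Trials exactly at the threshold are retained (strict inequality).
    """
    if len(rec.trial_table) < 5:
        raise PipelineAbort("need at least 5 trials for trial QC")
    var = _trial_variances(rec)
    bad: dict[int, float] = {}
    keep = np.arange(var.size)
    for _ in range(2):  # initial pass + one re-iteration
        thresh = variance_threshold(var[keep], n_sd)
        newly = keep[var[keep] > thresh]
        if newly.size == 0:
            break
        for idx in newly:
            bad[int(idx)] = float(var[idx])
        keep = np.setdiff1d(keep, newly)
    if keep.size < 5:
        warnings.warn("fewer than 5 trials survive variance rejection")
    return QCReport(bad_trials=bad, trial_variances=var,
                    fraction_trials_removed=len(bad) / var.size)


# ---------------------------------------------------------------------------
# homogeneous field correction
# ---------------------------------------------------------------------------

def hfc_projector(array: SensorArray,
                  good_channels: np.ndarray | None = None) -> np.ndarray:
    """Orthogonal projector onto the complement of the uniform-field space.

    The model is B_ch = n_ch . B0 for an unknown uniform field B0, i.e. the
    interference lives in the column space of the (n_channels, 3) matrix of
    channel orientations N.  Returns P = I - N (N^T N)^-1 N^T, which is
    symmetric, idempotent and of rank n_channels - 3.
    """
    n_mat = array.channel_orientations
    if good_channels is not None:
        n_mat = n_mat[good_channels]
    if n_mat.shape[0] < 4 or np.linalg.matrix_rank(n_mat) < 3:
        raise PipelineAbort("channel orientations span < 3 dimensions")
    pinv = np.linalg.solve(n_mat.T @ n_mat, n_mat.T)
    return np.eye(n_mat.shape[0]) - n_mat @ pinv


def homogeneous_field_correction(rec: Recording) -> Recording:
    """Remove the spatially homogeneous field component from the data.

    Applies the HFC projector over good channels; bad channels are left
    untouched (they are excluded from all downstream stages anyway).
    """
    good = rec.good_channel_indices()
    proj = hfc_projector(rec.array, good)
    out = rec.copy()
    out.data[good] = proj @ out.data[good]
    return out


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------

def run_preprocessing(rec: Recording, cfg: PreprocConfig = PreprocConfig()
                      ) -> tuple[Recording, QCReport]:
    """Bad channels -> filters -> trial rejection -> HFC."""
    report = QCReport(bad_channels=detect_bad_channels(rec))
    rec = rec.copy()
    rec.bad_channels |= set(report.bad_channels)
    rec = apply_filters(rec, cfg)
    trial_report = reject_trials(rec, n_sd=cfg.trial_var_sd)
    report.bad_trials = trial_report.bad_trials
    report.trial_variances = trial_report.trial_variances
    report.fraction_trials_removed = trial_report.fraction_trials_removed
    rec.bad_trials |= set(report.bad_trials)
    if cfg.hfc:
        rec = homogeneous_field_correction(rec)
    return rec, report
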