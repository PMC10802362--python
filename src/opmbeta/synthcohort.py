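"""Synthetic OPM-MEG cohort generator with planted, age-dependent structure.

Each simulated participant is a triaxial sensor-array recording of a
somatosensory task (0.5 s tactile stimulus every 3.5 s, two alternating
finger conditions, 42 trials each) containing:

* a left-sensorimotor source emitting pan-spectral bursts whose occupancy
  probability drops during the stimulus period,
* an evoked (M50-like) component time-locked to stimulus onset,
* beta-band network sources at cortical parcel centroids whose amplitude
  envelopes are correlated within frontal and occipital groups,
* 1/f background sources, white sensor noise, and (optionally) a spatially
  homogeneous interference field.

Age effects are planted as linear trends (burst modulation and frontal
envelope coupling grow with age; low-frequency burst carrier weight falls
while beta/gamma weights rise), so every downstream analysis stage has a
recoverable ground truth.  All randomness flows from explicit integer
seeds; a cohort is a pure function of (configuration, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .forward import sarvas_leadfield
from .geometry import HeadModel, SensorArray, head_radius_for_age, make_sensor_array

__all__ = [
    "Protocol", "BurstProcessSpec", "ParticipantSpec", "Recording",
    "GroundTruth", "AgeEffectSlopes", "simulate_burst_train",
    "sensorimotor_signal",
    "simulate_participant", "make_cohort", "make_cohort_specs", "iter_cohort",
    "envelope_coupled_signals",
]


class ParameterError(ValueError):
    """Invalid simulation parameter."""


# ---------------------------------------------------------------------------
# protocol and specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Protocol:
    """Task timing: alternating index/little-finger tactile stimulation."""

    fs: float = 1200.0
    trial_length: float = 3.5          # s
    stim_duration: float = 0.5         # s of actual tapping
    modulation_window: tuple = (0.0, 0.8)  # s, burst suppression period
    n_trials_per_condition: int = 42
    conditions: tuple = ("index", "little")

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.trial_length <= 0:
            raise ParameterError("fs and trial_length must be positive")

    @property
    def n_trials(self) -> int:
        return self.n_trials_per_condition * len(self.conditions)

    @property
    def samples_per_trial(self) -> int:
        return int(round(self.trial_length * self.fs))

    @property
    def n_samples(self) -> int:
        return self.n_trials * self.samples_per_trial

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def trial_table(self) -> pd.DataFrame:
        onsets = np.arange(self.n_trials) * self.samples_per_trial
        conds = [self.conditions[i % len(self.conditions)]
                 for i in range(self.n_trials)]
        return pd.DataFrame({"onset_sample": onsets, "condition": conds})


@dataclass(frozen=True)
class BurstProcessSpec:
    """Two-state (on/off) Markov burst process.

    ``p_stim`` / ``p_base`` are the stationary burst-ON occupancy
    probabilities during the stimulus window and at rest.  The exit rate is
    fixed by ``mean_duration`` and the entry rate is derived so that the
    chain's stationary ON probability equals the requested occupancy.
    During ON periods the waveform is a Tukey-gated sum of narrowband
    stochastic carriers (default centres 3/9/21/37 Hz), giving pan-spectral
    bursts whose spectral peaks sit at the carrier centres.
    """

    p_stim: float = 0.2
    p_base: float = 0.5
    mean_duration: float = 0.25        # s
    carrier_freqs: tuple = (3.0, 9.0, 21.0, 37.0)
    carrier_weights: tuple = (1.0, 0.6, 0.8, 0.3)
    carrier_bandwidth: float = 2.5     # Hz, width of each carrier component
    tukey_alpha: float = 0.4

    def __post_init__(self) -> None:
        for name in ("p_stim", "p_base"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1]")
        if self.mean_duration <= 0:
            raise ParameterError("mean_duration must be positive")
        w = np.asarray(self.carrier_weights, dtype=float)
        if len(self.carrier_freqs) != w.size:
            raise ParameterError("carrier_freqs/weights length mismatch")
        if np.any(w < 0) or not np.any(w > 0):
            raise ParameterError("weights must be >= 0 with one positive")

    def transition_matrix(self, p_on: float, fs: float) -> np.ndarray:
        """Per-sample transition matrix [[off->off, off->on], [on->off, on->on]].

        Exit probability q = 1 / (mean_duration * fs); entry probability
        e = p_on * q / (1 - p_on), giving stationary P(on) = p_on exactly.
        """
        q = min(1.0, 1.0 / (self.mean_duration * fs))
        if p_on >= 1.0:
            e = 1.0
        else:
            e = min(1.0, p_on * q / (1.0 - p_on))
        return np.array([[1.0 - e, e], [q, 1.0 - q]])


@dataclass(frozen=True)
class ParticipantSpec:
    """Everything needed to simulate one participant deterministically."""

    age: float                          # years
    head_radius: float                  # m
    burst_spec: BurstProcessSpec
    seed: int
    group: str = "adult"                # "child" | "adult"
    participant_id: str = "p000"
    burst_amplitude: float = 20e-9      # A m
    evoked_amplitude: float = 10e-9     # A m
    coupling_frontal: float = 0.3       # target envelope correlation
    coupling_occipital: float = 0.25
    network_amplitude: float = 4e-9     # A m per parcel source
    background_amplitude: float = 8e-9  # A m per 1/f source
    n_background: int = 6
    noise_floor: float = 15.0           # fT / sqrt(Hz)
    interference_amplitude: float = 0.0  # T rms per axis, homogeneous field

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ParameterError("age must be positive")
        for name in ("coupling_frontal", "coupling_occipital"):
            c = getattr(self, name)
            if not -1.0 <= c <= 1.0:
                raise ParameterError(f"{name} must lie in [-1, 1]")


@dataclass
class Recording:
    """Channels x samples field data (tesla) plus task and QC metadata."""

    data: np.ndarray                    # (n_channels, n_samples) tesla
    fs: float
    trial_table: pd.DataFrame           # onset_sample, condition
    array: SensorArray
    bad_channels: set = field(default_factory=set)
    bad_trials: set = field(default_factory=set)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.fs <= 0:
            raise ParameterError("fs must be positive")
        if self.data.ndim != 2:
            raise ParameterError("data must be 2-D (channels x samples)")
        n = self.data.shape[1]
        tl = self.trial_length_samples
        if tl is not None and len(self.trial_table):
            last = int(self.trial_table["onset_sample"].max())
            if last + tl > n:
                raise ParameterError("trial extends beyond recording")
        for idx in self.bad_channels:
            if not 0 <= idx < self.data.shape[0]:
                raise ParameterError("bad channel index out of range")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def trial_length_samples(self) -> int | None:
        if len(self.trial_table) < 2:
            return None
        on = np.sort(self.trial_table["onset_sample"].to_numpy())
        return int(np.min(np.diff(on)))

    def good_channel_indices(self) -> np.ndarray:
        return np.array([i for i in range(self.n_channels)
                         if i not in self.bad_channels], dtype=int)

    def good_trial_indices(self) -> np.ndarray:
        return np.array([i for i in range(len(self.trial_table))
                         if i not in self.bad_trials], dtype=int)

    def copy(self) -> "Recording":
        return Recording(self.data.copy(), self.fs,
                         self.trial_table.copy(), self.array,
                         set(self.bad_channels), set(self.bad_trials))


@dataclass
class GroundTruth:
    """Planted structure recorded alongside each simulated participant."""

    burst_binary: np.ndarray            # (n_samples,) bool, at recording fs
    burst_timecourse: np.ndarray        # (n_samples,) unit-RMS source signal
    burst_location: np.ndarray          # (3,) m
    source_locations: dict              # kind -> (n, 3) array
    coupling_frontal: float
    coupling_occipital: float
    frontal_parcels: np.ndarray
    occipital_parcels: np.ndarray
    age_slopes: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# burst train
# ---------------------------------------------------------------------------

def _phase_regimes(trial_table: pd.DataFrame, window: tuple,
                   fs: float, n_samples: int) -> np.ndarray:
    """Boolean mask, True where t (relative to nearest onset) is in window."""
    mask = np.zeros(n_samples, dtype=bool)
    for onset in trial_table["onset_sample"].to_numpy():
        lo = int(onset + round(window[0] * fs))
        hi = int(onset + round(window[1] * fs))
        mask[max(lo, 0):min(hi, n_samples)] = True
    return mask


def _markov_chain(entry: np.ndarray, exit_: np.ndarray, p0: float,
                  rng: np.random.Generator) -> np.ndarray:
    n = entry.size
    u = rng.random(n)
    state = np.zeros(n, dtype=bool)
    cur = u[0] < p0
    state[0] = cur
    for t in range(1, n):
        cur = (u[t] < entry[t]) if not cur else (u[t] >= exit_[t])
        state[t] = cur
    return state


def _narrowband(rng: np.random.Generator, n: int, fs: float,
                lo: float, hi: float) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise."""
    lo = max(lo, 0.1)
    hi = min(hi, 0.98 * fs / 2.0)
    b, a = sps.butter(4, (lo / (fs / 2.0), hi / (fs / 2.0)), btype="band")
    x = sps.filtfilt(b, a, rng.standard_normal(n))
    return x / x.std()


def _tukey_gate(state: np.ndarray, alpha: float) -> np.ndarray:
    """Smooth 0/1 gate: a Tukey window over every ON segment."""
    gate = np.zeros(state.size)
    edges = np.flatnonzero(np.diff(np.concatenate(
        [[0], state.view(np.int8), [0]])))
    for lo, hi in zip(edges[::2], edges[1::2]):
        gate[lo:hi] = sps.windows.tukey(hi - lo, alpha=alpha)
    return gate


def simulate_burst_train(spec: BurstProcessSpec, trial_table: pd.DataFrame,
                         fs: float, n_samples: int, seed: int,
                         modulation_window: tuple = (0.0, 0.8)
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Simulate the on/off burst chain and its pan-spectral waveform.

    Returns ``(burst_binary, timecourse)``.  The waveform is a sum of
    ``carrier_weights``-weighted narrowband stochastic carriers centred on
    ``carrier_freqs`` (unit total RMS), Tukey-gated so it is non-zero only
    during ON segments.
    """
    rng = np.random.default_rng(seed)
    stim_mask = _phase_regimes(trial_table, modulation_window, fs, n_samples)

    t_stim = spec.transition_matrix(spec.p_stim, fs)
    t_base = spec.transition_matrix(spec.p_base, fs)
    entry = np.where(stim_mask, t_stim[0, 1], t_base[0, 1])
    exit_ = np.where(stim_mask, t_stim[1, 0], t_base[1, 0])
    p0 = spec.p_stim if stim_mask[0] else spec.p_base
    state = _markov_chain(entry, exit_, p0, rng)

    weights = np.asarray(spec.carrier_weights, dtype=float)
    norm = np.sqrt(np.sum(weights ** 2))
    carrier = np.zeros(n_samples)
    if norm > 0 and state.any():
        bw = spec.carrier_bandwidth
        for f, w in zip(spec.carrier_freqs, weights):
            if w > 0:
                carrier += w * _narrowband(rng, n_samples, fs,
                                           f - bw / 2.0, f + bw / 2.0)
        carrier /= norm
    return state, _tukey_gate(state, spec.tukey_alpha) * carrier


def sensorimotor_signal(spec: BurstProcessSpec, trial_table: pd.DataFrame,
                        fs: float, n_samples: int, seed: int,
                        modulation_window: tuple = (0.0, 0.8),
                        mu_occupancy: float = 0.4,
                        mu_duration: float = 0.3,
                        mu_band: tuple = (7.5, 10.5),
                        mu_relative: float = 0.47,
                        noise_relative: float = 0.13
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Composite sensorimotor source: task bursts + mu rhythm + floor.

    Besides the task-modulated pan-spectral bursts the source carries a
    task-independent bursting mu/alpha rhythm (its own on/off chain, no
    stimulus modulation — alpha content is age- and task-stable here) and a
    small stochastic floor.  Amplitudes are relative to the unit-RMS burst
    waveform.  Returns ``(burst_binary, signal)``.
    """
    rng = np.random.default_rng(seed)
    sub = rng.integers(2 ** 31, size=3)
    burst_binary, burst_tc = simulate_burst_train(
        spec, trial_table, fs, n_samples, seed=int(sub[0]),
        modulation_window=modulation_window)

    rng_mu = np.random.default_rng(int(sub[1]))
    q = min(1.0, 1.0 / (mu_duration * fs))
    e = min(1.0, mu_occupancy * q / (1.0 - mu_occupancy))
    mu_state = _markov_chain(np.full(n_samples, e), np.full(n_samples, q),
                             mu_occupancy, rng_mu)
    mu_tc = _tukey_gate(mu_state, 0.4) * _narrowband(
        rng_mu, n_samples, fs, mu_band[0], mu_band[1])

    rng_fl = np.random.default_rng(int(sub[2]))
    signal = (burst_tc + mu_relative * mu_tc
              + noise_relative * rng_fl.standard_normal(n_samples))
    return burst_binary, signal


# ---------------------------------------------------------------------------
# auxiliary source signals
# ---------------------------------------------------------------------------

def _one_over_f(n: int, fs: float, rng: np.random.Generator,
                f_floor: float = 1.0) -> np.ndarray:
    """Unit-variance noise with amplitude spectrum ~ 1/f above f_floor."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    gain = 1.0 / np.maximum(f, f_floor)
    gain[0] = 0.0
    x = np.fft.irfft(spec * gain, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _slow_gaussian(n: int, fs: float, rng: np.random.Generator,
                   cutoff: float = 1.0) -> np.ndarray:
    """Unit-variance Gaussian process low-passed below ``cutoff`` Hz."""
    b, a = sps.butter(2, cutoff / (fs / 2.0), btype="low")
    x = sps.filtfilt(b, a, rng.standard_normal(n))
    return (x - x.mean()) / x.std()


def _drifting_carrier(n: int, fs: float, rng: np.random.Generator,
                      f0: float = 21.0, jitter: float = 1.5) -> np.ndarray:
    """Unit-envelope beta carrier: sinusoid with slowly drifting frequency.

    A phase-continuous cos with instantaneous frequency f0 + (slow jitter)
    stays spectrally tight inside the beta band, so band-pass filtering
    barely perturbs its (identically unit) envelope — planted envelope
    correlations survive the analysis chain almost unattenuated.
    """
    df = jitter * _slow_gaussian(n, fs, rng, cutoff=0.5)
    phase = 2.0 * np.pi * np.cumsum(f0 + df) / fs \
        + rng.uniform(0.0, 2.0 * np.pi)
    return np.cos(phase)


def envelope_coupled_signals(n_signals: int, coupling: float, n_samples: int,
                             fs: float, seed: int,
                             f0: float = 21.0,
                             depth: float = 0.35) -> np.ndarray:
    """Beta-band signals whose slow amplitude envelopes share correlation.

    Each signal is ``(1 + depth * z_i) * carrier_i`` where the carriers are
    independent unit-envelope beta processes and the slow modulators ``z_i``
    mix a common factor with an independent one so that every pairwise
    envelope correlation equals ``coupling``.
    """
    if not 0.0 <= coupling <= 1.0:
        raise ParameterError("coupling must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    shared = _slow_gaussian(n_samples, fs, rng)
    out = np.empty((n_signals, n_samples))
    for i in range(n_signals):
        own = _slow_gaussian(n_samples, fs, rng)
        z = np.sqrt(coupling) * shared + np.sqrt(1.0 - coupling) * own
        env = np.clip(1.0 + depth * z, 0.05, None)
        out[i] = env * _drifting_carrier(n_samples, fs, rng, f0=f0)
    return out


def _evoked_kernel(fs: float, trial_samples: int,
                   peak: float = 0.05, width: float = 0.02,
                   f0: float = 20.0) -> np.ndarray:
    """Biphasic Gaussian-windowed wave peaking ``peak`` s after onset."""
    t = np.arange(trial_samples) / fs
    return np.cos(2.0 * np.pi * f0 * (t - peak)) * np.exp(
        -0.5 * ((t - peak) / (width / 2.0)) ** 2)


# ---------------------------------------------------------------------------
# participant simulation
# ---------------------------------------------------------------------------

_SM_DIRECTION = np.array([-0.45, 0.15, 0.85])  # left sensorimotor, unit-ish


def sensorimotor_location(head_radius: float) -> np.ndarray:
    """Planted burst/evoked source location (left sensorimotor cortex)."""
    u = _SM_DIRECTION / np.linalg.norm(_SM_DIRECTION)
    return 0.75 * head_radius * u


def simulate_participant(p: ParticipantSpec, array: SensorArray,
                         protocol: Protocol,
                         parcellation=None) -> tuple[Recording, GroundTruth]:
    """Render one participant's multichannel recording plus ground truth.

    ``parcellation`` (from :mod:`opmbeta.connectivity`) supplies the network
    source geometry; when omitted a template scaled to the participant's
    head is built.
    """
    from .connectivity import template_parcellation  # local: avoid cycle

    rng = np.random.default_rng(p.seed)
    head = HeadModel(sphere_radius=p.head_radius)
    if parcellation is None:
        parcellation = template_parcellation(p.head_radius)
    table = protocol.trial_table()
    fs, n = protocol.fs, protocol.n_samples
    data = np.zeros((array.n_channels, n))

    # --- sensorimotor source: task bursts + mu rhythm --------------------
    loc_sm = sensorimotor_location(p.head_radius)
    burst_binary, burst_tc = sensorimotor_signal(
        p.burst_spec, table, fs, n,
        seed=int(rng.integers(2 ** 31)),
        modulation_window=protocol.modulation_window)

    # --- evoked component, same region, other tangential orientation ----
    kernel = _evoked_kernel(fs, protocol.samples_per_trial)
    evoked_tc = np.zeros(n)
    for onset in table["onset_sample"].to_numpy():
        hi = min(onset + kernel.size, n)
        evoked_tc[onset:hi] += kernel[:hi - onset]

    # --- network sources at parcel centroids ---------------------------
    centroids = parcellation.centroids
    frontal = np.flatnonzero(parcellation.lobes == "frontal")
    occipital = np.flatnonzero(parcellation.lobes == "occipital")
    network = np.zeros((centroids.shape[0], n))
    if p.network_amplitude > 0:
        network[frontal] = envelope_coupled_signals(
            frontal.size, p.coupling_frontal, n, fs,
            seed=int(rng.integers(2 ** 31)))
        network[occipital] = envelope_coupled_signals(
            occipital.size, p.coupling_occipital, n, fs,
            seed=int(rng.integers(2 ** 31)))
        others = np.setdiff1d(np.arange(centroids.shape[0]),
                              np.concatenate([frontal, occipital]))
        network[others] = envelope_coupled_signals(
            others.size, 0.0, n, fs, seed=int(rng.integers(2 ** 31)))

    # --- background 1/f sources -----------------------------------------
    bg_locs = np.empty((0, 3))
    if p.n_background > 0 and p.background_amplitude > 0:
        u = rng.standard_normal((p.n_background, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        bg_locs = u * (0.3 + 0.4 * rng.random((p.n_background, 1))) \
            * p.head_radius

    # --- project all dipolar sources through the forward model -----------
    def _random_tangential() -> np.ndarray:
        c = rng.standard_normal(2)
        return c / np.linalg.norm(c)

    # (location, coefficients in the local tangential 2-basis, time course)
    sources: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    if p.burst_amplitude > 0:
        sources.append((loc_sm, np.array([1.0, 0.0]),
                        p.burst_amplitude * burst_tc))
    if p.evoked_amplitude > 0:
        # second tangential direction: orthogonal to the burst dipole
        sources.append((loc_sm, np.array([0.0, 1.0]),
                        p.evoked_amplitude * evoked_tc))
    if p.network_amplitude > 0:
        for i in range(centroids.shape[0]):
            sources.append((centroids[i], _random_tangential(),
                            p.network_amplitude * network[i]))
    for i in range(bg_locs.shape[0]):
        sources.append((bg_locs[i], _random_tangential(),
                        p.background_amplitude * _one_over_f(n, fs, rng)))

    if sources:
        locs = np.array([s[0] for s in sources])
        lf = sarvas_leadfield(head, locs, array)
        for v, (_, coeff, tc) in enumerate(sources):
            data += np.outer(lf.fields[v] @ coeff, tc)

    # --- sensor noise and homogeneous interference -----------------------
    if p.noise_floor > 0:
        sigma = p.noise_floor * 1e-15 * np.sqrt(fs / 2.0)
        data += sigma * rng.standard_normal(data.shape)
    if p.interference_amplitude > 0:
        bfield = np.vstack([_one_over_f(n, fs, rng) for _ in range(3)])
        bfield *= p.interference_amplitude
        data += array.channel_orientations @ bfield

    rec = Recording(data, fs, table, array)
    gt = GroundTruth(
        burst_binary=burst_binary, burst_timecourse=burst_tc,
        burst_location=loc_sm,
        source_locations={"burst": loc_sm[None, :],
                          "network": centroids.copy(),
                          "background": bg_locs},
        coupling_frontal=p.coupling_frontal,
        coupling_occipital=p.coupling_occipital,
        frontal_parcels=frontal, occipital_parcels=occipital)
    return rec, gt


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AgeEffectSlopes:
    """Linear age trends planted in the cohort (per-year units).

    Defaults express the qualitative findings under study: burst-probability
    modulation, beta/gamma burst content, and frontal envelope coupling all
    increase with age; the low-frequency carrier and occipital coupling do
    not.  Intercepts are anchored at age 2.
    """

    p_base: float = 0.5
    p_stim_at_2: float = 0.45
    p_stim_per_year: float = -0.009
    low_weight_at_2: float = 1.2
    low_weight_per_year: float = -0.02
    alpha_weight: float = 0.6
    beta_weight_at_2: float = 0.35
    beta_weight_per_year: float = 0.015
    gamma_weight_at_2: float = 0.10
    gamma_weight_per_year: float = 0.008
    coupling_frontal_at_2: float = 0.15
    coupling_frontal_per_year: float = 0.009
    coupling_occipital: float = 0.25
    evoked_at_2: float = 8e-9
    evoked_per_year: float = 0.1e-9

    @classmethod
    def null(cls) -> "AgeEffectSlopes":
        """No planted age effects (all per-year slopes zero)."""
        mid = cls()
        return cls(p_stim_per_year=0.0, low_weight_per_year=0.0,
                   beta_weight_per_year=0.0, gamma_weight_per_year=0.0,
                   coupling_frontal_per_year=0.0, evoked_per_year=0.0,
                   p_stim_at_2=mid.p_stim_at_2 + 14 * mid.p_stim_per_year,
                   low_weight_at_2=mid.low_weight_at_2
                   + 14 * mid.low_weight_per_year,
                   beta_weight_at_2=mid.beta_weight_at_2
                   + 14 * mid.beta_weight_per_year,
                   gamma_weight_at_2=mid.gamma_weight_at_2
                   + 14 * mid.gamma_weight_per_year,
                   coupling_frontal_at_2=mid.coupling_frontal_at_2
                   + 14 * mid.coupling_frontal_per_year,
                   evoked_at_2=mid.evoked_at_2 + 14 * mid.evoked_per_year)

    def participant_spec(self, age: float, seed: int, group: str,
                         participant_id: str, **overrides) -> ParticipantSpec:
        dy = age - 2.0
        burst = BurstProcessSpec(
            p_stim=float(np.clip(self.p_stim_at_2
                                 + dy * self.p_stim_per_year, 0.0, 1.0)),
            p_base=self.p_base,
            carrier_weights=(
                max(0.0, self.low_weight_at_2 + dy * self.low_weight_per_year),
                self.alpha_weight,
                max(0.0, self.beta_weight_at_2 + dy * self.beta_weight_per_year),
                max(0.0, self.gamma_weight_at_2 + dy * self.gamma_weight_per_year),
            ))
        return ParticipantSpec(
            age=age, head_radius=head_radius_for_age(age), burst_spec=burst,
            seed=seed, group=group, participant_id=participant_id,
            evoked_amplitude=self.evoked_at_2 + dy * self.evoked_per_year,
            coupling_frontal=float(np.clip(
                self.coupling_frontal_at_2
                + dy * self.coupling_frontal_per_year, 0.0, 0.95)),
            coupling_occipital=self.coupling_occipital,
            **overrides)


def _participant_seed(root: int, index: int) -> int:
    ss = np.random.SeedSequence(entropy=root, spawn_key=(index,))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


def make_cohort_specs(n_children: int = 27, n_adults: int = 26,
                      slopes: AgeEffectSlopes | None = None,
                      seed: int = 0, **overrides) -> list:
    """Draw participant specs: children uniform 2-13 y, adults 21-34 y."""
    if n_children < 0 or n_adults < 0:
        raise ParameterError("cohort counts must be non-negative")
    slopes = slopes or AgeEffectSlopes()
    rng = np.random.default_rng(seed)
    ages = np.concatenate([rng.uniform(2.0, 13.0, size=n_children),
                           rng.uniform(21.0, 34.0, size=n_adults)])
    groups = ["child"] * n_children + ["adult"] * n_adults
    return [slopes.participant_spec(
                float(ages[i]), _participant_seed(seed, i), groups[i],
                participant_id=f"p{i:03d}", **overrides)
            for i in range(n_children + n_adults)]


def iter_cohort(n_children: int = 27, n_adults: int = 26,
                slopes: AgeEffectSlopes | None = None, seed: int = 0,
                protocol: Protocol | None = None,
                n_sensors: int = 64, scalp_offset: float = 0.01,
                **overrides):
    """Yield ``(ParticipantSpec, Recording, GroundTruth)`` lazily.

    Each participant gets an array fitted to their own head radius (the
    adaptable-helmet property of OPM arrays).
    """
    protocol = protocol or Protocol()
    slopes = slopes or AgeEffectSlopes()
    specs = make_cohort_specs(n_children, n_adults, slopes, seed, **overrides)
    for spec in specs:
        array = make_sensor_array(n_sensors, head_radius=spec.head_radius,
                                  scalp_offset=scalp_offset, seed=spec.seed)
        rec, gt = simulate_participant(spec, array, protocol)
        gt.age_slopes = {
            "p_stim_per_year": slopes.p_stim_per_year,
            "coupling_frontal_per_year": slopes.coupling_frontal_per_year,
            "beta_weight_per_year": slopes.beta_weight_per_year,
        }
        yield spec, rec, gt


def make_cohort(n_children: int = 27, n_adults: int = 26,
                slopes: AgeEffectSlopes | None = None, seed: int = 0,
                **kwargs) -> list:
    """Materialised cohort; see :func:`iter_cohort`."""
    return list(iter_cohort(n_children, n_adults, slopes, seed, **kwargs))
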