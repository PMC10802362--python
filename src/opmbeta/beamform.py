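"""LCMV beamforming: covariance, weights, pseudo-T imaging, virtual electrodes.

The scalar linearly-constrained minimum-variance (LCMV) beamformer passes a
unit-gain constraint at the target location while minimising output
variance.  Source orientation is chosen per voxel in the tangential plane
to maximise projected power (the 2x2 reduced eigenproblem).  Task contrast
images are pseudo-T maps of beta-band power between active and control
windows; the time course at a chosen voxel is a "virtual electrode".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .forward import LeadField, sarvas_leadfield
from .geometry import HeadModel
from .synthcohort import Recording

__all__ = [
    "CovarianceMatrix", "BeamformerWeights", "PseudoTImage",
    "VirtualElectrode", "source_grid", "compute_covariance", "regularize",
    "lcmv_weights", "pseudo_t_map", "peak_voxel", "extract_virtual_electrode",
]


class BeamformerError(RuntimeError):
    """Numerical failure in the spatial filter."""


@dataclass(frozen=True)
class CovarianceMatrix:
    matrix: np.ndarray                  # (n_ch, n_ch) tesla^2
    band: tuple                         # Hz
    n_samples_used: int
    good_channels: np.ndarray
    regularization_fraction: float = 0.0

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if not np.allclose(m, m.T, atol=1e-12 * max(1.0, np.abs(m).max())):
            raise BeamformerError("covariance matrix is not symmetric")
        object.__setattr__(self, "matrix", 0.5 * (m + m.T))


@dataclass(frozen=True)
class BeamformerWeights:
    weights: np.ndarray                 # (n_voxels, n_good_channels)
    orientations: np.ndarray            # (n_voxels, 3) unit source directions
    grid: np.ndarray                    # (n_voxels, 3) m
    spacing: float                      # m
    good_channels: np.ndarray
    band: tuple
    condition_number: float

    @property
    def n_voxels(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class PseudoTImage:
    grid: np.ndarray                    # (n_voxels, 3) m
    spacing: float                      # m
    values: np.ndarray                  # (n_voxels,), dimensionless

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise BeamformerError("pseudo-T image contains non-finite values")


@dataclass(frozen=True)
class VirtualElectrode:
    timecourse: np.ndarray              # (n_samples,), source units (A m)
    fs: float
    location: np.ndarray                # (3,) m
    voxel_index: int
    band: tuple


# ---------------------------------------------------------------------------

def source_grid(head: HeadModel, spacing: float = 0.008,
                radius_fraction: float = 0.85) -> np.ndarray:
    """Cubic lattice of candidate source locations inside the conductor.

    ``radius_fraction`` keeps voxels away from the conductor surface (a
    crude cortex/skull margin).
    """
    if spacing <= 0:
        raise ValueError("grid spacing must be positive")
    rmax = radius_fraction * head.sphere_radius
    ax = np.arange(-rmax, rmax + spacing / 2, spacing)
    xx, yy, zz = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    pts = pts[np.linalg.norm(pts, axis=1) <= rmax]
    return pts + head.sphere_origin


def _good_trial_samples(rec: Recording) -> np.ndarray:
    tl = rec.trial_length_samples or rec.n_samples
    idx = []
    for i in rec.good_trial_indices():
        onset = int(rec.trial_table["onset_sample"].iloc[i])
        idx.append(np.arange(onset, min(onset + tl, rec.n_samples)))
    return np.concatenate(idx) if idx else np.arange(rec.n_samples)


def bandpass(data: np.ndarray, band: tuple, fs: float,
             order: int = 4) -> np.ndarray:
    sos = sps.butter(order, [band[0] / (fs / 2), band[1] / (fs / 2)],
                     btype="band", output="sos")
    return sps.sosfiltfilt(sos, data, axis=-1)


def compute_covariance(rec: Recording, band: tuple) -> CovarianceMatrix:
    """Sample covariance of band-filtered data over good channels/trials."""
    good = rec.good_channel_indices()
    if good.size < 10:
        raise BeamformerError("need at least 10 good channels")
    samples = _good_trial_samples(rec)
    data = bandpass(rec.data[good], band, rec.fs)[:, samples]
    if data.shape[1] < data.shape[0]:
        warnings.warn("fewer samples than channels: covariance rank-deficient")
    cov = np.cov(data, ddof=1)
    return CovarianceMatrix(cov, band, data.shape[1], good)


def regularize(cov: CovarianceMatrix,
               fraction: float = 0.05) -> CovarianceMatrix:
    """Tikhonov regularisation: add ``fraction`` of the largest eigenvalue."""
    if fraction < 0:
        raise ValueError("regularization fraction must be >= 0")
    if fraction == 0:
        return cov
    lam_max = float(np.linalg.eigvalsh(cov.matrix)[-1])
    mat = cov.matrix + fraction * lam_max * np.eye(cov.matrix.shape[0])
    return CovarianceMatrix(mat, cov.band, cov.n_samples_used,
                            cov.good_channels, fraction)


def _inverse_via_eigh(mat: np.ndarray) -> tuple[np.ndarray, float]:
    vals, vecs = np.linalg.eigh(0.5 * (mat + mat.T))
    if vals[0] <= 0 or vals[-1] / vals[0] > 1e12:
        raise BeamformerError(
            f"covariance numerically singular (cond={vals[-1] / vals[0]:.3g})")
    inv = (vecs / vals) @ vecs.T
    return 0.5 * (inv + inv.T), float(vals[-1] / vals[0])


def lcmv_weights(lead: LeadField, cov: CovarianceMatrix,
                 spacing: float = 0.0) -> BeamformerWeights:
    """Unit-gain LCMV weights with power-maximising scalar orientation.

    Per voxel the source orientation u (in the tangential 2-basis) minimises
    l(u)^T C^-1 l(u) — equivalently maximises projected power 1/(l^T C^-1 l)
    — and the weight vector is w = C^-1 l / (l^T C^-1 l), so w^T l = 1.
    """
    ci, cond = _inverse_via_eigh(cov.matrix)
    fields = lead.fields                              # (nv, nch, 2)
    a = np.einsum("vci,cd,vdj->vij", fields, ci, fields)  # (nv, 2, 2)

    # closed-form smallest eigenvector of each symmetric 2x2 block
    p, q, r = a[:, 0, 0], a[:, 0, 1], a[:, 1, 1]
    disc = np.sqrt(((p - r) / 2) ** 2 + q ** 2)
    lam_min = (p + r) / 2 - disc
    u = np.column_stack([q, lam_min - p])
    # fall back to the dominant diagonal direction when q ~ 0
    degen = np.linalg.norm(u, axis=1) < 1e-30 * np.maximum(p, r)
    u[degen] = np.where((p < r)[degen, None],
                        np.array([1.0, 0.0]), np.array([0.0, 1.0]))
    u /= np.linalg.norm(u, axis=1, keepdims=True)

    l_or = np.einsum("vci,vi->vc", fields, u)         # oriented lead fields
    ci_l = l_or @ ci
    denom = np.einsum("vc,vc->v", l_or, ci_l)
    if np.any(denom <= 0):
        raise BeamformerError("non-positive projected power denominator")
    w = ci_l / denom[:, None]
    ori = np.einsum("vic,vi->vc", lead.basis, u)
    return BeamformerWeights(w, ori, lead.source_locations, spacing,
                             cov.good_channels, cov.band, cond)


def _window_samples(window: tuple, fs: float, trial_len: int) -> np.ndarray:
    lo = int(round(window[0] * fs))
    hi = int(round(window[1] * fs))
    if hi <= lo or hi > trial_len:
        raise ValueError(f"window {window} empty or outside trial")
    return np.arange(lo, hi)


def pseudo_t_map(w: BeamformerWeights, rec: Recording,
                 active_window: tuple = (0.3, 0.8),
                 control_window: tuple = (2.5, 3.0),
                 condition: str | None = None,
                 normalization: str = "sum",
                 chunk_elems: int = 20_000_000) -> PseudoTImage:
    """Voxelwise task-contrast of projected power.

    Power is the trial-averaged variance of the beamformer-projected time
    course in each window.  ``normalization="sum"`` gives
    (Pa - Pc)/(Pa + Pc); ``"noise"`` gives (Pa - Pc)/(2 Pn) with Pn the
    projected sensor-noise power (smallest covariance eigenvalue * |w|^2).
    """
    good = w.good_channels
    tl = rec.trial_length_samples or rec.n_samples
    act = _window_samples(active_window, rec.fs, tl)
    ctl = _window_samples(control_window, rec.fs, tl)

    trials = rec.good_trial_indices()
    onsets = rec.trial_table["onset_sample"].to_numpy()
    if condition is not None:
        conds = rec.trial_table["condition"].to_numpy()
        trials = np.array([i for i in trials if conds[i] == condition])
    act_idx = np.concatenate([onsets[i] + act for i in trials])
    ctl_idx = np.concatenate([onsets[i] + ctl for i in trials])

    data = rec.data[good]
    nv = w.n_voxels
    chunk = max(1, chunk_elems // max(1, data.shape[1]))
    p_act = np.empty(nv)
    p_ctl = np.empty(nv)
    for lo in range(0, nv, chunk):
        hi = min(lo + chunk, nv)
        proj = w.weights[lo:hi] @ data
        p_act[lo:hi] = proj[:, act_idx].var(axis=1)
        p_ctl[lo:hi] = proj[:, ctl_idx].var(axis=1)

    if normalization == "sum":
        values = (p_act - p_ctl) / (p_act + p_ctl)
    elif normalization == "noise":
        sigma2 = float(np.linalg.eigvalsh(np.cov(data, ddof=1))[0])
        p_noise = sigma2 * np.einsum("vc,vc->v", w.weights, w.weights)
        values = (p_act - p_ctl) / (2.0 * p_noise)
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    return PseudoTImage(w.grid, w.spacing, values)


def peak_voxel(image: PseudoTImage, mode: str = "min") -> int:
    """Index of the extremal voxel (ties -> lowest linear index).

    ``mode="min"`` picks the strongest desynchronisation (most negative
    pseudo-T), the convention for beta-band task contrast.
    """
    vals = image.values
    return int(np.argmin(vals) if mode == "min" else np.argmax(vals))


def extract_virtual_electrode(w: BeamformerWeights, rec: Recording,
                              voxel: int) -> VirtualElectrode:
    """Beamformer-projected time course at one voxel (unit source gain)."""
    if not 0 <= voxel < w.n_voxels:
        raise ValueError("voxel index outside grid")
    tc = w.weights[voxel] @ rec.data[w.good_channels]
    return VirtualElectrode(tc, rec.fs, w.grid[voxel], voxel, w.band)


def localize_and_extract(rec: Recording, head: HeadModel,
                         beta_band: tuple = (13.0, 30.0),
                         broad_band: tuple = (1.0, 48.0),
                         spacing: float = 0.008,
                         active_window: tuple = (0.3, 0.8),
                         control_window: tuple = (2.5, 3.0),
                         reg_fraction: float = 0.05):
    """Full localisation stage: pseudo-T image + broadband virtual electrode.

    Beta-band covariance drives the task-contrast image; the virtual
    electrode at the desynchronisation peak is extracted with broadband
    weights, as required for downstream burst analysis.

    Returns ``(image, ve, weights_broad)``.
    """
    grid = source_grid(head, spacing)
    lead = sarvas_leadfield(head, grid, rec.array)
    lead = LeadField(lead.source_locations, lead.basis,
                     lead.fields[:, rec.good_channel_indices(), :])

    cov_beta = regularize(compute_covariance(rec, beta_band), reg_fraction)
    w_beta = lcmv_weights(lead, cov_beta, spacing)
    rec_beta = rec.copy()
    rec_beta.data = bandpass(rec.data, beta_band, rec.fs)
    image = pseudo_t_map(w_beta, rec_beta, active_window, control_window)
    peak = peak_voxel(image, mode="min")

    # broadband weights only at the peak voxel (the virtual electrode)
    lead_peak = LeadField(lead.source_locations[[peak]],
                          lead.basis[[peak]], lead.fields[[peak]])
    cov_broad = regularize(compute_covariance(rec, broad_band), reg_fraction)
    w_broad = lcmv_weights(lead_peak, cov_broad, spacing)
    rec_broad = rec.copy()
    rec_broad.data = bandpass(rec.data, broad_band, rec.fs)
    ve = extract_virtual_electrode(w_broad, rec_broad, 0)
    ve = VirtualElectrode(ve.timecourse, ve.fs, w_broad.grid[0], peak,
                          broad_band)
    return image, ve, w_broad
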