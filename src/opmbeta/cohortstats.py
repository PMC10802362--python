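"""Cohort-level statistics and end-to-end pipeline orchestration.

Per-participant metrics (beta modulation index, M50 amplitude, burst
probability modulation, global connectivity, per-parcel node degree) are
assembled into a cohort table and regressed against age with Pearson
correlation (two-sided p from the t-distribution with n-2 df).  The
orchestrator is a pure function of (configuration, seed): rerunning with
the same inputs reproduces the cohort table bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import beamform, bursthmm, connectivity, spectral
from .geometry import HeadModel
from .preprocess import PreprocConfig, run_preprocessing
from .synthcohort import AgeEffectSlopes, Protocol, iter_cohort

__all__ = ["CorrelationResult", "AnalysisConfig", "StudyConfig",
           "pearson_fit", "zscore_within_group", "age_group_split",
           "degree_age_gradient", "analyze_participant", "run_pipeline"]


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    slope: float
    intercept: float
    n: int

    @property
    def r2(self) -> float:
        return self.r ** 2

    def to_dict(self) -> dict:
        return {"r": self.r, "r2": self.r2, "p": self.p,
                "slope": self.slope, "intercept": self.intercept,
                "n": self.n}


def pearson_fit(x, y) -> CorrelationResult:
    """Pearson correlation with least-squares line and two-sided p-value.

    Pairs with missing (NaN) values are excluded; the reported ``n`` is the
    number of complete pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input to correlation")
    fit = stats.linregress(x, y)
    return CorrelationResult(r=float(fit.rvalue), p=float(fit.pvalue),
                             slope=float(fit.slope),
                             intercept=float(fit.intercept), n=int(x.size))


def zscore_within_group(values, group_labels) -> np.ndarray:
    """Z-transform within each group (sample SD, ddof=1).

    Used to pool children and adults on one axis while removing the
    between-group age confound.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(group_labels)
    out = np.empty_like(values)
    for g in np.unique(groups):
        sel = groups == g
        if sel.sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 members")
        sd = values[sel].std(ddof=1)
        if sd == 0:
            raise ValueError(f"zero within-group SD in group {g!r}")
        out[sel] = (values[sel] - values[sel].mean()) / sd
    return out


def age_group_split(children: pd.DataFrame, age_col: str = "age",
                    id_col: str = "participant_id") -> list:
    """Age-sorted tertile split of the child group.

    With a count not divisible by three the remainder goes to the oldest
    group (with a warning).  Ties in age break deterministically by id.
    """
    n = len(children)
    if n < 3:
        raise ValueError("need at least 3 children to split")
    if n % 3:
        warnings.warn("child count not divisible by 3; remainder joins the "
                      "oldest group")
    ordered = children.sort_values([age_col, id_col], kind="mergesort")
    base = n // 3
    bounds = [0, base, 2 * base, n]
    return [ordered.iloc[bounds[i]:bounds[i + 1]] for i in range(3)]


def degree_age_gradient(cohort: pd.DataFrame,
                        degree_prefix: str = "degree_") -> pd.DataFrame:
    """Per-parcel linear fit of node degree against age."""
    cols = [c for c in cohort.columns if c.startswith(degree_prefix)]
    if not cols:
        raise ValueError("no node-degree columns in cohort table")
    rows = []
    for c in cols:
        res = pearson_fit(cohort["age"], cohort[c])
        rows.append({"parcel": c[len(degree_prefix):], "slope": res.slope,
                     "r2": res.r2, "p": res.p, "n": res.n})
    return pd.DataFrame(rows).set_index("parcel")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnalysisConfig:
    """Analysis-stage parameters (bands in Hz, windows in s, grid in m)."""

    beta_band: tuple = (13.0, 30.0)
    broad_band: tuple = (1.0, 48.0)
    active_window: tuple = (0.3, 0.8)
    control_window: tuple = (2.5, 3.0)
    post_window: tuple = (1.0, 1.5)
    grid_spacing: float = 0.008
    reg_fraction: float = 0.05
    hmm_fs: float = 100.0
    hmm_states: int = 3
    hmm_restarts: int = 5
    hmm_max_iter: int = 500
    hmm_tol: float = 1e-6
    aec_decimate: int = 1


@dataclass(frozen=True)
class StudyConfig:
    """Full study description: cohort generation plus analysis parameters."""

    n_children: int = 27
    n_adults: int = 26
    seed: int = 0
    n_sensors: int = 64
    fs: float = 1200.0
    band: tuple = (1.0, 150.0)
    slopes: AgeEffectSlopes = field(default_factory=AgeEffectSlopes)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    participant_overrides: dict = field(default_factory=dict)

    @classmethod
    def desk_scale(cls, **kwargs) -> "StudyConfig":
        """Reduced problem size for interactive use and routine testing.

        Lower sampling rate, a 14-sensor (42-channel) array, a 16 mm
        localisation grid, 2 EM restarts and decimated AEC envelopes keep a
        full 53-participant cohort tractable on one CPU core; the task
        structure (84 x 3.5 s trials) is unchanged.
        """
        defaults = dict(
            fs=200.0, n_sensors=14, band=(1.0, 90.0),
            analysis=AnalysisConfig(grid_spacing=0.016, hmm_restarts=2,
                                    hmm_max_iter=100, hmm_tol=1e-5,
                                    aec_decimate=2))
        defaults.update(kwargs)
        return cls(**defaults)

    def protocol(self) -> Protocol:
        return Protocol(fs=self.fs)

    def preproc(self) -> PreprocConfig:
        return PreprocConfig(band=self.band)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        if "slopes" in d and isinstance(d["slopes"], dict):
            d["slopes"] = AgeEffectSlopes(**d["slopes"])
        if "analysis" in d and isinstance(d["analysis"], dict):
            d["analysis"] = AnalysisConfig(
                **{k: tuple(v) if isinstance(v, list) else v
                   for k, v in d["analysis"].items()})
        if isinstance(d.get("band"), list):
            d["band"] = tuple(d["band"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# per-participant analysis
# ---------------------------------------------------------------------------

def parcel_weights(rec, head: HeadModel, parcellation,
                   band: tuple = (13.0, 30.0), reg_fraction: float = 0.05):
    """LCMV weights at the parcel centroids (beta-band covariance)."""
    from .forward import LeadField, sarvas_leadfield
    lead = sarvas_leadfield(head, parcellation.centroids, rec.array)
    lead = LeadField(lead.source_locations, lead.basis,
                     lead.fields[:, rec.good_channel_indices(), :])
    cov = beamform.regularize(beamform.compute_covariance(rec, band),
                              reg_fraction)
    return beamform.lcmv_weights(lead, cov)


def analyze_participant(rec, head: HeadModel, cfg: AnalysisConfig,
                        preproc: PreprocConfig, parcellation,
                        hmm_seed: int = 0) -> dict:
    """Run the full single-participant analysis chain.

    Returns a dict with scalar metrics plus the heavier artifacts
    (pseudo-T image, virtual electrode, burst statistics, connectome).
    """
    clean, qc = run_preprocessing(rec, preproc)
    good = clean.good_trial_indices()

    image, ve, _ = beamform.localize_and_extract(
        clean, head, beta_band=cfg.beta_band, broad_band=cfg.broad_band,
        spacing=cfg.grid_spacing, active_window=cfg.active_window,
        control_window=cfg.control_window, reg_fraction=cfg.reg_fraction)

    bmod = spectral.beta_modulation_index(
        ve, clean.trial_table, band=cfg.beta_band, good_trials=good,
        stim_window=cfg.active_window, post_window=cfg.post_window,
        baseline_window=cfg.control_window)
    evoked = spectral.evoked_response(ve, clean.trial_table,
                                      good_trials=good)

    model = bursthmm.TDEHMM.from_virtual_electrode(
        ve, band=cfg.broad_band, fs_target=cfg.hmm_fs,
        n_states=cfg.hmm_states)
    fitres = model.fit(n_restarts=cfg.hmm_restarts, seed=hmm_seed,
                       max_iter=cfg.hmm_max_iter, tol=cfg.hmm_tol)
    hmm_signal = _hmm_signal(ve, cfg)
    bstats = fitres.burst_statistics(
        clean.trial_table, clean.fs, stim_window=cfg.active_window,
        post_window=cfg.post_window, good_trials=good, signal=hmm_signal)
    freqs, psd = bursthmm.state_psd(hmm_signal, fitres.posterior,
                                    bstats.burst_state)

    w_parcel = parcel_weights(clean, head, parcellation,
                              band=cfg.beta_band,
                              reg_fraction=cfg.reg_fraction)
    tcs = connectivity.parcel_time_courses(w_parcel, clean,
                                           band=cfg.beta_band)
    conn = connectivity.connectome(tcs, decimate=cfg.aec_decimate)
    degrees = connectivity.node_degree(conn)

    metrics = {
        "betamod": bmod.betamod,
        "m50_amplitude": evoked.m50_amplitude,
        "m50_latency": evoked.m50_latency,
        "burst_modulation": bstats.modulation,
        "burst_amplitude": bstats.amplitude,
        "global_connectivity": connectivity.global_connectivity(conn),
        "fraction_trials_removed": qc.fraction_trials_removed,
        "n_bad_channels": len(qc.bad_channels),
    }
    for label, deg in zip(parcellation.labels, degrees):
        metrics[f"degree_{label}"] = float(deg)
    artifacts = {"image": image, "ve": ve, "hmm": fitres,
                 "burst_stats": bstats, "connectome": conn,
                 "qc": qc, "state_psd": (freqs, psd)}
    return {"metrics": metrics, "artifacts": artifacts}


def _hmm_signal(ve, cfg: AnalysisConfig) -> np.ndarray:
    from scipy import signal as sps
    factor = int(round(ve.fs / cfg.hmm_fs))
    hi = min(cfg.broad_band[1], 0.95 * cfg.hmm_fs / 2.0)
    sos = sps.butter(4, [cfg.broad_band[0] / (ve.fs / 2), hi / (ve.fs / 2)],
                     btype="band", output="sos")
    return sps.sosfiltfilt(sos, ve.timecourse)[::factor]


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

_CORR_METRICS = ("betamod", "burst_modulation", "global_connectivity",
                 "m50_amplitude")


def run_pipeline(config: StudyConfig, out_dir=None,
                 keep_artifacts: bool = False,
                 save_artifacts: bool = False) -> tuple[pd.DataFrame, dict]:
    """Simulate, preprocess and analyse a whole cohort.

    Returns the cohort table (one row per participant) and a report dict
    with the age correlations and per-parcel degree gradients.  When
    ``out_dir`` is given, writes ``cohort.csv`` and ``report.json``;
    ``save_artifacts`` additionally writes each participant's pseudo-T
    image and virtual electrode (HDF5), connectome and burst raster (CSV)
    under ``out_dir/<participant>/``.
    """
    from .connectivity import template_parcellation

    cfg = config.analysis
    protocol = config.protocol()
    preproc = config.preproc()
    rows = []
    statuses = {}
    artifacts = {} if keep_artifacts else None
    for spec, rec, gt in iter_cohort(
            config.n_children, config.n_adults, config.slopes,
            seed=config.seed, protocol=protocol,
            n_sensors=config.n_sensors, **config.participant_overrides):
        head = HeadModel(sphere_radius=spec.head_radius)
        parcellation = template_parcellation(spec.head_radius)
        row = {"participant_id": spec.participant_id, "age": spec.age,
               "group": spec.group}
        try:
            result = analyze_participant(rec, head, cfg, preproc,
                                         parcellation, hmm_seed=spec.seed)
            row.update(result["metrics"])
            statuses[spec.participant_id] = "ok"
            if keep_artifacts:
                artifacts[spec.participant_id] = result["artifacts"]
            if save_artifacts and out_dir is not None:
                _write_artifacts(result["artifacts"], parcellation,
                                 rec, Path(out_dir) / spec.participant_id)
        except Exception as exc:  # noqa: BLE001 - keep partial cohort
            statuses[spec.participant_id] = f"failed: {exc}"
            warnings.warn(f"{spec.participant_id} failed: {exc}")
        rows.append(row)
    table = pd.DataFrame(rows)

    report: dict = {"statuses": statuses, "correlations": {}}
    for metric in _CORR_METRICS:
        if metric in table and table[metric].notna().sum() >= 3:
            try:
                res = pearson_fit(table["age"], table[metric])
                report["correlations"][f"{metric}_vs_age"] = res.to_dict()
            except ValueError as exc:
                report["correlations"][f"{metric}_vs_age"] = str(exc)
    # beta modulation against burst modulation, z-transformed within the
    # child/adult groups to remove the shared age trend
    ok_rows = table["betamod"].notna() & table["burst_modulation"].notna()
    if ok_rows.sum() >= 6 and table.loc[ok_rows, "group"].nunique() >= 1:
        try:
            sub = table.loc[ok_rows]
            zb = zscore_within_group(sub["betamod"], sub["group"])
            zm = zscore_within_group(sub["burst_modulation"], sub["group"])
            report["correlations"]["betamod_vs_burst_modulation_z"] = \
                pearson_fit(zm, zb).to_dict()
        except ValueError:
            pass
    try:
        grad = degree_age_gradient(table)
        parc = template_parcellation()
        lobe_of = dict(zip(parc.labels, parc.lobes))
        grad["lobe"] = [lobe_of.get(p, "?") for p in grad.index]
        report["degree_gradient"] = {
            lobe: float(grad.loc[grad["lobe"] == lobe, "slope"].mean())
            for lobe in np.unique(grad["lobe"])}
        report["degree_table"] = grad.reset_index().to_dict("records")
    except ValueError:
        pass

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_cohort_csv(table, out / "cohort.csv")
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
    if keep_artifacts:
        report["artifacts"] = artifacts
    return table, report


def _write_artifacts(artifacts: dict, parcellation, rec, out: Path) -> None:
    from . import io as _io
    out.mkdir(parents=True, exist_ok=True)
    _io.save_pseudo_t_image(artifacts["image"], out / "pseudo_t.h5")
    _io.save_virtual_electrode(artifacts["ve"], out / "ve.h5")
    _io.save_connectome(artifacts["connectome"], parcellation.labels,
                        out / "connectome.csv")
    hmm = artifacts["hmm"]
    _io.save_burst_raster(hmm.posterior,
                          artifacts["burst_stats"].burst_state,
                          rec.trial_table, rec.fs, out / "burst_raster.csv")


def write_cohort_csv(table: pd.DataFrame, path) -> None:
    """Deterministic CSV serialisation (fixed float format, LF endings)."""
    table.to_csv(path, index=False, float_format="%.12g",
                 lineterminator="\n")
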