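"""Configuration and end-to-end orchestration of the dual-locked analysis.

``run_pipeline`` executes, for a cohort of (synthetic or file-based)
subjects: high-pass filtering, ocular correction, window-wise BSS-CCA
EMG removal, trial selection, stimulus- and response-locked epoching,
artifact rejection, averaging, CSD transformation, GFP window selection
and slope statistics, peak latency and latency-RT analyses, and the
depth-weighted minimum-norm source estimate with the empirical baseline
null — writing tab-separated result tables, a JSON report and a
manifest (config hash, seed, per-stage counts, output checksums).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import erpstats, inverse as inv_mod, io as sio, preprocess as pre
from .containers import rt_ms
from .csd import SplineConfig, csd_transform
from .emgcca import DEFAULT_RATIO_THRESHOLD, remove_emg
from .headmodel import HeadModel, forward_matrix
from .montage import build_montage
from .synth import (ArtifactSpec, TrialSchedule, default_sources,
                    simulate_recording)

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

logger = logging.getLogger(__name__)


@dataclass
class SynthConfig:
    enabled: bool = True
    n_trials: int = 100
    iti_s: float = 2.5
    rt_mean_ms: float = 651.0
    rt_sd_ms: float = 72.0
    between_subject_rt_sd_ms: float = 30.0
    artifacts: bool = True
    emg_amplitude_uv: float = 50.0
    background_rms_uv: float = 5.0
    write_raw: bool = False


@dataclass
class InputConfig:
    """Per-subject file inputs used when synthesis is disabled."""

    recordings: list = field(default_factory=list)  # EDF paths
    events: list = field(default_factory=list)  # events TSV paths
    montage: str = ""


@dataclass
class PreprocessConfig:
    highpass_hz: float = 0.16
    ptp_limit_uv: float = 150.0
    flat_limit_uv: float = 0.5
    local_z: float = 5.0


@dataclass
class EmgConfig:
    skip_emg_removal: bool = False
    window_s: float = 1.5
    ratio_threshold: float = DEFAULT_RATIO_THRESHOLD


@dataclass
class CsdConfig:
    m: int = 3
    n_max: int = 15
    r_head_cm: float = 10.0
    smoothing: float = 1e-5


@dataclass
class ErpConfig:
    gfp_k: int = 3
    gfp_win_ms: float = 25.0
    smooth_ms: float = 40.0
    ga_window_ms: float = 100.0
    frontomedial_electrodes: list = field(
        default_factory=lambda: ["FCz", "Cz", "FC1", "FC2"])


@dataclass
class InverseConfig:
    n_dipoles: int = 800
    depth_gamma: float = 0.5
    snr: float = 3.0
    alpha: float = 0.001


@dataclass
class PipelineConfig:
    seed: int = 0
    n_subjects: int = 12
    outdir: str = "speecherp_out"
    synth: SynthConfig = field(default_factory=SynthConfig)
    inputs: InputConfig = field(default_factory=InputConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    emg: EmgConfig = field(default_factory=EmgConfig)
    csd: CsdConfig = field(default_factory=CsdConfig)
    erp: ErpConfig = field(default_factory=ErpConfig)
    inverse: InverseConfig = field(default_factory=InverseConfig)

    def validate(self) -> "PipelineConfig":
        checks = [
            (self.n_subjects >= 1, "n_subjects must be >= 1"),
            (self.synth.n_trials >= 1, "synth.n_trials must be >= 1"),
            (0 < self.preprocess.highpass_hz < 256,
             "preprocess.highpass_hz out of range"),
            (self.preprocess.ptp_limit_uv > 0, "ptp_limit_uv must be > 0"),
            (self.emg.window_s > 0, "emg.window_s must be > 0"),
            (self.emg.ratio_threshold > 0, "emg.ratio_threshold must be > 0"),
            (self.csd.m >= 2, "csd.m must be >= 2"),
            (self.csd.n_max >= 1, "csd.n_max must be >= 1"),
            (self.csd.r_head_cm > 0, "csd.r_head_cm must be > 0"),
            (self.inverse.n_dipoles >= 10, "inverse.n_dipoles must be >= 10"),
            (0 < self.inverse.alpha < 0.5, "inverse.alpha must be in (0, 0.5)"),
            (self.erp.gfp_k >= 1, "erp.gfp_k must be >= 1"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"invalid config: {msg}")
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        kw = {}
        for f in dataclasses.fields(cls):
            if f.name not in d:
                continue
            v = d.pop(f.name)
            if dataclasses.is_dataclass(f.type) or f.name in (
                "synth", "inputs", "preprocess", "emg", "csd", "erp", "inverse"
            ):
                sub = {"synth": SynthConfig, "inputs": InputConfig,
                       "preprocess": PreprocessConfig, "emg": EmgConfig,
                       "csd": CsdConfig, "erp": ErpConfig,
                       "inverse": InverseConfig}[f.name]
                kw[f.name] = sub(**v)
            else:
                kw[f.name] = v
        if d:
            raise ValueError(f"unknown config keys: {sorted(d)}")
        return cls(**kw).validate()

    def set_override(self, dotted: str, value) -> None:
        """Apply one ``section.key=value`` override (value YAML-parsed)."""
        obj = self
        *parents, leaf = dotted.split(".")
        for p in parents:
            obj = getattr(obj, p)
        if not hasattr(obj, leaf):
            raise ValueError(f"unknown config key: {dotted}")
        setattr(obj, leaf, value)


def load_config(path=None, overrides=()) -> PipelineConfig:
    if path is None:
        cfg = PipelineConfig()
    else:
        cfg = PipelineConfig.from_dict(yaml.safe_load(Path(path).read_text()))
    for ov in overrides:
        key, _, raw = ov.partition("=")
        cfg.set_override(key.strip(), yaml.safe_load(raw))
    return cfg.validate()


def _config_hash(cfg: PipelineConfig) -> str:
    return hashlib.sha256(
        json.dumps(cfg.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def _grand_average(evokeds: list):
    out = evokeds[0].copy()
    out.data = np.mean([e.data for e in evokeds], axis=0)
    out.nave = sum(e.nave for e in evokeds)
    return out


def _stage(name, t0, counts, **extra):
    dt = time.perf_counter() - t0
    logger.info("stage %-14s %6.2f s %s", name, dt, extra or "")
    counts[name] = dict(seconds=round(dt, 3), **extra)
    return time.perf_counter()


def _subject_inputs(cfg: PipelineConfig, montage, head):
    """Yield (recording, events) per subject, synthetic or from files."""
    if cfg.synth.enabled:
        rng = np.random.default_rng(cfg.seed)
        subject_seeds = rng.integers(2**31, size=cfg.n_subjects)
        subj_rt = cfg.synth.rt_mean_ms + cfg.synth.between_subject_rt_sd_ms \
            * rng.standard_normal(cfg.n_subjects)
        for s in range(cfg.n_subjects):
            schedule = TrialSchedule(
                n_trials=cfg.synth.n_trials, iti_s=cfg.synth.iti_s,
                rt_mean_ms=float(subj_rt[s]), rt_sd_ms=cfg.synth.rt_sd_ms,
                seed=int(subject_seeds[s]))
            sources = default_sources(montage, head,
                                      subject_rt_mean_ms=float(subj_rt[s]))
            art = None
            if cfg.synth.artifacts:
                art = ArtifactSpec(
                    emg_amplitude_uv=cfg.synth.emg_amplitude_uv,
                    background_rms_uv=cfg.synth.background_rms_uv)
            rec, events, gt = simulate_recording(montage, head, sources, art,
                                                 schedule)
            yield s, rec, events, gt
    else:
        if not cfg.inputs.recordings:
            raise FileNotFoundError(
                "synthesis disabled and no input recordings configured")
        for s, (rp, ep) in enumerate(zip(cfg.inputs.recordings,
                                         cfg.inputs.events)):
            if not Path(rp).exists():
                raise FileNotFoundError(f"missing recording file: {rp}")
            if not Path(ep).exists():
                raise FileNotFoundError(f"missing events file: {ep}")
            yield s, sio.read_edf(rp), sio.read_events_tsv(ep), None


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full dual-locked analysis; returns the result bundle.

    The bundle maps result names to in-memory objects; all tables are
    also written under ``cfg.outdir`` together with ``report.json`` and
    ``manifest.json``.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict = {}
    t0 = time.perf_counter()

    montage = build_montage("biosemi64", cfg.csd.r_head_cm)
    head = HeadModel(r_head_cm=cfg.csd.r_head_cm)
    spline = SplineConfig(m=cfg.csd.m, n_max=cfg.csd.n_max,
                          r_head_cm=cfg.csd.r_head_cm,
                          smoothing=cfg.csd.smoothing)

    subj_ev = {"stimulus": [], "response": []}
    subj_csd = {"stimulus": [], "response": []}
    subj_rts = []
    retained_pct = {"stimulus": [], "response": []}
    noise_covs = []
    emg_reports = []

    for s, rec, events, _gt in _subject_inputs(cfg, montage, head):
        ts = time.perf_counter()
        rec = pre.highpass(rec, cfg.preprocess.highpass_hz)
        rec, _b = pre.ocular_correct(rec, events=events)
        if not cfg.emg.skip_emg_removal:
            rec, rep = remove_emg(rec, cfg.emg.window_s,
                                  cfg.emg.ratio_threshold)
            rep.insert(0, "subject", s)
            emg_reports.append(rep)
        good = pre.select_trials(events)
        subj_rts.append(float(np.nanmean(rt_ms(good))))
        for lock in ("stimulus", "response"):
            ep = pre.epoch(rec, good, lock)
            ep = pre.reject_artifacts(ep, cfg.preprocess.ptp_limit_uv,
                                      cfg.preprocess.flat_limit_uv,
                                      cfg.preprocess.local_z)
            retained_pct[lock].append(100.0 * ep.n_retained / ep.n_trials)
            ev = pre.average(ep)
            subj_ev[lock].append(ev)
            subj_csd[lock].append(csd_transform(ev, montage, spline))
            if lock == "stimulus":
                noise_covs.append(inv_mod.noise_covariance(ep))
        logger.info("subject %d done in %.2f s", s, time.perf_counter() - ts)
    t0 = _stage("subjects", t0, counts, n_subjects=len(subj_rts),
                retained_stim_pct=round(float(np.mean(retained_pct["stimulus"])), 2),
                retained_resp_pct=round(float(np.mean(retained_pct["response"])), 2))

    grand = {lock: _grand_average(subj_ev[lock]) for lock in subj_ev}
    grand_csd = {lock: _grand_average(subj_csd[lock]) for lock in subj_csd}

    # --- GFP windows + slope statistics (stimulus-locked CSD) ---------------
    curve = erpstats.gfp(grand_csd["stimulus"])
    windows = erpstats.select_gfp_windows(curve, k=cfg.erp.gfp_k,
                                          win_len_ms=cfg.erp.gfp_win_ms,
                                          t_min_ms=0.0)
    slope_rows = []
    for w in windows if len(subj_csd["stimulus"]) >= 3 else []:
        for el in cfg.erp.frontomedial_electrodes:
            wf = np.stack([e.channel(el) for e in subj_csd["stimulus"]])
            res = erpstats.slope_test(wf, grand_csd["stimulus"].times_ms, w,
                                      tail="two")
            slope_rows.append({
                "electrode": el, "window_start_ms": w.start_ms,
                "window_end_ms": w.end_ms,
                "mean_slope": float(res.slopes.mean()), "t": res.t,
                "df": res.df, "p": res.p})
    slopes_df = pd.DataFrame(slope_rows)
    t0 = _stage("erp_windows", t0, counts, n_windows=len(windows))

    # --- peak latencies and latency-RT relation -----------------------------
    lat_tables = {}
    peak_rows = []
    for lock in ("stimulus", "response"):
        search = (100.0, 650.0) if lock == "stimulus" else (-450.0, 0.0)
        cols = {}
        for el in cfg.erp.frontomedial_electrodes:
            pm = erpstats.peak_latency(grand_csd[lock], subj_csd[lock], el,
                                       polarity="min", search_ms=search,
                                       ga_window_ms=cfg.erp.ga_window_ms,
                                       smooth_ms=cfg.erp.smooth_ms)
            cols[el] = pm.latencies_ms
            for subj, lat in enumerate(pm.latencies_ms):
                peak_rows.append({"lock": lock, "electrode": el,
                                  "subject": subj, "latency_ms": lat})
        lat_tables[lock] = pd.DataFrame(cols)
    peaks_df = pd.DataFrame(peak_rows)
    rts = np.asarray(subj_rts)
    latrt = {}
    if len(subj_rts) >= 4:
        for lock in ("stimulus", "response"):
            corr, model = erpstats.latency_rt_relation(rts, lat_tables[lock])
            corr.insert(0, "lock", lock)
            latrt[lock] = {"corr": corr, "model": model}
        latrt_df = pd.concat([latrt[lk]["corr"] for lk in latrt],
                             ignore_index=True)
    else:
        latrt_df = pd.DataFrame()
    t0 = _stage("peaks", t0, counts)

    # --- minimum-norm source estimates --------------------------------------
    space = inv_mod.build_source_space(head, cfg.inverse.n_dipoles)
    gain = forward_matrix(head, montage, space.locations_cm)
    scalp = montage.scalp_picks
    gain = gain[scalp]
    scalp_names = [montage.labels[i] for i in scalp]
    cov = np.mean(noise_covs, axis=0)
    estimates = {}
    roi_rows = []
    for lock in ("stimulus", "response"):
        ev = grand[lock]
        sel_names = [c for c in ev.ch_names if c in scalp_names]
        idx = [scalp_names.index(c) for c in sel_names]
        op = inv_mod.make_inverse(gain[idx], cov[np.ix_(idx, idx)], space,
                                  sel_names, data=ev.data[
                                      [ev.ch_names.index(c) for c in sel_names]],
                                  depth_gamma=cfg.inverse.depth_gamma,
                                  snr=cfg.inverse.snr)
        est = inv_mod.apply_inverse(op, ev)
        b0, b1 = (pre.STIM_BASELINE_MS if lock == "stimulus"
                  else pre.RESP_BASELINE_MS)
        bl = (est.times_ms >= b0) & (est.times_ms <= b1)
        thr = inv_mod.h0_threshold(est.amplitudes[:, bl], cfg.inverse.alpha)
        est.apply_threshold(thr)
        estimates[lock] = est
        for roi, label in (("frontomedial", "FCz"), ("left_frontal", "FC5"),
                           ("right_frontal", "FC6")):
            center = space.radius_cm * montage.positions[montage.index(label)]
            near = np.linalg.norm(space.locations_cm - center, axis=1) < 2.5
            if not near.any():
                continue
            course = est.amplitudes[near].mean(axis=0)
            post = est.times_ms >= 0 if lock == "stimulus" else \
                est.times_ms <= 50
            tpk = est.times_ms[post][np.argmax(course[post])]
            roi_rows.append({"lock": lock, "roi": roi,
                             "peak_ms": float(tpk),
                             "peak_amplitude": float(course.max()),
                             "n_dipoles": int(near.sum()),
                             "threshold": thr})
    roi_df = pd.DataFrame(roi_rows)
    t0 = _stage("inverse", t0, counts, n_dipoles=space.n_dipoles)

    # --- outputs ------------------------------------------------------------
    tables = {
        "gfp_windows.tsv": pd.DataFrame(
            [{"rank": w.rank, "start_ms": w.start_ms, "end_ms": w.end_ms}
             for w in windows]),
        "slopes.tsv": slopes_df,
        "peak_latencies.tsv": peaks_df,
        "latency_rt.tsv": latrt_df,
        "source_rois.tsv": roi_df,
    }
    if emg_reports:
        tables["emg_report.tsv"] = pd.concat(emg_reports, ignore_index=True)
    written = {}
    for name, df in tables.items():
        p = outdir / name
        df.to_csv(p, sep="\t", index=False)
        written[name] = hashlib.sha256(p.read_bytes()).hexdigest()
    for lock in ("stimulus", "response"):
        for tag, ev in (("evoked", grand[lock]), ("csd", grand_csd[lock])):
            p = outdir / f"grand_{tag}_{lock}"
            sio.save_evoked(p, ev)
            for suffix in (".npz", ".json"):
                fp = p.with_suffix(suffix)
                written[fp.name] = hashlib.sha256(fp.read_bytes()).hexdigest()
    report = {
        "subject_mean_rt_ms": subj_rts,
        "retained_pct": {k: v for k, v in retained_pct.items()},
        "gfp_windows_ms": [[w.start_ms, w.end_ms] for w in windows],
        "h0_thresholds": {lk: estimates[lk].threshold for lk in estimates},
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2,
                                                   sort_keys=True))
    manifest = {
        "config": cfg.to_dict(),
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "stages": counts,
        "files": written,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     sort_keys=True))
    return {
        "config": cfg, "grand": grand, "grand_csd": grand_csd,
        "subject_evoked": subj_ev, "subject_csd": subj_csd,
        "subject_rts_ms": rts, "gfp_windows": windows, "slopes": slopes_df,
        "peak_latencies": peaks_df, "latency_tables": lat_tables,
        "latency_rt": latrt, "estimates": estimates, "rois": roi_df,
        "manifest": manifest,
    }
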