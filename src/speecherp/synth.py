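"""Synthetic speech-production EEG with known ground truth.

Emulates a picture-naming session: a 64-channel recording at 512 Hz with
per-trial stimulus and vocal-onset events, dipolar cortical sources locked
either to the stimulus or to the response, broadband articulation EMG
bursts straddling vocal onset, ocular (blink) artifacts, and 1/f + alpha
background activity.  Every stochastic element flows from one seed, and
the generator returns the clean source projection, the EMG-only and
ocular-only signals, and per-trial reaction times so that each downstream
stage can be validated against ground truth.

Study conditions baked into the defaults: reaction times follow a
truncated normal with mean 651 ms and SD 72 ms on (200, 1500] ms (the
response deadline), ~1.3% verbal errors and ~0.5% no-response/voice-key
failures; the fronto-medial response-locked generator peaks 250 ms before
vocal onset and the left-frontal generator ramps up from about 350 ms
before vocal onset to a peak just after it.

A deliberate cohort-level feature: the fronto-medial peak leads vocal
onset by an amount that grows with the subject's mean RT (slower speakers
engage response selection earlier relative to output).  This makes the
peak latency approximately a fixed delay after the *stimulus* on average,
so response-locked per-subject latencies correlate negatively with mean
RT while stimulus-locked latencies do not — the qualitative pattern the
dual-locking analysis is designed to detect.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.stats import truncnorm

from .containers import Recording, make_event_table
from .headmodel import HeadModel, forward_gain
from .montage import Montage

__all__ = [
    "GaussianBump",
    "RampBump",
    "DipoleSource",
    "ArtifactSpec",
    "TrialSchedule",
    "GroundTruth",
    "simulate_recording",
    "default_sources",
    "default_artifacts",
]


# ---------------------------------------------------------------------------
# source time courses


@dataclass(frozen=True)
class GaussianBump:
    """Gaussian-windowed half-sine bump, peak amplitude 1 at ``peak_ms``."""

    peak_ms: float
    dur_ms: float = 150.0

    @property
    def support_ms(self) -> tuple:
        return (self.peak_ms - self.dur_ms / 2.0, self.peak_ms + self.dur_ms / 2.0)

    def __call__(self, t_ms: np.ndarray) -> np.ndarray:
        tau = np.asarray(t_ms, float) - (self.peak_ms - self.dur_ms / 2.0)
        inside = (tau >= 0) & (tau <= self.dur_ms)
        s = np.where(inside, np.sin(np.pi * tau / self.dur_ms), 0.0)
        w = np.exp(-((tau - self.dur_ms / 2.0) ** 2) / (2.0 * (self.dur_ms / 6.0) ** 2))
        return s * w


@dataclass(frozen=True)
class RampBump:
    """Slow quarter-sine rise to a peak, quarter-cosine fall (asymmetric)."""

    peak_ms: float
    rise_ms: float = 350.0
    fall_ms: float = 120.0

    @property
    def support_ms(self) -> tuple:
        return (self.peak_ms - self.rise_ms, self.peak_ms + self.fall_ms)

    def __call__(self, t_ms: np.ndarray) -> np.ndarray:
        t = np.asarray(t_ms, float)
        out = np.zeros_like(t)
        rising = (t >= self.peak_ms - self.rise_ms) & (t < self.peak_ms)
        falling = (t >= self.peak_ms) & (t <= self.peak_ms + self.fall_ms)
        out[rising] = np.sin(0.5 * np.pi * (t[rising] - self.peak_ms + self.rise_ms)
                             / self.rise_ms)
        out[falling] = np.cos(0.5 * np.pi * (t[falling] - self.peak_ms) / self.fall_ms)
        return out


@dataclass(frozen=True)
class DipoleSource:
    """One cortical generator with a trial-locked time course.

    ``lock`` selects the per-trial anchor: stimulus onset or vocal onset.
    ``amplitude_nAm`` is the peak dipole moment; per-trial amplitudes are
    jittered multiplicatively with SD ``amp_jitter_sd`` (clipped at 0).
    """

    name: str
    location_cm: tuple
    orientation: tuple
    time_course: object
    lock: str = "stimulus"
    amplitude_nAm: float = 50.0
    amp_jitter_sd: float = 0.2

    def __post_init__(self):
        ori = np.asarray(self.orientation, float)
        if not np.isclose(np.linalg.norm(ori), 1.0, atol=1e-6):
            raise ValueError(f"source {self.name!r}: orientation must be unit-norm")
        if self.lock not in ("stimulus", "response"):
            raise ValueError("lock must be 'stimulus' or 'response'")


# ---------------------------------------------------------------------------
# artifacts and schedule


@dataclass(frozen=True)
class ArtifactSpec:
    """Artifact generator parameters (all amplitudes in µV).

    EMG bursts are band-limited (default 15-110 Hz) noise, Hann-windowed,
    starting ``emg_onset_ms`` relative to vocal onset and lasting
    ``emg_duration_ms``; they load frontotemporal/inferior channels via
    smooth gain maps around left/right jaw anchors.  Ocular activity is a
    smooth blink template propagated from the periocular channels into the
    EEG with distance-decaying factors.  Background is per-channel 1/f
    noise plus posterior-weighted alpha.
    """

    emg_amplitude_uv: float = 50.0
    emg_band_hz: tuple = (15.0, 110.0)
    emg_onset_ms: float = -100.0
    emg_duration_ms: float = 400.0
    n_emg_sources: int = 3
    blink_rate_hz: float = 0.12
    blink_amplitude_uv: float = 150.0
    blink_duration_ms: float = 300.0
    background_rms_uv: float = 5.0
    n_background_sources: int = 40
    sensor_noise_rms_uv: float = 0.8
    alpha_rms_uv: float = 2.0

    def __post_init__(self):
        if self.emg_amplitude_uv < 0 or self.blink_amplitude_uv < 0:
            raise ValueError("artifact amplitudes must be >= 0")
        lo, hi = self.emg_band_hz
        if not (0 < lo < hi):
            raise ValueError("EMG band must satisfy 0 < low < high")


@dataclass(frozen=True)
class TrialSchedule:
    """Trial timing and reaction-time distribution.

    RTs are truncated-normal on ``rt_bounds_ms`` (upper bound = response
    deadline).  Error and missing-response probabilities default to the
    observed behavioral rates of the emulated task.
    """

    n_trials: int = 400
    iti_s: float = 2.5
    rt_mean_ms: float = 651.0
    rt_sd_ms: float = 72.0
    rt_bounds_ms: tuple = (200.0, 1500.0)
    p_error: float = 0.0131
    p_no_response: float = 0.0024
    p_voicekey_fail: float = 0.0024
    seed: int = 0

    def __post_init__(self):
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")
        lo, hi = self.rt_bounds_ms
        if not (0 < lo < hi <= 1500.0):
            raise ValueError("RT bounds must lie within (0, 1500] ms")
        if self.iti_s * 1000.0 <= hi:
            raise ValueError("inter-trial interval shorter than RT deadline")


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline must recover."""

    rts_ms: np.ndarray  # per trial, NaN where no vocal onset
    accuracy: np.ndarray
    clean: np.ndarray  # source projections only (n_channels, n_samples)
    emg: np.ndarray  # EMG-only signal
    ocular: np.ndarray  # blink-only signal
    background: np.ndarray  # 1/f + alpha noise
    source_gains: dict  # name -> per-channel gain (µV per nAm)
    source_waveforms: dict  # name -> continuous moment amplitude (nAm)
    blink_propagation: np.ndarray = None  # per-channel factor re: VEOGU
    seed: int = 0


# ---------------------------------------------------------------------------
# default study configuration


def default_sources(
    montage: Montage,
    head: HeadModel,
    subject_rt_mean_ms: float = 651.0,
    depth_frac: float = 0.8,
) -> list:
    """The five generators emulated by the study conditions.

    Three stimulus-locked sources (occipital 100 ms, parieto-occipital
    150 ms, fronto-central 300 ms) and two response-locked sources (the
    fronto-medial selection component and the left-frontal production
    ramp).  Orientations point inward so the overlying surface
    deflections are negativities, matching the polarity convention of
    the components this pipeline measures.  The fronto-medial pre-onset
    lead grows with the subject's mean RT (see module docstring).
    """
    r = depth_frac * head.brain_radius_cm

    def under(label):
        return tuple(r * montage.positions[montage.index(label)])

    def radial(label):
        return tuple(-montage.positions[montage.index(label)])

    fm_peak = -250.0 - (subject_rt_mean_ms - 651.0)
    return [
        DipoleSource("occipital_vep", under("Oz"), radial("Oz"),
                     GaussianBump(100.0, 90.0), "stimulus", 65.0, 0.2),
        DipoleSource("parieto_occipital", under("POz"), radial("POz"),
                     GaussianBump(150.0, 120.0), "stimulus", 55.0, 0.2),
        DipoleSource("frontocentral_stim", under("FCz"), radial("FCz"),
                     GaussianBump(300.0, 200.0), "stimulus", 45.0, 0.25),
        DipoleSource("frontomedial_resp", under("FCz"), radial("FCz"),
                     GaussianBump(fm_peak, 200.0), "response", 50.0, 0.25),
        DipoleSource("left_frontal_ramp", under("FC5"), radial("FC5"),
                     RampBump(42.0, 392.0, 120.0), "response", 45.0, 0.25),
    ]


def default_artifacts(**overrides) -> ArtifactSpec:
    return ArtifactSpec(**overrides)


# ---------------------------------------------------------------------------
# generator internals


def _source_rng(seed: int, name: str) -> np.random.Generator:
    # keyed by source name so that adding/removing other sources does not
    # perturb this source's draws (linearity of the generator)
    return np.random.default_rng([seed, zlib.crc32(name.encode())])


def _emg_gain_maps(montage: Montage, n_sources: int) -> np.ndarray:
    """Smooth per-channel gain maps peaking at jaw/temporal anchors."""
    anchors = np.array(
        [
            [-0.90, 0.25, -0.35],  # left jaw/masseter
            [0.90, 0.25, -0.35],  # right jaw/masseter
            [0.0, 0.95, -0.32],  # mentalis / lower face
        ]
    )
    anchors = anchors / np.linalg.norm(anchors, axis=1, keepdims=True)
    maps = []
    for k in range(n_sources):
        a = anchors[k % len(anchors)]
        ang = np.arccos(np.clip(montage.positions @ a, -1, 1))
        g = np.exp(-2.2 * ang)
        maps.append(g / g.max())
    return np.array(maps)


def _blink_propagation(montage: Montage) -> np.ndarray:
    """Per-channel blink factors relative to the VEOGU template."""
    eye = np.array([-0.15, 0.97, -0.05])
    eye /= np.linalg.norm(eye)
    ang = np.arccos(np.clip(montage.positions @ eye, -1, 1))
    prop = 0.38 * np.exp(-3.0 * ang)
    for lab, val in (("VEOGU", 1.0), ("VEOGL", -0.55), ("HEOGL", 0.12),
                     ("HEOGR", 0.12)):
        prop[montage.index(lab)] = val
    return prop


def _one_over_f(rng, n_ch, n_samp, fs) -> np.ndarray:
    white = rng.standard_normal((n_ch, n_samp))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n_samp, 1.0 / fs)
    # amplitude ~ 1/f (power ~ 1/f**2), the typical background falloff
    shape = 1.0 / np.maximum(f, 0.5)
    shape[0] = 0.0  # no DC
    x = np.fft.irfft(spec * shape, n=n_samp, axis=1)
    rms = x.std(axis=1, keepdims=True)
    return x / np.where(rms > 0, rms, 1.0)


def _alpha_map(montage: Montage) -> np.ndarray:
    post = np.array([0.0, -0.9, 0.35])
    post /= np.linalg.norm(post)
    ang = np.arccos(np.clip(montage.positions @ post, -1, 1))
    g = np.exp(-2.0 * ang)
    g[montage.eog_picks] *= 0.2
    return g / g.max()


def _add_windowed(target: np.ndarray, idx0: int, segment: np.ndarray):
    """Add ``segment`` into 1-D ``target`` starting at idx0, clipped."""
    n = target.shape[-1]
    a = max(idx0, 0)
    b = min(idx0 + segment.shape[-1], n)
    if b > a:
        target[..., a:b] += segment[..., a - idx0: b - idx0]


# ---------------------------------------------------------------------------
# main entry point


def simulate_recording(
    montage: Montage,
    head: HeadModel,
    sources: list,
    artifacts: ArtifactSpec | None,
    schedule: TrialSchedule,
    fs: float = 512.0,
):
    """Generate a continuous synthetic recording.

    Parameters
    ----------
    montage, head : Montage, HeadModel
        Geometry shared with the forward/inverse stages.
    sources : list of DipoleSource
        Trial-locked generators (may be empty).
    artifacts : ArtifactSpec or None
        None disables EMG, ocular and background noise entirely.
    schedule : TrialSchedule
        Trial timing, RT distribution and the master RNG seed.
    fs : float
        Sampling rate in Hz (must exceed twice the highest simulated
        frequency).

    Returns
    -------
    (Recording, events, GroundTruth)
        ``events`` is the per-trial event table (see containers docs).
    """
    if artifacts is not None and fs < 2.0 * artifacts.emg_band_hz[1]:
        raise ValueError("sampling rate below twice the highest EMG frequency")

    master = np.random.default_rng(schedule.seed)
    seed_sched, seed_src, seed_art, seed_bg = master.integers(2**31, size=4)

    n_tr = schedule.n_trials
    lead_s = 1.5
    dur_s = lead_s + n_tr * schedule.iti_s + 1.0
    n_samp = int(round(dur_s * fs))
    n_ch = montage.n_channels
    t_s = np.arange(n_samp) / fs

    # --- behavioral schedule -------------------------------------------------
    rng_s = np.random.default_rng(seed_sched)
    stim_onsets = lead_s + np.arange(n_tr) * schedule.iti_s
    u = rng_s.random(n_tr)
    accuracy = np.full(n_tr, "correct", dtype=object)
    accuracy[u < schedule.p_no_response] = "no_response"
    accuracy[(u >= schedule.p_no_response)
             & (u < schedule.p_no_response + schedule.p_voicekey_fail)] = \
        "voicekey_fail"
    hi = schedule.p_no_response + schedule.p_voicekey_fail + schedule.p_error
    accuracy[(u >= schedule.p_no_response + schedule.p_voicekey_fail)
             & (u < hi)] = "error"
    lo_b, hi_b = schedule.rt_bounds_ms
    a = (lo_b - schedule.rt_mean_ms) / schedule.rt_sd_ms
    b = (hi_b - schedule.rt_mean_ms) / schedule.rt_sd_ms
    rts = truncnorm.rvs(a, b, loc=schedule.rt_mean_ms, scale=schedule.rt_sd_ms,
                        size=n_tr, random_state=rng_s)
    has_vocal = np.isin(accuracy, ["correct", "error"])
    rts = np.where(has_vocal, rts, np.nan)
    vocal_onsets = stim_onsets + rts / 1000.0

    # --- cortical sources ----------------------------------------------------
    clean = np.zeros((n_ch, n_samp))
    source_gains, source_waveforms = {}, {}
    for src in sources:
        g = forward_gain(head, montage, np.asarray(src.location_cm),
                         np.asarray(src.orientation))
        rng_k = _source_rng(seed_src, src.name)
        jitter = np.clip(1.0 + src.amp_jitter_sd * rng_k.standard_normal(n_tr),
                         0.0, None)
        anchors = stim_onsets if src.lock == "stimulus" else vocal_onsets
        wave = np.zeros(n_samp)
        sup0, sup1 = src.time_course.support_ms
        for i in range(n_tr):
            if not np.isfinite(anchors[i]):
                continue
            t0 = anchors[i] + sup0 / 1000.0
            i0 = int(np.floor(t0 * fs))
            i1 = int(np.ceil((anchors[i] + sup1 / 1000.0) * fs)) + 1
            tt = (np.arange(i0, i1) / fs - anchors[i]) * 1000.0
            _add_windowed(wave, i0,
                          src.amplitude_nAm * jitter[i] * src.time_course(tt))
        clean += np.outer(g, wave)
        source_gains[src.name] = g
        source_waveforms[src.name] = wave.astype(np.float32)

    # accumulate artifacts straight into the output signal and keep the
    # per-kind ground truth in float32 to bound memory at long recordings
    data = clean.copy()
    emg = np.zeros((n_ch, n_samp), dtype=np.float32)
    ocular = np.zeros((n_ch, n_samp), dtype=np.float32)
    background = np.zeros((n_ch, n_samp), dtype=np.float32)
    blink_prop = _blink_propagation(montage)

    if artifacts is not None:
        rng_a = np.random.default_rng(seed_art)
        # --- EMG bursts around each vocal onset ------------------------------
        if artifacts.emg_amplitude_uv > 0:
            gain_maps = _emg_gain_maps(montage, artifacts.n_emg_sources)
            n_burst = max(int(round(artifacts.emg_duration_ms / 1000.0 * fs)), 8)
            sos = sps.butter(4, artifacts.emg_band_hz, btype="bandpass", fs=fs,
                             output="sos")
            win = np.hanning(n_burst)
            for i in range(n_tr):
                if not np.isfinite(vocal_onsets[i]):
                    continue
                i0 = int(round((vocal_onsets[i]
                                + artifacts.emg_onset_ms / 1000.0) * fs))
                for m in range(artifacts.n_emg_sources):
                    noise = rng_a.standard_normal(n_burst + 64)
                    burst = sps.sosfiltfilt(sos, noise)[32:32 + n_burst] * win
                    rms = burst.std()
                    if rms > 0:
                        burst *= (artifacts.emg_amplitude_uv
                                  * rng_a.uniform(0.7, 1.3) / rms)
                    # burst-to-burst recruitment variability: each burst has
                    # its own perturbed spatial pattern, so EMG is not one
                    # static low-rank subspace over the whole recording
                    gmap = gain_maps[m] * rng_a.uniform(0.5, 1.5, n_ch)
                    for c in np.nonzero(gmap > 1e-4)[0]:
                        seg = gmap[c] * burst
                        _add_windowed(emg[c], i0, seg)
                        _add_windowed(data[c], i0, seg)

        # --- blinks ----------------------------------------------------------
        if artifacts.blink_amplitude_uv > 0 and artifacts.blink_rate_hz > 0:
            n_blinks = rng_a.poisson(artifacts.blink_rate_hz * dur_s)
            blink_times = rng_a.uniform(0.5, dur_s - 0.5, size=n_blinks)
            n_b = int(round(artifacts.blink_duration_ms / 1000.0 * fs))
            tpl = np.sin(np.pi * np.arange(n_b) / max(n_b - 1, 1)) ** 2
            tpl *= artifacts.blink_amplitude_uv
            for bt in blink_times:
                i0 = int(round(bt * fs))
                amp = rng_a.uniform(0.8, 1.2)
                for c in range(n_ch):
                    if abs(blink_prop[c]) > 1e-4:
                        seg = blink_prop[c] * amp * tpl
                        _add_windowed(ocular[c], i0, seg)
                        _add_windowed(data[c], i0, seg)

        # --- background ------------------------------------------------------
        # Ongoing brain noise is *spatially correlated*: 1/f sources at
        # random cortical locations projected through the head model, so
        # that its effective sensor-space rank matches real EEG; only the
        # small instrumentation noise is spatially white.
        rng_b = np.random.default_rng(seed_bg)
        if artifacts.background_rms_uv > 0:
            n_bg = artifacts.n_background_sources
            dirs = rng_b.standard_normal((n_bg, 3))
            dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
            radii = head.brain_radius_cm * rng_b.uniform(0.4, 0.8, n_bg)
            from .headmodel import forward_matrix

            Gbg = forward_matrix(head, montage, dirs * radii[:, None])
            ori = rng_b.standard_normal((n_bg, 3))
            ori /= np.linalg.norm(ori, axis=1, keepdims=True)
            gains = np.stack([Gbg[:, 3 * k: 3 * k + 3] @ ori[k]
                              for k in range(n_bg)], axis=1)  # (n_ch, n_bg)
            waves = _one_over_f(rng_b, n_bg, n_samp, fs)
            brain = gains @ waves
            del waves
            rms = brain[montage.scalp_picks].std()
            brain *= artifacts.background_rms_uv / max(rms, 1e-12)
            data += brain
            background += brain.astype(np.float32)
            del brain
        if artifacts.sensor_noise_rms_uv > 0:
            noise = rng_b.standard_normal((n_ch, n_samp))
            noise *= artifacts.sensor_noise_rms_uv
            data += noise
            background += noise.astype(np.float32)
            del noise
        if artifacts.alpha_rms_uv > 0:
            amap = _alpha_map(montage)
            env = sps.sosfiltfilt(
                sps.butter(2, 0.5, btype="lowpass", fs=fs, output="sos"),
                rng_b.standard_normal(n_samp))
            env = 1.0 + env / max(env.std(), 1e-12) * 0.5
            osc = np.sin(2 * np.pi * 10.0 * t_s + rng_b.uniform(0, 2 * np.pi))
            alpha = osc * np.clip(env, 0, None)
            alpha *= artifacts.alpha_rms_uv / max(alpha.std(), 1e-12)
            wave = np.outer(amap, alpha)
            data += wave
            background += wave.astype(np.float32)
            del wave

    rec = Recording(data, fs, list(montage.labels), list(montage.ch_types),
                    montage)
    events = make_event_table(stim_onsets, vocal_onsets, accuracy)
    gt = GroundTruth(
        rts_ms=rts,
        accuracy=accuracy,
        clean=clean.astype(np.float32),
        emg=emg,
        ocular=ocular,
        background=background,
        source_gains=source_gains,
        source_waveforms=source_waveforms,
        blink_propagation=blink_prop,
        seed=schedule.seed,
    )
    return rec, events, gt
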