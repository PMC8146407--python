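"""Synthetic study generator: complete subjects with ground truth.

Emulates the signal structure of a simultaneous EEG-fNIRS mini-block
flanker session so that every downstream stage can be verified without
real recordings:

* behavioral log: lognormal reaction times with a congruency shift
  (defaults 368.18 / 410.27 ms), truncated to the 1 s response window
  (late responses become missing trials), condition accuracies
  (defaults 96.84 / 87.35 percent);
* continuous EEG at 1000 Hz: per-trial condition ERP templates — a
  right centro-parietal Gaussian negativity around 275 ms (N2pc-like,
  larger for incongruent trials) and a broad posterior positivity whose
  latency shifts between conditions (P300-like, defaults 385 / 421 ms,
  smaller and later for incongruent) — on top of 1/f background noise,
  posterior alpha, and blink artifacts that originate at the vertical
  EOG (FP2) and propagate to the scalp with front-to-back decaying
  coefficients;
* dual-wavelength fNIRS intensities at 7.81 Hz: the exact forward
  modified-Beer-Lambert image of HRF-convolved block activations
  (coupled HbO increase / HbR decrease) plus cardiac, Mayer-wave,
  drift, and white noise in optical density.

Every random quantity derives from the seed; the realized per-subject
parameters are returned as ground truth so tests can compare pipeline
estimates against what was injected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sp_fft
from scipy import signal as sp_signal

from . import fnirs as fn
from .behavior import ResponseEvent
from .eeg import ALL_CHANNELS, EOG_CHANNELS, SCALP_CHANNELS, ContinuousEEG
from .paradigm import (MAINLY_CONGRUENT, MAINLY_INCONGRUENT, StimulusSchedule,
                       generate_sequence, schedule_to_events)

__all__ = [
    "EffectConfig",
    "NoiseConfig",
    "SubjectTruth",
    "SubjectDataset",
    "simulate_subject",
    "simulate_cohort",
    "iter_cohort",
]

EEG_SFREQ = 1000.0

#: coarse anterior-to-posterior rank of each electrode (0 = frontal pole),
#: used for blink-propagation decay and posterior component topographies.
_AP_RANK = {"FP": 0.0, "F": 1.0, "FT": 2.0, "FC": 2.0, "T": 3.0, "C": 3.0,
            "TP": 4.0, "CP": 4.0, "CPP": 4.5, "P": 5.0}


def _ap_rank(channel: str) -> float:
    for prefix in ("CPP", "FT", "FC", "TP", "CP", "FP", "F", "T", "C", "P"):
        if channel.upper().startswith(prefix):
            return _AP_RANK[prefix]
    raise KeyError(channel)


def blink_propagation_map(base: float = 0.5, decay: float = 1.8) -> dict[str, float]:
    """Per-channel blink propagation coefficients, decaying front-to-back."""
    out = {}
    for ch in SCALP_CHANNELS:
        out[ch] = base * np.exp(-_ap_rank(ch) / decay)
    out["F10"] = 0.35  # horizontal EOG sits next to the eye
    out["TP10"] = base * np.exp(-4.0 / decay) * 0.5
    return out


def p300_topography() -> dict[str, float]:
    """Broad positivity, posterior maximum."""
    return {ch: min(1.0, 0.4 + 0.12 * _ap_rank(ch)) for ch in SCALP_CHANNELS}


@dataclass(frozen=True)
class EffectConfig:
    """Injected condition effects; defaults emulate the reference study's
    measured behavioral and ERP values at plausible scalp amplitudes."""

    # N2pc-like negativity (condition -> microvolt; negative = negativity)
    n2pc_amp: dict = field(default_factory=lambda: {"congruent": -2.0, "incongruent": -3.5})
    n2pc_latency_ms: dict = field(default_factory=lambda: {"congruent": 275.0, "incongruent": 277.0})
    n2pc_sigma_ms: float = 12.0
    n2pc_electrodes: tuple[str, ...] = ("C4", "CP4", "CPP6H", "P4", "P8", "Pz")
    # P300-like positivity
    p300_amp: dict = field(default_factory=lambda: {"congruent": 8.0, "incongruent": 6.4})
    p300_latency_ms: dict = field(default_factory=lambda: {"congruent": 385.0, "incongruent": 421.0})
    p300_sigma_ms: float = 35.0
    # behavior
    rt_mean_ms: dict = field(default_factory=lambda: {"congruent": 368.18, "incongruent": 410.27})
    rt_sd_ms: float = 60.0
    accuracy: dict = field(default_factory=lambda: {"congruent": 96.84, "incongruent": 87.35})
    # fNIRS condition betas (umol/l) per chromophore and block type
    fnirs_beta: dict = field(default_factory=lambda: {
        "hbo": {MAINLY_CONGRUENT: 0.5, MAINLY_INCONGRUENT: 0.8},
        "hbr": {MAINLY_CONGRUENT: -0.5 / 3, MAINLY_INCONGRUENT: -0.8 / 3},
    })
    # between-subject variability
    amp_scale_sd: float = 0.2  # lognormal sd of template amplitude scaling
    latency_jitter_sd_ms: float = 8.0  # shared shift of both conditions
    rt_subject_sd_ms: float = 20.0
    rt_delta_sd_ms: float = 5.0
    accuracy_logit_sd: float = 0.3
    fnirs_beta_scale_sd: float = 0.2

    def __post_init__(self) -> None:
        for cond, acc in self.accuracy.items():
            if not 0.0 <= acc <= 100.0:
                raise ValueError(f"accuracy[{cond}] outside [0, 100]")
        for el in self.n2pc_electrodes:
            if el not in SCALP_CHANNELS:
                raise ValueError(f"unknown electrode {el}")


@dataclass(frozen=True)
class NoiseConfig:
    """Background and artifact levels; all amplitudes >= 0."""

    pink_sd_uv: float = 8.0
    eog_pink_sd_uv: float = 3.0
    alpha_amp_uv: float = 3.0
    alpha_freq_hz: float = 10.0
    blink_rate_per_min: float = 15.0
    blink_amp_uv: float = 150.0
    blink_sigma_ms: float = 50.0
    blink_base: float = 0.5
    blink_decay: float = 1.8
    artifact_rate: float = 0.01  # fraction of trials with an injected spike
    artifact_amp_uv: float = 400.0
    fnirs_cardiac_amp_od: float = 0.003
    fnirs_cardiac_freq_hz: float = 1.1
    fnirs_mayer_amp_od: float = 0.002
    fnirs_mayer_freq_hz: float = 0.1
    fnirs_drift_od_per_min: float = 0.002
    fnirs_white_sd_od: float = 0.001
    fnirs_spike_rate_per_min: float = 0.0  # step/spike artifacts, off by default
    fnirs_spike_amp_od: float = 0.05

    def __post_init__(self) -> None:
        if self.fnirs_cardiac_freq_hz >= fn.FNIRS_SFREQ / 2:
            raise ValueError("cardiac frequency must be below the fNIRS Nyquist")
        for name in ("pink_sd_uv", "alpha_amp_uv", "blink_rate_per_min",
                     "blink_amp_uv", "fnirs_cardiac_amp_od", "fnirs_white_sd_od"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SubjectTruth:
    """Realized per-subject parameters, sufficient to predict the expected
    value of every downstream estimate."""

    subject: str
    group: str
    seed_entropy: int
    n2pc_amp: dict
    n2pc_latency_ms: dict
    p300_amp: dict
    p300_latency_ms: dict
    rt_mean_ms: dict
    accuracy: dict
    blink_coeffs: dict
    fnirs_betas: dict  # chromophore -> (n_channels, 2) per block type
    artifact_injections: list  # (trial_idx, channel)
    fnirs_spike_spans: dict  # channel -> list of (lo, hi)


@dataclass
class SubjectDataset:
    subject: str
    group: str
    schedule: StimulusSchedule
    eeg: ContinuousEEG
    fnirs: fn.OpticalSeries
    responses: dict[int, list[ResponseEvent]]
    clinical: dict = field(default_factory=dict)


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """1/f-shaped Gaussian noise, unit standard deviation."""
    m = sp_fft.next_fast_len(n)  # pad to an FFT-friendly length
    white = rng.standard_normal(m)
    spec = sp_fft.rfft(white)
    f = sp_fft.rfftfreq(m)
    f[0] = f[1]
    spec /= np.sqrt(f)
    x = sp_fft.irfft(spec, m)[:n]
    return x / x.std()


def _gauss(t_ms: np.ndarray, mu_ms: float, sigma_ms: float) -> np.ndarray:
    return np.exp(-0.5 * ((t_ms - mu_ms) / sigma_ms) ** 2)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def simulate_subject(schedule: StimulusSchedule | None = None,
                     effects: EffectConfig | None = None,
                     noise: NoiseConfig | None = None,
                     group: str = "control",
                     seed=0,
                     subject: str = "S01"
                     ) -> tuple[SubjectDataset, SubjectTruth]:
    """Generate one subject's behavioral log, continuous EEG and fNIRS.

    All randomness comes from ``seed`` (int or ``np.random.SeedSequence``).
    Training trials receive stimulation (ERP templates) but no logged
    responses; they are excluded from analysis by design.
    """
    effects = effects or EffectConfig()
    noise = noise or NoiseConfig()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    if schedule is None:
        schedule = generate_sequence(seed=int(rng.integers(2**31)))

    conditions = ("congruent", "incongruent")
    # ---- subject-level random effects -------------------------------------
    n2pc_scale = float(np.exp(rng.normal(0.0, effects.amp_scale_sd)))
    p300_scale = float(np.exp(rng.normal(0.0, effects.amp_scale_sd)))
    lat_shift = float(rng.normal(0.0, effects.latency_jitter_sd_ms))
    rt_shift = float(rng.normal(0.0, effects.rt_subject_sd_ms))
    rt_delta = float(rng.normal(0.0, effects.rt_delta_sd_ms))
    acc_shift = float(rng.normal(0.0, effects.accuracy_logit_sd))

    n2pc_amp = {c: effects.n2pc_amp[c] * n2pc_scale for c in conditions}
    n2pc_lat = {c: effects.n2pc_latency_ms[c] + lat_shift for c in conditions}
    p300_amp = {c: effects.p300_amp[c] * p300_scale for c in conditions}
    p300_lat = {c: effects.p300_latency_ms[c] + lat_shift for c in conditions}
    rt_mean = {c: effects.rt_mean_ms[c] + rt_shift
               + (rt_delta / 2 if c == "incongruent" else -rt_delta / 2)
               for c in conditions}

    def _acc(c):
        p = min(max(effects.accuracy[c] / 100.0, 1e-6), 1 - 1e-6)
        logit = np.log(p / (1 - p)) + acc_shift
        return 1.0 / (1.0 + np.exp(-logit))

    acc = {c: float(_acc(c)) for c in conditions}

    # ---- behavior ---------------------------------------------------------
    responses: dict[int, list[ResponseEvent]] = {}
    for tr in schedule.trials:
        mu, sg = _lognormal_params(rt_mean[tr.congruency], effects.rt_sd_ms)
        rt = float(rng.lognormal(mu, sg))
        if rt > 1000.0:
            continue  # no response inside the window -> missing trial
        rt = max(rt, 100.0)
        correct = rng.random() < acc[tr.congruency]
        key = tr.direction if correct else ("left" if tr.direction == "right" else "right")
        responses[tr.index] = [ResponseEvent(key, rt)]

    # ---- EEG --------------------------------------------------------------
    sf = EEG_SFREQ
    n_samples = int(np.ceil(schedule.duration_s * sf)) + int(sf)
    n_ch = len(ALL_CHANNELS)
    data = np.zeros((n_ch, n_samples), dtype=np.float32)
    t_all = np.arange(n_samples) / sf

    alpha_w = {ch: 0.3 + 0.14 * _ap_rank(ch) for ch in SCALP_CHANNELS}
    alpha_sos = None
    if noise.alpha_amp_uv > 0:
        # ongoing alpha: narrowband noise around alpha_freq (real alpha
        # dephases within ~1 s, so it must not be a rigid sinusoid that
        # stays phase-locked to the 1 s trial pitch)
        band = (noise.alpha_freq_hz - 1.0, noise.alpha_freq_hz + 1.0)
        alpha_sos = sp_signal.butter(2, band, btype="bandpass", fs=sf,
                                     output="sos")
    for ci, ch in enumerate(ALL_CHANNELS):
        if ch == "TP9":
            continue  # online reference
        sd = noise.eog_pink_sd_uv if ch in EOG_CHANNELS else noise.pink_sd_uv
        if sd > 0:
            data[ci] += (sd * _pink_noise(n_samples, rng)).astype(np.float32)
        if ch in alpha_w and alpha_sos is not None:
            raw = sp_signal.sosfilt(alpha_sos, rng.standard_normal(n_samples))
            raw *= noise.alpha_amp_uv / np.sqrt(2) / max(raw.std(), 1e-12)
            data[ci] += (alpha_w[ch] * raw).astype(np.float32)

    # condition ERP templates on the epoch grid [-300, 1000] ms
    ep_t = np.arange(-300, 1001, 1000.0 / sf)
    templates = {}
    topo = p300_topography()
    for c in conditions:
        tmpl = np.zeros((n_ch, ep_t.size), dtype=np.float32)
        neg = n2pc_amp[c] * _gauss(ep_t, n2pc_lat[c], effects.n2pc_sigma_ms)
        pos = p300_amp[c] * _gauss(ep_t, p300_lat[c], effects.p300_sigma_ms)
        for ci, ch in enumerate(ALL_CHANNELS):
            if ch not in SCALP_CHANNELS:
                continue
            w = topo[ch] * pos
            if ch in effects.n2pc_electrodes:
                w = w + neg
            tmpl[ci] = w
        templates[c] = tmpl

    pre = int(0.3 * sf)
    for tr in list(schedule.training_trials) + list(schedule.trials):
        onset = round(tr.onset * sf)
        lo, hi = onset - pre, onset - pre + ep_t.size
        if lo >= 0 and hi <= n_samples:
            data[:, lo:hi] += templates[tr.congruency]

    # blinks at the vertical EOG, propagated front-to-back
    coeffs = blink_propagation_map(noise.blink_base, noise.blink_decay)
    n_blinks = rng.poisson(noise.blink_rate_per_min * schedule.duration_s / 60.0)
    blink_times = np.sort(rng.uniform(1.0, schedule.duration_s - 1.0, n_blinks))
    half = int(4 * noise.blink_sigma_ms / 1000.0 * sf)
    b_t = (np.arange(-half, half + 1)) / sf * 1000.0
    blink_wave = noise.blink_amp_uv * _gauss(b_t, 0.0, noise.blink_sigma_ms)
    fp2 = ALL_CHANNELS.index("FP2")
    for bt in blink_times:
        s = round(bt * sf)
        lo, hi = s - half, s + half + 1
        if lo < 0 or hi > n_samples:
            continue
        data[fp2, lo:hi] += blink_wave.astype(np.float32)
        for ci, ch in enumerate(ALL_CHANNELS):
            if ch in coeffs:
                data[ci, lo:hi] += (coeffs[ch] * blink_wave).astype(np.float32)

    # occasional non-ocular artifacts (for rejection sensitivity checks)
    injections = []
    if noise.artifact_rate > 0:
        scalp_idx = [ALL_CHANNELS.index(ch) for ch in SCALP_CHANNELS]
        for tr in schedule.trials:
            if rng.random() < noise.artifact_rate:
                ci = int(rng.choice(scalp_idx))
                at = round((tr.onset + rng.uniform(0.0, 0.8)) * sf)
                data[ci, at:at + 10] += np.float32(
                    noise.artifact_amp_uv * rng.choice([-1.0, 1.0]))
                injections.append((tr.index, ALL_CHANNELS[ci]))

    events = [(round(onset * sf), code, label)
              for onset, code, label in schedule_to_events(schedule, include_training=True)]
    eeg = ContinuousEEG(ALL_CHANNELS, sf, data, events)

    # ---- fNIRS ------------------------------------------------------------
    fs = fn.FNIRS_SFREQ
    n_f = int(np.ceil(schedule.duration_s * fs)) + int(10 * fs)
    design = fn.build_design(schedule, fs, n_f)
    t_f = np.arange(n_f) / fs
    ch_weights = np.ones(len(fn.FNIRS_CHANNELS))
    beta_scale = np.exp(rng.normal(0.0, effects.fnirs_beta_scale_sd,
                                   len(fn.FNIRS_CHANNELS)))
    block_types = [MAINLY_CONGRUENT, MAINLY_INCONGRUENT]
    reg_cols = {bt: design.names.index(bt) for bt in block_types
                if bt in design.names}
    true_betas = {}
    conc = {}
    for chrom in ("hbo", "hbr"):
        b = np.zeros((len(fn.FNIRS_CHANNELS), len(block_types)))
        sig = np.zeros((len(fn.FNIRS_CHANNELS), n_f))
        for k, bt in enumerate(block_types):
            if bt not in reg_cols:
                continue
            b[:, k] = effects.fnirs_beta[chrom][bt] * ch_weights * beta_scale
            sig += b[:, k:k + 1] * design.matrix[:, reg_cols[bt]][None, :]
        true_betas[chrom] = b
        conc[chrom] = sig

    od = np.zeros((len(fn.FNIRS_CHANNELS), 2, n_f))
    for wi, wl in enumerate(fn.WAVELENGTHS_NM):
        e_hbo, e_hbr = fn.EXTINCTION[wl]
        path = fn.INTEROPTODE_CM * fn.DPF[wl]
        od[:, wi, :] = (e_hbo * conc["hbo"] + e_hbr * conc["hbr"]) / 1000.0 * path

    cardiac_f = noise.fnirs_cardiac_freq_hz * float(rng.uniform(0.95, 1.05))
    spike_spans: dict[str, list[tuple[int, int]]] = {}
    for ci, ch in enumerate(fn.FNIRS_CHANNELS):
        for wi in range(2):
            phase_c = rng.uniform(0, 2 * np.pi)
            phase_m = rng.uniform(0, 2 * np.pi)
            drift = rng.normal(0.0, noise.fnirs_drift_od_per_min) / 60.0
            od[ci, wi] += (noise.fnirs_cardiac_amp_od * np.sin(2 * np.pi * cardiac_f * t_f + phase_c)
                           + noise.fnirs_mayer_amp_od * np.sin(2 * np.pi * noise.fnirs_mayer_freq_hz * t_f + phase_m)
                           + drift * t_f
                           + noise.fnirs_white_sd_od * rng.standard_normal(n_f))
        if noise.fnirs_spike_rate_per_min > 0:
            n_sp = rng.poisson(noise.fnirs_spike_rate_per_min * schedule.duration_s / 60.0)
            for _ in range(n_sp):
                lo = int(rng.integers(1, n_f - 5))
                hi = lo + int(rng.integers(1, 4))
                od[ci, :, lo:hi] += noise.fnirs_spike_amp_od * rng.choice([-1.0, 1.0])
                spike_spans.setdefault(ch, []).append((lo, hi))

    i0 = rng.uniform(1.0, 2.0, size=(len(fn.FNIRS_CHANNELS), 2, 1))
    intensity = i0 * 10.0 ** (-od)
    block_onsets = [(min(tr.onset for tr in schedule.trials if tr.block_index == blk.block_index),
                     blk.block_type) for blk in schedule.blocks]
    optical = fn.OpticalSeries(fn.FNIRS_CHANNELS, fs, intensity,
                               kind="intensity", block_onsets=block_onsets)

    dataset = SubjectDataset(subject, group, schedule, eeg, optical, responses)
    truth = SubjectTruth(subject, group, int(ss.entropy), n2pc_amp, n2pc_lat,
                         p300_amp, p300_lat, rt_mean, acc, coeffs, true_betas,
                         injections, spike_spans)
    return dataset, truth


def iter_cohort(n_patients: int = 28, n_controls: int = 29,
                effects: EffectConfig | dict | None = None,
                noise: NoiseConfig | None = None,
                seed: int = 0, schedule: StimulusSchedule | None = None):
    """Lazily yield (SubjectDataset, SubjectTruth) pairs; patients first.

    ``effects`` may be a single config or a ``{"patient": ..., "control":
    ...}`` dict for group-specific effects.  Each subject gets an
    independent child seed (and, when ``schedule`` is None, an
    independent pseudorandomized schedule), so the cohort is fully
    reproducible from ``seed``.
    """
    if not isinstance(effects, dict):
        effects = {"patient": effects, "control": effects}
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_patients + n_controls)
    labels = [("patient", f"P{k + 1:02d}") for k in range(n_patients)] + \
             [("control", f"C{k + 1:02d}") for k in range(n_controls)]
    for (group, name), child in zip(labels, children):
        yield simulate_subject(schedule, effects[group], noise, group, child, name)


def simulate_cohort(n_patients: int = 28, n_controls: int = 29,
                    effects: EffectConfig | dict | None = None,
                    noise: NoiseConfig | None = None,
                    seed: int = 0, schedule: StimulusSchedule | None = None
                    ) -> list[tuple[SubjectDataset, SubjectTruth]]:
    """Materialized cohort; intended for small n (continuous EEG is large —
    use :func:`iter_cohort` and process subject-by-subject otherwise)."""
    return list(iter_cohort(n_patients, n_controls, effects, noise, seed, schedule))
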