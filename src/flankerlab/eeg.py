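"""Continuous-EEG-to-ERP preprocessing chain.

Order of operations for one subject: zero-phase low-pass + notch
filtering of the continuous recording, segmentation around the stimulus
markers of correctly answered trials (-300..1000 ms), regression-based
ocular correction (Gratton-Coles), threshold-based artifact rejection,
a subject inclusion gate (at least one third of the segments per
condition surviving on at least 15 of the 29 scalp electrodes),
100 ms pre-stimulus baseline, re-referencing to averaged mastoids, and
condition-wise averaging.

The montage is fixed: 29 scalp electrodes, vertical/horizontal EOG at
FP2/F10, online reference at the left mastoid TP9 and an additional
right mastoid TP10.  Time windows use the half-open convention [a, b)
with 0 ms at the stimulus-onset sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .paradigm import TRIAL_CODES

__all__ = [
    "SCALP_CHANNELS",
    "EOG_CHANNELS",
    "MASTOID_CHANNELS",
    "ALL_CHANNELS",
    "ContinuousEEG",
    "EpochSet",
    "ErpSet",
    "RejectionCriteria",
    "filter_continuous",
    "segment",
    "ocular_correct",
    "reject_artifacts",
    "gate_subject",
    "baseline_and_rereference",
    "average_erp",
]

SCALP_CHANNELS = (
    "F5", "F3", "FT7", "FC5", "FC3", "T7", "C5", "C3", "CP3", "CPP5H",
    "P7", "P5", "P3", "F4", "F6", "FC4", "FC6", "FT8", "C4", "C6",
    "T8", "CP4", "CPP6H", "P4", "P6", "P8", "Fz", "Pz", "Cz",
)
EOG_CHANNELS = ("FP2", "F10")
MASTOID_CHANNELS = ("TP9", "TP10")
ALL_CHANNELS = SCALP_CHANNELS + EOG_CHANNELS + MASTOID_CHANNELS

CODE_TO_CONDITION = {code: cond for (cond, _d), code in TRIAL_CODES.items()}


@dataclass
class ContinuousEEG:
    channels: tuple[str, ...]
    sfreq: float
    data: np.ndarray  # (n_channels, n_samples), microvolt
    events: list[tuple[int, int, str]]  # (sample, code, label)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data))
        if self.data.shape[0] != len(self.channels):
            raise ValueError("channel count does not match data rows")

    def channel_index(self, name: str) -> int:
        return self.channels.index(name)


@dataclass
class EpochSet:
    channels: tuple[str, ...]
    sfreq: float
    tmin: float  # seconds, e.g. -0.3
    data: np.ndarray  # (n_epochs, n_channels, n_times), microvolt
    conditions: np.ndarray  # per-epoch condition label
    trial_ids: np.ndarray  # per-epoch schedule trial index
    rejected: np.ndarray = None  # (n_epochs, n_channels) bool
    baselined: bool = False
    rereferenced: bool = False
    ocular_corrected: bool = False

    def __post_init__(self) -> None:
        if self.rejected is None:
            self.rejected = np.zeros(self.data.shape[:2], dtype=bool)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def times_ms(self) -> np.ndarray:
        n = self.data.shape[2]
        return (self.tmin + np.arange(n) / self.sfreq) * 1000.0

    def window_slice(self, start_ms: float, end_ms: float) -> slice:
        """Sample slice for the half-open window [start_ms, end_ms)."""
        i0 = round((start_ms / 1000.0 - self.tmin) * self.sfreq)
        i1 = round((end_ms / 1000.0 - self.tmin) * self.sfreq)
        if i0 < 0 or i1 > self.data.shape[2] or i1 <= i0:
            raise ValueError(f"window [{start_ms}, {end_ms}) ms outside the epoch")
        return slice(i0, i1)

    def channel_index(self, name: str) -> int:
        return self.channels.index(name)


@dataclass
class ErpSet:
    """Per-condition averaged waveforms with contributing trial counts."""

    channels: tuple[str, ...]
    sfreq: float
    tmin: float
    data: dict[str, np.ndarray]  # condition -> (n_channels, n_times)
    counts: dict[str, np.ndarray]  # condition -> (n_channels,) trials per channel

    @property
    def times_ms(self) -> np.ndarray:
        n = next(iter(self.data.values())).shape[1]
        return (self.tmin + np.arange(n) / self.sfreq) * 1000.0

    def window_slice(self, start_ms: float, end_ms: float) -> slice:
        n = next(iter(self.data.values())).shape[1]
        i0 = round((start_ms / 1000.0 - self.tmin) * self.sfreq)
        i1 = round((end_ms / 1000.0 - self.tmin) * self.sfreq)
        if i0 < 0 or i1 > n or i1 <= i0:
            raise ValueError(f"window [{start_ms}, {end_ms}) ms outside the epoch")
        return slice(i0, i1)

    def channel_index(self, name: str) -> int:
        return self.channels.index(name)


def filter_continuous(eeg: ContinuousEEG, lowpass_hz: float = 50.0,
                      notch_hz: float = 50.0,
                      notch_halfwidth_hz: float = 2.0) -> ContinuousEEG:
    """Zero-phase low-pass Butterworth plus mains notch.

    The low-pass is a 2nd-order Butterworth (12 dB/oct single-pass)
    applied forward-backward; the notch is a band-stop of twice that
    slope with ``notch_halfwidth_hz`` half-width around ``notch_hz``.
    """
    nyq = eeg.sfreq / 2.0
    if lowpass_hz >= nyq:
        raise ValueError("low-pass cutoff must be below Nyquist")
    sos_lp = signal.butter(2, lowpass_hz, btype="lowpass", fs=eeg.sfreq, output="sos")
    out = signal.sosfiltfilt(sos_lp, eeg.data, axis=-1)
    band = (notch_hz - notch_halfwidth_hz, notch_hz + notch_halfwidth_hz)
    if band[1] < nyq:
        sos_notch = signal.butter(2, band, btype="bandstop", fs=eeg.sfreq, output="sos")
        out = signal.sosfiltfilt(sos_notch, out, axis=-1)
    return replace(eeg, data=out.astype(eeg.data.dtype, copy=False))


def segment(eeg: ContinuousEEG, correct_trial_ids, tmin: float = -0.3,
            tmax: float = 1.0) -> tuple[EpochSet, list[int]]:
    """Cut one epoch per correctly answered trial.

    Trial markers are the stimulus-code events of the recording, in
    temporal order; the n-th such marker belongs to trial index n of the
    analyzed schedule.  Epochs that would run over a recording edge are
    dropped; their trial indices are returned for the processing log.
    """
    correct = set(int(i) for i in correct_trial_ids)
    n_pre = round(-tmin * eeg.sfreq)
    n_post = round(tmax * eeg.sfreq)
    n_times = n_pre + n_post + 1
    n_samples = eeg.data.shape[1]

    trial_markers = [(s, c) for s, c, _ in eeg.events if c in CODE_TO_CONDITION]
    epochs, conds, ids, dropped = [], [], [], []
    for trial_idx, (sample, code) in enumerate(trial_markers):
        if trial_idx not in correct:
            continue
        lo, hi = sample - n_pre, sample + n_post + 1
        if lo < 0 or hi > n_samples:
            dropped.append(trial_idx)
            continue
        epochs.append(eeg.data[:, lo:hi])
        conds.append(CODE_TO_CONDITION[code])
        ids.append(trial_idx)
    data = (np.stack(epochs) if epochs
            else np.empty((0, len(eeg.channels), n_times), dtype=eeg.data.dtype))
    es = EpochSet(eeg.channels, eeg.sfreq, tmin, data,
                  np.array(conds, dtype=object), np.array(ids, dtype=int))
    return es, dropped


def ocular_correct(epochs: EpochSet, veog_channel: str = "FP2",
                   heog_channel: str | None = None
                   ) -> tuple[EpochSet, dict[str, np.ndarray]]:
    """Gratton-Coles regression correction of ocular artifacts.

    The condition-average ERP is subtracted from every epoch (and from
    the EOG) before estimating per-channel propagation coefficients by
    least squares over the pooled residuals; coefficient x raw EOG is
    then subtracted from the raw epochs, which leaves the stimulus-locked
    ERP in place.  With a horizontal EOG channel the two regressors are
    fit jointly.  A zero-variance EOG yields zero coefficients and
    unchanged data.
    """
    regs = [veog_channel] + ([heog_channel] if heog_channel else [])
    reg_idx = [epochs.channel_index(ch) for ch in regs]
    if epochs.n_epochs < 2:
        raise ValueError("ocular correction needs at least 2 epochs")

    data = epochs.data.astype(np.float64, copy=False)
    resid = np.empty_like(data)
    for cond in np.unique(epochs.conditions):
        sel = epochs.conditions == cond
        resid[sel] = data[sel] - data[sel].mean(axis=0, keepdims=True)

    n_ep, n_ch, n_t = data.shape
    x = resid[:, reg_idx, :].transpose(1, 0, 2).reshape(len(regs), -1)  # (r, N)
    y = resid.transpose(1, 0, 2).reshape(n_ch, -1)  # (ch, N)
    xtx = x @ x.T
    if np.linalg.cond(xtx) > 1e12 or np.allclose(np.diag(xtx), 0):
        coeffs = np.zeros((n_ch, len(regs)))
    else:
        coeffs = np.linalg.solve(xtx, x @ y.T).T  # (ch, r)
    coeffs[reg_idx, :] = 0.0  # never correct a regressor with itself

    raw_eog = epochs.data[:, reg_idx, :]  # (ep, r, t)
    corrected = epochs.data - np.einsum("cr,ert->ect", coeffs, raw_eog)
    out = replace(epochs, data=corrected.astype(epochs.data.dtype, copy=False),
                  rejected=epochs.rejected.copy(), ocular_corrected=True)
    return out, {ch: coeffs[:, k] for k, ch in enumerate(regs)}


@dataclass(frozen=True)
class RejectionCriteria:
    """Automated stand-in for manual segment-wise visual rejection."""

    max_abs_uv: float = 100.0
    max_peak_to_peak_uv: float = 150.0
    max_gradient_uv_per_ms: float = 50.0


def reject_artifacts(epochs: EpochSet,
                     criteria: RejectionCriteria = RejectionCriteria()
                     ) -> tuple[EpochSet, dict]:
    """Flag epoch x channel cells exceeding amplitude, peak-to-peak or
    sample-to-sample gradient thresholds.  Scalp channels only; an
    existing rejection is never undone (the mask is monotone)."""
    scalp = [epochs.channel_index(ch) for ch in SCALP_CHANNELS
             if ch in epochs.channels]
    d = epochs.data[:, scalp, :]
    ms_per_sample = 1000.0 / epochs.sfreq
    bad_amp = np.abs(d).max(axis=2) > criteria.max_abs_uv
    bad_ptp = (d.max(axis=2) - d.min(axis=2)) > criteria.max_peak_to_peak_uv
    grad = np.abs(np.diff(d, axis=2)).max(axis=2) / ms_per_sample
    bad_grad = grad > criteria.max_gradient_uv_per_ms

    mask = epochs.rejected.copy()
    mask[:, scalp] |= bad_amp | bad_ptp | bad_grad
    report = {
        "n_rejected_cells": int(mask[:, scalp].sum()),
        "by_rule": {
            "amplitude": int(bad_amp.sum()),
            "peak_to_peak": int(bad_ptp.sum()),
            "gradient": int(bad_grad.sum()),
        },
    }
    return replace(epochs, data=epochs.data, rejected=mask), report


def gate_subject(epochs: EpochSet, total_per_condition: int = 120,
                 min_electrodes: int = 15) -> tuple[bool, dict]:
    """Subject inclusion gate.

    The cutoff is one third of the presented segments per condition,
    rounded up (120 -> 40).  The subject is included iff for *every*
    condition at least ``min_electrodes`` of the scalp electrodes retain
    at least that many surviving segments.
    """
    cutoff = math.ceil(total_per_condition / 3)
    scalp = [epochs.channel_index(ch) for ch in SCALP_CHANNELS
             if ch in epochs.channels]
    detail: dict[str, dict] = {}
    include = True
    for cond in ("congruent", "incongruent"):
        sel = epochs.conditions == cond
        surviving = (~epochs.rejected[sel][:, scalp]).sum(axis=0)  # per electrode
        n_ok = int((surviving >= cutoff).sum())
        detail[cond] = {
            "surviving_per_electrode": surviving,
            "electrodes_above_cutoff": n_ok,
        }
        if n_ok < min_electrodes:
            include = False
    return include, {"cutoff": cutoff, "min_electrodes": min_electrodes,
                     "conditions": detail}


def baseline_and_rereference(epochs: EpochSet,
                             baseline_ms: tuple[float, float] = (-100.0, 0.0)
                             ) -> EpochSet:
    """Subtract the pre-stimulus baseline mean, then re-reference every
    scalp and EOG channel to the average of the two mastoids."""
    for ch in MASTOID_CHANNELS:
        if ch not in epochs.channels:
            raise ValueError(f"mastoid channel {ch} missing")
    sl = epochs.window_slice(*baseline_ms)
    data = epochs.data.astype(np.float64, copy=True)
    data -= data[:, :, sl].mean(axis=2, keepdims=True)
    m_idx = [epochs.channel_index(ch) for ch in MASTOID_CHANNELS]
    mast = data[:, m_idx, :].mean(axis=1, keepdims=True)
    non_mast = [i for i in range(len(epochs.channels)) if i not in m_idx]
    data[:, non_mast, :] -= mast
    return replace(epochs, data=data.astype(epochs.data.dtype, copy=False),
                   rejected=epochs.rejected.copy(), baselined=True,
                   rereferenced=True)


def average_erp(epochs: EpochSet, merge_directions: bool = True) -> ErpSet:
    """Channel-wise mean over non-rejected epochs per condition.

    A channel with zero surviving epochs in a condition gets a NaN
    waveform (flagged absent) and count 0.
    """
    data, counts = {}, {}
    for cond in np.unique(epochs.conditions):
        sel = epochs.conditions == cond
        d = epochs.data[sel].astype(np.float64)
        keep = ~epochs.rejected[sel]  # (ep, ch)
        w = keep[:, :, None].astype(float)
        n = keep.sum(axis=0)  # per channel
        with np.errstate(invalid="ignore"):
            mean = (d * w).sum(axis=0) / n[:, None]
        mean[n == 0] = np.nan
        data[str(cond)] = mean
        counts[str(cond)] = n
    return ErpSet(epochs.channels, epochs.sfreq, epochs.tmin, data, counts)
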