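"""Dual-wavelength fNIRS processing: optical densities, modified
Beer-Lambert conversion, artifact interpolation, low-pass filtering,
hemodynamic design matrix and per-channel GLM.

The montage has 16 source-detector channels (8 per hemisphere) over
bilateral fronto-temporo-parietal cortex, 3.5 cm interoptode distance,
sampled at 7.81 Hz with continuous-wave light at 760 and 850 nm.
Concentration changes are expressed in umol/l; extinction coefficients
(cm^-1 per mmol/l, compiled molar absorptivities of oxy- and
deoxyhemoglobin) and differential pathlength factors are configurable
constants recorded in the output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats as sps

from .paradigm import MAINLY_CONGRUENT, MAINLY_INCONGRUENT, StimulusSchedule
from .stats import rm_anova

__all__ = [
    "FNIRS_CHANNELS",
    "FNIRS_REGIONS",
    "WAVELENGTHS_NM",
    "OpticalSeries",
    "HemoglobinSeries",
    "DesignMatrix",
    "GlmFit",
    "canonical_hrf",
    "mbll_convert",
    "interpolate_artifacts",
    "lowpass_04",
    "build_design",
    "glm_fit",
    "fnirs_anova",
]

WAVELENGTHS_NM = (760, 850)
FNIRS_SFREQ = 7.81
INTEROPTODE_CM = 3.5
BLOCK_DURATION_S = 24.0

#: source_detector channel labels and their cortical region, left/right.
FNIRS_REGIONS = {
    "1_1": ("prefrontal inferior", "left"), "1_5": ("prefrontal inferior", "right"),
    "2_1": ("prefrontal superior", "left"), "2_5": ("prefrontal superior", "right"),
    "3_2": ("frontal", "left"), "6_6": ("frontal", "right"),
    "3_3": ("fronto-temporal", "left"), "6_7": ("fronto-temporal", "right"),
    "4_3": ("temporal inferior", "left"), "7_7": ("temporal inferior", "right"),
    "5_3": ("temporal superior", "left"), "8_7": ("temporal superior", "right"),
    "4_4": ("temporo-parietal inferior", "left"), "7_8": ("temporo-parietal inferior", "right"),
    "5_4": ("temporo-parietal superior", "left"), "8_8": ("temporo-parietal superior", "right"),
}
FNIRS_CHANNELS = tuple(FNIRS_REGIONS)

#: molar extinction coefficients, cm^-1 per (mmol/l): {wavelength: (HbO, HbR)}
EXTINCTION = {760: (0.5860, 1.5485), 850: (1.0580, 0.6913)}
#: differential pathlength factors per wavelength (adult head)
DPF = {760: 7.25, 850: 6.38}


@dataclass
class OpticalSeries:
    channels: tuple[str, ...]
    sfreq: float
    data: np.ndarray  # (n_channels, n_wavelengths, n_samples)
    kind: str = "intensity"  # "intensity" | "od"
    wavelengths: tuple[int, ...] = WAVELENGTHS_NM
    distance_cm: float = INTEROPTODE_CM
    block_onsets: list[tuple[float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape[:2] != (len(self.channels), len(self.wavelengths)):
            raise ValueError("data must be (channels, wavelengths, samples)")

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


@dataclass
class HemoglobinSeries:
    channels: tuple[str, ...]
    sfreq: float
    hbo: np.ndarray  # (n_channels, n_samples), umol/l
    hbr: np.ndarray
    unit: str = "umol/l"
    meta: dict = field(default_factory=dict)


@dataclass
class DesignMatrix:
    names: list[str]
    matrix: np.ndarray  # (n_samples, n_regressors); includes intercept

    @property
    def condition_names(self) -> list[str]:
        return [n for n in self.names if n != "intercept"]


@dataclass
class GlmFit:
    channels: tuple[str, ...]
    design: DesignMatrix
    betas: dict[str, np.ndarray]  # chromophore -> (n_channels, n_regressors)
    residual_var: dict[str, np.ndarray]  # chromophore -> (n_channels,)

    def condition_betas(self, chromophore: str) -> pd.DataFrame:
        cols = self.design.condition_names
        idx = [self.design.names.index(c) for c in cols]
        return pd.DataFrame(self.betas[chromophore][:, idx],
                            index=list(self.channels), columns=cols)


_HRF_SCALE: float | None = None


def _double_gamma(t: np.ndarray) -> np.ndarray:
    h = sps.gamma.pdf(t, a=6.0) - sps.gamma.pdf(t, a=16.0) / 6.0
    return h


def canonical_hrf(t) -> np.ndarray:
    """Canonical double-gamma HRF, time-scaled so its mode is exactly at
    5 s, normalized to unit peak; undershoot ratio 1/6."""
    global _HRF_SCALE
    if _HRF_SCALE is None:
        fine = np.arange(0, 30, 0.001)
        _HRF_SCALE = fine[int(np.argmax(_double_gamma(fine)))] / 5.0
    t = np.asarray(t, dtype=float)
    h = _double_gamma(t * _HRF_SCALE)
    h = h / _double_gamma(np.array([5.0 * _HRF_SCALE]))[0]
    return np.where(t >= 0, h, 0.0)


def mbll_convert(optical: OpticalSeries, dpf: dict[int, float] | None = None,
                 extinction: dict[int, tuple[float, float]] | None = None,
                 baseline: str = "mean") -> HemoglobinSeries:
    """Modified Beer-Lambert conversion of dual-wavelength series.

    Intensity input is turned into optical-density change via
    ``dOD = -log10(I / I0)`` with I0 the channel mean (or first-minute
    mean with ``baseline='first60s'``); OD input is used as is.  The
    2x2 linear system ``dOD(lambda) = [eps_HbO dHbO + eps_HbR dHbR]
    * d * DPF(lambda)`` is solved per sample; concentrations are
    returned in umol/l.
    """
    dpf = dpf or DPF
    extinction = extinction or EXTINCTION
    wl = optical.wavelengths
    if optical.kind == "intensity":
        if np.any(optical.data <= 0):
            raise ValueError("nonpositive intensity; interpolate artifacts first")
        if baseline == "mean":
            i0 = optical.data.mean(axis=2, keepdims=True)
        elif baseline == "first60s":
            n0 = max(1, int(60 * optical.sfreq))
            i0 = optical.data[:, :, :n0].mean(axis=2, keepdims=True)
        else:
            raise ValueError(f"unknown baseline {baseline!r}")
        od = -np.log10(optical.data / i0)
    elif optical.kind == "od":
        od = optical.data
    else:
        raise ValueError(f"unknown series kind {optical.kind!r}")

    e = np.array([[extinction[w][0], extinction[w][1]] for w in wl])  # per mmol/l
    path = np.array([optical.distance_cm * dpf[w] for w in wl])
    a = e * path[:, None]  # (wl, chromophore)
    inv = np.linalg.inv(a)
    conc_mmol = np.einsum("cw,kws->kcs", inv, od)  # (ch, [hbo,hbr], samples)
    conc = conc_mmol * 1000.0  # mmol/l -> umol/l
    return HemoglobinSeries(optical.channels, optical.sfreq,
                            conc[:, 0, :], conc[:, 1, :],
                            meta={"dpf": dict(dpf),
                                  "extinction": {w: tuple(extinction[w]) for w in wl},
                                  "distance_cm": optical.distance_cm,
                                  "baseline": baseline})


def detect_abrupt_changes(x: np.ndarray, k: float = 6.0,
                          margin: int = 2) -> list[tuple[int, int]]:
    """Mark half-open spans around samples whose first difference exceeds
    ``k`` robust (MAD-based) standard deviations."""
    d = np.diff(x)
    mad = np.median(np.abs(d - np.median(d)))
    scale = 1.4826 * mad
    if scale == 0:
        return []
    bad = np.nonzero(np.abs(d - np.median(d)) > k * scale)[0]
    spans: list[list[int]] = []
    for i in bad:
        lo, hi = max(0, i - margin + 1), min(len(x), i + margin + 1)
        if spans and lo <= spans[-1][1]:
            spans[-1][1] = max(spans[-1][1], hi)
        else:
            spans.append([lo, hi])
    return [tuple(s) for s in spans]


def interpolate_artifacts(x: np.ndarray, spans: list[tuple[int, int]] | None = None,
                          k: float = 6.0) -> np.ndarray:
    """Replace artifact spans by linear interpolation between span edges.

    ``spans`` are half-open [start, stop) sample intervals; when None
    they are auto-detected from abrupt first differences.  A span
    touching a record edge holds the nearest valid value.
    """
    x = np.asarray(x, dtype=float)
    out = x.copy()
    if spans is None:
        spans = detect_abrupt_changes(x, k=k)
    n = x.size
    for lo, hi in spans:
        lo, hi = max(0, int(lo)), min(n, int(hi))
        if hi <= lo:
            continue
        left = lo - 1
        right = hi
        if left < 0 and right >= n:
            continue
        if left < 0:
            out[lo:hi] = out[right]
        elif right >= n:
            out[lo:hi] = out[left]
        else:
            out[lo:hi] = np.linspace(out[left], out[right], hi - lo + 2)[1:-1]
    return out


def interpolate_artifacts_rows(data: np.ndarray, k: float = 6.0) -> np.ndarray:
    """Row-wise :func:`interpolate_artifacts` for (channels, samples) arrays."""
    return np.stack([interpolate_artifacts(row, k=k) for row in np.atleast_2d(data)])


def lowpass_04(data: np.ndarray, sfreq: float = FNIRS_SFREQ,
               cutoff_hz: float = 0.4) -> np.ndarray:
    """3rd-order zero-phase Butterworth low-pass attenuating cardiac
    pulsation (~1.1 Hz) and other high-frequency physiology."""
    if sfreq <= 2 * cutoff_hz:
        raise ValueError("sampling rate too low for the requested cutoff")
    sos = signal.butter(3, cutoff_hz, btype="lowpass", fs=sfreq, output="sos")
    return signal.sosfiltfilt(sos, data, axis=-1)


def build_design(schedule: StimulusSchedule, sfreq: float = FNIRS_SFREQ,
                 n_samples: int | None = None,
                 block_duration_s: float = BLOCK_DURATION_S,
                 combined: bool = False) -> DesignMatrix:
    """Boxcar-times-HRF design matrix of the mini-block stimulation.

    One 24 s boxcar per mini-block labeled by its type, convolved with
    the canonical HRF; one regressor per block type plus an intercept
    (or a single combined task regressor with ``combined=True``).
    """
    if n_samples is None:
        n_samples = int(np.ceil(schedule.duration_s * sfreq))
    t = np.arange(n_samples) / sfreq
    onsets: dict[str, list[float]] = {MAINLY_CONGRUENT: [], MAINLY_INCONGRUENT: []}
    first_of_block: dict[int, float] = {}
    for tr in schedule.trials:
        first_of_block.setdefault(tr.block_index, tr.onset)
    for blk in schedule.blocks:
        onsets[blk.block_type].append(first_of_block[blk.block_index])

    hrf_len = int(np.ceil(30 * sfreq))
    hrf = canonical_hrf(np.arange(hrf_len) / sfreq)

    def regressor(onset_list):
        box = np.zeros(n_samples)
        for onset in onset_list:
            box[(t >= onset) & (t < onset + block_duration_s)] = 1.0
        return np.convolve(box, hrf)[:n_samples] / sfreq

    cols = [np.ones(n_samples)]
    names = ["intercept"]
    if combined:
        cols.append(regressor(onsets[MAINLY_CONGRUENT] + onsets[MAINLY_INCONGRUENT]))
        names.append("task")
    else:
        for btype in (MAINLY_CONGRUENT, MAINLY_INCONGRUENT):
            if onsets[btype]:
                cols.append(regressor(onsets[btype]))
                names.append(btype)
    return DesignMatrix(names, np.column_stack(cols))


def glm_fit(hemo: HemoglobinSeries, design: DesignMatrix) -> GlmFit:
    """Ordinary least squares per channel and chromophore."""
    x = design.matrix
    n, p = x.shape
    rank = np.linalg.matrix_rank(x)
    if rank < p:
        raise ValueError(f"design matrix rank-deficient (rank {rank} < {p})")
    betas, resvar = {}, {}
    for name, y in (("hbo", hemo.hbo), ("hbr", hemo.hbr)):
        if y.shape[1] != n:
            raise ValueError("series length does not match design")
        b, *_ = np.linalg.lstsq(x, y.T, rcond=None)
        resid = y.T - x @ b
        dof = max(n - p, 1)
        betas[name] = b.T
        resvar[name] = (resid**2).sum(axis=0) / dof
    return GlmFit(hemo.channels, design, betas, resvar)


def fnirs_anova(betas: np.ndarray, groups=None,
                channels: tuple[str, ...] = FNIRS_CHANNELS):
    """Congruency x channel (x group) mixed ANOVA on condition betas.

    ``betas`` is (subjects, 2 conditions, n_channels) for one
    chromophore; subjects with NaN cells are dropped and reported.
    """
    betas = np.asarray(betas, dtype=float)
    keep = ~np.isnan(betas).any(axis=(1, 2))
    dropped = np.nonzero(~keep)[0].tolist()
    vals = betas[keep]
    glab = None if groups is None else np.asarray(groups)[keep]
    if glab is not None and len(np.unique(glab)) < 2:
        glab = None
    return rm_anova(vals, ("congruency", "channel"), glab), dropped
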