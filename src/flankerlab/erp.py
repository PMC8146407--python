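"""Data-driven ERP window discovery and window-based statistics.

The sliding 20-ms analysis runs paired t-tests (congruent vs incongruent
subject-wise window means) per electrode and per group over the 35
windows tiling [0, 700) ms.  Clusters are maximal runs of at least two
consecutive significant windows in which at least two electrodes are
significant throughout; the union of the clusters found in the two
groups defines the analysis windows.  Mean-amplitude and peak measures
within those windows feed congruency x electrode x group mixed ANOVAs
with Greenhouse-Geisser correction and BH-FDR-adjusted per-electrode
post-hoc paired t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .eeg import SCALP_CHANNELS, ErpSet
from .stats import fdr_adjust, paired_t, rm_anova

__all__ = [
    "WindowCluster",
    "PeakMeasure",
    "window_grid",
    "sliding_window_ttests",
    "find_clusters",
    "union_windows",
    "mean_amplitude",
    "peak_measures",
    "measures_table",
    "erp_anova",
]

CONGRUENT = "congruent"
INCONGRUENT = "incongruent"

#: Default analysis windows (ms) when no data-driven discovery is run.
DEFAULT_WINDOWS = ((260.0, 300.0), (300.0, 400.0), (420.0, 660.0))


@dataclass(frozen=True)
class WindowCluster:
    start_ms: float
    end_ms: float
    electrodes: tuple[str, ...]
    sign: int  # sign of (incongruent - congruent) mean difference
    group: str


@dataclass(frozen=True)
class PeakMeasure:
    electrode: str
    condition: str
    polarity: str  # "negative" | "positive"
    amplitude: float  # microvolt
    latency_ms: float
    window: tuple[float, float]


def window_grid(start_ms: float = 0.0, end_ms: float = 700.0,
                step_ms: float = 20.0) -> list[tuple[float, float]]:
    """Consecutive half-open windows tiling [start, end) ms."""
    n = int(round((end_ms - start_ms) / step_ms))
    return [(start_ms + k * step_ms, start_ms + (k + 1) * step_ms)
            for k in range(n)]


def sliding_window_ttests(erps: list[ErpSet], groups,
                          windows: list[tuple[float, float]] | None = None,
                          electrodes: tuple[str, ...] = SCALP_CHANNELS
                          ) -> pd.DataFrame:
    """Per-group, per-electrode, per-window paired t-tests.

    Returns a tidy frame with columns group, electrode, win_start,
    win_end, t, df, p, mean_diff (incongruent - congruent).
    """
    windows = windows or window_grid()
    groups = np.asarray(groups)
    if len(groups) != len(erps):
        raise ValueError("one group label per subject required")
    rows = []
    for glabel in np.unique(groups):
        sel = [e for e, g in zip(erps, groups) if g == glabel]
        if len(sel) < 2:
            raise ValueError(f"group {glabel!r} has fewer than 2 subjects")
        # subject x electrode x window means, per condition
        per_cond = {}
        for cond in (CONGRUENT, INCONGRUENT):
            per_cond[cond] = np.stack([
                np.array([[erp.data[cond][erp.channel_index(el)][erp.window_slice(a, b)].mean()
                           for (a, b) in windows]
                          for el in electrodes])
                for erp in sel
            ])  # (subjects, electrodes, windows)
        for ei, el in enumerate(electrodes):
            for wi, (a, b) in enumerate(windows):
                x = per_cond[CONGRUENT][:, ei, wi]
                y = per_cond[INCONGRUENT][:, ei, wi]
                res = paired_t(y, x, effect=f"{el} [{a:.0f},{b:.0f})")
                rows.append({"group": glabel, "electrode": el,
                             "win_start": a, "win_end": b,
                             "t": res.statistic, "df": res.df[1], "p": res.p,
                             "mean_diff": float(np.mean(y - x))})
    return pd.DataFrame(rows)


def find_clusters(window_results: pd.DataFrame, alpha: float = 0.05,
                  min_windows: int = 2, min_electrodes: int = 2
                  ) -> list[WindowCluster]:
    """Maximal runs of >= ``min_windows`` consecutive significant windows
    with >= ``min_electrodes`` electrodes significant throughout the run.

    Output is invariant to electrode ordering; clusters are reported per
    group, sorted by onset.
    """
    clusters: list[WindowCluster] = []
    for glabel, gdf in window_results.groupby("group"):
        wins = sorted(gdf[["win_start", "win_end"]].drop_duplicates()
                      .itertuples(index=False, name=None))
        electrodes = sorted(gdf["electrode"].unique())
        sig = np.zeros((len(electrodes), len(wins)), dtype=bool)
        diff = np.zeros_like(sig, dtype=float)
        for _, row in gdf.iterrows():
            ei = electrodes.index(row["electrode"])
            wi = wins.index((row["win_start"], row["win_end"]))
            sig[ei, wi] = row["p"] <= alpha
            diff[ei, wi] = row["mean_diff"]
        n_w = len(wins)
        candidates = []
        for i in range(n_w):
            for j in range(i + min_windows - 1, n_w):
                common = sig[:, i:j + 1].all(axis=1)
                if common.sum() >= min_electrodes:
                    candidates.append((i, j, frozenset(np.nonzero(common)[0])))
        # keep only maximal intervals (not contained in a kept one)
        kept = []
        for i, j, els in sorted(candidates, key=lambda c: (c[0] - c[1], c[0])):
            if not any(ki <= i and j <= kj for ki, kj, _ in kept):
                kept.append((i, j, els))
        for i, j, els in sorted(kept):
            el_names = tuple(electrodes[e] for e in sorted(els))
            idx = sorted(els)
            mean_diff = diff[idx, i:j + 1].mean()
            clusters.append(WindowCluster(wins[i][0], wins[j][1], el_names,
                                          int(np.sign(mean_diff)), str(glabel)))
    return clusters


def union_windows(clusters: list[WindowCluster]) -> list[tuple[float, float]]:
    """Merge overlapping cluster spans across groups into analysis windows."""
    spans = sorted((c.start_ms, c.end_ms) for c in clusters)
    merged: list[list[float]] = []
    for a, b in spans:
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [tuple(m) for m in merged]


def mean_amplitude(erp: ErpSet, window: tuple[float, float],
                   electrodes: tuple[str, ...] = SCALP_CHANNELS
                   ) -> dict[str, dict[str, float]]:
    """Per-electrode, per-condition arithmetic mean over the half-open
    window; {condition: {electrode: microvolt}}."""
    sl = erp.window_slice(*window)
    out: dict[str, dict[str, float]] = {}
    for cond, wave in erp.data.items():
        out[cond] = {el: float(wave[erp.channel_index(el), sl].mean())
                     for el in electrodes}
    return out


def peak_measures(erp: ErpSet, polarity: str, window: tuple[float, float],
                  electrodes: tuple[str, ...] = SCALP_CHANNELS
                  ) -> list[PeakMeasure]:
    """Extremum amplitude and latency per electrode and condition.

    Negative polarity takes the minimum, positive the maximum; ties are
    broken by the earliest sample.
    """
    if polarity not in ("negative", "positive"):
        raise ValueError("polarity must be 'negative' or 'positive'")
    sl = erp.window_slice(*window)
    times = erp.times_ms[sl]
    out = []
    for cond, wave in erp.data.items():
        for el in electrodes:
            seg = wave[erp.channel_index(el), sl]
            k = int(np.argmin(seg) if polarity == "negative" else np.argmax(seg))
            out.append(PeakMeasure(el, cond, polarity, float(seg[k]),
                                   float(times[k]), tuple(window)))
    return out


def measures_table(erps: list[ErpSet], window: tuple[float, float],
                   kind: str = "mean", polarity: str = "positive",
                   value: str = "amplitude",
                   electrodes: tuple[str, ...] = SCALP_CHANNELS) -> np.ndarray:
    """Subject x condition x electrode array of window measures.

    ``kind`` selects mean amplitude or a peak measure (amplitude or
    latency via ``value``).
    """
    rows = []
    for erp in erps:
        if kind == "mean":
            ma = mean_amplitude(erp, window, electrodes)
            rows.append([[ma[c][el] for el in electrodes]
                         for c in (CONGRUENT, INCONGRUENT)])
        else:
            pm = peak_measures(erp, polarity, window, electrodes)
            lut = {(p.condition, p.electrode): p for p in pm}
            attr = "amplitude" if value == "amplitude" else "latency_ms"
            rows.append([[getattr(lut[(c, el)], attr) for el in electrodes]
                         for c in (CONGRUENT, INCONGRUENT)])
    return np.asarray(rows)


def erp_anova(values: np.ndarray, groups=None,
              electrodes: tuple[str, ...] = SCALP_CHANNELS,
              posthoc_alpha: float = 0.05):
    """Congruency x electrode (x group) mixed ANOVA on window measures.

    ``values`` is (subjects, 2 conditions, n_electrodes); subjects with
    any NaN cell are dropped and reported.  Returns ``(results, posthoc,
    dropped)`` where ``posthoc`` is a per-electrode paired-t table with
    BH-FDR adjusted p-values, computed whenever the congruency main
    effect or the congruency x electrode interaction is significant.
    """
    values = np.asarray(values, dtype=float)
    keep = ~np.isnan(values).any(axis=(1, 2))
    dropped = np.nonzero(~keep)[0].tolist()
    vals = values[keep]
    glab = None if groups is None else np.asarray(groups)[keep]
    if glab is not None and len(np.unique(glab)) < 2:
        glab = None
    results = rm_anova(vals, ("congruency", "electrode"), glab)

    by_name = {r.effect: r for r in results}
    trigger = [r for name, r in by_name.items()
               if "congruency" in name and r.p <= posthoc_alpha]
    posthoc = None
    if trigger:
        rows = []
        for ei, el in enumerate(electrodes):
            res = paired_t(vals[:, 1, ei], vals[:, 0, ei], effect=el)
            rows.append({"electrode": el, "df": res.df[1], "t": res.statistic,
                         "p_raw": res.p_raw})
        posthoc = pd.DataFrame(rows)
        posthoc["p_fdr"] = fdr_adjust(posthoc["p_raw"].to_numpy())
    return results, posthoc, dropped
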