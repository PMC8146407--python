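"""Cohort-level parameter recovery on synthetic data.

Runs the complete analysis chain on a freshly simulated cohort and
compares every recovered quantity with the generator's ground truth:
reaction-time compatibility effect, condition accuracies, the
N2pc-window amplitude difference, P300 peak latencies, the sliding-
window localization of the injected negativity, and the fNIRS condition
betas.  Used by the acceptance machinery and the analysis drivers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import erp
from .paradigm import MAINLY_CONGRUENT, MAINLY_INCONGRUENT
from .study import StudyConfig, process_subject
from .synthetic import iter_cohort

__all__ = ["RecoveryReport", "evaluate_recovery", "null_calibration"]

_CONDS = ("congruent", "incongruent")


def null_calibration(seed: int = 0, n_reps_behavior: int = 500,
                     n_reps_erp: int = 200, n_reps_fnirs: int = 200,
                     n_per_group: int = 8, alpha: float = 0.05) -> dict:
    """Rejection rates of the congruency main effect under the null.

    Simulates measure-level cohorts with *no* injected congruency effect
    — behavioral condition means with subject-level shifts and sampling
    error, ERP window measures over 29 electrodes, fNIRS betas over 16
    channels — and counts how often the mixed ANOVA rejects at ``alpha``.
    Under a correct F calibration each rate stays near ``alpha``.
    """
    from .stats import rm_anova

    rng = np.random.default_rng(seed)
    groups = ["patient"] * n_per_group + ["control"] * n_per_group
    n = 2 * n_per_group

    def _rate(n_reps, draw):
        hits = 0
        for _ in range(n_reps):
            res = rm_anova(draw(), ("congruency",) if draw.__name__ == "_beh"
                           else ("congruency", "site"), groups)
            p = next(r.p for r in res if r.effect == "congruency")
            hits += p <= alpha
        return hits / n_reps, n_reps

    def _beh():
        subj = rng.normal(380.0, 20.0, (n, 1))
        return subj + rng.normal(0.0, 6.0, (n, 2))

    def _erp():
        subj = rng.normal(0.0, 1.0, (n, 1, 1))
        site = rng.normal(0.0, 1.0, (1, 1, 29))
        return subj + site + rng.normal(0.0, 0.8, (n, 2, 29))

    def _fnirs():
        subj = rng.normal(0.0, 0.1, (n, 1, 1))
        return subj + rng.normal(0.0, 0.08, (n, 2, 16))

    out = {}
    for name, reps, draw in (("behavior", n_reps_behavior, _beh),
                             ("erp", n_reps_erp, _erp),
                             ("fnirs", n_reps_fnirs, _fnirs)):
        rate, n_reps = _rate(reps, draw)
        out[name] = {"rate": rate, "n_reps": n_reps, "alpha": alpha}
    return out


def _window_mean_of_template(amp: float, mu: float, sigma: float,
                             window: tuple[float, float]) -> float:
    """Expected half-open-window mean of a Gaussian template sampled at
    1 ms (the measurement-space image of an injected amplitude)."""
    t = np.arange(window[0], window[1])
    return float(amp * np.exp(-0.5 * ((t - mu) / sigma) ** 2).mean())


@dataclass
class RecoveryReport:
    n_subjects: int
    n_included: int
    rt_mean_ms: dict
    rt_effect_ms: float
    rt_effect_injected_ms: float
    accuracy_pct: dict
    accuracy_injected_pct: dict
    n2pc_delta_uv: float
    n2pc_delta_expected_uv: float
    p300_latency_ms: dict
    p300_latency_injected_ms: dict
    p300_shift_ms: float
    p300_shift_injected_ms: float
    n2pc_latency_ms: dict
    clusters: list
    analysis_windows: list
    n2pc_cluster: object  # WindowCluster or None
    fnirs_hbo_betas: dict
    fnirs_hbo_betas_injected: dict
    fnirs_beta_se: dict
    mean_amp_300_400: dict = field(default_factory=dict)
    mean_amp_420_660: dict = field(default_factory=dict)


def evaluate_recovery(n_patients: int = 20, n_controls: int = 20,
                      seed: int = 1, config: StudyConfig | None = None
                      ) -> RecoveryReport:
    """Simulate a cohort, run the full pipeline, compare with ground truth.

    Every subject gets an independently pseudorandomized full-length
    session; processing is streamed subject by subject.
    """
    config = config or StudyConfig(n_patients=n_patients,
                                   n_controls=n_controls, seed=seed)
    results, truths = [], []
    for ds, truth in iter_cohort(n_patients, n_controls, config.effects,
                                 config.noise, seed):
        results.append(process_subject(ds, config))
        truths.append(truth)

    included = [(r, t) for r, t in zip(results, truths) if r.included]
    inc_res = [r for r, _ in included]
    inc_tru = [t for _, t in included]
    groups = [r.group for r in inc_res]
    erps = [r.erps for r in inc_res]

    # ---- behavior ---------------------------------------------------------
    rt_mean = {c: float(np.mean([r.summary.mean_rt[c] for r in results]))
               for c in _CONDS}
    rt_effect = rt_mean["incongruent"] - rt_mean["congruent"]
    rt_injected = float(np.mean([t.rt_mean_ms["incongruent"]
                                 - t.rt_mean_ms["congruent"] for t in truths]))
    acc = {c: float(np.mean([r.summary.accuracy[c] for r in results]))
           for c in _CONDS}
    acc_injected = {c: float(np.mean([100 * t.accuracy[c] for t in truths]))
                    for c in _CONDS}

    # ---- sliding-window localization --------------------------------------
    window_tests = erp.sliding_window_ttests(erps, groups)
    clusters = erp.find_clusters(window_tests)
    windows = erp.union_windows(clusters)
    targets = set(config.effects.n2pc_electrodes)
    n2pc_cluster = None
    for c in clusters:
        covers = c.start_ms <= 260.0 and c.end_ms >= 300.0
        if covers and c.sign < 0 and len(targets & set(c.electrodes)) >= 2:
            n2pc_cluster = c
            break

    # ---- N2pc amplitude delta in measurement space ------------------------
    deltas, expected = [], []
    for r, t in included:
        ma = erp.mean_amplitude(r.erps, (260.0, 300.0),
                                tuple(config.effects.n2pc_electrodes))
        deltas.append(np.mean([ma["incongruent"][el] - ma["congruent"][el]
                               for el in config.effects.n2pc_electrodes]))
        exp = 0.0
        for cond, sign in (("incongruent", 1.0), ("congruent", -1.0)):
            exp += sign * _window_mean_of_template(
                t.n2pc_amp[cond], t.n2pc_latency_ms[cond],
                config.effects.n2pc_sigma_ms, (260.0, 300.0))
            exp += sign * _window_mean_of_template(
                t.p300_amp[cond], t.p300_latency_ms[cond],
                config.effects.p300_sigma_ms, (260.0, 300.0))
        expected.append(exp)
    n2pc_delta = float(np.mean(deltas))
    n2pc_expected = float(np.mean(expected))

    # ---- peak latencies ----------------------------------------------------
    p300_lat = {c: [] for c in _CONDS}
    n2pc_lat = {c: [] for c in _CONDS}
    # posterior electrode outside the N2pc set: the positivity is strong
    # there and its peak is not skewed by the overlapping negativity
    lat_electrode = next(el for el in ("P3", "CP3", "P5")
                         if el not in config.effects.n2pc_electrodes)
    for r in inc_res:
        pm = {p.condition: p for p in
              erp.peak_measures(r.erps, "positive", (300.0, 660.0),
                                (lat_electrode,))}
        for c in _CONDS:
            p300_lat[c].append(pm[c].latency_ms)
        nm = erp.peak_measures(r.erps, "negative", (260.0, 300.0),
                               tuple(config.effects.n2pc_electrodes))
        for c in _CONDS:
            n2pc_lat[c].append(np.mean([p.latency_ms for p in nm
                                        if p.condition == c]))
    p300_mean = {c: float(np.mean(p300_lat[c])) for c in _CONDS}
    p300_injected = {c: float(np.mean([t.p300_latency_ms[c] for t in inc_tru]))
                     for c in _CONDS}
    shift = float(np.mean(np.array(p300_lat["incongruent"])
                          - np.array(p300_lat["congruent"])))
    shift_injected = float(np.mean([t.p300_latency_ms["incongruent"]
                                    - t.p300_latency_ms["congruent"]
                                    for t in inc_tru]))

    # ---- inverse mean-amplitude pattern (latency-shift signature) ----------
    amp_300_400, amp_420_660 = {}, {}
    for c in _CONDS:
        vals_e = [np.mean(list(erp.mean_amplitude(r.erps, (300.0, 400.0))[c]
                               .values())) for r in inc_res]
        vals_l = [np.mean(list(erp.mean_amplitude(r.erps, (420.0, 660.0))[c]
                               .values())) for r in inc_res]
        amp_300_400[c] = float(np.mean(vals_e))
        amp_420_660[c] = float(np.mean(vals_l))

    # ---- fNIRS betas -------------------------------------------------------
    hbo_est, hbo_truth, hbo_se = {}, {}, {}
    for k, bt in enumerate((MAINLY_CONGRUENT, MAINLY_INCONGRUENT)):
        per_subj = [r.fnirs_betas["hbo"][k].mean() for r in results]
        hbo_est[bt] = float(np.mean(per_subj))
        hbo_truth[bt] = float(np.mean([t.fnirs_betas["hbo"][:, k].mean()
                                       for t in truths]))
        hbo_se[bt] = float(np.std(per_subj, ddof=1) / np.sqrt(len(per_subj)))

    return RecoveryReport(
        n_subjects=len(results), n_included=len(inc_res),
        rt_mean_ms=rt_mean, rt_effect_ms=float(rt_effect),
        rt_effect_injected_ms=rt_injected,
        accuracy_pct=acc, accuracy_injected_pct=acc_injected,
        n2pc_delta_uv=n2pc_delta, n2pc_delta_expected_uv=n2pc_expected,
        p300_latency_ms=p300_mean, p300_latency_injected_ms=p300_injected,
        p300_shift_ms=shift, p300_shift_injected_ms=shift_injected,
        n2pc_latency_ms={c: float(np.mean(n2pc_lat[c])) for c in _CONDS},
        clusters=clusters, analysis_windows=windows,
        n2pc_cluster=n2pc_cluster,
        fnirs_hbo_betas=hbo_est, fnirs_hbo_betas_injected=hbo_truth,
        fnirs_beta_se=hbo_se,
        mean_amp_300_400=amp_300_400, mean_amp_420_660=amp_420_660)
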